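"""Conformer-string analytics on a synthetic two-linkage dihedral series.

Builds a jump process between free-energy basins on two (phi, psi) tori,
encodes every frame into a two-letter conformer string, and reports the
cluster count, transition rate, dwell-filtered conformer set and a
lifetime-filtered event search on a synthetic RMSD-like coordinate.
"""
import numpy as np

from selgamd.conformer_analysis import (
    LinkageDefinition,
    count_clusters,
    count_transitions,
    detect_events,
    dwell_filter,
    encode,
    hamming,
)

rng = np.random.default_rng(3)
quadrants = {
    "A": ((-180.0, 0.0), (-180.0, 0.0)),
    "B": ((-180.0, 0.0), (0.0, 180.0)),
    "C": ((0.0, 180.0), (-180.0, 0.0)),
    "D": ((0.0, 180.0), (0.0, 180.0)),
}
linkages = [
    LinkageDefinition("lk1", ("phi1", "psi1"), quadrants),
    LinkageDefinition("lk2", ("phi2", "psi2"), quadrants),
]

# basin-hopping angles: stay ~20 frames per basin, jitter within the basin
n, dt = 2000, 1.0  # frames, ps
centers = {"A": (-90, -90), "B": (-90, 90), "C": (90, -90), "D": (90, 90)}
series = {}
for lk in linkages:
    basins = rng.choice(list("ABCD"), size=n // 20 + 1)
    seq = np.repeat(basins, 20)[:n]
    phi = np.array([centers[b][0] for b in seq]) + rng.normal(0, 25, n)
    psi = np.array([centers[b][1] for b in seq]) + rng.normal(0, 25, n)
    series[lk.dihedrals[0]] = phi
    series[lk.dihedrals[1]] = psi

cs = encode(series, linkages, times=np.arange(n) * dt)
clusters = count_clusters(cs)
transitions = count_transitions(cs)
dwelt = dwell_filter(cs, tau=10.0, frame_dt=dt)
print(f"unique conformers: {clusters.total} of {4 ** len(linkages)} possible")
print(f"transitions: {transitions.count} "
      f"({transitions.rate_per_ns:.0f} per ns)")
print(f"conformers resident >= 10 ps: {len(dwelt)}")
print(f"Hamming distance first vs last frame: "
      f"{hamming(cs.strings[0], cs.strings[-1])}")

# lifetime-filtered events on a scalar CV (e.g. RMSD to a reference)
rmsd = 0.6 + 0.15 * rng.standard_normal(n)
rmsd[400:520] = 0.15   # one long folded stretch (120 ps)
rmsd[900:905] = 0.15   # a 5 ps blip: filtered out
events = detect_events(rmsd, threshold=0.3, min_lifetime=100.0, frame_dt=dt)
print(f"folding events (<= 0.3 for >= 100 ps): {len(events)} at {events}")
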