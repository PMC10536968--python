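"""Per-group energy decomposition and acceleration-region composition.

The potential of a bead system is split automatically into per-group bonded
terms, nonbonded self terms and inter-group nonbonded pair terms: for *N*
atom groups the catalogue holds exactly ``N + N + N(N-1)/2`` entries (plus
up to *N* dihedral terms when dual boosting is requested, carved out of the
bonded terms).  Users then compose *M* acceleration regions as arbitrary
sets of catalogue entries; each region receives one boost potential.

Groups must partition the beads, and a bonded interaction (bond or torsion)
whose beads span two groups is an error: only nonbonded interactions are
split across groups, which keeps the decomposition exactly conservative.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import math
import numpy as np

from .terms import TermIndex
from .toy_systems import BeadSystem

__all__ = [
    "GroupDefinition",
    "AccelerationRegionSpec",
    "AccelerationRegion",
    "RegionSet",
    "DecompositionError",
    "groups_from_system",
    "build_catalogue",
    "split_energy",
    "split_forces",
    "validate_regions",
    "DecomposedSystem",
]


class DecompositionError(ValueError):
    """Raised for invalid group partitions or region specifications."""


@dataclass(frozen=True)
class GroupDefinition:
    """A named set of bead indices; groups must form a partition."""

    label: str
    atom_indices: frozenset

    def __post_init__(self):
        object.__setattr__(self, "atom_indices", frozenset(self.atom_indices))
        if not self.atom_indices:
            raise DecompositionError(f"group {self.label!r} is empty")


def groups_from_system(system: BeadSystem) -> list:
    """Derive the group partition from the system's per-bead labels."""
    labels = system.group_label
    return [
        GroupDefinition(str(g), frozenset(np.flatnonzero(labels == g).tolist()))
        for g in range(int(labels.max()) + 1)
    ]


def build_catalogue(
    groups: list, dual_boost: bool = False, n_beads: int | None = None
) -> list:
    """Build the energy-term catalogue for a group partition.

    Returns ``N`` bonded, ``N`` self and ``N(N-1)/2`` pair terms in a fixed
    deterministic order (bonded, dihedral if requested, self, pairs by
    (i, j)).
    """
    seen: set = set()
    total = 0
    for g in groups:
        if seen & g.atom_indices:
            raise DecompositionError(f"group {g.label!r} overlaps another group")
        seen |= g.atom_indices
        total += len(g.atom_indices)
    if n_beads is None:
        n_beads = max(seen) + 1
    if seen != set(range(n_beads)):
        missing = sorted(set(range(n_beads)) - seen)
        raise DecompositionError(f"beads not covered by any group: {missing}")

    n = len(groups)
    catalogue = [TermIndex("bonded", i) for i in range(n)]
    if dual_boost:
        catalogue += [TermIndex("dihedral", i) for i in range(n)]
    catalogue += [TermIndex("self", i) for i in range(n)]
    catalogue += [
        TermIndex("pair", i, j) for i in range(n) for j in range(i + 1, n)
    ]
    return catalogue


# --------------------------------------------------------------------------
# splitting machinery
# --------------------------------------------------------------------------

def _owner_group(labels: np.ndarray, beads, what: str):
    gs = {int(labels[b]) for b in beads}
    if len(gs) > 1:
        raise DecompositionError(
            f"bonded interaction {what} spans groups {sorted(gs)}; draw group "
            "boundaries at nonbonded interfaces"
        )
    return gs.pop()


@dataclass
class _SplitPlan:
    """Precomputed interaction->term-slot assignment for one system."""

    catalogue: list
    slot_of: dict
    bond_slots: np.ndarray
    torsion_slots: np.ndarray
    pair_i: np.ndarray
    pair_j: np.ndarray
    pair_slots: np.ndarray

    @classmethod
    def build(cls, system: BeadSystem, catalogue: list) -> "_SplitPlan":
        labels = system.group_label
        slot_of = {t: s for s, t in enumerate(catalogue)}
        dual = any(t.kind == "dihedral" for t in catalogue)

        bond_slots = np.array(
            [
                slot_of[TermIndex("bonded", _owner_group(labels, (i, j), f"bond {i}-{j}"))]
                for (i, j, *_r) in system.bonds
            ],
            dtype=int,
        )
        tkind = "dihedral" if dual else "bonded"
        torsion_slots = np.array(
            [
                slot_of[
                    TermIndex(
                        tkind,
                        _owner_group(labels, (i, j, k, l), f"torsion {i}-{j}-{k}-{l}"),
                    )
                ]
                for (i, j, k, l, *_r) in system.torsions
            ],
            dtype=int,
        )

        excl = system.excluded_pairs
        n = system.n_beads
        pi, pj, pslots = [], [], []
        for i in range(n):
            gi = int(labels[i])
            for j in range(i + 1, n):
                if (i, j) in excl:
                    continue
                gj = int(labels[j])
                if gi == gj:
                    t = TermIndex("self", gi)
                else:
                    t = TermIndex("pair", min(gi, gj), max(gi, gj))
                pi.append(i)
                pj.append(j)
                pslots.append(slot_of[t])
        return cls(
            catalogue=list(catalogue),
            slot_of=slot_of,
            bond_slots=bond_slots,
            torsion_slots=torsion_slots,
            pair_i=np.array(pi, dtype=int),
            pair_j=np.array(pj, dtype=int),
            pair_slots=np.array(pslots, dtype=int),
        )


def _dihedral_and_grad(x, quad, box):
    """Dihedral angle (radians) and its gradient w.r.t. the four beads."""
    i, j, k, l = quad
    def mi(d):
        if box is not None:
            d = d - box * np.round(d / box)
        return d

    b1 = mi(x[j] - x[i])
    b2 = mi(x[k] - x[j])
    b3 = mi(x[l] - x[k])
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = float(np.linalg.norm(b2))
    m1 = np.cross(n1, b2 / nb2)
    phi = math.atan2(float(m1 @ n2), float(n1 @ n2))

    sq1 = float(n1 @ n1)
    sq2 = float(n2 @ n2)
    dphi_d1 = (nb2 / sq1) * n1
    dphi_d4 = -(nb2 / sq2) * n2
    s = float(b1 @ b2) / nb2**2
    t = float(b3 @ b2) / nb2**2
    dphi_d2 = -(s + 1.0) * dphi_d1 + t * dphi_d4
    dphi_d3 = s * dphi_d1 - (t + 1.0) * dphi_d4
    return phi, (dphi_d1, dphi_d2, dphi_d3, dphi_d4)


def _compute_terms(system: BeadSystem, positions: np.ndarray, plan: _SplitPlan):
    """Per-term energies and forces in catalogue order."""
    x = np.asarray(positions, dtype=float)
    n_terms = len(plan.catalogue)
    n = system.n_beads
    energies = np.zeros(n_terms)
    forces = np.zeros((n_terms, n, 3))
    box = system.box

    for (i, j, r0, kb), slot in zip(system.bonds, plan.bond_slots):
        d = x[j] - x[i]
        if box is not None:
            d -= box * np.round(d / box)
        r = float(np.linalg.norm(d))
        energies[slot] += 0.5 * kb * (r - r0) ** 2
        fmag = -kb * (r - r0)  # force on j along +d
        fvec = fmag * d / r
        forces[slot, j] += fvec
        forces[slot, i] -= fvec

    for (i, j, k, l, kt, mult, phase), slot in zip(
        system.torsions, plan.torsion_slots
    ):
        phi, grads = _dihedral_and_grad(x, (i, j, k, l), box)
        arg = mult * phi - math.radians(phase)
        energies[slot] += kt * (1.0 + math.cos(arg))
        dU_dphi = -kt * mult * math.sin(arg)
        for bead, g in zip((i, j, k, l), grads):
            forces[slot, bead] -= dU_dphi * g

    if plan.pair_i.size:
        eps, sig, cut = system.nonbonded
        d = x[plan.pair_j] - x[plan.pair_i]
        if box is not None:
            d -= box * np.round(d / box)
        r = np.linalg.norm(d, axis=1)
        inside = r < cut
        if inside.any():
            rr = r[inside]
            s6 = (sig / rr) ** 6
            sc6 = (sig / cut) ** 6
            e_pair = eps * (s6 * s6 - 2.0 * s6) - eps * (sc6 * sc6 - 2.0 * sc6)
            np.add.at(energies, plan.pair_slots[inside], e_pair)
            # dU/dr = -12 eps (s12 - s6)/r ; force on j is -dU/dr * unit(d)
            dU_dr = -12.0 * eps * (s6 * s6 - s6) / rr
            fvec = (-dU_dr / rr)[:, None] * d[inside]
            np.add.at(
                forces, (plan.pair_slots[inside], plan.pair_j[inside]), fvec
            )
            np.add.at(
                forces, (plan.pair_slots[inside], plan.pair_i[inside]), -fvec
            )
    return energies, forces


def split_energy(system: BeadSystem, positions, catalogue: list) -> dict:
    """Split the potential energy over the term catalogue.

    Returns a mapping TermIndex -> energy (kJ/mol) whose values sum to the
    total potential.
    """
    plan = _SplitPlan.build(system, catalogue)
    energies, _ = _compute_terms(system, positions, plan)
    return dict(zip(plan.catalogue, energies))


def split_forces(system: BeadSystem, positions, catalogue: list) -> dict:
    """Split forces over the term catalogue (each entry: (n_beads, 3))."""
    plan = _SplitPlan.build(system, catalogue)
    _, forces = _compute_terms(system, positions, plan)
    return dict(zip(plan.catalogue, forces))


# --------------------------------------------------------------------------
# acceleration regions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AccelerationRegionSpec:
    """User-facing region definition: a name plus a set of term indices.

    ``member_terms`` may hold :class:`TermIndex` objects or their string
    labels ("b0", "0-0", "0-1", "d0").  ``sigma0`` is the target standard
    deviation of the boost (kJ/mol) fed to the parameter estimator.
    """

    name: str
    member_terms: frozenset
    accelerate: bool = True
    dual_boost: bool = False
    sigma0: float = 10.0
    sigma0_dihedral: float | None = None

    def resolved_terms(self) -> set:
        out = set()
        for t in self.member_terms:
            out.add(t if isinstance(t, TermIndex) else TermIndex.from_label(t))
        return out


@dataclass(frozen=True)
class AccelerationRegion:
    """Validated region: catalogue slots resolved, dihedral slots split out."""

    name: str
    term_slots: tuple  # non-dihedral member slots
    dihedral_slots: tuple
    accelerate: bool
    dual_boost: bool
    sigma0: float
    sigma0_dihedral: float

    @property
    def all_slots(self) -> tuple:
        return self.term_slots + self.dihedral_slots


@dataclass
class RegionSet:
    """The validated outcome: regions plus the unassigned (unboosted) slots."""

    catalogue: list
    regions: list
    unassigned_slots: tuple = field(default=())

    @property
    def accelerated(self) -> list:
        return [r for r in self.regions if r.accelerate]


def validate_regions(specs: list, catalogue: list) -> RegionSet:
    """Resolve region specs against a catalogue.

    Every term may belong to at most one region; terms in no region remain
    unbiased.  An accelerated region must have at least one member term, and
    dual boosting over a region without dihedral terms degrades to a zero
    dihedral sub-boost with a warning.
    """
    slot_of = {t: s for s, t in enumerate(catalogue)}
    claimed: dict = {}
    regions = []
    for spec in specs:
        terms = spec.resolved_terms()
        if spec.accelerate and not terms:
            raise DecompositionError(
                f"accelerated region {spec.name!r} has no member terms"
            )
        slots, dih_slots = [], []
        for t in sorted(terms):
            if t not in slot_of:
                raise DecompositionError(
                    f"region {spec.name!r} references unknown term {t.label!r}"
                )
            if t in claimed:
                raise DecompositionError(
                    f"term {t.label!r} claimed by both {claimed[t]!r} "
                    f"and {spec.name!r}"
                )
            claimed[t] = spec.name
            (dih_slots if t.kind == "dihedral" else slots).append(slot_of[t])
        # keep catalogue order within the region (stable force summation)
        slots.sort()
        dih_slots.sort()
        if spec.dual_boost and not dih_slots:
            warnings.warn(
                f"region {spec.name!r} requests dual boosting but has no "
                "dihedral terms; dihedral sub-boost will be zero",
                stacklevel=2,
            )
        regions.append(
            AccelerationRegion(
                name=spec.name,
                term_slots=tuple(slots),
                dihedral_slots=tuple(dih_slots),
                accelerate=spec.accelerate,
                dual_boost=spec.dual_boost,
                sigma0=spec.sigma0,
                sigma0_dihedral=(
                    spec.sigma0_dihedral
                    if spec.sigma0_dihedral is not None
                    else spec.sigma0
                ),
            )
        )
    unassigned = tuple(
        s for s, t in enumerate(catalogue) if t not in claimed
    )
    return RegionSet(catalogue=list(catalogue), regions=regions,
                     unassigned_slots=unassigned)


# --------------------------------------------------------------------------
# engine adapter
# --------------------------------------------------------------------------

class DecomposedSystem:
    """A bead system bound to its group partition and term catalogue.

    Implements the dynamics-engine system protocol: per-term energies and
    forces in catalogue order, masses broadcast per Cartesian component.
    """

    def __init__(self, system: BeadSystem, dual_boost: bool = False):
        self.system = system
        self.groups = groups_from_system(system)
        self.catalogue = build_catalogue(
            self.groups, dual_boost=dual_boost, n_beads=system.n_beads
        )
        self._plan = _SplitPlan.build(system, self.catalogue)

    @property
    def masses(self) -> np.ndarray:
        return np.repeat(self.system.masses[:, None], 3, axis=1)

    def initial_positions(self) -> np.ndarray:
        return self.system.positions.copy()

    def wrap(self, x: np.ndarray) -> np.ndarray:
        # periodic box: interactions use minimum image, coordinates free
        return x

    def term_energies_forces(self, x):
        return _compute_terms(self.system, x, self._plan)
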