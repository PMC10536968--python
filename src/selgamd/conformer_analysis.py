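"""Conformer string encoding and sampling analytics for dihedral series.

Each glycosidic-linkage-like coordinate set is classified per frame into a
lettered free-energy basin (A-D) on the torus of its dihedral angles; the
concatenated letters, one per linkage, form the conformer string of the
frame.  Strings support cluster counting, transition counting, dwell-time
filtering (a conformer "counts" once it has been occupied contiguously for
at least tau, 10 ps by default) and Hamming distances.  A generic
threshold-crossing detector with a minimum-lifetime criterion covers
folding-event counting on any scalar CV (e.g. RMSD <= 0.3 nm held for
>= 100 ps).

Durations use the convention that each recorded frame represents one
``frame_dt`` of residence, so a run of m frames lasts m*frame_dt.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .toy_systems import wrap_angle

__all__ = [
    "LinkageDefinition",
    "ConformerSeries",
    "encode",
    "count_clusters",
    "ClusterCount",
    "count_transitions",
    "TransitionCount",
    "dwell_filter",
    "hamming",
    "detect_events",
]

LETTERS = ("A", "B", "C", "D")


def _interval_contains(lo: float, hi: float, a: float) -> bool:
    # half-open [lo, hi) on the circle; wrapping intervals have lo > hi
    if lo <= hi:
        return lo <= a < hi
    return a >= lo or a < hi


def _interval_center(lo: float, hi: float) -> float:
    if lo <= hi:
        return 0.5 * (lo + hi)
    return float(wrap_angle(0.5 * (lo + hi + 360.0)))


@dataclass(frozen=True)
class LinkageDefinition:
    """One linkage: named dihedrals plus lettered basin regions on the torus.

    ``regions`` maps a letter (A-D) to a tuple of per-angle half-open
    intervals (lo, hi) in degrees; an interval with lo > hi wraps through
    +-180.  Regions must be pairwise disjoint.
    """

    name: str
    dihedrals: tuple
    regions: dict

    def __post_init__(self):
        for letter, intervals in self.regions.items():
            if letter not in LETTERS:
                raise ValueError(f"letter {letter!r} not in {LETTERS}")
            if len(intervals) != len(self.dihedrals):
                raise ValueError(
                    f"region {letter!r} of {self.name!r} needs one interval "
                    "per dihedral"
                )
        letters = sorted(self.regions)
        probe = 360  # disjointness check on a coarse torus grid
        grid = np.linspace(-180.0, 180.0, probe, endpoint=False)
        for i, la in enumerate(letters):
            for lb in letters[i + 1 :]:
                for dim in range(len(self.dihedrals)):
                    a_lo, a_hi = self.regions[la][dim]
                    b_lo, b_hi = self.regions[lb][dim]
                    overlap = any(
                        _interval_contains(a_lo, a_hi, g)
                        and _interval_contains(b_lo, b_hi, g)
                        for g in grid
                    )
                    if not overlap:
                        break
                else:
                    raise ValueError(
                        f"regions {la!r} and {lb!r} of {self.name!r} overlap"
                    )

    def classify(self, angles) -> str | None:
        """Letter of the region containing the angle tuple, else None."""
        angles = np.atleast_1d(wrap_angle(np.asarray(angles, dtype=float)))
        for letter in sorted(self.regions):
            ivs = self.regions[letter]
            if all(
                _interval_contains(lo, hi, float(a))
                for (lo, hi), a in zip(ivs, angles)
            ):
                return letter
        return None

    def nearest(self, angles) -> str:
        """Letter of the region whose center is closest (periodic distance)."""
        angles = np.atleast_1d(wrap_angle(np.asarray(angles, dtype=float)))
        best, best_d = None, np.inf
        for letter in sorted(self.regions):
            centers = np.array(
                [_interval_center(lo, hi) for (lo, hi) in self.regions[letter]]
            )
            d = float(np.sum(wrap_angle(angles - centers) ** 2))
            if d < best_d:
                best, best_d = letter, d
        return best


@dataclass
class ConformerSeries:
    """Per-frame conformer strings (one letter per linkage)."""

    times: np.ndarray
    strings: list

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.strings) != len(self.times):
            raise ValueError("one string per frame required")
        lengths = {len(s) for s in self.strings}
        if len(lengths) > 1:
            raise ValueError("conformer strings must have constant length")

    @property
    def n_frames(self) -> int:
        return len(self.times)


def encode(
    dihedral_series,
    linkages: list,
    times=None,
    out_of_basin: str = "nearest",
) -> ConformerSeries:
    """Encode dihedral time series into conformer strings.

    ``dihedral_series`` maps dihedral name -> angle array (a mapping or a
    pandas DataFrame).  Angles outside every defined region are assigned to
    the nearest region by periodic angular distance (``out_of_basin =
    "nearest"``, the default) or to the placeholder letter ``"X"``
    (``out_of_basin = "label_x"``).
    """
    if out_of_basin not in ("nearest", "label_x"):
        raise ValueError("out_of_basin must be 'nearest' or 'label_x'")
    cols = {}
    for lk in linkages:
        for name in lk.dihedrals:
            if name in cols:
                continue
            try:
                cols[name] = np.asarray(dihedral_series[name], dtype=float)
            except (KeyError, IndexError) as exc:
                raise KeyError(f"missing dihedral column {name!r}") from exc
    n = len(next(iter(cols.values())))
    if times is None:
        try:
            times = np.asarray(dihedral_series["time_ps"], dtype=float)
        except (KeyError, IndexError, TypeError):
            times = np.arange(n, dtype=float)

    strings = []
    per_link = [
        np.column_stack([cols[name] for name in lk.dihedrals])
        for lk in linkages
    ]
    for f in range(n):
        letters = []
        for lk, angles in zip(linkages, per_link):
            letter = lk.classify(angles[f])
            if letter is None:
                letter = lk.nearest(angles[f]) if out_of_basin == "nearest" else "X"
            letters.append(letter)
        strings.append("".join(letters))
    return ConformerSeries(times=np.asarray(times, dtype=float), strings=strings)


@dataclass(frozen=True)
class ClusterCount:
    """Cumulative distinct-conformer curve and its final total."""

    cumulative: np.ndarray
    total: int


def count_clusters(series: ConformerSeries) -> ClusterCount:
    """Number of distinct strings observed up to each frame, plus the total."""
    if series.n_frames == 0:
        raise ValueError("empty conformer series")
    seen: set = set()
    cum = np.empty(series.n_frames, dtype=int)
    for i, s in enumerate(series.strings):
        seen.add(s)
        cum[i] = len(seen)
    return ClusterCount(cumulative=cum, total=len(seen))


@dataclass(frozen=True)
class TransitionCount:
    """Adjacent-frame string changes and the corresponding per-ns rate."""

    count: int
    rate_per_ns: float


def count_transitions(series: ConformerSeries) -> TransitionCount:
    """Count frame pairs (t, t+1) with differing strings; rate per ns."""
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames to count transitions")
    s = series.strings
    count = sum(1 for a, b in zip(s[:-1], s[1:]) if a != b)
    duration_ns = (series.times[-1] - series.times[0]) / 1000.0
    rate = count / duration_ns if duration_ns > 0 else float("nan")
    return TransitionCount(count=count, rate_per_ns=rate)


def _runs(strings):
    """Yield (string, run_length) for maximal constant runs."""
    current, length = strings[0], 1
    for s in strings[1:]:
        if s == current:
            length += 1
        else:
            yield current, length
            current, length = s, 1
    yield current, length


def dwell_filter(
    series: ConformerSeries,
    tau: float = 10.0,
    frame_dt: float | None = None,
    mode: str = "contiguous",
) -> set:
    """Strings resident for at least ``tau`` ps.

    ``mode="contiguous"`` (default) requires a single maximal run of
    duration >= tau (a run of m frames lasts m*frame_dt, boundary
    inclusive); ``mode="cumulative"`` sums all residence time of the
    string.  ``frame_dt`` defaults to the series' time spacing.
    """
    if mode not in ("contiguous", "cumulative"):
        raise ValueError("mode must be 'contiguous' or 'cumulative'")
    if series.n_frames == 0:
        raise ValueError("empty conformer series")
    if frame_dt is None:
        if series.n_frames < 2:
            raise ValueError("cannot infer frame_dt from a single frame")
        frame_dt = float(series.times[1] - series.times[0])
    if tau < frame_dt:
        raise ValueError("tau must be at least one frame interval")

    if mode == "contiguous":
        return {
            s for s, length in _runs(series.strings)
            if length * frame_dt >= tau
        }
    totals: dict = {}
    for s, length in _runs(series.strings):
        totals[s] = totals.get(s, 0) + length
    return {s for s, length in totals.items() if length * frame_dt >= tau}


def hamming(s1: str, s2: str) -> int:
    """Number of differing positions between two equal-length strings."""
    if len(s1) != len(s2):
        raise ValueError("Hamming distance requires equal-length strings")
    return sum(1 for a, b in zip(s1, s2) if a != b)


def detect_events(
    values,
    threshold: float,
    min_lifetime: float,
    frame_dt: float,
    below: bool = True,
) -> list:
    """Maximal intervals with the value past the threshold for >= min_lifetime.

    Returns a list of (start_index, end_index) inclusive frame-index pairs;
    an interval of m frames lasts m*frame_dt and the lifetime criterion is
    boundary inclusive.  ``below=True`` detects values <= threshold (e.g.
    RMSD within 0.3 nm of a reference), ``below=False`` values >= threshold.
    """
    if min_lifetime < frame_dt:
        raise ValueError("min_lifetime must be at least one frame interval")
    v = np.asarray(values, dtype=float).ravel()
    inside = v <= threshold if below else v >= threshold
    events = []
    start = None
    for i, flag in enumerate(inside):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if (i - start) * frame_dt >= min_lifetime:
                events.append((start, i - 1))
            start = None
    if start is not None and (len(v) - start) * frame_dt >= min_lifetime:
        events.append((start, len(v) - 1))
    return events
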