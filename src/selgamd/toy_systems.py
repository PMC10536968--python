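"""Analytic model potentials and small bead systems.

These stand in for the atomistic systems a production enhanced-sampling run
would target: a one- or two-dimensional :class:`PotentialSurface` plays the
role of a dihedral free-energy landscape (double wells, Gaussian basins),
and a :class:`BeadSystem` is a minimal solute/solvent mixture with bonds,
torsions and a smooth cutoff nonbonded interaction, enough structure for
the per-group energy decomposition and the boost machinery to be exercised
and property-tested without a forcefield.

Unit conventions: energies kJ/mol, lengths nm, times ps, masses u, angles
degrees in [-180, 180).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import KB
from .terms import TermIndex

__all__ = [
    "PotentialSurface",
    "CosineTerm",
    "GaussianWell",
    "HarmonicTerm",
    "BeadSystem",
    "make_double_well",
    "make_harmonic_well",
    "make_solute_solvent",
    "make_random_system",
    "wrap_angle",
]


def wrap_angle(x, period: float = 360.0):
    """Wrap coordinate(s) into the canonical interval [-period/2, period/2)."""
    return (np.asarray(x) + period / 2.0) % period - period / 2.0


def _wrap_scalar(x: float, period: float) -> float:
    return (x + period / 2.0) % period - period / 2.0


# --------------------------------------------------------------------------
# analytic surfaces
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CosineTerm:
    """A*cos(m * 2*pi*(x_dim - phase)/period) on a periodic dimension."""

    dim: int
    amplitude: float
    multiplicity: int
    phase: float = 0.0


@dataclass(frozen=True)
class GaussianWell:
    """-depth * exp(-sum_d MI(x_d - center_d)^2 / (2*width^2))."""

    center: tuple
    depth: float
    width: float


@dataclass(frozen=True)
class HarmonicTerm:
    """0.5 * k * MI(x_dim - center)^2."""

    dim: int
    center: float
    k: float


@dataclass(frozen=True)
class PotentialSurface:
    """Analytic potential on a 1D or 2D coordinate.

    The surface acts as a complete "system" for the dynamics engine: it
    exposes a one-term catalogue (all its energy in ``bonded_0``), an
    effective inertia per coordinate, and analytic gradients.  For one
    coordinate the potential of mean force equals the surface itself up to
    an additive constant, which is what makes these surfaces useful as
    exact references for reweighting tests.

    ``inertia`` is the effective mass of the coordinate in
    kJ mol^-1 ps^2 deg^-2 (or nm^-2 for non-angular coordinates); the
    default gives oscillation periods of a few ps for ~10 kJ/mol barriers.
    """

    dimension: int
    periodic: tuple
    period: tuple
    terms: tuple
    offset: float = 0.0
    inertia: float = 0.005
    name: str = "surface"

    def __post_init__(self):
        if self.dimension not in (1, 2):
            raise ValueError("surface dimension must be 1 or 2")
        if len(self.periodic) != self.dimension or len(self.period) != self.dimension:
            raise ValueError("periodic/period length must equal dimension")

    # --- energetics -------------------------------------------------------
    def energy(self, x) -> float:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        e = self.offset
        for t in self.terms:
            if isinstance(t, CosineTerm):
                a = 2.0 * math.pi / self.period[t.dim]
                e += t.amplitude * math.cos(t.multiplicity * a * (x[t.dim] - t.phase))
            elif isinstance(t, GaussianWell):
                d2 = 0.0
                for d in range(self.dimension):
                    dx = x[d] - t.center[d]
                    if self.periodic[d]:
                        dx = _wrap_scalar(dx, self.period[d])
                    d2 += dx * dx
                e -= t.depth * math.exp(-d2 / (2.0 * t.width**2))
            elif isinstance(t, HarmonicTerm):
                dx = x[t.dim] - t.center
                if self.periodic[t.dim]:
                    dx = _wrap_scalar(dx, self.period[t.dim])
                e += 0.5 * t.k * dx * dx
            else:  # pragma: no cover - guarded by construction
                raise TypeError(f"unknown surface term {t!r}")
        if not math.isfinite(e):
            raise FloatingPointError("non-finite surface energy")
        return e

    def gradient(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        g = np.zeros(self.dimension)
        for t in self.terms:
            if isinstance(t, CosineTerm):
                a = 2.0 * math.pi / self.period[t.dim]
                g[t.dim] += (
                    -t.amplitude
                    * t.multiplicity
                    * a
                    * math.sin(t.multiplicity * a * (x[t.dim] - t.phase))
                )
            elif isinstance(t, GaussianWell):
                dx = np.empty(self.dimension)
                for d in range(self.dimension):
                    dd = x[d] - t.center[d]
                    if self.periodic[d]:
                        dd = _wrap_scalar(dd, self.period[d])
                    dx[d] = dd
                w2 = t.width**2
                e = -t.depth * math.exp(-float(dx @ dx) / (2.0 * w2))
                g += -e * dx / w2
            elif isinstance(t, HarmonicTerm):
                dd = x[t.dim] - t.center
                if self.periodic[t.dim]:
                    dd = _wrap_scalar(dd, self.period[t.dim])
                g[t.dim] += t.k * dd
        return g

    # --- engine protocol --------------------------------------------------
    @property
    def catalogue(self) -> tuple:
        return (TermIndex("bonded", 0),)

    @property
    def masses(self) -> np.ndarray:
        return np.full(self.dimension, self.inertia)

    def initial_positions(self) -> np.ndarray:
        # start in the deepest basin found on a coarse grid
        grid = np.linspace(-180.0, 180.0, 73)
        if self.dimension == 1:
            pts = grid[:, None]
        else:
            gx, gy = np.meshgrid(grid, grid)
            pts = np.column_stack([gx.ravel(), gy.ravel()])
        energies = [self.energy(p) for p in pts]
        return pts[int(np.argmin(energies))].copy()

    def wrap(self, x: np.ndarray) -> np.ndarray:
        out = np.array(x, dtype=float, copy=True)
        for d in range(self.dimension):
            if self.periodic[d]:
                out[d] = _wrap_scalar(out[d], self.period[d])
        return out

    def term_energies_forces(self, x):
        e = np.array([self.energy(x)])
        f = -self.gradient(x)[None, :]
        return e, f

    # --- references -------------------------------------------------------
    def pmf(self, points) -> np.ndarray:
        """Analytic PMF at the given coordinate values, anchored at 0.

        For these low-dimensional surfaces the configurational measure is
        uniform, so the PMF equals the potential up to a constant.
        """
        points = np.atleast_1d(np.asarray(points, dtype=float))
        if self.dimension == 1:
            vals = np.array([self.energy([p]) for p in points])
        else:
            vals = np.array([self.energy(p) for p in points])
        return vals - vals.min()

    def boltzmann_density(self, points, temperature: float) -> np.ndarray:
        """Normalized Boltzmann density on a 1D grid (trapezoid quadrature)."""
        if self.dimension != 1:
            raise ValueError("boltzmann_density is defined for 1D surfaces")
        points = np.asarray(points, dtype=float)
        w = np.exp(-self.pmf(points) / (KB * temperature))
        return w / np.trapezoid(w, points)


def make_double_well(barrier: float, period: float = 360.0) -> PotentialSurface:
    """Symmetric periodic double well: minima at +-period/4, maxima 0 and
    period/2, well depth equal to ``barrier`` (kJ/mol).

    V(x) = (barrier/2) * (1 + cos(2 * 2*pi*x/period))
    """
    if barrier <= 0:
        raise ValueError("barrier must be positive")
    return PotentialSurface(
        dimension=1,
        periodic=(True,),
        period=(period,),
        terms=(CosineTerm(0, barrier / 2.0, 2),),
        offset=barrier / 2.0,
        name="double_well",
    )


def make_harmonic_well(k_spring: float, center: float = 0.0) -> PotentialSurface:
    """Non-periodic 1D harmonic well 0.5*k*(x-center)^2 (k in kJ/mol/deg^2)."""
    if k_spring <= 0:
        raise ValueError("spring constant must be positive")
    return PotentialSurface(
        dimension=1,
        periodic=(False,),
        period=(360.0,),
        terms=(HarmonicTerm(0, center, k_spring),),
        name="harmonic_well",
    )


# --------------------------------------------------------------------------
# bead systems
# --------------------------------------------------------------------------

@dataclass
class BeadSystem:
    """A small 3D bead model with bonds, torsions and cutoff nonbonded pairs.

    ``bonds`` are (i, j, r0 nm, k kJ/mol/nm^2) harmonic springs; ``torsions``
    are (i, j, k, l, K kJ/mol, multiplicity, phase deg) proper dihedrals
    K*(1 + cos(m*phi - phase)); the nonbonded interaction is a 12-6 form
    eps*((sigma/r)^12 - 2*(sigma/r)^6) shifted to zero at the cutoff,
    applied to every bead pair except directly bonded (1-2) pairs.  With a
    periodic cubic ``box`` all distances use minimum-image displacements.
    """

    positions: np.ndarray
    masses: np.ndarray
    group_label: np.ndarray
    bonds: list = field(default_factory=list)
    torsions: list = field(default_factory=list)
    nonbonded: tuple = (0.4, 0.3, 0.9)  # epsilon kJ/mol, sigma nm, cutoff nm
    box: float | None = None
    name: str = "beads"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.group_label = np.asarray(self.group_label, dtype=int)
        n = self.n_beads
        if self.masses.shape != (n,) or self.group_label.shape != (n,):
            raise ValueError("masses/group_label must have one entry per bead")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_groups(self) -> int:
        return int(self.group_label.max()) + 1

    @property
    def excluded_pairs(self) -> set:
        return {(min(i, j), max(i, j)) for (i, j, *_rest) in self.bonds}

    def displacement(self, ri, rj):
        d = rj - ri
        if self.box is not None:
            d -= self.box * np.round(d / self.box)
        return d

    def pair_energy(self, r: float) -> float:
        eps, sig, cut = self.nonbonded
        if r >= cut:
            return 0.0
        s6 = (sig / r) ** 6
        sc6 = (sig / cut) ** 6
        return eps * (s6 * s6 - 2.0 * s6) - eps * (sc6 * sc6 - 2.0 * sc6)

    def potential_energy(self, positions=None) -> float:
        """Plain independent summation of all interactions (test oracle)."""
        x = self.positions if positions is None else np.asarray(positions, float)
        e = 0.0
        for (i, j, r0, kb) in self.bonds:
            r = float(np.linalg.norm(self.displacement(x[i], x[j])))
            e += 0.5 * kb * (r - r0) ** 2
        for (i, j, k, l, kt, mult, phase) in self.torsions:
            phi = dihedral_angle(x[i], x[j], x[k], x[l], self.box)
            e += kt * (1.0 + math.cos(math.radians(mult * phi - phase)))
        excl = self.excluded_pairs
        n = self.n_beads
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in excl:
                    continue
                r = float(np.linalg.norm(self.displacement(x[i], x[j])))
                e += self.pair_energy(r)
        return e

    def with_positions(self, positions: np.ndarray) -> "BeadSystem":
        return replace(self, positions=np.asarray(positions, dtype=float))


def dihedral_angle(r1, r2, r3, r4, box: float | None = None) -> float:
    """Proper dihedral angle in degrees in [-180, 180)."""
    def mi(d):
        if box is not None:
            d = d - box * np.round(d / box)
        return d

    b1 = mi(r2 - r1)
    b2 = mi(r3 - r2)
    b3 = mi(r4 - r3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = math.degrees(math.atan2(float(m1 @ n2), float(n1 @ n2)))
    return _wrap_scalar(ang, 360.0)


def make_solute_solvent(
    n_solute: int,
    n_solvent: int,
    seed: int = 0,
    box: float | None = None,
) -> BeadSystem:
    """Bonded solute chain (group 0) plus free solvent beads (group 1).

    The chain is laid out as a non-collinear zigzag so every consecutive
    bead quadruple defines a proper dihedral; chains of four or more beads
    carry one 3-fold torsion per quadruple.  Solvent beads are placed on a
    jittered grid avoiding overlap with the solute.
    """
    if n_solute < 2:
        raise ValueError("need at least 2 solute beads")
    if n_solvent < 0:
        raise ValueError("n_solvent must be >= 0")
    rng = np.random.default_rng(seed)

    chain = np.zeros((n_solute, 3))
    for t in range(n_solute):
        chain[t] = (0.13 * t, 0.055 * (t % 2), 0.03 * ((t // 2) % 2))
    bonds = []
    for t in range(n_solute - 1):
        r0 = float(np.linalg.norm(chain[t + 1] - chain[t]))
        bonds.append((t, t + 1, r0, 5000.0))
    torsions = [
        (t, t + 1, t + 2, t + 3, 4.0, 3, 0.0) for t in range(n_solute - 3)
    ]

    n_total = n_solute + n_solvent
    if box is None:
        box = max(1.4, 0.42 * math.ceil(n_total ** (1.0 / 3.0)) + 0.6)

    solvent = []
    if n_solvent > 0:
        n_side = int(math.ceil(box / 0.42))
        spacing = box / n_side  # commensurate with the periodic box
        candidates = []
        for ix in range(n_side):
            for iy in range(n_side):
                for iz in range(n_side):
                    candidates.append(
                        np.array([ix, iy, iz], dtype=float) * spacing
                        - box / 2.0
                        + spacing / 2.0
                    )
        # keep grid sites clear of the solute chain (placed near the origin)
        keep = [
            c
            for c in candidates
            if np.min(np.linalg.norm(chain - c, axis=1)) > 0.32
        ]
        if len(keep) < n_solvent:
            raise ValueError("box too small to place solvent without overlap")
        order = rng.permutation(len(keep))[:n_solvent]
        for idx in order:
            solvent.append(keep[idx] + rng.uniform(-0.04, 0.04, size=3))

    positions = np.vstack([chain] + ([np.array(solvent)] if solvent else []))
    masses = np.concatenate(
        [np.full(n_solute, 12.0), np.full(n_solvent, 18.0)]
    )
    labels = np.concatenate(
        [np.zeros(n_solute, dtype=int), np.ones(n_solvent, dtype=int)]
    )
    system = BeadSystem(
        positions=positions,
        masses=masses,
        group_label=labels,
        bonds=bonds,
        torsions=torsions,
        box=box,
        name=f"solute{n_solute}_solvent{n_solvent}",
    )
    _check_overlaps(system)
    return system


def make_random_system(
    n_beads: int,
    n_groups: int,
    seed: int = 0,
    with_torsions: bool = True,
) -> BeadSystem:
    """Randomized bead system with contiguous groups, for property tests.

    Beads form a single bonded chain; group boundaries are drawn at random
    chain positions so bonds never cross groups only if boundaries align —
    bonds *within* each contiguous block stay internal, and the chain is cut
    at group boundaries so that no bonded interaction spans two groups.
    """
    if n_groups < 1 or n_beads < n_groups * 2:
        raise ValueError("need at least 2 beads per group")
    rng = np.random.default_rng(seed)
    # contiguous group sizes >= 2
    cuts = np.sort(rng.choice(np.arange(2, n_beads - 1), size=n_groups - 1, replace=False)) if n_groups > 1 else np.array([], dtype=int)
    # enforce minimum block size of 2 by regular fallback if draw is bad
    sizes = np.diff(np.concatenate([[0], cuts, [n_beads]]))
    if (sizes < 2).any():
        base = n_beads // n_groups
        sizes = np.full(n_groups, base)
        sizes[: n_beads - base * n_groups] += 1
    labels = np.repeat(np.arange(n_groups), sizes)

    positions = np.zeros((n_beads, 3))
    for t in range(1, n_beads):
        step = rng.normal(size=3)
        step = 0.14 * step / np.linalg.norm(step)
        positions[t] = positions[t - 1] + step
    positions += rng.normal(scale=0.01, size=positions.shape)

    bonds = []
    torsions = []
    start = 0
    for size in sizes:
        for t in range(start, start + size - 1):
            r0 = float(np.linalg.norm(positions[t + 1] - positions[t]))
            bonds.append((t, t + 1, r0, 4000.0))
        if with_torsions:
            for t in range(start, start + size - 3):
                torsions.append((t, t + 1, t + 2, t + 3, 3.0, 3, 0.0))
        start += size

    masses = rng.uniform(10.0, 20.0, size=n_beads)
    return BeadSystem(
        positions=positions,
        masses=masses,
        group_label=labels,
        bonds=bonds,
        torsions=torsions,
        box=None,
        name=f"random_{n_groups}group",
    )


def _check_overlaps(system: BeadSystem, min_dist: float = 0.18) -> None:
    x = system.positions
    n = system.n_beads
    excluded = system.excluded_pairs  # bonded neighbors sit below min_dist
    for i in range(n):
        d = x[i + 1 :] - x[i]
        if system.box is not None:
            d -= system.box * np.round(d / system.box)
        r = np.linalg.norm(d, axis=1)
        for off in np.flatnonzero(r < min_dist):
            j = i + 1 + int(off)
            if (i, j) in excluded:
                continue
            raise ValueError(
                f"beads {i} and {j} overlap at {r[off]:.3f} nm; "
                "initial positions not resolvable"
            )
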