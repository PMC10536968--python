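"""Local elevation umbrella sampling (LEUS) on periodic CV grids.

The bias is a sum of grid-based kernels

    B(Q) = c * sum_k n_k * prod_d g(MI(Q_d - Q*_k,d))

over the cells k of an N_l-dimensional periodic grid with N_g points per
dimension, where n_k counts the visits to cell k, MI is the minimum-image
difference and c is the force constant per visit.  During the build-up (LE)
phase the visit count of the current cell is incremented every step, which
progressively fills the free-energy basins; the bias is then frozen and an
equilibrium umbrella-sampling (US) phase runs with a time-independent
Hamiltonian, whose samples are unbiased by the weight exp(+beta*B(Q)).

The kernel g is pluggable.  The default is a finite-support Gaussian with
its truncation offset removed,

    g(d) = (exp(-d^2/(2 sigma^2)) - exp(-kappa^2/2)) / (1 - exp(-kappa^2/2))

for |d| <= kappa*sigma (kappa = 2) and 0 beyond, so that g(0) = 1 and the
bias energy is continuous everywhere; a continuous bias keeps the US-phase
ensemble well defined.  The raw truncated Gaussian is also provided.
"""
from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .md_engine import IntegratorConfig, Trajectory, run
from .reweighting import BiasedSamples, FreeEnergySurface, _bin_samples, _finish

__all__ = [
    "LEUSBias",
    "le_update",
    "bias_energy",
    "run_leus",
    "reweight_us",
    "LEUSResult",
    "gaussian_kernel",
    "truncated_gaussian_kernel",
]

_KAPPA = 2.0


def gaussian_kernel(d: np.ndarray, sigma: float) -> np.ndarray:
    """Continuity-corrected finite-support Gaussian, g(0)=1, g(+-2 sigma)=0."""
    off = math.exp(-0.5 * _KAPPA**2)
    g = (np.exp(-(d * d) / (2.0 * sigma * sigma)) - off) / (1.0 - off)
    return np.where(np.abs(d) < _KAPPA * sigma, g, 0.0)


def gaussian_kernel_grad(d: np.ndarray, sigma: float) -> np.ndarray:
    off = math.exp(-0.5 * _KAPPA**2)
    g = -(d / sigma**2) * np.exp(-(d * d) / (2.0 * sigma * sigma)) / (1.0 - off)
    return np.where(np.abs(d) < _KAPPA * sigma, g, 0.0)


def truncated_gaussian_kernel(d: np.ndarray, sigma: float) -> np.ndarray:
    """Raw truncated Gaussian (discontinuous at the cutoff); g(0)=1."""
    g = np.exp(-(d * d) / (2.0 * sigma * sigma))
    return np.where(np.abs(d) < _KAPPA * sigma, g, 0.0)


@dataclass
class LEUSBias:
    """Periodic grid bias with per-cell visit counts.

    ``n_grid`` grid cells per dimension over the periodic ``ranges``
    ((lo, hi) per dimension); grid points sit at cell centers and cell
    assignment is floor-based.  ``sigma`` defaults to the grid spacing
    (span / n_grid) per dimension.
    """

    n_dims: int
    n_grid: int
    c: float
    sigma: tuple = ()
    ranges: tuple = ()
    visits: np.ndarray = field(default=None)
    frozen: bool = False

    def __post_init__(self):
        if self.n_dims < 1 or self.n_dims > 2:
            raise ValueError("n_dims must be 1 or 2")
        if not self.ranges:
            self.ranges = tuple((-180.0, 180.0) for _ in range(self.n_dims))
        if not self.sigma:
            self.sigma = tuple(
                (hi - lo) / self.n_grid for (lo, hi) in self.ranges
            )
        if self.visits is None:
            self.visits = np.zeros((self.n_grid,) * self.n_dims, dtype=np.int64)
        else:
            self.visits = np.asarray(self.visits, dtype=np.int64)
            if self.visits.shape != (self.n_grid,) * self.n_dims:
                raise ValueError("visit grid shape mismatch")
        if (self.visits < 0).any():
            raise ValueError("visit counts must be non-negative")

    # --- grid geometry ------------------------------------------------------
    def span(self, d: int) -> float:
        lo, hi = self.ranges[d]
        return hi - lo

    def spacing(self, d: int) -> float:
        return self.span(d) / self.n_grid

    def centers(self, d: int) -> np.ndarray:
        lo, _ = self.ranges[d]
        h = self.spacing(d)
        return lo + h * (np.arange(self.n_grid) + 0.5)

    def cell_index(self, q) -> tuple:
        q = np.atleast_1d(np.asarray(q, dtype=float))
        idx = []
        for d in range(self.n_dims):
            lo, _ = self.ranges[d]
            i = int(math.floor((q[d] - lo) / self.spacing(d))) % self.n_grid
            idx.append(i)
        return tuple(idx)

    def _mi(self, d: int, delta: np.ndarray) -> np.ndarray:
        span = self.span(d)
        return (delta + span / 2.0) % span - span / 2.0

    # --- energetics ---------------------------------------------------------
    def _kernel_vectors(self, q, grad_dim: int = -1):
        q = np.atleast_1d(np.asarray(q, dtype=float))
        vecs = []
        for d in range(self.n_dims):
            delta = self._mi(d, q[d] - self.centers(d))
            if d == grad_dim:
                vecs.append(gaussian_kernel_grad(delta, self.sigma[d]))
            else:
                vecs.append(gaussian_kernel(delta, self.sigma[d]))
        return vecs

    def energy(self, q) -> float:
        """B(Q) in kJ/mol; 0 when no visits or c = 0."""
        if self.c == 0.0 or not self.visits.any():
            return 0.0
        vecs = self._kernel_vectors(q)
        v = self.visits.astype(float)
        if self.n_dims == 1:
            return float(self.c * (vecs[0] @ v))
        return float(self.c * (vecs[0] @ v @ vecs[1]))

    def gradient(self, q) -> np.ndarray:
        g = np.zeros(self.n_dims)
        if self.c == 0.0 or not self.visits.any():
            return g
        v = self.visits.astype(float)
        for d in range(self.n_dims):
            vecs = self._kernel_vectors(q, grad_dim=d)
            if self.n_dims == 1:
                g[d] = self.c * (vecs[0] @ v)
            else:
                g[d] = self.c * (vecs[0] @ v @ vecs[1])
        return g

    def update(self, q) -> None:
        """Increment the visit count of the cell containing Q."""
        if self.frozen:
            raise RuntimeError("cannot update a frozen LEUS bias")
        self.visits[self.cell_index(q)] += 1

    def freeze(self) -> None:
        self.frozen = True

    # --- serialization ------------------------------------------------------
    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"# leus_bias n_dims={self.n_dims} n_grid={self.n_grid} ")
        buf.write(f"c={self.c!r} frozen={int(self.frozen)}\n")
        buf.write("# sigma\t" + "\t".join(repr(s) for s in self.sigma) + "\n")
        for lo, hi in self.ranges:
            buf.write(f"# range\t{lo!r}\t{hi!r}\n")
        for row in self.visits.reshape(self.visits.shape[0], -1):
            buf.write("\t".join(str(int(v)) for v in row) + "\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "LEUSBias":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        head = dict(
            kv.split("=") for kv in lines[0].lstrip("# ").split()[1:]
        )
        n_dims, n_grid = int(head["n_dims"]), int(head["n_grid"])
        sigma = tuple(float(s) for s in lines[1].split("\t")[1:])
        ranges = []
        k = 2
        while lines[k].startswith("# range"):
            _, lo, hi = lines[k].split("\t")
            ranges.append((float(lo), float(hi)))
            k += 1
        rows = [[int(v) for v in ln.split("\t")] for ln in lines[k:]]
        visits = np.array(rows, dtype=np.int64).reshape((n_grid,) * n_dims)
        return cls(
            n_dims=n_dims,
            n_grid=n_grid,
            c=float(head["c"]),
            sigma=sigma,
            ranges=tuple(ranges),
            visits=visits,
            frozen=bool(int(head["frozen"])),
        )


def le_update(bias: LEUSBias, q) -> LEUSBias:
    """Increment the visit count of the cell containing Q (in place)."""
    bias.update(q)
    return bias


def bias_energy(bias: LEUSBias, q) -> float:
    """B(Q) = c * sum_k n_k * prod_d g(MI(Q - Q*_k)); >= 0."""
    return bias.energy(q)


class LEUSProvider:
    """Engine bias provider: CV-space grid bias, optional LE updates."""

    def __init__(self, bias: LEUSBias, cv_func=None, updating: bool = False):
        self.bias = bias
        self.cv_func = cv_func
        self.updating = updating
        if updating and bias.frozen:
            raise RuntimeError("cannot run an LE phase on a frozen bias")

    def _q(self, x):
        return x if self.cv_func is None else self.cv_func(x)

    def force_and_bias(self, x, energies, forces):
        q = self._q(x)
        total = forces.sum(axis=0)
        b = self.bias.energy(q)
        if b != 0.0:
            # chain rule is the identity when the CV is the coordinate itself
            if self.cv_func is not None:
                raise NotImplementedError(
                    "LEUS dynamics is supported on surface coordinates only"
                )
            total = total - self.bias.gradient(q)
        return total, b, {"leus": b}

    def post_step(self, x, energies):
        if self.updating:
            self.bias.update(self._q(x))


@dataclass
class LEUSResult:
    bias: LEUSBias
    le: Trajectory | None
    us: Trajectory


def run_leus(
    system,
    cfg: IntegratorConfig,
    le_steps: int,
    us_steps: int,
    n_grid: int = 36,
    c: float = 0.005,
    sigma: tuple = (),
    bias: LEUSBias | None = None,
) -> LEUSResult:
    """Build-up (LE) phase followed by a frozen umbrella (US) phase.

    Defaults follow common practice for dihedral CVs: N_g = 36 cells,
    sigma = 360/N_g degrees, c = 0.005 kJ/mol per visit.  With
    ``le_steps = 0`` the US phase is plain unbiased dynamics.  Stage seeds
    are ``cfg.seed`` (LE) and ``cfg.seed + 1`` (US).
    """
    if le_steps < 0 or us_steps <= 0:
        raise ValueError("le_steps must be >= 0 and us_steps > 0")
    if bias is None:
        ranges = tuple(
            (-p / 2.0, p / 2.0) for p in system.period[: system.dimension]
        )
        bias = LEUSBias(
            n_dims=system.dimension, n_grid=n_grid, c=c, sigma=sigma,
            ranges=ranges,
        )

    le_traj = None
    x0 = v0 = None
    if le_steps > 0:
        le_cfg = IntegratorConfig(
            timestep=cfg.timestep, temperature=cfg.temperature,
            friction=cfg.friction, n_steps=le_steps,
            output_stride=cfg.output_stride, seed=cfg.seed,
        )
        le_traj = run(
            system, le_cfg, bias=LEUSProvider(bias, updating=True)
        )
        x0, v0 = le_traj.final_positions, le_traj.final_velocities

    bias.freeze()
    us_cfg = IntegratorConfig(
        timestep=cfg.timestep, temperature=cfg.temperature,
        friction=cfg.friction, n_steps=us_steps,
        output_stride=cfg.output_stride, seed=cfg.seed + 1,
    )
    us_traj = run(
        system, us_cfg, bias=LEUSProvider(bias, updating=False),
        x0=x0, v0=v0,
    )
    return LEUSResult(bias=bias, le=le_traj, us=us_traj)


def reweight_us(
    samples: BiasedSamples,
    bins=36,
    temperature: float = 300.0,
    range=None,
    bias: LEUSBias | None = None,
) -> FreeEnergySurface:
    """Unbias US-phase samples: p(j) proportional to p_biased(j)*<exp(+beta B)>_j.

    ``samples.delta_v`` carries B(Q) per frame.  When the originating bias
    is passed it must be frozen (a time-dependent Hamiltonian has no single
    umbrella weight).
    """
    if bias is not None and not bias.frozen:
        raise RuntimeError("US reweighting requires a frozen bias")
    if samples.n == 0:
        raise ValueError("no samples to reweight")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    b = 1.0 / (KB * temperature)
    counts, edges, flat, ok, shape = _bin_samples(samples, bins, range)
    nbins = int(np.prod(shape))
    bq = samples.delta_v[ok]
    fi = flat[ok]
    b_max = np.full(nbins, -np.inf)
    np.maximum.at(b_max, fi, bq)
    s = np.bincount(fi, weights=np.exp(b * (bq - b_max[fi])), minlength=nbins)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_w = np.log(s / max(1, samples.n)) + b * b_max
    return _finish(log_w.reshape(shape), counts, edges, temperature)
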