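"""Langevin dynamics on toy systems with per-term energy bookkeeping.

The integrator is the BAOAB splitting of Langevin dynamics: two velocity
half-kicks around a half-drift / Ornstein-Uhlenbeck / half-drift core.  It
samples the canonical ensemble at the configured temperature (exactly
canonical in the small-timestep limit, with very small configurational bias
at practical timesteps), and reduces to velocity Verlet when the friction
is zero.  Bias providers (selective boosts, LEUS grids) transform the
per-term forces into a total biased force and report the instantaneous
bias energy; they receive no randomness, so runs are bit-reproducible for
a fixed seed regardless of the bias attached.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["IntegratorConfig", "Trajectory", "EngineError", "run", "torsion_cv"]


class EngineError(RuntimeError):
    """Non-finite energies/forces or inconsistent configuration."""


@dataclass(frozen=True)
class IntegratorConfig:
    """Leapfrog-Langevin integration settings.

    timestep ps, temperature K, friction ps^-1 (0 disables the thermostat),
    n_steps total steps, output_stride steps between recorded frames.
    """

    timestep: float
    temperature: float
    friction: float
    n_steps: int
    output_stride: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")
        if self.output_stride < 1:
            raise ValueError("output_stride must be >= 1")


@dataclass
class Trajectory:
    """Recorded time series of a run.

    ``term_energies`` has one column per catalogue entry (labels in
    ``term_labels``); ``region_dv`` holds the per-region boost energy
    (empty when unbiased) and ``total_dv`` their per-frame sum.
    """

    times: np.ndarray
    positions: np.ndarray
    term_labels: list
    term_energies: np.ndarray
    total_dv: np.ndarray
    region_dv: dict = field(default_factory=dict)
    cv: np.ndarray | None = None
    final_positions: np.ndarray | None = None
    final_velocities: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def total_energy(self) -> np.ndarray:
        """Per-frame total (unbiased) potential energy."""
        return self.term_energies.sum(axis=1)

    def energy_of(self, label: str) -> np.ndarray:
        return self.term_energies[:, self.term_labels.index(label)]


class _NullBias:
    def force_and_bias(self, x, energies, forces):
        return forces.sum(axis=0), 0.0, {}

    def post_step(self, x, energies):
        pass


def run(
    system,
    cfg: IntegratorConfig,
    bias=None,
    cv_func=None,
    x0: np.ndarray | None = None,
    v0: np.ndarray | None = None,
    record_positions: bool = True,
) -> Trajectory:
    """Propagate ``system`` and record frames every ``output_stride`` steps.

    ``system`` implements the toy-system protocol (``masses``,
    ``initial_positions``, ``wrap``, ``catalogue``,
    ``term_energies_forces``).  ``bias`` implements ``force_and_bias`` and
    ``post_step``; when absent the total force is the plain sum of term
    forces.  ``cv_func`` maps positions to a CV vector; for 1D/2D surfaces
    the coordinate itself is used by default.

    Returns a trajectory with ``n_steps // output_stride + 1`` frames
    (initial state included).
    """
    from .constants import KB

    provider = bias if bias is not None else _NullBias()
    catalogue = system.catalogue
    labels = [t.label for t in catalogue]
    m = np.asarray(system.masses, dtype=float)

    x = np.array(
        system.initial_positions() if x0 is None else x0, dtype=float
    )
    if x.shape != m.shape:
        raise EngineError(
            f"positions shape {x.shape} does not match masses {m.shape}"
        )
    rng = np.random.default_rng(cfg.seed)
    kT = KB * cfg.temperature
    if v0 is None:
        v = rng.standard_normal(x.shape) * np.sqrt(kT / m)
    else:
        v = np.array(v0, dtype=float)

    if cv_func is None and x.ndim == 1:
        cv_func = lambda q: q.copy()  # noqa: E731 - surface coordinate is the CV

    dt = cfg.timestep
    c1 = math.exp(-cfg.friction * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    noise_scale = c2 * np.sqrt(kT / m)

    n_frames = cfg.n_steps // cfg.output_stride + 1
    times = np.empty(n_frames)
    positions = (
        np.empty((n_frames,) + x.shape) if record_positions else None
    )
    term_e = np.empty((n_frames, len(catalogue)))
    total_dv = np.empty(n_frames)
    cv0 = cv_func(x) if cv_func is not None else None
    cv_out = (
        np.empty((n_frames, np.size(cv0))) if cv0 is not None else None
    )

    energies, forces = system.term_energies_forces(x)
    if len(energies) != len(catalogue):
        raise EngineError("system returned wrong number of energy terms")
    f_tot, dv, dv_reg = provider.force_and_bias(x, energies, forces)
    region_names = list(dv_reg.keys())
    region_dv = {name: np.empty(n_frames) for name in region_names}

    def _record(frame, step):
        times[frame] = step * dt
        if positions is not None:
            positions[frame] = x
        term_e[frame] = energies
        total_dv[frame] = dv
        for name in region_names:
            region_dv[name][frame] = dv_reg[name]
        if cv_out is not None:
            cv_out[frame] = np.atleast_1d(cv_func(x))

    _record(0, 0)
    frame = 1
    inv_m = 1.0 / m
    half = 0.5 * dt
    for step in range(1, cfg.n_steps + 1):
        v += half * f_tot * inv_m
        x += half * v
        x = system.wrap(x)
        if c2 > 0.0:
            v = c1 * v + noise_scale * rng.standard_normal(x.shape)
        x += half * v
        x = system.wrap(x)
        try:
            energies, forces = system.term_energies_forces(x)
        except FloatingPointError as exc:
            raise EngineError(f"non-finite energy at step {step}") from exc
        f_tot, dv, dv_reg = provider.force_and_bias(x, energies, forces)
        e_sum = float(energies.sum())
        if not math.isfinite(e_sum) or not np.isfinite(f_tot).all():
            raise EngineError(f"non-finite energy or force at step {step}")
        v += half * f_tot * inv_m
        provider.post_step(x, energies)
        if step % cfg.output_stride == 0:
            _record(frame, step)
            frame += 1

    return Trajectory(
        times=times,
        positions=positions if positions is not None else np.empty((0,)),
        term_labels=labels,
        term_energies=term_e,
        total_dv=total_dv,
        region_dv=region_dv,
        cv=cv_out,
        final_positions=x.copy(),
        final_velocities=v.copy(),
    )


def torsion_cv(quads, box: float | None = None):
    """CV function returning the dihedral angles (degrees) of bead quadruples."""
    from .toy_systems import dihedral_angle

    quads = [tuple(q) for q in quads]

    def cv(x):
        return np.array(
            [dihedral_angle(x[i], x[j], x[k], x[l], box) for (i, j, k, l) in quads]
        )

    return cv
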