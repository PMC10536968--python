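"""Selective Gaussian-accelerated MD boosts.

Each acceleration region carries one harmonic boost

    dV = 1/2 * k * (E - V)^2   for V < E,   0 otherwise,

where V is the summed energy of the region's member terms, E an energy
threshold and k the force constant.  Biased per-term forces are the
unbiased forces scaled by lambda = 1 - k*(E - V): at V = v_min with
E = v_max and k0 = 1 the landscape of the region is locally flattened
(lambda = 0).  Under dual boosting the dihedral sub-term of a region gets
its own independent (E_dih, k_dih) boost.

Parameters are estimated from search-run statistics with the standard
lower-bound rule: E = v_max (the maximal observed energy for the region)
and k = k0 / (v_max - v_min) with

    k0 = min(1, (sigma0 / sigma_V) * (v_max - v_min) / (v_max - v_avg)),

so the boost standard deviation stays near the user's sigma0 and the
biased distribution stays near-Gaussian, which is what makes the
second-order cumulant reweighting reliable.

The staged protocol mirrors common practice: an unbiased search collecting
running statistics, a boosted search with the parameters periodically
re-estimated from cumulative statistics, and a production run with the
parameters frozen at the final search values.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .md_engine import IntegratorConfig, Trajectory, run
from .region_decomposition import RegionSet

__all__ = [
    "RegionStatistics",
    "BoostParameters",
    "StageLengths",
    "ProtocolResult",
    "boost_energy",
    "force_scale",
    "estimate_parameters",
    "apply_dual_boost",
    "SelectiveBoostProvider",
    "StatisticsProvider",
    "AdaptiveBoostProvider",
    "run_protocol",
    "run_standard_gamd",
]


@dataclass
class RegionStatistics:
    """Streaming min/max/mean/std of a region's energy (Welford update)."""

    n_samples: int = 0
    _mean: float = 0.0
    _m2: float = 0.0
    v_min: float = math.inf
    v_max: float = -math.inf

    def update(self, v: float) -> None:
        v = float(v)
        self.n_samples += 1
        delta = v - self._mean
        self._mean += delta / self.n_samples
        self._m2 += delta * (v - self._mean)
        if v < self.v_min:
            self.v_min = v
        if v > self.v_max:
            self.v_max = v

    @property
    def v_avg(self) -> float:
        if self.n_samples == 0:
            raise ValueError("no samples collected")
        return self._mean

    @property
    def v_std(self) -> float:
        if self.n_samples == 0:
            raise ValueError("no samples collected")
        return math.sqrt(self._m2 / self.n_samples)


@dataclass(frozen=True)
class BoostParameters:
    """Harmonic boost parameters for one region (or dihedral sub-term).

    E kJ/mol threshold; k 1/(kJ/mol) curvature; k0 = k*(v_max - v_min)
    dimensionless in [0, 1]; sigma0 the user's target boost width.
    """

    E: float
    k: float
    k0: float = 0.0
    sigma0: float = 0.0

    @classmethod
    def none(cls) -> "BoostParameters":
        """Parameters producing an identically-zero boost."""
        return cls(E=-math.inf, k=0.0, k0=0.0, sigma0=0.0)


def boost_energy(V: float, params: BoostParameters) -> float:
    """dV = 1/2 k (E - V)^2 when V < E, else 0; always >= 0."""
    if V >= params.E or params.k == 0.0:
        return 0.0
    d = params.E - V
    return 0.5 * params.k * d * d


def force_scale(V: float, params: BoostParameters) -> float:
    """lambda = d(V + dV)/dV = 1 - k (E - V) when V < E, else 1."""
    if V >= params.E or params.k == 0.0:
        return 1.0
    return 1.0 - params.k * (params.E - V)


def estimate_parameters(
    stats: RegionStatistics, sigma0: float, mode: str = "lower"
) -> BoostParameters:
    """Lower-bound parameter rule: E = v_max, k = k0/(v_max - v_min)."""
    if mode != "lower":
        raise ValueError("only the lower-bound threshold rule is implemented")
    if stats.n_samples < 2:
        raise ValueError("need at least 2 samples to estimate boost parameters")
    spread = stats.v_max - stats.v_min
    if spread <= 0.0:
        warnings.warn(
            "degenerate region statistics (v_max == v_min); boost disabled",
            stacklevel=2,
        )
        return BoostParameters(E=stats.v_max, k=0.0, k0=0.0, sigma0=sigma0)
    v_std = stats.v_std
    denom = stats.v_max - stats.v_avg
    if v_std == 0.0 or denom <= 0.0:
        k0 = 1.0
    else:
        k0 = min(1.0, (sigma0 / v_std) * (spread / denom))
    return BoostParameters(E=stats.v_max, k=k0 / spread, k0=k0, sigma0=sigma0)


# --------------------------------------------------------------------------
# bias providers
# --------------------------------------------------------------------------

class SelectiveBoostProvider:
    """Fixed-parameter selective boost over a validated region set.

    ``params`` maps region name -> BoostParameters for the region's
    non-dihedral energy; ``dihedral_params`` (for dual-boost regions) maps
    region name -> BoostParameters for its dihedral sub-term.  Terms not in
    any region contribute unscaled forces.
    """

    def __init__(
        self,
        region_set: RegionSet,
        params: dict,
        dihedral_params: dict | None = None,
    ):
        self.region_set = region_set
        self.params = dict(params)
        self.dihedral_params = dict(dihedral_params or {})
        self._members = []
        for r in region_set.regions:
            p = self.params.get(r.name, BoostParameters.none())
            pd = self.dihedral_params.get(r.name, BoostParameters.none())
            self._members.append(
                (r.name, np.array(r.term_slots, dtype=int),
                 np.array(r.dihedral_slots, dtype=int), r.accelerate, p, pd)
            )
        self._unassigned = np.array(region_set.unassigned_slots, dtype=int)

    def region_boosts(self, energies: np.ndarray) -> dict:
        """Per-region (dV_region, dV_dihedral) at the given term energies."""
        out = {}
        for name, slots, dslots, accel, p, pd in self._members:
            if not accel:
                out[name] = (0.0, 0.0)
                continue
            dv = boost_energy(float(energies[slots].sum()), p) if slots.size else 0.0
            dvd = (
                boost_energy(float(energies[dslots].sum()), pd)
                if dslots.size
                else 0.0
            )
            out[name] = (dv, dvd)
        return out

    def force_and_bias(self, x, energies, forces):
        total = (
            forces[self._unassigned].sum(axis=0)
            if self._unassigned.size
            else np.zeros(forces.shape[1:])
        )
        dv_total = 0.0
        dv_reg = {}
        for name, slots, dslots, accel, p, pd in self._members:
            dv = 0.0
            if slots.size:
                v = float(energies[slots].sum())
                f = forces[slots].sum(axis=0)
                if accel:
                    lam = force_scale(v, p)
                    total += lam * f
                    dv += boost_energy(v, p)
                else:
                    total += f
            if dslots.size:
                vd = float(energies[dslots].sum())
                fd = forces[dslots].sum(axis=0)
                if accel:
                    lam_d = force_scale(vd, pd)
                    total += lam_d * fd
                    dv += boost_energy(vd, pd)
                else:
                    total += fd
            dv_reg[name] = dv
            dv_total += dv
        return total, dv_total, dv_reg

    def post_step(self, x, energies):
        pass


class StatisticsProvider:
    """Unbiased run that accumulates per-region energy statistics."""

    def __init__(self, region_set: RegionSet, stats: dict | None = None,
                 dihedral_stats: dict | None = None):
        self.region_set = region_set
        self.stats = stats if stats is not None else {
            r.name: RegionStatistics() for r in region_set.regions
        }
        self.dihedral_stats = dihedral_stats if dihedral_stats is not None else {
            r.name: RegionStatistics()
            for r in region_set.regions
            if r.dihedral_slots
        }
        self._members = [
            (r.name, np.array(r.term_slots, dtype=int),
             np.array(r.dihedral_slots, dtype=int))
            for r in region_set.regions
        ]

    def force_and_bias(self, x, energies, forces):
        return forces.sum(axis=0), 0.0, {n: 0.0 for n, *_ in self._members}

    def post_step(self, x, energies):
        for name, slots, dslots in self._members:
            if slots.size:
                self.stats[name].update(float(energies[slots].sum()))
            if dslots.size:
                self.dihedral_stats[name].update(float(energies[dslots].sum()))


class AdaptiveBoostProvider(SelectiveBoostProvider):
    """Boosted search: parameters re-estimated from cumulative statistics.

    Statistics keep accumulating (on the *unbiased* region energies) while
    the boost runs; every ``update_interval`` steps the parameters are
    re-derived, so v_max/v_min are monotone over the whole search.
    """

    def __init__(
        self,
        region_set: RegionSet,
        stats: dict,
        dihedral_stats: dict,
        update_interval: int,
    ):
        self.stats = stats
        self.dihedral_stats = dihedral_stats
        self.update_interval = int(update_interval)
        if self.update_interval < 1:
            raise ValueError("update interval must be >= 1")
        self._step = 0
        params, dparams = self._estimate_all(region_set)
        super().__init__(region_set, params, dparams)

    def _estimate_all(self, region_set):
        params, dparams = {}, {}
        for r in region_set.regions:
            if not r.accelerate:
                continue
            if r.term_slots:
                params[r.name] = estimate_parameters(self.stats[r.name], r.sigma0)
            if r.dihedral_slots:
                dparams[r.name] = estimate_parameters(
                    self.dihedral_stats[r.name], r.sigma0_dihedral
                )
        return params, dparams

    def _refresh(self):
        params, dparams = self._estimate_all(self.region_set)
        self.params = params
        self.dihedral_params = dparams
        members = []
        for r in self.region_set.regions:
            p = params.get(r.name, BoostParameters.none())
            pd = dparams.get(r.name, BoostParameters.none())
            members.append(
                (r.name, np.array(r.term_slots, dtype=int),
                 np.array(r.dihedral_slots, dtype=int), r.accelerate, p, pd)
            )
        self._members = members

    def post_step(self, x, energies):
        for name, slots, dslots, _accel, _p, _pd in self._members:
            if slots.size:
                self.stats[name].update(float(energies[slots].sum()))
            if dslots.size:
                self.dihedral_stats[name].update(float(energies[dslots].sum()))
        self._step += 1
        if self._step % self.update_interval == 0:
            self._refresh()


def apply_dual_boost(
    energies: np.ndarray,
    region_set: RegionSet,
    params: dict,
    dihedral_params: dict,
) -> dict:
    """Per-region (dV_region, dV_dihedral) for given term energies.

    The total boost of a region is the sum of the two harmonic boosts;
    regions without dihedral terms get a zero dihedral sub-boost.
    """
    provider = SelectiveBoostProvider(region_set, params, dihedral_params)
    return provider.region_boosts(np.asarray(energies, dtype=float))


# --------------------------------------------------------------------------
# staged protocol
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StageLengths:
    """Steps for the unbiased search, boosted search, and production."""

    cmd: int
    search: int
    production: int

    def __post_init__(self):
        if self.cmd <= 0 or self.production <= 0:
            raise ValueError("cmd and production stage lengths must be > 0")
        if self.search < 0:
            raise ValueError("search stage length must be >= 0")


@dataclass
class ProtocolResult:
    params: dict
    dihedral_params: dict
    stats: dict
    dihedral_stats: dict
    cmd: Trajectory
    search: Trajectory | None
    production: Trajectory


def _stage_cfg(cfg: IntegratorConfig, n_steps: int, seed: int) -> IntegratorConfig:
    return IntegratorConfig(
        timestep=cfg.timestep,
        temperature=cfg.temperature,
        friction=cfg.friction,
        n_steps=n_steps,
        output_stride=cfg.output_stride,
        seed=seed,
    )


def run_protocol(
    system,
    region_set: RegionSet,
    cfg: IntegratorConfig,
    stages: StageLengths,
    update_interval: int | None = None,
    cv_func=None,
) -> ProtocolResult:
    """Three-stage selective GaMD: cMD search, adaptive search, production.

    Stage seeds are ``cfg.seed``, ``cfg.seed + 1``, ``cfg.seed + 2``; each
    stage continues from the previous stage's final phase-space point.  The
    default update interval is ``search/50`` (at least 1).
    """
    if update_interval is None:
        update_interval = max(1, stages.search // 50)
    if stages.search and update_interval > stages.search:
        raise ValueError("update interval exceeds the search stage length")

    collector = StatisticsProvider(region_set)
    cmd_traj = run(
        system, _stage_cfg(cfg, stages.cmd, cfg.seed), bias=collector,
        cv_func=cv_func,
    )
    stats, dstats = collector.stats, collector.dihedral_stats

    search_traj = None
    if stages.search > 0:
        adaptive = AdaptiveBoostProvider(region_set, stats, dstats, update_interval)
        search_traj = run(
            system,
            _stage_cfg(cfg, stages.search, cfg.seed + 1),
            bias=adaptive,
            cv_func=cv_func,
            x0=cmd_traj.final_positions,
            v0=cmd_traj.final_velocities,
        )
        params, dparams = adaptive.params, adaptive.dihedral_params
    else:
        tmp = AdaptiveBoostProvider(region_set, stats, dstats, 1)
        params, dparams = tmp.params, tmp.dihedral_params

    start = search_traj if search_traj is not None else cmd_traj
    production = run(
        system,
        _stage_cfg(cfg, stages.production, cfg.seed + 2),
        bias=SelectiveBoostProvider(region_set, params, dparams),
        cv_func=cv_func,
        x0=start.final_positions,
        v0=start.final_velocities,
    )
    return ProtocolResult(
        params=params,
        dihedral_params=dparams,
        stats=stats,
        dihedral_stats=dstats,
        cmd=cmd_traj,
        search=search_traj,
        production=production,
    )


# --------------------------------------------------------------------------
# monolithic single-boost reference
# --------------------------------------------------------------------------

class _MonolithicStats:
    """Scalar running statistics for the reference implementation."""

    def __init__(self):
        self.n = 0
        self.mean = 0.0
        self.m2 = 0.0
        self.vmin = math.inf
        self.vmax = -math.inf

    def add(self, v: float) -> None:
        self.n += 1
        d = v - self.mean
        self.mean += d / self.n
        self.m2 += d * (v - self.mean)
        if v < self.vmin:
            self.vmin = v
        if v > self.vmax:
            self.vmax = v

    def suggest(self, sigma0: float):
        spread = self.vmax - self.vmin
        if spread <= 0.0:
            return self.vmax, 0.0
        std = math.sqrt(self.m2 / self.n)
        denom = self.vmax - self.mean
        if std == 0.0 or denom <= 0.0:
            k0 = 1.0
        else:
            k0 = min(1.0, (sigma0 / std) * (spread / denom))
        return self.vmax, k0 / spread


class _MonolithicCollector:
    def __init__(self, stats: _MonolithicStats):
        self.stats = stats

    def force_and_bias(self, x, energies, forces):
        return forces.sum(axis=0), 0.0, {"total": 0.0}

    def post_step(self, x, energies):
        self.stats.add(float(energies.sum()))


class _MonolithicBoost:
    """Single boost on the total potential; optionally adaptive."""

    def __init__(self, E, k, stats=None, sigma0=0.0, update_interval=0):
        self.E = E
        self.k = k
        self.stats = stats
        self.sigma0 = sigma0
        self.update_interval = update_interval
        self._step = 0

    def force_and_bias(self, x, energies, forces):
        v = float(energies.sum())
        f = forces.sum(axis=0)
        if v >= self.E or self.k == 0.0:
            return f, 0.0, {"total": 0.0}
        d = self.E - v
        dv = 0.5 * self.k * d * d
        return (1.0 - self.k * d) * f, dv, {"total": dv}

    def post_step(self, x, energies):
        if self.stats is None:
            return
        self.stats.add(float(energies.sum()))
        self._step += 1
        if self.update_interval and self._step % self.update_interval == 0:
            self.E, self.k = self.stats.suggest(self.sigma0)


def run_standard_gamd(
    system,
    cfg: IntegratorConfig,
    stages: StageLengths,
    sigma0: float = 10.0,
    update_interval: int | None = None,
    cv_func=None,
):
    """Reference non-selective GaMD: one boost on the whole potential.

    Written with its own scalar bookkeeping, independent of the region
    machinery, as the comparison point for the single-region equivalence
    property.  Stage seeds follow the same convention as ``run_protocol``.
    """
    if update_interval is None:
        update_interval = max(1, stages.search // 50)
    stats = _MonolithicStats()
    cmd_traj = run(
        system, _stage_cfg(cfg, stages.cmd, cfg.seed),
        bias=_MonolithicCollector(stats), cv_func=cv_func,
    )
    E, k = stats.suggest(sigma0)
    search_traj = None
    if stages.search > 0:
        adaptive = _MonolithicBoost(E, k, stats, sigma0, update_interval)
        search_traj = run(
            system, _stage_cfg(cfg, stages.search, cfg.seed + 1),
            bias=adaptive, cv_func=cv_func,
            x0=cmd_traj.final_positions, v0=cmd_traj.final_velocities,
        )
        E, k = adaptive.E, adaptive.k
    start = search_traj if search_traj is not None else cmd_traj
    production = run(
        system, _stage_cfg(cfg, stages.production, cfg.seed + 2),
        bias=_MonolithicBoost(E, k), cv_func=cv_func,
        x0=start.final_positions, v0=start.final_velocities,
    )
    return (E, k), cmd_traj, search_traj, production
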