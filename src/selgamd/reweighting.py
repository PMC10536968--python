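"""Free-energy recovery from boosted sampling.

Given per-frame CV values and the total boost energy dV, the unbiased
probability of CV bin j follows from the ensemble average of exp(beta*dV)
restricted to the bin.  Two estimators are provided:

* exponential averaging -- p(j) proportional to p_biased(j) * <exp(beta dV)>_j,
  exact but noisy when a few large boosts dominate;
* cumulant expansion to second order -- p(j) proportional to
  p_biased(j) * exp(beta*<dV>_j + beta^2*var(dV)_j/2), exact when the
  per-bin boost distribution is Gaussian and far more robust to noise.

The anharmonicity gamma = S_gauss - S_empirical (the entropy deficit of the
boost distribution relative to a Gaussian of the same variance) is the
standard reliability diagnostic: gamma near 0 means the cumulant expansion
can be trusted.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import KB

__all__ = [
    "BiasedSamples",
    "FreeEnergySurface",
    "BoostSummary",
    "pmf_cumulant",
    "pmf_exponential",
    "anharmonicity",
    "boost_summary",
]


@dataclass
class BiasedSamples:
    """Per-frame CV values and total boost energies, the unit of reweighting."""

    time: np.ndarray
    cv: np.ndarray  # (n, d)
    delta_v: np.ndarray  # (n,)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.cv = np.atleast_2d(np.asarray(self.cv, dtype=float))
        if self.cv.shape[0] != self.time.shape[0]:
            self.cv = self.cv.T
        self.delta_v = np.asarray(self.delta_v, dtype=float)
        if (self.delta_v < -1e-12).any():
            raise ValueError("boost energies must be non-negative")

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_cv(self) -> int:
        return self.cv.shape[1]

    @classmethod
    def from_trajectory(cls, traj) -> "BiasedSamples":
        if traj.cv is None:
            raise ValueError("trajectory carries no CV series")
        return cls(time=traj.times, cv=traj.cv, delta_v=traj.total_dv)


@dataclass
class FreeEnergySurface:
    """Binned PMF: -kB*T*ln p on the CV grid, anchored to 0 at its minimum.

    Empty bins carry NaN.  ``reliable`` marks bins with at least
    ``reliable_threshold`` biased samples; the threshold is reported, not
    enforced.
    """

    bin_edges: list
    pmf: np.ndarray
    counts: np.ndarray
    temperature: float
    reliable_threshold: int = 10

    @property
    def centers(self) -> list:
        return [0.5 * (e[1:] + e[:-1]) for e in self.bin_edges]

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    @property
    def reliable(self) -> np.ndarray:
        return self.counts >= self.reliable_threshold


def _bin_samples(samples: BiasedSamples, bins, range=None):
    counts, edges = np.histogramdd(samples.cv, bins=bins, range=range)
    flat_idx = np.full(samples.n, -1, dtype=int)
    idx_nd = []
    ok = np.ones(samples.n, dtype=bool)
    for d, e in enumerate(edges):
        i = np.searchsorted(e, samples.cv[:, d], side="right") - 1
        # histogramdd puts values equal to the last edge into the last bin
        i = np.where(samples.cv[:, d] == e[-1], len(e) - 2, i)
        ok &= (i >= 0) & (i < len(e) - 1)
        idx_nd.append(i)
    shape = tuple(len(e) - 1 for e in edges)
    flat_idx[ok] = np.ravel_multi_index(
        tuple(i[ok] for i in idx_nd), shape
    )
    return counts, edges, flat_idx, ok, shape


def _finish(log_w, counts, edges, temperature) -> FreeEnergySurface:
    kt = KB * temperature
    pmf = np.where(counts > 0, -kt * log_w, np.nan)
    occ = counts > 0
    pmf = pmf - np.nanmin(pmf[occ])
    return FreeEnergySurface(
        bin_edges=list(edges), pmf=pmf, counts=counts.astype(int),
        temperature=temperature,
    )


def _check_inputs(samples: BiasedSamples, temperature: float) -> None:
    if samples.n == 0:
        raise ValueError("no samples to reweight")
    if temperature <= 0:
        raise ValueError("temperature must be positive")


def pmf_cumulant(
    samples: BiasedSamples,
    bins=36,
    temperature: float = 300.0,
    range=None,
) -> FreeEnergySurface:
    """Second-order cumulant-expansion reweighted PMF.

    Per occupied bin j: p(j) proportional to
    p_biased(j) * exp(beta*mean(dV|j) + beta^2*var(dV|j)/2); var is the
    population variance.  The PMF is anchored to 0 at its occupied minimum.
    """
    _check_inputs(samples, temperature)
    b = 1.0 / (KB * temperature)
    counts, edges, flat, ok, shape = _bin_samples(samples, bins, range)
    nbins = int(np.prod(shape))
    s1 = np.bincount(flat[ok], weights=samples.delta_v[ok], minlength=nbins)
    s2 = np.bincount(
        flat[ok], weights=samples.delta_v[ok] ** 2, minlength=nbins
    )
    cnt = np.bincount(flat[ok], minlength=nbins).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = s1 / cnt
        var = np.maximum(s2 / cnt - mean**2, 0.0)
        log_w = np.log(cnt / cnt.sum()) + b * mean + 0.5 * b * b * var
    return _finish(log_w.reshape(shape), counts, edges, temperature)


def pmf_exponential(
    samples: BiasedSamples,
    bins=36,
    temperature: float = 300.0,
    range=None,
) -> FreeEnergySurface:
    """Exponential-averaging reweighted PMF.

    Per occupied bin j: p(j) proportional to
    p_biased(j) * mean(exp(beta*dV) | j), evaluated with the per-bin
    maximum subtracted before exponentiation to avoid overflow.
    """
    _check_inputs(samples, temperature)
    b = 1.0 / (KB * temperature)
    counts, edges, flat, ok, shape = _bin_samples(samples, bins, range)
    nbins = int(np.prod(shape))
    dv = samples.delta_v[ok]
    fi = flat[ok]
    dv_max = np.full(nbins, -np.inf)
    np.maximum.at(dv_max, fi, dv)
    shifted = np.exp(b * (dv - dv_max[fi]))
    s = np.bincount(fi, weights=shifted, minlength=nbins)
    cnt = np.bincount(fi, minlength=nbins).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_w = np.log(cnt / cnt.sum()) + b * dv_max + np.log(s / cnt)
    return _finish(log_w.reshape(shape), counts, edges, temperature)


def anharmonicity(delta_v, min_samples: int = 100) -> float:
    """Entropy deficit of the boost distribution relative to a Gaussian.

    gamma = S_gauss - S_empirical with S_gauss = 0.5*ln(2*pi*e*var) and
    S_empirical the differential entropy of a Freedman-Diaconis histogram
    of the samples.  gamma is ~0 for near-Gaussian boosts and grows with
    multimodality or heavy tails; by construction the population value is
    non-negative, so the estimate is clipped at 0 (small negative values
    are estimator noise).
    """
    dv = np.asarray(delta_v, dtype=float).ravel()
    if dv.size < min_samples:
        raise ValueError(f"need at least {min_samples} samples")
    var = dv.var()
    if var == 0.0 or dv.max() == dv.min():
        warnings.warn(
            "degenerate (constant) boost distribution; anharmonicity := 0",
            stacklevel=2,
        )
        return 0.0
    s_gauss = 0.5 * math.log(2.0 * math.pi * math.e * var)

    q75, q25 = np.percentile(dv, [75, 25])
    iqr = q75 - q25
    width = 2.0 * iqr / dv.size ** (1.0 / 3.0)
    if width <= 0.0:
        width = 3.5 * math.sqrt(var) / dv.size ** (1.0 / 3.0)
    n_bins = max(1, int(math.ceil((dv.max() - dv.min()) / width)))
    counts, _ = np.histogram(dv, bins=n_bins)
    p = counts[counts > 0] / dv.size
    s_emp = -np.sum(p * np.log(p)) + math.log(width)
    return max(0.0, s_gauss - s_emp)


@dataclass(frozen=True)
class BoostSummary:
    """Mean and population standard deviation of the boost, kJ/mol."""

    mean: float
    std: float
    n: int

    def __str__(self) -> str:
        return f"{self.mean:.1f} ± {self.std:.1f} kJ/mol"


def boost_summary(delta_v) -> BoostSummary:
    """Sample mean +- population standard deviation of the boost energy."""
    dv = np.asarray(delta_v, dtype=float).ravel()
    if dv.size == 0:
        raise ValueError("empty boost series")
    return BoostSummary(mean=float(dv.mean()), std=float(dv.std()), n=dv.size)
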