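"""Spatial correlation structure of avalanche patterns and model comparison.

The pairwise correlation of -1/+1 avalanche patterns,

    G_ij = <sigma_i sigma_j> - <sigma_i><sigma_j>,

is grouped by inter-site distance and normalized by its nearest-neighbor
value; a slow (power-law, exponent near zero) decay of G with distance is the
long-range-correlation signature of a critical system.  The decay exponent is
fit by least squares in log-log coordinates, since the normalized correlation
function is not a probability distribution.

Model-vs-counting comparison: pattern probabilities estimated by a
dichotomized-Gaussian fit versus direct counting are scored against held-out
data with the Jensen-Shannon divergence (base-2 logs, so disjoint supports
score exactly 1) under 2-fold cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .dg import dg_pattern_distribution, fit_dg_from_patterns
from .patterns import PatternDistribution, distribution_from_patterns

__all__ = [
    "CorrelationFunction",
    "CorrelationDecayFit",
    "CrossValResult",
    "correlation_function",
    "fit_correlation_decay",
    "js_divergence",
    "crossval_model_comparison",
]


@dataclass
class CorrelationFunction:
    """Mean pairwise covariance per inter-site distance bin, normalized at the
    smallest distance."""

    distances: np.ndarray
    g_values: np.ndarray
    normalization_distance: float

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.g_values = np.asarray(self.g_values, dtype=float)
        if self.distances.shape != self.g_values.shape:
            raise ValueError("distances and values must align")
        if np.any(self.distances <= 0) or np.any(np.diff(self.distances) <= 0):
            raise ValueError("distances must be positive and increasing")


@dataclass
class CorrelationDecayFit:
    """Log-log least-squares line through the correlation function."""

    exponent: float
    intercept: float
    residual: float
    n_points: int


def correlation_function(patterns: np.ndarray,
                         coords: np.ndarray) -> CorrelationFunction:
    """G(r) from -1/+1 pattern samples and per-channel coordinates.

    Pairs are grouped by their distance rounded to 3 decimals (electrode
    grids have discrete spacings); the per-bin mean covariance is normalized
    by the smallest-distance bin.  Zero-variance channels are skipped with a
    warning.
    """
    patterns = np.asarray(patterns, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if patterns.ndim != 2 or patterns.shape[0] < 2:
        raise ValueError("need >= 2 pattern samples")
    n = patterns.shape[1]
    if coords.shape[0] != n or n < 2:
        raise ValueError("need coordinates for >= 2 channels")

    var = patterns.var(axis=0)
    keep = var > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} zero-variance channel(s) skipped", stacklevel=2)
    idx = np.flatnonzero(keep)
    if idx.size < 2:
        raise ValueError("fewer than 2 channels with variance")

    G = np.cov(patterns[:, idx], rowvar=False, bias=True)
    ii, jj = np.triu_indices(idx.size, k=1)
    d = np.linalg.norm(coords[idx[ii]] - coords[idx[jj]], axis=1)
    d = np.round(d, 3)
    g = G[ii, jj]
    dist_bins = np.unique(d)
    g_mean = np.array([g[d == r].mean() for r in dist_bins])
    g0 = g_mean[0]
    if g0 == 0:
        raise ValueError("nearest-neighbor covariance is zero; cannot normalize")
    return CorrelationFunction(dist_bins, g_mean / g0, float(dist_bins[0]))


def fit_correlation_decay(cf: CorrelationFunction,
                          r_min: Optional[float] = None) -> CorrelationDecayFit:
    """Least-squares line in log-log coordinates over bins with r >= r_min.

    Non-positive G values in range are excluded with a warning; fewer than 3
    remaining points is an error.
    """
    mask = np.ones(cf.distances.size, dtype=bool)
    if r_min is not None:
        mask &= cf.distances >= r_min
    pos = cf.g_values > 0
    if np.any(mask & ~pos):
        warnings.warn(
            f"{int((mask & ~pos).sum())} non-positive correlation value(s) "
            f"excluded from the log-log fit", stacklevel=2)
    mask &= pos
    if mask.sum() < 3:
        raise ValueError("need >= 3 positive points for the decay fit")
    logr = np.log10(cf.distances[mask])
    logg = np.log10(cf.g_values[mask])
    A = np.vstack([logr, np.ones_like(logr)]).T
    (slope, intercept), res, *_ = np.linalg.lstsq(A, logg, rcond=None)
    residual = float(res[0]) if res.size else 0.0
    return CorrelationDecayFit(float(slope), float(intercept), residual,
                               int(mask.sum()))


def js_divergence(p: PatternDistribution, q: PatternDistribution) -> float:
    """Jensen-Shannon divergence in bits: JS = (KL(p||m) + KL(q||m))/2, m=(p+q)/2."""
    if p.n_units != q.n_units:
        raise ValueError("distributions must have the same number of units")
    pv, qv = p.probabilities, q.probabilities
    m = 0.5 * (pv + qv)

    def _kl(a: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / m[mask])))

    return 0.5 * _kl(pv) + 0.5 * _kl(qv)


@dataclass
class CrossValResult:
    """Paired held-out JS divergences: DG model vs direct counting."""

    js_dg: np.ndarray
    js_counting: np.ndarray

    @property
    def dg_wins(self) -> int:
        """Folds where the DG model is closer to held-out data than counting."""
        return int(np.sum(self.js_dg < self.js_counting))

    @property
    def n_folds(self) -> int:
        return self.js_dg.size


def crossval_model_comparison(patterns: np.ndarray, subset_size: Optional[int] = None,
                              seed: int = 0, tolerance: float = 1e-6) -> CrossValResult:
    """2-fold cross-validated comparison of DG-fit vs counting estimates.

    Samples (projected onto the first ``subset_size`` units if given) are
    split in half at random; per fold, pattern probabilities estimated on the
    training half by direct counting and by a DG fit are scored with the JS
    divergence against the held-out empirical distribution.
    """
    patterns = np.asarray(patterns)
    if subset_size is not None:
        patterns = patterns[:, :subset_size]
    n_units = patterns.shape[1]
    n_samples = patterns.shape[0]
    if n_samples < 4:
        raise ValueError("need at least 4 samples for 2-fold cross-validation")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    halves = [perm[: n_samples // 2], perm[n_samples // 2:]]

    js_dg, js_count = [], []
    for fold in range(2):
        train = patterns[halves[fold]]
        test = patterns[halves[1 - fold]]
        test_dist = distribution_from_patterns(test, n_units)
        count_dist = distribution_from_patterns(train, n_units)
        dg_dist = dg_pattern_distribution(
            fit_dg_from_patterns(train), tolerance=tolerance, seed=seed)
        js_count.append(js_divergence(count_dist, test_dist))
        js_dg.append(js_divergence(dg_dist, test_dist))
    return CrossValResult(np.asarray(js_dg), np.asarray(js_count))
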