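"""Binary spatial-pattern conventions shared across the package.

A spatial pattern sigma is a vector in {-1, +1}^n marking which channels
participate in an avalanche.  Distributions over all 2^n patterns are stored
as flat probability vectors with the index convention

    bit j of the index set  <=>  sigma_j = +1,   channel 0 = least significant bit,

so index 0 is the quiescent (all -1) state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PatternDistribution",
    "pattern_matrix",
    "pattern_sizes",
    "pattern_index",
]


def pattern_matrix(n_units: int) -> np.ndarray:
    """All 2^n patterns as a (2^n, n) array of -1/+1 (int8), row i = pattern i."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    idx = np.arange(2**n_units, dtype=np.int64)
    bits = (idx[:, None] >> np.arange(n_units)) & 1
    return (2 * bits - 1).astype(np.int8)


def pattern_sizes(n_units: int) -> np.ndarray:
    """Number of +1 entries (active channels) of every pattern index."""
    idx = np.arange(2**n_units, dtype=np.int64)
    sizes = np.zeros_like(idx)
    for j in range(n_units):
        sizes += (idx >> j) & 1
    return sizes


def pattern_index(sigma: np.ndarray) -> int:
    """Index of a single -1/+1 pattern under the package convention."""
    sigma = np.asarray(sigma)
    active = (sigma > 0).astype(np.int64)
    return int((active << np.arange(sigma.size)).sum())


@dataclass
class PatternDistribution:
    """Probability vector over all 2^n spatial patterns (quiescent included).

    Parameters
    ----------
    probabilities : array of length 2^n, non-negative, summing to 1.
    n_units : number of channels n.
    """

    probabilities: np.ndarray
    n_units: int

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 1:
            raise ValueError("probabilities must be a flat vector")
        if self.probabilities.size != 2**self.n_units:
            raise ValueError(
                f"expected {2**self.n_units} probabilities for n={self.n_units}, "
                f"got {self.probabilities.size}"
            )
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")
        total = self.probabilities.sum()
        if not np.isfinite(total) or abs(total - 1.0) > 1e-8:
            raise ValueError(f"probabilities must sum to 1 (got {total!r})")

    # -- convenience views ------------------------------------------------
    @property
    def p0(self) -> float:
        """Probability of the quiescent (all inactive) state."""
        return float(self.probabilities[0])

    def patterns(self) -> np.ndarray:
        return pattern_matrix(self.n_units)

    def sizes(self) -> np.ndarray:
        return pattern_sizes(self.n_units)

    def rates(self) -> np.ndarray:
        """Per-unit activation probability P(sigma_j = +1)."""
        active = (self.patterns() > 0)
        return self.probabilities @ active

    def indicator_covariance(self) -> np.ndarray:
        """Covariance matrix of the 0/1 activity indicators."""
        y = (self.patterns() > 0).astype(float)
        mean = self.probabilities @ y
        second = (y * self.probabilities[:, None]).T @ y
        return second - np.outer(mean, mean)

    def sign_covariance(self) -> np.ndarray:
        """Covariance of the -1/+1 coded patterns (4x the indicator covariance)."""
        return 4.0 * self.indicator_covariance()

    def size_marginal(self, include_quiescent: bool = True) -> np.ndarray:
        """Probability of each pattern size 0..n (or 1..n renormalized)."""
        marg = np.bincount(self.sizes(), weights=self.probabilities,
                           minlength=self.n_units + 1)
        if not include_quiescent:
            marg = marg[1:]
            total = marg.sum()
            if total <= 0:
                raise ValueError("all probability mass on the quiescent state")
            marg = marg / total
        return marg

    def marginal(self, subset) -> "PatternDistribution":
        """Exact marginal distribution over a subset of units (brute-force sum).

        subset order defines the bit order of the result (subset[0] -> LSB).
        """
        subset = list(subset)
        pats = self.patterns()
        k = len(subset)
        idx = np.zeros(self.probabilities.size, dtype=np.int64)
        for b, j in enumerate(subset):
            idx += ((pats[:, j] > 0).astype(np.int64)) << b
        probs = np.bincount(idx, weights=self.probabilities, minlength=2**k)
        return PatternDistribution(probs, k)


def distribution_from_patterns(samples: np.ndarray, n_units: int) -> PatternDistribution:
    """Empirical pattern distribution from an array of -1/+1 samples (rows)."""
    samples = np.asarray(samples)
    if samples.ndim != 2 or samples.shape[1] != n_units:
        raise ValueError("samples must be (n_samples, n_units)")
    active = (samples > 0).astype(np.int64)
    idx = active @ (1 << np.arange(n_units, dtype=np.int64))
    counts = np.bincount(idx, minlength=2**n_units).astype(float)
    return PatternDistribution(counts / counts.sum(), n_units)
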