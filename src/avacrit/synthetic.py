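"""Synthetic generators for every input the analysis pipeline needs.

Covers the validation models used throughout the analysis:

* ring-configured dichotomized-Gaussian ensembles whose latent covariance
  decays as a Gaussian function of ring distance (criticality is approached
  as the decay width omega -> infinity),
* a critical branching-process avalanche simulator (mean offspring 1 gives
  the -3/2 power law in avalanche size, with a cutoff set by channel count),
* independent-Poisson surrogate rasters at matched per-channel rates,
* per-channel time shuffles, and
* exact discrete power-law samplers for fitter fixtures.

All generators take explicit seeds; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri

from .avalanche import BinnedRaster
from .dg import DGParams

__all__ = [
    "RingModelSpec",
    "BranchingSpec",
    "ring_dg_params",
    "ring_distances",
    "simulate_branching",
    "poisson_surrogate",
    "shuffle_raster",
    "sample_discrete_powerlaw",
]


@dataclass
class RingModelSpec:
    """Units on a ring; latent covariance decays as a Gaussian of ring distance.

    lambda_max is the covariance amplitude in [0, 1); omega the Gaussian decay
    width in ring-distance units (math.inf for the exchangeable, critical
    limit in which every pair shares the same covariance); rate the per-unit
    activation probability.
    """

    n_units: int
    lambda_max: float
    omega: float
    rate: float

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ValueError("n_units must be >= 2")
        if not 0.0 <= self.lambda_max < 1.0:
            raise ValueError("lambda_max must lie in [0, 1)")
        if not (self.omega > 0 or math.isinf(self.omega)):
            raise ValueError("omega must be positive or infinite")
        if not 0.0 < self.rate < 1.0:
            raise ValueError("rate must lie in (0, 1)")


@dataclass
class BranchingSpec:
    """Branching-process cascade over a finite set of channels."""

    n_channels: int
    branching_ratio: float
    n_avalanches: int
    max_duration: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.n_avalanches < 1 or self.max_duration < 1:
            raise ValueError("counts must be positive")
        if self.branching_ratio < 0:
            raise ValueError("branching_ratio must be >= 0")


def ring_distances(n_units: int) -> np.ndarray:
    """Pairwise wrap-around distances r_ij = min(|i-j|, n-|i-j|), adjacent = 1."""
    idx = np.arange(n_units)
    diff = np.abs(idx[:, None] - idx[None, :])
    return np.minimum(diff, n_units - diff)


def ring_dg_params(spec: RingModelSpec) -> DGParams:
    """DG parameters of the ring model.

    delta_i = Phi^{-1}(rate); Lambda_ij = lambda_max * exp(-(r_ij/omega)^2/2)
    with unit diagonal.  A non-positive-semidefinite Lambda (possible at large
    lambda_max with small omega) raises rather than being silently repaired:
    synthetic specs should be valid by construction.
    """
    n = spec.n_units
    delta = np.full(n, ndtri(spec.rate))
    if math.isinf(spec.omega):
        factor = np.ones((n, n))
    else:
        r = ring_distances(n)
        factor = np.exp(-0.5 * (r / spec.omega) ** 2)
    Lam = spec.lambda_max * factor
    np.fill_diagonal(Lam, 1.0)
    smallest = float(np.linalg.eigvalsh(Lam)[0])
    if smallest < -1e-10:
        raise ValueError(
            f"ring covariance is not positive semidefinite "
            f"(smallest eigenvalue {smallest:.3e}); "
            f"reduce lambda_max or increase omega"
        )
    return DGParams(delta, Lam)


def simulate_branching(spec: BranchingSpec) -> tuple[np.ndarray, BinnedRaster]:
    """Simulate branching-process avalanches and assemble them into a raster.

    Each avalanche starts with one active unit on a uniformly random channel.
    At each subsequent bin every active unit independently attempts to
    activate units among the currently inactive channels, with per-channel
    probability branching_ratio / n_available (binomial thinning; expected
    descendants per parent equal the branching ratio up to the finite-channel
    cap).  Draws from different parents targeting the same channel merge,
    which produces the system-size cutoff of the size distribution.  The
    avalanche ends when no unit is active or max_duration is reached; its
    size is the total number of (channel, bin) activations.  Consecutive
    avalanches are separated by one empty bin in the emitted raster.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_channels
    sizes = np.empty(spec.n_avalanches, dtype=np.int64)
    blocks: list[np.ndarray] = []
    for a in range(spec.n_avalanches):
        active = np.zeros(n, dtype=bool)
        active[rng.integers(n)] = True
        cols = [active.copy()]
        size = 1
        for _ in range(spec.max_duration - 1):
            inactive = np.flatnonzero(~active)
            n_avail = inactive.size
            if n_avail == 0:
                break
            n_active = int(active.sum())
            p = min(spec.branching_ratio / n_avail, 1.0)
            # union of independent per-parent binomial draws over the
            # available channels: each is hit with prob 1 - (1-p)^n_active
            hit = rng.random(n_avail) < -np.expm1(n_active * np.log1p(-p)) \
                if p < 1.0 else np.ones(n_avail, dtype=bool)
            if not hit.any():
                break
            active = np.zeros(n, dtype=bool)
            active[inactive[hit]] = True
            cols.append(active.copy())
            size += int(hit.sum())
        sizes[a] = size
        blocks.append(np.column_stack(cols))

    n_bins = sum(b.shape[1] for b in blocks) + len(blocks)
    occ = np.zeros((n, n_bins), dtype=bool)
    t = 0
    for b in blocks:
        occ[:, t:t + b.shape[1]] = b
        t += b.shape[1] + 1  # one empty separator bin
    return sizes, BinnedRaster(occ, bin_width_ms=1.0)


def poisson_surrogate(rates, n_bins: int, seed: int) -> BinnedRaster:
    """Independent Bernoulli occupancy per channel and bin at the given rates."""
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    if np.any(rates < 0) or np.any(rates > 1):
        raise ValueError("rates must lie in [0, 1]")
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    rng = np.random.default_rng(seed)
    occ = rng.random((rates.size, n_bins)) < rates[:, None]
    return BinnedRaster(occ, bin_width_ms=1.0)


def shuffle_raster(raster: BinnedRaster, seed: int) -> BinnedRaster:
    """Permute each channel's bin occupancy independently in time.

    Per-channel event counts are conserved exactly; cross-channel correlations
    are destroyed.
    """
    if raster.n_bins == 0:
        raise ValueError("raster is empty")
    rng = np.random.default_rng(seed)
    occ = raster.occupancy.copy()
    for ch in range(raster.n_channels):
        occ[ch] = occ[ch, rng.permutation(raster.n_bins)]
    return BinnedRaster(occ, raster.bin_width_ms)


def sample_discrete_powerlaw(exponent: float, s_max: int, n_samples: int,
                             seed: int) -> np.ndarray:
    """I.i.d. samples from P(s) proportional to s^exponent on {1, ..., s_max}."""
    if exponent >= 0:
        raise ValueError("exponent must be negative")
    if s_max < 2:
        raise ValueError("s_max must be >= 2")
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    support = np.arange(1, s_max + 1, dtype=float)
    logp = exponent * np.log(support)
    logp -= logp.max()
    pmf = np.exp(logp)
    pmf /= pmf.sum()
    rng = np.random.default_rng(seed)
    return rng.choice(np.arange(1, s_max + 1), size=n_samples, p=pmf)
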