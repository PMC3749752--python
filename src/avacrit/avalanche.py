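"""Avalanche extraction from continuous recordings or binary event rasters.

The processing chain mirrors the standard nLFP workflow: threshold-crossing
event detection on each channel (one event per sub-threshold excursion, at
the excursion minimum), binning of event times into windows of width dt,
extraction of avalanches as maximal runs of consecutive occupied bins, and
collapse of each avalanche to its spatial pattern sigma in {-1, +1}^n.

Avalanche-size distributions are fit with a discrete power law normalized on
the observed support by minimizing the Kolmogorov-Smirnov distance

    D_KS = max_s | CDF_emp(s) - CDF_powerlaw(s) |.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .patterns import PatternDistribution

__all__ = [
    "SignalMatrix",
    "EventRaster",
    "BinnedRaster",
    "Avalanche",
    "SizeDistribution",
    "PowerLawFit",
    "SegmentStability",
    "detect_nlfps",
    "bin_events",
    "extract_avalanches",
    "avalanche_sizes",
    "empirical_pattern_distribution",
    "fit_power_law",
    "segment_stability",
]

logger = logging.getLogger(__name__)


@dataclass
class SignalMatrix:
    """Continuous multichannel recording: channels x samples, with sampling rate."""

    values: np.ndarray
    sampling_rate: float
    channel_coords: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal values must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.channel_coords is not None:
            self.channel_coords = np.asarray(self.channel_coords, dtype=float)
            if len(self.channel_coords) != self.values.shape[0]:
                raise ValueError("one coordinate pair per channel required")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class EventRaster:
    """Detected events as (channel, sample-index) pairs."""

    channels: np.ndarray
    samples: np.ndarray
    n_channels: int
    sampling_rate: float
    n_samples: Optional[int] = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.int64)
        self.samples = np.asarray(self.samples, dtype=np.int64)
        if self.channels.shape != self.samples.shape:
            raise ValueError("channels and samples must align")
        if self.channels.size and (self.channels.min() < 0
                                   or self.channels.max() >= self.n_channels):
            raise ValueError("channel index out of range")
        if self.n_samples is not None and self.samples.size \
                and self.samples.max() >= self.n_samples:
            raise ValueError("sample index beyond recording length")
        order = np.lexsort((self.samples, self.channels))
        self.channels = self.channels[order]
        self.samples = self.samples[order]

    @property
    def n_events(self) -> int:
        return self.channels.size


@dataclass
class BinnedRaster:
    """Boolean channels x bins occupancy matrix at bin width dt (ms)."""

    occupancy: np.ndarray
    bin_width_ms: float

    def __post_init__(self) -> None:
        self.occupancy = np.atleast_2d(np.asarray(self.occupancy, dtype=bool))
        if self.bin_width_ms <= 0:
            raise ValueError("bin width must be positive")

    @property
    def n_channels(self) -> int:
        return self.occupancy.shape[0]

    @property
    def n_bins(self) -> int:
        return self.occupancy.shape[1]

    @property
    def event_count(self) -> int:
        return int(self.occupancy.sum())


@dataclass
class Avalanche:
    """A maximal run of consecutive occupied bins, with its spatial pattern."""

    start_bin: int
    duration_bins: int
    events: np.ndarray  # channels x duration boolean submatrix
    size: int
    pattern: np.ndarray  # -1/+1 over channels

    @classmethod
    def from_submatrix(cls, start_bin: int, sub: np.ndarray) -> "Avalanche":
        sub = np.asarray(sub, dtype=bool)
        pattern = np.where(sub.any(axis=1), 1, -1).astype(np.int8)
        return cls(start_bin=start_bin, duration_bins=sub.shape[1],
                   events=sub, size=int(sub.sum()), pattern=pattern)


@dataclass
class SizeDistribution:
    """Empirical (or model) probability distribution over avalanche sizes >= 1."""

    sizes: np.ndarray
    probabilities: np.ndarray
    sample_count: int

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.sizes.shape != self.probabilities.shape:
            raise ValueError("sizes and probabilities must align")
        if np.any(self.sizes < 1):
            raise ValueError("sizes must be >= 1")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-8:
            raise ValueError("probabilities must sum to 1")

    @classmethod
    def from_samples(cls, samples: Sequence[int]) -> "SizeDistribution":
        samples = np.asarray(samples, dtype=np.int64)
        if samples.size == 0:
            raise ValueError("no sizes supplied")
        sizes, counts = np.unique(samples, return_counts=True)
        return cls(sizes, counts / counts.sum(), int(samples.size))


@dataclass
class PowerLawFit:
    """KS-minimizing discrete power-law fit on the observed support."""

    exponent: float
    ks_distance: float
    fit_support: tuple[int, int]


# ---------------------------------------------------------------------------
# detection / binning / extraction


def detect_nlfps(signal: SignalMatrix, threshold_sd: float = -2.5) -> EventRaster:
    """Detect negative-deflection events at a per-channel SD threshold.

    The threshold is ``mean + threshold_sd * SD`` of each channel's full trace
    (threshold_sd < 0 by convention, e.g. -2.5 for LFP, -3.0 for MEG).  One
    event is emitted per contiguous sub-threshold excursion, at the sample of
    its minimum (earliest sample on ties).
    """
    if threshold_sd >= 0:
        raise ValueError("threshold_sd must be negative (negative-deflection convention)")
    sd = signal.values.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"channel {zero[0]} has zero standard deviation")
    thresh = signal.values.mean(axis=1) + threshold_sd * sd

    ch_idx: list[int] = []
    sample_idx: list[int] = []
    for ch in range(signal.n_channels):
        below = signal.values[ch] < thresh[ch]
        if not below.any():
            continue
        edges = np.diff(below.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if below[0]:
            starts = np.r_[0, starts]
        if below[-1]:
            ends = np.r_[ends, below.size]
        for s, e in zip(starts, ends):
            sample_idx.append(s + int(np.argmin(signal.values[ch, s:e])))
            ch_idx.append(ch)
    return EventRaster(np.asarray(ch_idx), np.asarray(sample_idx),
                       n_channels=signal.n_channels,
                       sampling_rate=signal.sampling_rate,
                       n_samples=signal.n_samples)


def bin_events(raster: EventRaster, bin_width_ms: float = 2.0) -> BinnedRaster:
    """Bin event times into half-open windows [k dt, (k+1) dt), 0-based."""
    if bin_width_ms <= 0:
        raise ValueError("bin width must be positive")
    times_ms = raster.samples / raster.sampling_rate * 1000.0
    bins = np.floor(times_ms / bin_width_ms).astype(np.int64)
    if raster.n_samples is not None:
        duration_ms = raster.n_samples / raster.sampling_rate * 1000.0
        n_bins = max(int(np.ceil(duration_ms / bin_width_ms)), 1)
    else:
        n_bins = int(bins.max()) + 1 if bins.size else 1
    occ = np.zeros((raster.n_channels, n_bins), dtype=bool)
    occ[raster.channels, bins] = True
    return BinnedRaster(occ, bin_width_ms)


def extract_avalanches(raster: BinnedRaster) -> list[Avalanche]:
    """Maximal runs of consecutive occupied bins, bounded by empty bins or edges."""
    occupied = raster.occupancy.any(axis=0)
    if not occupied.any():
        return []
    edges = np.diff(occupied.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if occupied[0]:
        starts = np.r_[0, starts]
    if occupied[-1]:
        ends = np.r_[ends, occupied.size]
    return [Avalanche.from_submatrix(int(s), raster.occupancy[:, s:e])
            for s, e in zip(starts, ends)]


def avalanche_sizes(raster: BinnedRaster) -> np.ndarray:
    """Sizes of all avalanches in a raster (vectorized; no submatrix copies)."""
    counts = raster.occupancy.sum(axis=0)
    occupied = counts > 0
    if not occupied.any():
        return np.empty(0, dtype=np.int64)
    run_id = np.cumsum(np.r_[occupied[0], (~occupied[:-1]) & occupied[1:]]) - 1
    sizes = np.bincount(run_id[occupied], weights=counts[occupied])
    return sizes.astype(np.int64)


def empirical_pattern_distribution(avalanches: Sequence[Avalanche],
                                   channel_subset: Sequence[int]) -> PatternDistribution:
    """Empirical pattern distribution of avalanches projected onto a channel subset.

    Avalanches must have been extracted on the full reference channel set;
    each contributes one sample, its pattern restricted to ``channel_subset``
    (subset[0] maps to the least significant bit).  The all-inactive
    projection is allowed, so the quiescent probability can be positive for
    proper subsets.
    """
    if len(avalanches) == 0:
        raise ValueError("no avalanches supplied")
    subset = np.asarray(list(channel_subset), dtype=int)
    k = subset.size
    weights = 1 << np.arange(k, dtype=np.int64)
    counts = np.zeros(2**k)
    for av in avalanches:
        active = (av.pattern[subset] > 0).astype(np.int64)
        counts[int(active @ weights)] += 1
    return PatternDistribution(counts / counts.sum(), k)


# ---------------------------------------------------------------------------
# power-law fitting


def _empirical_pmf(data: Union[np.ndarray, Sequence[int], SizeDistribution]):
    if isinstance(data, SizeDistribution):
        return data.sizes, data.probabilities
    dist = SizeDistribution.from_samples(np.asarray(data))
    return dist.sizes, dist.probabilities


def _ks_distance(sizes: np.ndarray, probs: np.ndarray, exponent: float,
                 support: np.ndarray) -> float:
    logp = exponent * np.log(support)
    logp -= logp.max()
    pl = np.exp(logp)
    pl /= pl.sum()
    cdf_pl = np.cumsum(pl)
    emp = np.zeros(support.size)
    emp[np.searchsorted(support, sizes)] = probs
    cdf_emp = np.cumsum(emp)
    return float(np.max(np.abs(cdf_emp - cdf_pl)))


def fit_power_law(data: Union[np.ndarray, Sequence[int], SizeDistribution],
                  fixed_exponent: Optional[float] = None,
                  exponent_bounds: tuple[float, float] = (-8.0, -0.01)) -> PowerLawFit:
    """Fit a discrete power law P(s) ~ s^eps on the observed support [min, max].

    The exponent minimizes the KS distance between the empirical CDF and the
    power-law CDF (coarse grid + bounded 1-D refinement).  With
    ``fixed_exponent`` given (e.g. -1.5) only the KS distance is evaluated.
    """
    sizes, probs = _empirical_pmf(data)
    support = np.arange(sizes.min(), sizes.max() + 1, dtype=np.int64)
    if fixed_exponent is not None:
        d = _ks_distance(sizes, probs, fixed_exponent, support)
        return PowerLawFit(float(fixed_exponent), d, (int(sizes.min()), int(sizes.max())))
    if sizes.size < 2:
        raise ValueError("need >= 2 distinct sizes to fit an exponent "
                         "(or pass fixed_exponent)")

    grid = np.linspace(exponent_bounds[0], exponent_bounds[1], 160)
    dvals = [_ks_distance(sizes, probs, e, support) for e in grid]
    k = int(np.argmin(dvals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    # golden-section refinement: D_KS is V-shaped (only piecewise smooth) at
    # the optimum, where parabolic-interpolation methods stall near sqrt(eps)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _ks_distance(sizes, probs, c, support)
    fd = _ks_distance(sizes, probs, d, support)
    while b - a > 1e-12:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _ks_distance(sizes, probs, c, support)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _ks_distance(sizes, probs, d, support)
    best = c if fc < fd else d
    return PowerLawFit(float(best),
                       float(_ks_distance(sizes, probs, best, support)),
                       (int(sizes.min()), int(sizes.max())))


@dataclass
class SegmentStability:
    """Per-segment power-law fits plus summary of the exponent across segments."""

    fits: list[PowerLawFit]
    mean_exponent: float
    sd_exponent: float
    excluded_segments: list[int] = field(default_factory=list)


def segment_stability(raster: BinnedRaster, n_segments: int = 10) -> SegmentStability:
    """Split the raster into consecutive equal-length segments and fit each.

    Segments with no avalanches (or a degenerate single size) are excluded
    with a logged warning.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if raster.n_bins < n_segments:
        raise ValueError("raster too short for the requested number of segments")
    bounds = np.linspace(0, raster.n_bins, n_segments + 1, dtype=int)
    fits: list[PowerLawFit] = []
    excluded: list[int] = []
    for i, (s, e) in enumerate(zip(bounds[:-1], bounds[1:])):
        seg = BinnedRaster(raster.occupancy[:, s:e], raster.bin_width_ms)
        sizes = avalanche_sizes(seg)
        if sizes.size == 0 or np.unique(sizes).size < 2:
            logger.warning("segment %d has no fittable avalanches; excluded", i)
            excluded.append(i)
            continue
        fits.append(fit_power_law(sizes))
    if not fits:
        raise ValueError("no segment produced a fittable size distribution")
    exps = np.array([f.exponent for f in fits])
    return SegmentStability(fits, float(exps.mean()), float(exps.std()), excluded)
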