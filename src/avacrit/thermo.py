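"""Temperature reweighting of pattern distributions and thermodynamic observables.

The measured pattern distribution defines pattern energies E_i = -ln p_i(1)
(natural-log convention with the physiological condition at T = 1 and
Z(1) = 1; every observable below is invariant to the constant energy offset,
so the unknown true normalization is immaterial).  The single-histogram
method then yields the distribution at any fictitious temperature T:

    p_i(T) proportional to p_i(1)^(1/T),

computed in log space and renormalized.  Observables, per unit:

    specific heat   C(T)   = (<E^2> - <E>^2) / (n T^2)
    order parameter M(T)   = (1/n) sum_i p_i m_i,   m_i = sum_j sigma_j^i
    susceptibility  chi(T) = (<m^2> - <m>^2) / (n T)

with expectations under p(T).  chi is the zero-field response of M to a weak
external field, expressed through the fluctuation identity; no field is ever
applied explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .avalanche import PowerLawFit, SizeDistribution, fit_power_law
from .patterns import PatternDistribution, pattern_sizes

__all__ = [
    "EnergySpectrum",
    "ThermoCurve",
    "TemperatureScan",
    "energies",
    "reweight",
    "specific_heat",
    "order_parameter",
    "susceptibility",
    "thermo_curves",
    "size_distribution_at_T",
    "perturb_quiescent",
    "default_t_grid",
]

PROBABILITY_FLOOR = 1e-300


def default_t_grid(t_min: float = 0.5, t_max: float = 2.5,
                   n_points: int = 201) -> np.ndarray:
    """The temperature grid used throughout: 0.5 to 2.5, step 0.01."""
    return np.linspace(t_min, t_max, n_points)


@dataclass
class EnergySpectrum:
    """Pattern energies E_i = -ln p_i(1) (dimensionless, Z(1) = 1 convention)."""

    energies: np.ndarray
    n_units: int

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.size != 2**self.n_units:
            raise ValueError("one energy per pattern required")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("energies must be finite")


@dataclass
class ThermoCurve:
    """One observable as a function of T for one system size."""

    quantity: str  # susceptibility | specific_heat | order_parameter
    system_size: int
    T_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.T_grid = np.asarray(self.T_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.T_grid.shape != self.values.shape:
            raise ValueError("T grid and values must align")
        if np.any(np.diff(self.T_grid) <= 0) or np.any(self.T_grid <= 0):
            raise ValueError("T grid must be strictly increasing and positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")


def energies(dist: PatternDistribution) -> EnergySpectrum:
    """Pattern energies from the measured (T = 1) distribution."""
    p = dist.probabilities
    if np.any(p <= 0):
        warnings.warn(
            "distribution has zero-probability patterns; floored at 1e-300 "
            "(consider a DG-modeled distribution instead of raw counts)",
            stacklevel=2,
        )
        p = np.clip(p, PROBABILITY_FLOOR, None)
    return EnergySpectrum(-np.log(p), dist.n_units)


def reweight(dist: PatternDistribution, T: float) -> PatternDistribution:
    """Single-histogram reweighting p_i(T) ~ p_i(1)^(1/T), in log space."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    logp = np.log(np.clip(dist.probabilities, PROBABILITY_FLOOR, None)) / T
    logp -= logsumexp(logp)
    p = np.exp(logp)
    return PatternDistribution(p / p.sum(), dist.n_units)


def _weighted_var(values: np.ndarray, probs: np.ndarray) -> float:
    mean = float(probs @ values)
    return float(probs @ (values - mean) ** 2)


def specific_heat(dist_at_T: PatternDistribution, spectrum: EnergySpectrum,
                  T: float, n: Optional[int] = None) -> float:
    """C = var(E) / (n T^2) under the reweighted distribution."""
    if dist_at_T.n_units != spectrum.n_units:
        raise ValueError("distribution and energy spectrum sizes differ")
    n = dist_at_T.n_units if n is None else n
    return _weighted_var(spectrum.energies, dist_at_T.probabilities) / (n * T**2)


def order_parameter(dist_at_T: PatternDistribution,
                    n: Optional[int] = None) -> float:
    """M = (1/n) sum_i p_i m_i with m_i the summed -1/+1 pattern activity."""
    n = dist_at_T.n_units if n is None else n
    m = 2.0 * pattern_sizes(dist_at_T.n_units) - dist_at_T.n_units
    return float(dist_at_T.probabilities @ m) / n


def susceptibility(dist_at_T: PatternDistribution, T: float,
                   n: Optional[int] = None) -> float:
    """chi = var(m) / (n T) under the reweighted distribution."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    n = dist_at_T.n_units if n is None else n
    m = 2.0 * pattern_sizes(dist_at_T.n_units) - dist_at_T.n_units
    return _weighted_var(m.astype(float), dist_at_T.probabilities) / (n * T)


def thermo_curves(dists_by_size: Mapping[int, PatternDistribution],
                  T_grid: Optional[np.ndarray] = None) -> list[ThermoCurve]:
    """chi(T), C(T), M(T) for each system size in the family.

    ``dists_by_size`` maps system size n to its measured (T = 1) pattern
    distribution; typically nested DG marginals or empirical projections.
    Returns 3 * len(sizes) curves.
    """
    T_grid = default_t_grid() if T_grid is None else np.asarray(T_grid, dtype=float)
    curves: list[ThermoCurve] = []
    for n, dist in sorted(dists_by_size.items()):
        spec = energies(dist)
        chi = np.empty(T_grid.size)
        C = np.empty(T_grid.size)
        M = np.empty(T_grid.size)
        for k, T in enumerate(T_grid):
            d = reweight(dist, T)
            chi[k] = susceptibility(d, T, n)
            C[k] = specific_heat(d, spec, T, n)
            M[k] = order_parameter(d, n)
        curves.append(ThermoCurve("susceptibility", n, T_grid, chi))
        curves.append(ThermoCurve("specific_heat", n, T_grid, C))
        curves.append(ThermoCurve("order_parameter", n, T_grid, M))
    return curves


@dataclass
class TemperatureScan:
    """Avalanche-size distributions under reweighting, with KS-vs-T diagnostics."""

    T_grid: np.ndarray
    size_distributions: list[SizeDistribution]
    best_fit: list[PowerLawFit]
    fixed_fit: list[PowerLawFit]
    T_min_best: float
    T_min_fixed: float


def size_distribution_at_T(dist: PatternDistribution,
                           T_grid: Optional[np.ndarray] = None,
                           fixed_exponent: float = -1.5) -> TemperatureScan:
    """Scan T, aggregate pattern probabilities by size (quiescent excluded),
    and locate the T minimizing the KS distance to a power law.

    At each temperature the reweighted pattern distribution is collapsed to a
    distribution over sizes 1..n (renormalized excluding size 0) and compared
    against (a) the KS-minimizing power law and (b) the fixed-exponent power
    law (default -1.5).  Returns the arg-min temperature for both.
    """
    if dist.n_units < 2:
        raise ValueError("need at least 2 units for a size distribution")
    T_grid = default_t_grid() if T_grid is None else np.asarray(T_grid, dtype=float)
    sizes = np.arange(1, dist.n_units + 1)
    dists: list[SizeDistribution] = []
    best: list[PowerLawFit] = []
    fixed: list[PowerLawFit] = []
    for T in T_grid:
        marg = reweight(dist, T).size_marginal(include_quiescent=False)
        keep = marg > 0
        sd = SizeDistribution(sizes[keep], marg[keep] / marg[keep].sum(), 0)
        dists.append(sd)
        best.append(fit_power_law(sd))
        fixed.append(fit_power_law(sd, fixed_exponent=fixed_exponent))
    d_best = np.array([f.ks_distance for f in best])
    d_fixed = np.array([f.ks_distance for f in fixed])
    return TemperatureScan(
        T_grid, dists, best, fixed,
        float(T_grid[int(np.argmin(d_best))]),
        float(T_grid[int(np.argmin(d_fixed))]),
    )


def perturb_quiescent(dist: PatternDistribution, new_p0: float) -> PatternDistribution:
    """Replace the quiescent probability, renormalizing all active patterns.

    p_0 <- new_p0 and p_i <- p_i (1 - new_p0) / (1 - p_0_old) for i != 0, so
    the conditional-on-active (hence the size) distribution is unchanged.
    """
    if not 0.0 <= new_p0 < 1.0:
        raise ValueError("new_p0 must lie in [0, 1)")
    p0_old = dist.p0
    if p0_old >= 1.0:
        raise ValueError("all probability mass is on the quiescent state")
    p = dist.probabilities * ((1.0 - new_p0) / (1.0 - p0_old))
    p[0] = new_p0
    return PatternDistribution(p / p.sum(), dist.n_units)
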