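"""Dichotomized Gaussian (DG) model of binary avalanche patterns.

A latent Gaussian vector u ~ N(delta, Lambda) (unit-diagonal Lambda) is
thresholded at zero: sigma_j = +1 iff u_j > 0.  The model is fit by matching
the observed per-unit rates r_j = P(sigma_j = +1) and the pairwise covariances
of the 0/1 activity indicators:

    delta_j   = Phi^{-1}(r_j)
    Sigma_jk  = Phi_2(delta_j, delta_k; lambda_jk) - Phi(delta_j) Phi(delta_k)

with Phi/Phi_2 the uni-/bivariate standard normal CDF; each lambda_jk is found
by bracketed root finding (the left side is monotone increasing in lambda).

Exact pattern probabilities are Gaussian orthant integrals, evaluated with
scipy's Genz quasi-Monte-Carlo CDF.  A homogeneous exchangeable model
(constant delta, constant non-negative off-diagonal lambda) instead uses exact
1-D quadrature over the shared latent factor, which is much faster and fully
deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtr, ndtri

from .patterns import PatternDistribution, pattern_matrix, pattern_sizes

__all__ = [
    "DGParams",
    "fit_dg",
    "dg_pattern_distribution",
    "sample_dg",
    "marginalize_dg",
    "fit_dg_from_patterns",
    "dg_family_distributions",
    "indicator_to_sign_covariance",
    "sign_to_indicator_covariance",
]

logger = logging.getLogger(__name__)

#: exact pattern enumeration becomes impractical beyond this many units
DEFAULT_MAX_UNITS = 20


@dataclass
class DGParams:
    """Latent mean ``delta`` and unit-diagonal covariance ``Lambda`` of a DG model."""

    delta: np.ndarray
    Lambda: np.ndarray

    def __post_init__(self) -> None:
        self.delta = np.atleast_1d(np.asarray(self.delta, dtype=float))
        self.Lambda = np.atleast_2d(np.asarray(self.Lambda, dtype=float))
        n = self.delta.size
        if self.Lambda.shape != (n, n):
            raise ValueError("Lambda must be square and match delta")
        if not np.allclose(self.Lambda, self.Lambda.T, atol=1e-12):
            raise ValueError("Lambda must be symmetric")
        if not np.allclose(np.diag(self.Lambda), 1.0, atol=1e-10):
            raise ValueError("Lambda must have unit diagonal")
        if np.any(np.abs(self.Lambda) > 1 + 1e-12):
            raise ValueError("latent correlations must lie in [-1, 1]")

    @property
    def n_units(self) -> int:
        return self.delta.size

    def rates(self) -> np.ndarray:
        """Per-unit activation probability Phi(delta_j)."""
        return ndtr(self.delta)


def indicator_to_sign_covariance(cov01: np.ndarray) -> np.ndarray:
    """Convert a covariance of 0/1 indicators to the -1/+1 coding (factor 4)."""
    return 4.0 * np.asarray(cov01, dtype=float)


def sign_to_indicator_covariance(cov_pm: np.ndarray) -> np.ndarray:
    """Convert a covariance of -1/+1 variables to the 0/1 coding (factor 1/4)."""
    return np.asarray(cov_pm, dtype=float) / 4.0


def _bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(W1 < h, W2 < k) for standard bivariate normal with correlation rho."""
    if rho >= 1.0 - 1e-15:
        return float(ndtr(min(h, k)))
    if rho <= -1.0 + 1e-15:
        return float(max(0.0, ndtr(h) + ndtr(k) - 1.0))
    return float(
        stats.multivariate_normal.cdf(
            np.array([h, k]),
            mean=np.zeros(2),
            cov=np.array([[1.0, rho], [rho, 1.0]]),
            abseps=1e-12,
            releps=0.0,
        )
    )


def _solve_pair_correlation(di: float, dj: float, target_cov: float,
                            tol: float = 1e-10) -> float:
    """Solve Sigma_ij = Phi2(di, dj; lam) - Phi(di) Phi(dj) for lam in (-1, 1)."""
    ri, rj = ndtr(di), ndtr(dj)
    lo, hi = -1.0 + 1e-9, 1.0 - 1e-9
    # Frechet bounds of the achievable covariance
    cov_min = max(0.0, ri + rj - 1.0) - ri * rj
    cov_max = min(ri, rj) - ri * rj
    if not (cov_min - 1e-12 <= target_cov <= cov_max + 1e-12):
        raise ValueError(
            f"infeasible covariance {target_cov:.6g} for rates ({ri:.4g}, {rj:.4g}): "
            f"achievable range is [{cov_min:.6g}, {cov_max:.6g}]"
        )

    def f(lam: float) -> float:
        return _bvn_cdf(di, dj, lam) - ri * rj - target_cov

    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:  # target at/beyond the numeric bracket edge
        return lo if flo > 0 else hi
    return float(optimize.brentq(f, lo, hi, xtol=tol))


def fit_dg(rates: np.ndarray, covariances: np.ndarray,
           psd_repair: bool = True) -> DGParams:
    """Fit DG parameters to per-unit rates and 0/1-indicator covariances.

    If the assembled latent correlation matrix is not positive semidefinite
    (possible for empirical inputs), negative eigenvalues are clipped at zero
    and the diagonal rescaled to 1; a warning reports the maximum elementwise
    change.  Set ``psd_repair=False`` to raise instead.
    """
    rates = np.asarray(rates, dtype=float)
    covariances = np.asarray(covariances, dtype=float)
    n = rates.size
    if np.any(rates <= 0) or np.any(rates >= 1):
        raise ValueError("rates must lie strictly inside (0, 1)")
    if covariances.shape != (n, n):
        raise ValueError("covariance matrix must be n x n")

    delta = ndtri(rates)
    Lam = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                lam = _solve_pair_correlation(delta[i], delta[j], covariances[i, j])
            except ValueError as exc:
                raise ValueError(f"pair ({i}, {j}): {exc}") from exc
            Lam[i, j] = Lam[j, i] = lam

    eigvals = np.linalg.eigvalsh(Lam)
    if eigvals[0] < -1e-10:
        if not psd_repair:
            raise ValueError(
                f"fitted latent correlation matrix is not PSD "
                f"(smallest eigenvalue {eigvals[0]:.3e})"
            )
        w, V = np.linalg.eigh(Lam)
        repaired = (V * np.clip(w, 0.0, None)) @ V.T
        d = np.sqrt(np.clip(np.diag(repaired), 1e-300, None))
        repaired = repaired / np.outer(d, d)
        np.fill_diagonal(repaired, 1.0)
        change = float(np.max(np.abs(repaired - Lam)))
        warnings.warn(
            f"latent correlation matrix projected to PSD "
            f"(smallest eigenvalue {eigvals[0]:.3e}, max elementwise change {change:.3e})",
            stacklevel=2,
        )
        Lam = repaired
    return DGParams(delta, Lam)


# ---------------------------------------------------------------------------
# pattern probabilities


def _is_exchangeable(params: DGParams) -> float | None:
    """Constant off-diagonal lambda if the model is homogeneous, else None."""
    n = params.n_units
    if n < 2:
        return None
    if np.ptp(params.delta) > 1e-12:
        return None
    off = params.Lambda[~np.eye(n, dtype=bool)]
    lam = off[0]
    if np.ptp(off) > 1e-12 or lam < 0.0 or lam >= 1.0:
        return None
    return float(lam)


def _exchangeable_size_probs(delta: float, lam: float, n: int) -> np.ndarray:
    """P(one specific pattern with k active units), k = 0..n, by 1-D quadrature.

    With constant correlation lam >= 0 the latent variables share a common
    factor: u_j = delta + sqrt(lam) z + sqrt(1-lam) e_j, so conditionally on z
    the units are independent with activation q(z) = Phi((delta + sqrt(lam) z)
    / sqrt(1-lam)).
    """
    if lam < 1e-14:
        q = ndtr(delta)
        k = np.arange(n + 1)
        return q**k * (1 - q) ** (n - k)
    nodes, weights = np.polynomial.hermite_e.hermegauss(201)
    # probabilists' Hermite: integral f(z) exp(-z^2/2) dz -> weights need 1/sqrt(2pi)
    w = weights / np.sqrt(2 * np.pi)
    q = ndtr((delta + np.sqrt(lam) * nodes) / np.sqrt(1.0 - lam))
    k = np.arange(n + 1)
    with np.errstate(divide="ignore"):
        logq = np.log(np.clip(q, 1e-300, None))
        log1q = np.log(np.clip(1 - q, 1e-300, None))
    vals = np.exp(k[:, None] * logq[None, :] + (n - k)[:, None] * log1q[None, :])
    return vals @ w


def _orthant_probability(delta: np.ndarray, Lam: np.ndarray, signs: np.ndarray,
                         tolerance: float, rng: np.random.Generator) -> float:
    """P(u_j > 0 where signs_j=+1 and u_j <= 0 elsewhere), u ~ N(delta, Lam).

    Sign-flipping maps the orthant to a lower-tail probability:
    P = Phi_n(signs * delta; cov = S Lam S) with S = diag(signs).
    """
    s = signs.astype(float)
    cov = Lam * np.outer(s, s)
    upper = s * delta
    if delta.size == 1:
        return float(ndtr(upper[0]))
    return float(
        stats.multivariate_normal.cdf(
            upper, mean=np.zeros(delta.size), cov=cov, allow_singular=True,
            abseps=tolerance, releps=0.0, rng=rng,
        )
    )


def dg_pattern_distribution(params: DGParams, tolerance: float = 1e-6,
                            max_units: int = DEFAULT_MAX_UNITS,
                            seed: int = 0) -> PatternDistribution:
    """Exact pattern probabilities of a DG model over all 2^n patterns.

    Each orthant integral is evaluated to the given absolute tolerance; the
    final vector is renormalized to sum to 1 (absorbing integration error) and
    the renormalization factor is logged.  ``seed`` fixes the quasi-Monte-Carlo
    stream so results are bit-reproducible.
    """
    n = params.n_units
    if n > max_units:
        raise ValueError(
            f"n={n} exceeds the exact-enumeration cap ({max_units}); "
            f"use sample_dg for a sampling-based estimate"
        )

    lam = _is_exchangeable(params)
    if lam is not None:
        per_pattern = _exchangeable_size_probs(float(params.delta[0]), lam, n)
        probs = per_pattern[pattern_sizes(n)]
    else:
        pats = pattern_matrix(n)
        probs = np.empty(2**n)
        for i in range(2**n):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
            probs[i] = _orthant_probability(params.delta, params.Lambda,
                                            pats[i], tolerance, rng)
    probs = np.clip(probs, 0.0, None)
    total = probs.sum()
    if total <= 0:
        raise ValueError("orthant integration returned no probability mass")
    logger.info("pattern distribution renormalization factor: %.12g", total)
    return PatternDistribution(probs / total, n)


def sample_dg(params: DGParams, n_samples: int, seed: int) -> np.ndarray:
    """Draw -1/+1 pattern samples (n_samples x n) from a DG model."""
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    u = rng.multivariate_normal(params.delta, params.Lambda, size=n_samples,
                                method="eigh")
    return np.where(u > 0, 1, -1).astype(np.int8)


def marginalize_dg(params: DGParams, subset) -> DGParams:
    """Restrict a DG model to a subset of units (exact under the latent Gaussian)."""
    subset = np.asarray(list(subset), dtype=int)
    if subset.size == 0:
        raise ValueError("subset must be non-empty")
    if np.any(subset < 0) or np.any(subset >= params.n_units):
        raise IndexError("subset index out of range")
    return DGParams(params.delta[subset], params.Lambda[np.ix_(subset, subset)])


def fit_dg_from_patterns(samples: np.ndarray, psd_repair: bool = True) -> DGParams:
    """Fit a DG model to -1/+1 pattern samples (rows).

    Empirical rates of exactly 0 or 1 are clipped to the open interval at
    1/(2 N) to keep Phi^{-1} finite.
    """
    samples = np.asarray(samples)
    y = (samples > 0).astype(float)
    n_samples = y.shape[0]
    rates = y.mean(axis=0)
    eps = 1.0 / (2.0 * n_samples)
    clipped = np.clip(rates, eps, 1.0 - eps)
    if np.any(clipped != rates):
        warnings.warn("empirical rates of 0 or 1 clipped for the DG fit", stacklevel=2)
    cov = np.cov(y, rowvar=False, bias=True)
    cov = np.atleast_2d(cov)
    # keep each pairwise covariance inside the Frechet bounds of the clipped rates
    for i in range(cov.shape[0]):
        for j in range(cov.shape[1]):
            if i == j:
                continue
            ri, rj = clipped[i], clipped[j]
            lo = max(0.0, ri + rj - 1.0) - ri * rj
            hi = min(ri, rj) - ri * rj
            cov[i, j] = min(max(cov[i, j], lo), hi)
    return fit_dg(clipped, cov, psd_repair=psd_repair)


def dg_family_distributions(params: DGParams, sizes, tolerance: float = 1e-6,
                            seed: int = 0) -> dict[int, PatternDistribution]:
    """Per-size pattern distributions from nested subsets (first n units)."""
    out: dict[int, PatternDistribution] = {}
    for n in sizes:
        sub = marginalize_dg(params, range(n))
        out[n] = dg_pattern_distribution(sub, tolerance=tolerance, seed=seed)
    return out
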