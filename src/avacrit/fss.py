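"""Finite-size-scaling (FSS) collapse of thermodynamic observable families.

Near a critical temperature T_c the observables of systems with n units
collapse onto a master curve when the reduced temperature t = (T - T_c)/T_c
is stretched by L^{1/nu} and the ordinate rescaled by a power of L, where
L = n^{1/d} is the linear size.  The dimensionality d of a cortical network
is unknown, so only the combined exponent nu*d is identified and every power
of L is expressed through n:

    abscissa  x = n^{1/(nu d)} (T - T_c)/T_c
    ordinate  y = n^{-gamma/(nu d)} chi,  n^{-alpha/(nu d)} C,  n^{+beta/(nu d)} M

The goodness of collapse GC = MSD_after / MSD_before compares the mean
squared deviation of the curves from their point-wise across-size mean after
vs. before scaling; both are evaluated on a fixed 200-point grid spanning the
common abscissa interval (linear interpolation), since scaling destroys the
shared T grid.  GC is minimized over (T_c, nu d, exponent) by Nelder-Mead
simplex refinement from a grid of starting points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .thermo import ThermoCurve

__all__ = [
    "ScaledCurveFamily",
    "FSSResult",
    "scale_curves",
    "goodness_of_collapse",
    "fit_collapse",
]

#: ordinate n-power sign per quantity: y = n^{sign * exponent / nu_d} * value
_ORDINATE_SIGN = {"susceptibility": -1.0, "specific_heat": -1.0,
                  "order_parameter": +1.0}

GRID_POINTS = 200


@dataclass
class ScaledCurveFamily:
    """Scaled (x, y) curves plus the originals they were derived from."""

    quantity: str
    sizes: list[int]
    scaled: list[tuple[np.ndarray, np.ndarray]]
    original: list[tuple[np.ndarray, np.ndarray]]


@dataclass
class FSSResult:
    """Best collapse estimate for one observable family."""

    T_c: float
    nu_d: float
    quantity_exponent: float
    gc: float
    quantity: str
    optimizer_trace: list[dict] = field(default_factory=list)


def _check_family(curves: Sequence[ThermoCurve]) -> str:
    if len(curves) < 2:
        raise ValueError("need at least 2 system sizes to collapse")
    quantities = {c.quantity for c in curves}
    if len(quantities) != 1:
        raise ValueError(f"mixed quantities in one family: {sorted(quantities)}")
    sizes = [c.system_size for c in curves]
    if len(set(sizes)) != len(sizes):
        raise ValueError("duplicate system sizes in family")
    (quantity,) = quantities
    if quantity not in _ORDINATE_SIGN:
        raise ValueError(f"unknown quantity {quantity!r}")
    return quantity


def scale_curves(curves: Sequence[ThermoCurve], T_c: float, nu_d: float,
                 quantity_exponent: float) -> ScaledCurveFamily:
    """Apply the FSS transformation to a family of same-quantity curves.

    nu_d = inf is allowed and leaves the abscissa unstretched (n^0 = 1).
    """
    quantity = _check_family(curves)
    if T_c <= 0:
        raise ValueError("T_c must be positive")
    if not (nu_d > 0):
        raise ValueError("nu_d must be positive")
    sign = _ORDINATE_SIGN[quantity]
    ns = np.array([float(c.system_size) for c in curves])
    if math.isinf(nu_d):
        stretches = np.ones_like(ns)
        yscales = np.ones_like(ns)
    else:
        stretches = ns ** (1.0 / nu_d)
        yscales = ns ** (sign * quantity_exponent / nu_d)
        # canonicalize to geometric mean 1: collapse quality depends only on
        # the RELATIVE size-dependent factors, and an unnormalized power of n
        # has a spurious optimum where every ordinate underflows to zero
        yscales = yscales / np.exp(np.mean(np.log(yscales)))
    scaled = []
    original = []
    for c, stretch, yscale in zip(curves, stretches, yscales):
        x = stretch * (c.T_grid - T_c) / T_c
        scaled.append((x, yscale * c.values))
        original.append((c.T_grid.copy(), c.values.copy()))
    return ScaledCurveFamily(quantity, [c.system_size for c in curves],
                             scaled, original)


def _msd(curves: Sequence[tuple[np.ndarray, np.ndarray]]) -> float:
    """Mean squared deviation from the point-wise across-size mean, on a
    200-point grid spanning the intersection of the abscissa ranges."""
    lo = max(x[0] for x, _ in curves)
    hi = min(x[-1] for x, _ in curves)
    if hi <= lo:
        raise ValueError("curves have no common abscissa interval")
    grid = np.linspace(lo, hi, GRID_POINTS)
    ys = np.stack([np.interp(grid, x, y) for x, y in curves])
    mean = ys.mean(axis=0)
    return float(((ys - mean) ** 2).mean())


def goodness_of_collapse(family: ScaledCurveFamily) -> float:
    """GC = MSD_after / MSD_before for a scaled curve family."""
    before = _msd(family.original)
    if before == 0.0:
        raise ValueError("degenerate family: identical input curves")
    after = _msd(family.scaled)
    return after / before


_STARTS_TC = (0.8, 1.0, 1.2, 1.5)
_STARTS_NUD = (0.5, 1.0, 1.5)
_STARTS_EXP = {"susceptibility": (0.5, 1.0, 1.5),
               "specific_heat": (0.5, 1.0, 1.5),
               "order_parameter": (-0.1, 0.0, 0.1)}


def fit_collapse(curves: Sequence[ThermoCurve],
                 starts: Optional[Sequence[tuple[float, float, float]]] = None,
                 gc_tol: float = 1e-8, max_iter: int = 2000) -> FSSResult:
    """Estimate (T_c, nu d, quantity exponent) by minimizing GC.

    Derivative-free Nelder-Mead refinement from a full grid of initial
    conditions; the global best is returned and every local optimum is kept
    in the optimizer trace.
    """
    quantity = _check_family(curves)
    if starts is None:
        starts = [(tc, nd, ex)
                  for tc in _STARTS_TC
                  for nd in _STARTS_NUD
                  for ex in _STARTS_EXP[quantity]]

    t_lo = max(float(c.T_grid[0]) for c in curves)
    t_hi = min(float(c.T_grid[-1]) for c in curves)

    def objective(theta: np.ndarray) -> float:
        T_c, nu_d, expo = theta
        # T_c is only meaningful inside the measured temperature window; a
        # candidate outside it leaves no data on one side of the transition
        # and lets flat curve tails collapse spuriously
        if not (t_lo <= T_c <= t_hi) or nu_d <= 0.05:
            return 1e6 + float(np.sum(np.square(theta)))
        try:
            return goodness_of_collapse(scale_curves(curves, T_c, nu_d, expo))
        except ValueError:
            return 1e6

    trace: list[dict] = []
    best = None
    for start in starts:
        res = optimize.minimize(
            objective, np.asarray(start, dtype=float), method="Nelder-Mead",
            options={"fatol": gc_tol, "xatol": 1e-6, "maxiter": max_iter,
                     "maxfev": 4 * max_iter},
        )
        entry = {"start": tuple(start), "x": tuple(float(v) for v in res.x),
                 "gc": float(res.fun), "converged": bool(res.success),
                 "n_iter": int(res.nit)}
        trace.append(entry)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e6:
        raise RuntimeError("collapse optimizer failed from every start; "
                           f"trace: {trace}")
    T_c, nu_d, expo = (float(v) for v in best.x)
    return FSSResult(T_c, nu_d, expo, float(best.fun), quantity, trace)
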