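"""First-order photodegradation kinetics.

The residual parent fraction follows ln[%parent] = -k1 * t + ln(100), so
k1 is estimated as minus the slope of an ordinary least-squares line
through (t, ln %).  The photostability summary t0.1 is the time at which
10% of the compound has degraded.

Two t0.1 conventions are provided: the exact first-order value
ln(10/9)/k1, and a "table-compatible" constant 0.1100/k1 that reproduces
the tabulated values this pipeline ships as fixtures (equivalent to an
intercept of ~4.61 rather than ln 100 = 4.605; the source of the 0.1100
constant is empirical, see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .simulate import KineticScheme, kinetic_profiles

__all__ = ["KineticFit", "percent_normalize", "fit_first_order", "fit_secondary", "t01"]

T01_COMPAT_CONSTANT = 0.1100  # reproduces the fixture t0.1 = const / k1
T01_EXACT_CONSTANT = float(np.log(10.0 / 9.0))  # 0.10536...


@dataclass
class KineticFit:
    """First-order fit: rate (s^-1), its SE, intercept of ln% (expected
    ~ln 100), R2 (%) of the line, and t0.1 in minutes."""

    k1: float
    k1_sd: float
    intercept: float
    r2_percent: float
    t01_min: float
    k2: float | None = None
    k2_sd: float | None = None
    n_points: int = 0


def percent_normalize(profile, times=None) -> np.ndarray:
    """Profile as percent of its initial value (first entry exactly 100)."""
    profile = np.asarray(profile, dtype=float)
    if profile[0] <= 0:
        raise ValueError("initial value must be > 0 to normalize to percent")
    out = 100.0 * profile / profile[0]
    out[0] = 100.0
    return out


def fit_first_order(percent, times, drop_below: float = 1.0,
                    fixed_intercept: float | None = None,
                    t01_mode: str = "exact") -> KineticFit:
    """OLS line through (t, ln %): k1 = -slope.

    Points with percent <= ``drop_below`` are excluded (the logarithm
    blows up as the compound nears complete degradation).  Set
    ``fixed_intercept`` to force the line through a chosen ln% value at
    t=0 (e.g. ln 100) instead of estimating it.
    """
    percent = np.asarray(percent, dtype=float)
    times = np.asarray(times, dtype=float)
    mask = percent > drop_below
    if mask.sum() < 3:
        raise ValueError("need at least 3 points above the drop_below threshold")
    t, lp = times[mask], np.log(percent[mask])
    if fixed_intercept is None:
        res = stats.linregress(t, lp)
        slope, intercept, stderr = res.slope, res.intercept, res.stderr
        r2 = 100.0 * res.rvalue**2
    else:
        lp0 = lp - fixed_intercept
        slope = float(t @ lp0 / (t @ t))
        intercept = fixed_intercept
        resid = lp0 - slope * t
        dof = max(t.size - 1, 1)
        stderr = float(np.sqrt((resid @ resid) / dof / (t @ t)))
        ss_tot = float(np.sum((lp - lp.mean()) ** 2))
        r2 = 100.0 * (1.0 - float(resid @ resid) / ss_tot) if ss_tot > 0 else 100.0
    k1 = -slope
    if k1 <= 0:
        raise ValueError("profile is non-decreasing: estimated rate is not positive")
    return KineticFit(k1=k1, k1_sd=float(stderr), intercept=float(intercept),
                      r2_percent=float(r2), t01_min=t01(k1, t01_mode),
                      n_points=int(mask.sum()))


def fit_secondary(c: np.ndarray, times, c0: float | None = None) -> tuple[float, float]:
    """Joint nonlinear fit of the two-step scheme A -> P1 -> P2 to all
    three concentration columns; returns (k1, k2).

    Initialization: k1 from the log-linear fit of the parent column;
    k2 from a small multi-start around k1 (the secondary rate is weakly
    identified when P2 stays at trace level).
    """
    c = np.asarray(c, dtype=float)
    times = np.asarray(times, dtype=float)
    if c.ndim != 2 or c.shape[1] < 3:
        raise ValueError("need a concentration matrix with parent, PhP1 and PhP2 columns")
    c = c[:, :3]
    c0 = float(c[0].sum()) if c0 is None else float(c0)

    k1_init = fit_first_order(percent_normalize(c[:, 0]), times).k1

    def residuals(log_k):
        k1, k2 = np.exp(log_k)
        if abs(k2 - k1) < 1e-12 * k1:
            k2 = k1 * (1 + 1e-9)
        model = kinetic_profiles(KineticScheme("sequential", k1=k1, k2=k2, c0=c0), times)
        return (model - c).ravel()

    best = None
    for f in (0.1, 0.5, 2.0, 10.0):
        sol = optimize.least_squares(residuals, x0=np.log([k1_init, k1_init * f]),
                                     method="lm", max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
    if not best.success and best.cost > 1e-6 * float(np.sum(c * c)):
        raise RuntimeError("secondary kinetic fit did not converge")
    k1, k2 = np.exp(best.x)
    if abs(k2 - k1) < 1e-6 * k1:
        raise RuntimeError("k2 ~= k1: the two-step rates are not separable on these data")
    return float(k1), float(k2)


def t01(k1: float, mode: str = "exact") -> float:
    """Time to 10% degradation, in minutes.

    mode='exact':        ln(10/9) / k1 / 60
    mode='table_compat': 0.1100 / k1 / 60  (reproduces the fixture tables)
    """
    if k1 <= 0:
        raise ValueError("k1 must be > 0")
    if mode == "exact":
        const = T01_EXACT_CONSTANT
    elif mode == "table_compat":
        const = T01_COMPAT_CONSTANT
    else:
        raise ValueError(f"unknown t01 mode {mode!r}")
    return const / k1 / 60.0
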