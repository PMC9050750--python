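"""Estimation of pump descriptors (J0, dP*) from PPC point sets.

A measured pump performance curve is a cloud of (dP, J) points.  The
zero-pressure flux J0 is the intercept at dP = 0 and the stall pressure
dP* is the zero crossing of J.  Printed epithelial PPCs are close to
linear, so the default estimator is an ordinary least-squares line
J = J0 + slope * dP with dP* = -J0/slope; an isotonic-decreasing fit is
available when curvature matters.  Per-curve uncertainty comes from a
case-resampling bootstrap, and groups of device-level estimates are
compared with the two-sided Mann-Whitney rank-sum test, as is standard
for small per-device samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import mannwhitneyu
from sklearn.isotonic import IsotonicRegression

from .pump_model import ConfigurationError, PPCCurve

__all__ = [
    "PPCEstimate",
    "BootstrapCI",
    "GroupComparison",
    "fit_ppc",
    "bootstrap_ci",
    "compare_groups",
]


@dataclass(frozen=True)
class PPCEstimate:
    """Fitted pump descriptors for one curve.

    ``extrapolated`` marks stalls estimated without an observed sign
    change in J (a device that never sampled past its stall).
    """

    J0: float
    deltaP_star: float
    slope: float
    n_points: int
    method: Literal["linear", "monotone"]
    extrapolated: bool = False
    ci_J0: tuple[float, float] | None = None
    ci_deltaP_star: tuple[float, float] | None = None

    def __post_init__(self):
        for ci in (self.ci_J0, self.ci_deltaP_star):
            if ci is not None and ci[0] > ci[1]:
                raise ConfigurationError("confidence interval bounds must be ordered")


@dataclass(frozen=True)
class BootstrapCI:
    ci_J0: tuple[float, float]
    ci_deltaP_star: tuple[float, float]
    n_degenerate: int


@dataclass(frozen=True)
class GroupComparison:
    U: float
    p_value: float
    median_a: float
    median_b: float
    method: Literal["exact", "normal_approx"]
    ties: bool


def _ols_line(dp: np.ndarray, j: np.ndarray) -> tuple[float, float]:
    """(intercept, slope) of J on dP by ordinary least squares."""
    res = sm.OLS(j, sm.add_constant(dp)).fit()
    return float(res.params[0]), float(res.params[1])


def fit_ppc(curve: PPCCurve, method: Literal["linear", "monotone"] = "linear") -> PPCEstimate:
    """Estimate (J0, dP*, slope) from a PPC point set.

    ``linear`` fits J = J0 + slope*dP by OLS and takes dP* = -J0/slope.
    ``monotone`` fits an isotonic-decreasing curve and interpolates its
    zero crossing; J0 is the fitted value at dP = 0.  If J never changes
    sign the stall is an extrapolation and is flagged, not refused.
    """
    dp, j = curve.delta_P, curve.J
    if dp.size < 3:
        raise ConfigurationError("need at least 3 points to fit a PPC")
    if np.all(dp == dp[0]):
        raise ConfigurationError("degenerate design: all delta_P equal")
    if method not in ("linear", "monotone"):
        raise ConfigurationError(f"unknown fit method {method!r}")

    intercept, slope = _ols_line(dp, j)
    if slope >= 0:
        warnings.warn("non-pump-like PPC: fitted slope is non-negative", stacklevel=2)
    sign_change = bool(np.any(j > 0) and np.any(j < 0))

    if method == "linear":
        j0 = intercept
        stall = -intercept / slope if slope != 0 else np.nan
    else:
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        fitted = iso.fit_transform(dp, j)
        j0 = float(np.interp(0.0, dp, fitted))
        crossing = np.nonzero(np.diff(np.sign(fitted)) != 0)[0]
        if crossing.size:
            i = int(crossing[0])
            f0, f1 = fitted[i], fitted[i + 1]
            stall = float(dp[i] + (dp[i + 1] - dp[i]) * f0 / (f0 - f1)) if f0 != f1 else float(
                0.5 * (dp[i] + dp[i + 1])
            )
        else:
            # no crossing inside the sampled range: extrapolate the OLS line
            stall = -intercept / slope if slope != 0 else np.nan
            sign_change = False

    return PPCEstimate(
        J0=float(j0),
        deltaP_star=float(stall),
        slope=slope,
        n_points=int(dp.size),
        method=method,
        extrapolated=not sign_change,
    )


def bootstrap_ci(
    curve: PPCCurve,
    B: int = 1000,
    seed: int = 0,
    *,
    alpha: float = 0.05,
) -> BootstrapCI:
    """Case-resampling percentile bootstrap intervals for J0 and dP*.

    Resamples the (dP, J) points with replacement B times, refits the
    OLS line in each resample, and reports the alpha/2 and 1-alpha/2
    percentiles.  Resamples in which all dP coincide cannot be fitted
    and are skipped; their count is reported.  Deterministic given the
    seed.
    """
    if B < 100:
        raise ConfigurationError("B must be >= 100")
    dp, j = curve.delta_P, curve.J
    n = dp.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    x, y = dp[idx], j[idx]
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    sxx = ((x - xm) ** 2).sum(axis=1)
    good = sxx > 0
    sxy = ((x - xm) * (y - ym)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(good, sxy / np.where(good, sxx, 1.0), np.nan)
        j0 = ym[:, 0] - slope * xm[:, 0]
        stall = np.where(slope != 0, -j0 / slope, np.nan)
    keep = good & np.isfinite(stall)
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    ci_j0 = tuple(np.percentile(j0[good], [lo, hi]))
    ci_stall = tuple(np.percentile(stall[keep], [lo, hi]))
    return BootstrapCI(ci_J0=ci_j0, ci_deltaP_star=ci_stall, n_degenerate=int(B - good.sum()))


def _values(group: Sequence, statistic: str) -> np.ndarray:
    vals = [getattr(e, statistic) if isinstance(e, PPCEstimate) else float(e) for e in group]
    return np.asarray(vals, dtype=float)


def compare_groups(
    a: Sequence,
    b: Sequence,
    statistic: Literal["J0", "deltaP_star"] = "deltaP_star",
) -> GroupComparison:
    """Two-sided Mann-Whitney rank-sum comparison of two estimate groups.

    Accepts sequences of :class:`PPCEstimate` or plain numbers.  The
    exact null distribution is used for small groups (both n <= 10,
    no ties); otherwise the normal approximation with mid-rank tie
    correction, flagged in the result.
    """
    xa, xb = _values(a, statistic), _values(b, statistic)
    if xa.size < 3 or xb.size < 3:
        raise ConfigurationError("each group needs at least 3 values")
    ties = bool(np.intersect1d(xa, xb).size or xa.size != np.unique(xa).size
                or xb.size != np.unique(xb).size)
    exact = xa.size <= 10 and xb.size <= 10 and not ties
    res = mannwhitneyu(xa, xb, alternative="two-sided",
                       method="exact" if exact else "asymptotic")
    return GroupComparison(
        U=float(res.statistic),
        p_value=float(res.pvalue),
        median_a=float(np.median(xa)),
        median_b=float(np.median(xb)),
        method="exact" if exact else "normal_approx",
        ties=ties,
    )
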