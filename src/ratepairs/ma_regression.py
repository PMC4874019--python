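"""Major-axis (model II) regression with slope confidence intervals.

The major axis is the first principal axis of the sample covariance
matrix: the line minimizing summed squared *perpendicular* distances.
Unlike ordinary least squares it treats x and y symmetrically — swapping
the axes inverts the slope — which is the right errors-in-both-variables
model when comparing two branch lengths measured with the same noise.

Closed form: with sample (co)variances s_xx, s_yy, s_xy and s_xy != 0,

    b = (s_yy − s_xx + sqrt((s_yy − s_xx)^2 + 4 s_xy^2)) / (2 s_xy).

The analytic confidence interval inverts the exact F test of a
hypothesized slope β: under H0 the residual scores (y − βx) and axis
scores (x + βy) are uncorrelated, and the squared correlation threshold
F/(F + n − 2) translates, in the rotated frame, into

    limits = tan(θ̂ ± ½ arcsin(2 sqrt(Q) / (λ1 − λ2))),
    Q = F_{1,n−2;1−α} · λ1 λ2 / (n − 2),

with λ1 ≥ λ2 the covariance eigenvalues and θ̂ = atan(b). When
2 sqrt(Q) exceeds λ1 − λ2 the data cannot reject any direction and the
interval is unbounded. A pairs-percentile bootstrap is available as an
alternative interval.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["MAFit", "MADegenerateError", "ma_fit", "classify", "CALLS"]

CALLS = ("sig_above", "sig_below", "not_significant")


class MADegenerateError(ValueError):
    """Raised when the major axis is undefined (vertical or zero variance)."""


@dataclass(frozen=True)
class MAFit:
    """A fitted major axis with its slope confidence interval."""

    n: int
    slope: float
    intercept: float
    pearson_r: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05


def _moments(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    sxx = float(np.var(x, ddof=1))
    syy = float(np.var(y, ddof=1))
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    return sxx, syy, sxy


def _ma_slope(sxx: float, syy: float, sxy: float) -> float:
    if sxy == 0.0:
        if sxx > syy:
            return 0.0
        raise MADegenerateError(
            "no finite MA slope: zero covariance with var(y) >= var(x)"
        )
    return (syy - sxx + np.hypot(syy - sxx, 2.0 * sxy)) / (2.0 * sxy)


def _analytic_ci(
    sxx: float, syy: float, sxy: float, slope: float, n: int, alpha: float
) -> tuple[float, float]:
    tr = sxx + syy
    disc = np.hypot(syy - sxx, 2.0 * sxy)
    lam1 = 0.5 * (tr + disc)
    lam2 = 0.5 * (tr - disc)
    fcrit = stats.f.ppf(1.0 - alpha, 1, n - 2)
    q = fcrit * lam1 * lam2 / (n - 2)
    if disc <= 0.0:
        return -np.inf, np.inf
    sin_arg = 2.0 * np.sqrt(max(q, 0.0)) / disc
    if sin_arg >= 1.0:
        return -np.inf, np.inf
    theta = np.arctan(slope)
    delta = 0.5 * np.arcsin(sin_arg)
    lo_ang, hi_ang = theta - delta, theta + delta
    lo = np.tan(lo_ang) if lo_ang > -np.pi / 2 else -np.inf
    hi = np.tan(hi_ang) if hi_ang < np.pi / 2 else np.inf
    # guard the bracket invariant against tan/arctan round-trip error
    return float(min(lo, slope)), float(max(hi, slope))


def _bootstrap_ci(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int,
    alpha: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    xb = x[idx]
    yb = y[idx]
    sxx = xb.var(axis=1, ddof=1)
    syy = yb.var(axis=1, ddof=1)
    sxy = ((xb - xb.mean(axis=1, keepdims=True))
           * (yb - yb.mean(axis=1, keepdims=True))).sum(axis=1) / (n - 1)
    ok = sxy != 0
    slopes = (syy[ok] - sxx[ok]
              + np.hypot(syy[ok] - sxx[ok], 2 * sxy[ok])) / (2 * sxy[ok])
    lo, hi = np.percentile(slopes, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def ma_fit(
    x,
    y,
    alpha: float = 0.05,
    ci_method: str = "analytic",
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> MAFit:
    """Fit the major axis of (x, y) with a slope CI at level 1 − alpha.

    ``ci_method`` is ``"analytic"`` (F-test inversion, default) or
    ``"bootstrap"`` (pairs percentile bootstrap; needs ``rng``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 points, got {n}")
    sxx, syy, sxy = _moments(x, y)
    if sxx == 0.0 or syy == 0.0:
        raise MADegenerateError("x and y must each have nonzero variance")
    slope = float(_ma_slope(sxx, syy, sxy))
    intercept = float(np.mean(y) - slope * np.mean(x))
    r = sxy / np.sqrt(sxx * syy)
    if ci_method == "analytic":
        lo, hi = _analytic_ci(sxx, syy, sxy, slope, n, alpha)
    elif ci_method == "bootstrap":
        if rng is None:
            raise ValueError("bootstrap CI requires an rng")
        lo, hi = _bootstrap_ci(x, y, n_boot, alpha, rng)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return MAFit(
        n=n,
        slope=slope,
        intercept=intercept,
        pearson_r=float(r),
        ci_low=lo,
        ci_high=hi,
        alpha=alpha,
    )


def classify(fit: MAFit, reference_slope: float) -> str:
    """Significance of the slope against a reference (1 or 0 here).

    ``sig_above`` if the whole interval lies above the reference,
    ``sig_below`` if below, else ``not_significant``.
    """
    if fit.ci_low > reference_slope:
        return "sig_above"
    if fit.ci_high < reference_slope:
        return "sig_below"
    return "not_significant"
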