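"""Method-comparison statistics: OLS linearity and ICC(1,1) agreement.

Two methods measuring the same targets are compared by (a) ordinary
least-squares regression with Pearson's r and its two-sided p-value,
and (b) the one-way random-effects intraclass correlation ICC(1,1)
(Shrout & Fleiss), which — unlike r — penalizes systematic offset and
scale differences, with an exact-F 95% confidence interval and F-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class MethodComparison:
    """Linearity and agreement of one candidate method against a reference."""

    slope: float
    intercept: float
    r: float
    p_value: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    icc_p: float
    n: int


def linear_fit(x, y) -> tuple[float, float, float, float]:
    """OLS of y on x: (slope, intercept, Pearson r, two-sided p).

    The p-value comes from the t transform of r with n - 2 degrees of
    freedom, as standard for testing linearity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.pvalue)


def icc_1_1(x, y, alpha: float = 0.05) -> tuple[float, float, float, float]:
    """One-way random-effects ICC(1,1) for two ratings per target.

    Each target i is measured once by each method; the one-way ANOVA
    decomposition gives between-target (BMS) and within-target (WMS)
    mean squares and

        ICC(1,1) = (BMS - WMS) / (BMS + (k-1) * WMS),   k = 2.

    The confidence interval uses the exact F bounds
    ``F_L = F / F_{1-a/2}(n-1, n(k-1))`` and
    ``F_U = F * F_{1-a/2}(n(k-1), n-1)`` mapped through
    ``(F - 1) / (F + k - 1)``; the p-value tests F = BMS/WMS.

    Returns (icc, ci_low, ci_high, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 targets")
    k = 2
    ratings = np.stack([x, y], axis=1)  # (n targets, k raters)
    grand = ratings.mean()
    target_means = ratings.mean(axis=1)
    bss = k * float(((target_means - grand) ** 2).sum())
    wss = float(((ratings - target_means[:, None]) ** 2).sum())
    df_b = n - 1
    df_w = n * (k - 1)
    bms = bss / df_b
    wms = wss / df_w
    if bms == 0 and wms == 0:
        raise ValueError("zero total variance; ICC undefined")
    if wms == 0:
        return 1.0, 1.0, 1.0, 0.0
    icc = (bms - wms) / (bms + (k - 1) * wms)
    f_obs = bms / wms
    f_low = f_obs / stats.f.ppf(1 - alpha / 2, df_b, df_w)
    f_up = f_obs * stats.f.ppf(1 - alpha / 2, df_w, df_b)
    ci_low = (f_low - 1) / (f_low + k - 1)
    ci_high = (f_up - 1) / (f_up + k - 1)
    p = float(stats.f.sf(f_obs, df_b, df_w))
    return float(icc), float(ci_low), float(ci_high), p


def compare_methods(reference, candidate) -> MethodComparison:
    """Full Table-style comparison of a candidate method vs a reference."""
    slope, intercept, r, p = linear_fit(reference, candidate)
    icc, lo, hi, icc_p = icc_1_1(reference, candidate)
    return MethodComparison(
        slope=slope,
        intercept=intercept,
        r=r,
        p_value=p,
        icc=icc,
        icc_ci_low=lo,
        icc_ci_high=hi,
        icc_p=icc_p,
        n=int(np.asarray(reference).size),
    )
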