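"""Quantitative BRET (qBRET) analysis.

Works on tidy tables of wells (pandas DataFrames) with the columns

- ``fluorescence``       — acceptor (Venus) fluorescence, arbitrary units
- ``total_luminescence`` — total luciferase luminescence, a donor-expression
  proxy
- ``bret_ratio``         — baseline-subtracted Em530/Em485
- ``intensity_ratio``    — fluorescence / total_luminescence, proportional to
  the acceptor/donor expression ratio

Two complementary representations of a titration experiment are supported:

* **Type I** — BRET ratio versus acceptor expression, stratified into donor
  (luminescence) groups. Specific binding shows up as a steeper slope in the
  low-donor group (each acceptor saturates a larger donor fraction);
  non-specific adjacency gives the same slope in every group. Slope equality
  is tested by ANCOVA (extra-sum-of-squares F test on the group x slope
  interaction).
* **Type II** — BRET ratio versus acceptor/donor ratio, pooled; the classical
  saturation analysis, fit with the one-site specific binding hyperbola
  ``y = Bmax * x / (B50 + x)``. Its R-squared is the diagnostic: a good
  hyperbolic fit supports specific binding, a poor one non-specific
  adjacency. This representation is confounded when donor expression falls
  as acceptor expression rises, which is why the classifier lets Type I
  evidence override Type II.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "OneSiteFit",
    "LinearFit",
    "SlopeComparison",
    "Type1Report",
    "Classification",
    "bret_ratio",
    "intensity_ratio",
    "group_by_luminescence",
    "fit_one_site",
    "fit_linear",
    "ancova_equal_slopes",
    "type1_analysis",
    "type2_analysis",
    "classify_interaction",
]

GROUP_LABELS = {2: ["low", "high"], 3: ["low", "medium", "high"]}


# ---------------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------------


def bret_ratio(em530, em485, donor_only_baseline: float = 0.0):
    """Baseline-subtracted BRET ratio: ``em530/em485 - baseline``.

    ``donor_only_baseline`` is the mean em530/em485 of donor-only wells; the
    result may be slightly negative from measurement noise and is not
    clipped.
    """
    em530 = np.asarray(em530, dtype=float)
    em485 = np.asarray(em485, dtype=float)
    if np.any(em485 <= 0):
        raise ValueError("em485 must be positive")
    out = em530 / em485 - donor_only_baseline
    return float(out) if out.ndim == 0 else out


def intensity_ratio(fluorescence, total_luminescence):
    """Acceptor fluorescence / total luminescence; proportional to the
    acceptor/donor expression ratio (unit scale: 1.0 ~ 1:1)."""
    fluorescence = np.asarray(fluorescence, dtype=float)
    total_luminescence = np.asarray(total_luminescence, dtype=float)
    if np.any(total_luminescence <= 0):
        raise ValueError("total_luminescence must be positive")
    out = fluorescence / total_luminescence
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------


def group_by_luminescence(records: pd.DataFrame, n_groups: int = 2) -> pd.DataFrame:
    """Partition wells into equal-count luminescence groups.

    Returns a copy of ``records`` with a categorical ``lum_group`` column
    labeled low/(medium)/high by ascending total luminescence. Ties are
    broken by stable input order so the partition always has equal counts
    (up to remainder).
    """
    if n_groups not in GROUP_LABELS:
        raise ValueError("n_groups must be 2 or 3")
    if len(records) < n_groups:
        raise ValueError(
            f"need at least {n_groups} records to form {n_groups} groups"
        )
    lum = records["total_luminescence"].to_numpy(dtype=float)
    if np.any(lum <= 0):
        raise ValueError("total_luminescence must be positive for grouping")
    order = np.argsort(lum, kind="stable")
    ranks = np.empty(len(lum), dtype=int)
    ranks[order] = np.arange(len(lum))
    labels = GROUP_LABELS[n_groups]
    # equal-count split of the rank range
    bins = (ranks * n_groups) // len(lum)
    out = records.copy()
    out["lum_group"] = pd.Categorical(
        [labels[b] for b in bins], categories=labels, ordered=True
    )
    return out


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OneSiteFit:
    """One-site specific binding fit ``y = bret_max * x / (bret_50 + x)``."""

    bret_max: float
    bret_50: float
    se_bret_max: float
    se_bret_50: float
    r_squared: float
    n_points: int
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class SlopeComparison:
    """ANCOVA test of slope equality between two groups."""

    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    slopes: tuple[float, float]


def _one_site(x, bmax, b50):
    return bmax * x / (b50 + x)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return np.nan
    return 1.0 - ss_res / ss_tot


def fit_one_site(x: Sequence[float], y: Sequence[float]) -> OneSiteFit:
    """Nonnegative least-squares fit of the one-site binding hyperbola.

    Initialization Bmax0 = max(y), B50_0 = median(x); both parameters bounded
    below by 0. Non-convergence or a degenerate response is flagged on the
    report rather than raised, so batch pipelines can keep going.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("one-site fit needs at least 3 points")
    if np.any(x < 0):
        raise ValueError("acceptor/donor ratios must be nonnegative")
    n = len(x)
    if np.allclose(y, y[0]):
        return OneSiteFit(
            bret_max=float(y[0]), bret_50=np.nan, se_bret_max=np.nan,
            se_bret_50=np.nan, r_squared=np.nan, n_points=n,
            converged=False, message="degenerate: constant response",
        )
    bmax0 = max(float(np.max(y)), 1e-12)
    b50_0 = max(float(np.median(x)), 1e-12)
    try:
        popt, pcov = optimize.curve_fit(
            _one_site, x, y, p0=[bmax0, b50_0],
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        return OneSiteFit(
            bret_max=np.nan, bret_50=np.nan, se_bret_max=np.nan,
            se_bret_50=np.nan, r_squared=np.nan, n_points=n,
            converged=False, message=str(exc),
        )
    perr = np.sqrt(np.diag(pcov))
    r2 = _r_squared(y, _one_site(x, *popt))
    return OneSiteFit(
        bret_max=float(popt[0]), bret_50=float(popt[1]),
        se_bret_max=float(perr[0]), se_bret_50=float(perr[1]),
        r_squared=r2, n_points=n, converged=True,
    )


def fit_linear(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least squares line with parameter standard errors and R²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("linear fit needs at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("x is constant; slope undefined")
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - 2
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    r2 = _r_squared(y, X @ beta)
    if np.isnan(r2):  # constant y: define R² = 0 (model explains nothing)
        r2 = 0.0
    return LinearFit(
        slope=float(beta[1]), intercept=float(beta[0]),
        se_slope=float(np.sqrt(cov[1, 1])), se_intercept=float(np.sqrt(cov[0, 0])),
        r_squared=r2, n_points=n,
    )


def ancova_equal_slopes(
    group_a: tuple[Sequence[float], Sequence[float]],
    group_b: tuple[Sequence[float], Sequence[float]],
) -> SlopeComparison:
    """Test-of-parallelism ANCOVA for two regression lines.

    Compares the full model (separate intercepts and slopes per group)
    against the reduced common-slope model (separate intercepts, one slope)
    by the extra-sum-of-squares F test on the group x slope interaction:
    ``F = (SSE_reduced - SSE_full) / (SSE_full / (n - 4))`` on (1, n-4)
    degrees of freedom.
    """
    xa, ya = (np.asarray(v, dtype=float) for v in group_a)
    xb, yb = (np.asarray(v, dtype=float) for v in group_b)
    for x, y, name in ((xa, ya, "A"), (xb, yb, "B")):
        if len(x) != len(y):
            raise ValueError(f"group {name}: x and y must have equal length")
        if len(x) < 3:
            raise ValueError(f"group {name}: need at least 3 points")
        if np.allclose(x, x[0]):
            raise ValueError(f"group {name}: x is constant; slope undefined")
    n = len(xa) + len(xb)
    g = np.concatenate([np.zeros(len(xa)), np.ones(len(xb))])
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    # full: intercept, group, x, group*x; reduced: drop the interaction
    X_full = np.column_stack([np.ones(n), g, x, g * x])
    X_red = X_full[:, :3]
    beta_f, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    beta_r, *_ = np.linalg.lstsq(X_red, y, rcond=None)
    sse_f = float(np.sum((y - X_full @ beta_f) ** 2))
    sse_r = float(np.sum((y - X_red @ beta_r) ** 2))
    df_num = 1
    df_den = n - 4
    if df_den <= 0:
        raise ValueError("not enough points for the slope comparison")
    if sse_f <= 0:
        f = np.inf if sse_r > sse_f else 0.0
    else:
        f = max(sse_r - sse_f, 0.0) / df_num / (sse_f / df_den)
    p = float(stats.f.sf(f, df_num, df_den)) if np.isfinite(f) else 0.0
    slope_a = float(beta_f[2])
    slope_b = float(beta_f[2] + beta_f[3])
    return SlopeComparison(
        f_stat=float(f), df_num=df_num, df_den=df_den, p_value=p,
        slopes=(slope_a, slope_b),
    )


# ---------------------------------------------------------------------------
# Type I / Type II pipelines
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Type1Report:
    """Per-donor-group linear fits of BRET ratio vs acceptor expression,
    plus the low-vs-high slope comparison (None for a single group)."""

    group_fits: dict
    comparison: SlopeComparison | None


def type1_analysis(records: pd.DataFrame, n_groups: int = 2) -> Type1Report:
    """Type I analysis: stratify wells by total luminescence (donor
    expression), regress BRET ratio on fluorescence (acceptor expression)
    within each group, and compare the lowest vs highest group's slopes by
    ANCOVA. With ``n_groups=1`` only the pooled linear fit is returned."""
    if n_groups == 1:
        fit = fit_linear(records["fluorescence"], records["bret_ratio"])
        return Type1Report(group_fits={"all": fit}, comparison=None)
    grouped = group_by_luminescence(records, n_groups)
    fits = {}
    for label, sub in grouped.groupby("lum_group", observed=True):
        fits[str(label)] = fit_linear(sub["fluorescence"], sub["bret_ratio"])
    low = grouped[grouped["lum_group"] == "low"]
    high = grouped[grouped["lum_group"] == "high"]
    comparison = ancova_equal_slopes(
        (low["fluorescence"], low["bret_ratio"]),
        (high["fluorescence"], high["bret_ratio"]),
    )
    return Type1Report(group_fits=fits, comparison=comparison)


def type2_analysis(records: pd.DataFrame) -> OneSiteFit:
    """Type II (classical) analysis: pooled one-site fit of BRET ratio
    versus acceptor/donor intensity ratio, ignoring donor grouping. The fit
    R² is the diagnostic of interest."""
    if "intensity_ratio" in records.columns:
        x = records["intensity_ratio"]
    else:
        x = intensity_ratio(
            records["fluorescence"], records["total_luminescence"]
        )
    return fit_one_site(x, records["bret_ratio"])


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Classification:
    verdict: str  # "specific" | "non_specific" | "indeterminate"
    type1_verdict: str
    type2_verdict: str
    type1: Type1Report | None = None
    type2: OneSiteFit | None = None
    reason: str = ""


def classify_interaction(
    records: pd.DataFrame,
    alpha: float = 0.001,
    r2_specific: float = 0.8,
    r2_non_specific: float = 0.5,
) -> Classification:
    """Decide whether a titration dataset reflects specific binding or
    non-specific (bystander) adjacency.

    Primary rule (Type I): the interaction is called *specific* when the
    low-donor slope is positive and significantly steeper than the
    high-donor slope (ANCOVA p < ``alpha``); *non_specific* when the slopes
    are statistically indistinguishable.

    Secondary rule (Type II): pooled one-site R² above ``r2_specific``
    supports specific, below ``r2_non_specific`` supports non_specific,
    in between is inconclusive.

    The Type I verdict takes precedence when the two rules conflict — at
    small sample sizes an adversarial donor/acceptor draw can produce a
    convincing Type II saturation curve from purely non-specific data, while
    the stratified Type I slopes still read non-specific. Both diagnostics
    are always reported.
    """
    if len(records) < 6:
        return Classification(
            verdict="indeterminate", type1_verdict="none", type2_verdict="none",
            reason=f"too few wells ({len(records)}) to stratify and fit",
        )
    try:
        t1 = type1_analysis(records, n_groups=2)
    except ValueError as exc:
        return Classification(
            verdict="indeterminate", type1_verdict="none", type2_verdict="none",
            reason=f"Type I analysis failed: {exc}",
        )
    t2 = type2_analysis(records)

    cmp = t1.comparison
    s_low, s_high = cmp.slopes
    if cmp.p_value < alpha and s_low > s_high and s_low > 0:
        t1_verdict = "specific"
    elif cmp.p_value >= alpha:
        t1_verdict = "non_specific"
    else:  # significant difference in the unexpected direction
        t1_verdict = "inconclusive"

    if not t2.converged or not np.isfinite(t2.r_squared):
        t2_verdict = "inconclusive"
    elif t2.r_squared > r2_specific:
        t2_verdict = "specific"
    elif t2.r_squared < r2_non_specific:
        t2_verdict = "non_specific"
    else:
        t2_verdict = "inconclusive"

    if t1_verdict in ("specific", "non_specific"):
        verdict = t1_verdict
        reason = (
            "Type I and Type II agree"
            if t2_verdict in (t1_verdict, "inconclusive")
            else "Type I overrides conflicting Type II evidence"
        )
    elif t2_verdict in ("specific", "non_specific"):
        verdict = t2_verdict
        reason = "Type I inconclusive; falling back to Type II"
    else:
        verdict = "indeterminate"
        reason = "both diagnostics inconclusive"
    return Classification(
        verdict=verdict, type1_verdict=t1_verdict, type2_verdict=t2_verdict,
        type1=t1, type2=t2, reason=reason,
    )
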