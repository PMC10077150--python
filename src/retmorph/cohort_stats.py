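"""Cohort-level statistics for the morphometric metrics.

Mirrors the analysis plan of a cross-sectional pediatric cohort: per-metric
ordinary least-squares regressions on age in days (curvature on the natural
log scale), a segmented regression for caliber with a fixed breakpoint at
1,095 days (3 years), the density–fractal-dimension Pearson correlation,
one-way ANOVA across six one-year age groups with Tukey HSD pairwise
comparisons, per-group sex t-tests, D'Agostino–Pearson normality checks,
and group mean ± SD summaries. Significance is assessed at α = 0.05 with no
multiple-testing correction across metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .synthetic import BREAKPOINT_DAYS, DAYS_PER_YEAR

__all__ = [
    "LinearFit",
    "SegmentedFit",
    "GroupComparison",
    "TTestResult",
    "NormalityResult",
    "fit_linear",
    "fit_segmented",
    "pearson_corr",
    "anova_oneway",
    "ttest_by_sex",
    "normality_test",
    "loess_smooth",
    "analyze_cohort",
    "METRIC_COLUMNS",
]

#: Metric columns of a cohort table, in report order.
METRIC_COLUMNS = [
    "disc_diameter_mm",
    "fractal_dimension",
    "caliber_um",
    "density_fraction",
    "curvature_px_inv",
]

_REQUIRED_COLUMNS = ["age_days", "sex"] + METRIC_COLUMNS


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    residual_sd: float

    def as_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r_squared": self.r_squared, "p_value": self.p_value,
                "n": self.n, "residual_sd": self.residual_sd}


@dataclass(frozen=True)
class SegmentedFit:
    breakpoint_days: int
    left: LinearFit
    right: LinearFit

    def as_dict(self) -> dict:
        return {"breakpoint_days": self.breakpoint_days,
                "left": self.left.as_dict(), "right": self.right.as_dict()}


@dataclass(frozen=True)
class GroupComparison:
    f_statistic: float
    p_value: float
    group_means: list[float]
    group_sds: list[float]
    group_ns: list[int]
    pairwise: list[tuple[int, int, float]]  # (group_i, group_j, adjusted p)

    def as_dict(self) -> dict:
        return {"f_statistic": self.f_statistic, "p_value": self.p_value,
                "group_means": self.group_means, "group_sds": self.group_sds,
                "group_ns": self.group_ns,
                "pairwise": [list(t) for t in self.pairwise]}


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    p_value: float
    mean_female: float
    mean_male: float
    n_female: int
    n_male: int

    def as_dict(self) -> dict:
        return {"t_statistic": self.t_statistic, "p_value": self.p_value,
                "mean_female": self.mean_female, "mean_male": self.mean_male,
                "n_female": self.n_female, "n_male": self.n_male}


@dataclass(frozen=True)
class NormalityResult:
    k2_statistic: float
    p_value: float
    verdict: str  # "normal" or "skewed"

    def as_dict(self) -> dict:
        return {"k2_statistic": self.k2_statistic, "p_value": self.p_value,
                "verdict": self.verdict}


def fit_linear(age_days, metric) -> LinearFit:
    """OLS of metric on age; two-sided slope p from t with n−2 df."""
    x = np.asarray(age_days, dtype=float)
    y = np.asarray(metric, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("age and metric must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) == 0:
        raise ValueError("constant predictor: age has zero variance")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    rsd = float(np.sqrt(resid @ resid / (n - 2)))
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=float(res.rvalue ** 2), p_value=float(res.pvalue),
                     n=n, residual_sd=rsd)


def fit_segmented(age_days, metric, breakpoint: int = BREAKPOINT_DAYS) -> SegmentedFit:
    """Two independent OLS fits split at a fixed breakpoint (no continuity).

    Points with age < breakpoint form the left piece, the rest the right
    piece; each side needs at least three points.
    """
    x = np.asarray(age_days, dtype=float)
    y = np.asarray(metric, dtype=float)
    left = x < breakpoint
    if left.sum() < 3 or (~left).sum() < 3:
        raise ValueError(
            f"segmented fit needs >= 3 points on each side of {breakpoint} "
            f"(got {int(left.sum())} left, {int((~left).sum())} right)")
    return SegmentedFit(breakpoint_days=int(breakpoint),
                        left=fit_linear(x[left], y[left]),
                        right=fit_linear(x[~left], y[~left]))


def pearson_corr(a, b) -> dict[str, float]:
    """Sample Pearson correlation with two-sided p and r²."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(a, b)
    return {"r": float(r), "p": float(p), "r_squared": float(r * r)}


def anova_oneway(metric_by_group: list[np.ndarray],
                 posthoc: str = "tukey") -> GroupComparison:
    """One-way ANOVA across groups with optional Tukey HSD pairwise tests."""
    groups = [np.asarray(g, dtype=float) for g in metric_by_group if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    f, p = stats.f_oneway(*groups)
    pairwise: list[tuple[int, int, float]] = []
    if posthoc == "tukey":
        values = np.concatenate(groups)
        labels = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
        res = pairwise_tukeyhsd(values, labels)
        # pairwise_tukeyhsd orders comparisons (0,1), (0,2), ..., (k-2,k-1)
        idx = 0
        k = len(groups)
        for i in range(k):
            for j in range(i + 1, k):
                pairwise.append((i, j, float(res.pvalues[idx])))
                idx += 1
    return GroupComparison(
        f_statistic=float(f), p_value=float(p),
        group_means=[float(g.mean()) for g in groups],
        group_sds=[float(g.std(ddof=1)) for g in groups],
        group_ns=[len(g) for g in groups],
        pairwise=pairwise)


def ttest_by_sex(metric, sex, equal_var: bool = True) -> TTestResult:
    """Two-sided two-sample t-test, female vs male (Welch via equal_var=False)."""
    y = np.asarray(metric, dtype=float)
    s = np.asarray(sex)
    f = y[s == "female"]
    m = y[s == "male"]
    if len(f) < 2 or len(m) < 2:
        raise ValueError("both sexes need n >= 2")
    t, p = stats.ttest_ind(f, m, equal_var=equal_var)
    return TTestResult(t_statistic=float(t), p_value=float(p),
                       mean_female=float(f.mean()), mean_male=float(m.mean()),
                       n_female=len(f), n_male=len(m))


def normality_test(metric, alpha: float = 0.05) -> NormalityResult:
    """D'Agostino–Pearson K² omnibus normality test (skewness + kurtosis).

    The verdict selects mean ± SD ("normal") vs median [IQR] ("skewed")
    reporting downstream.
    """
    y = np.asarray(metric, dtype=float)
    if len(y) < 20:
        raise ValueError("normality test requires n >= 20")
    if np.var(y) == 0:
        raise ValueError("zero-variance input")
    k2, p = stats.normaltest(y)
    return NormalityResult(k2_statistic=float(k2), p_value=float(p),
                           verdict="normal" if p >= alpha else "skewed")


def loess_smooth(x, y, frac: float = 0.75) -> np.ndarray:
    """Tri-cube weighted local linear (LOESS) smooth, for plotting only."""
    return lowess(np.asarray(y, float), np.asarray(x, float), frac=frac,
                  return_sorted=True)


def _age_group(age_days: np.ndarray) -> np.ndarray:
    return np.minimum(np.asarray(age_days) // DAYS_PER_YEAR, 5).astype(int)


def _try(fn, *args, **kw):
    try:
        out = fn(*args, **kw)
        return out.as_dict() if hasattr(out, "as_dict") else out
    except ValueError as e:
        return {"error": str(e)}


def analyze_cohort(table: pd.DataFrame, breakpoint: int = BREAKPOINT_DAYS,
                   equal_var: bool = True, posthoc: str = "tukey",
                   alpha: float = 0.05) -> dict:
    """Full statistical report for one cohort table.

    Per metric: normality verdict and group summaries, the OLS age trend
    (curvature regressed on its natural log), one-way ANOVA over the six
    age groups with pairwise comparisons, and a per-age-group sex t-test.
    Caliber additionally receives the segmented fit at the fixed breakpoint
    and a LOESS smooth (plotting aid, not a statistic). Density and fractal
    dimension are correlated across the whole cohort. Individual tests that
    fail their preconditions (e.g. a single-sex age group) are reported as
    ``{"error": ...}`` entries rather than aborting the report.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    age = table["age_days"].to_numpy()
    groups = _age_group(age)
    report: dict = {"n": int(len(table)), "metrics": {}}
    for col in METRIC_COLUMNS:
        y = table[col].to_numpy(dtype=float)
        y_fit = np.log(y) if col == "curvature_px_inv" else y
        entry: dict = {
            "normality": _try(normality_test, y, alpha),
            "linear_fit": _try(fit_linear, age, y_fit),
            "linear_fit_scale": "ln" if col == "curvature_px_inv" else "identity",
            "anova": _try(anova_oneway, [y[groups == g] for g in range(6)], posthoc),
            "sex_ttests": {
                str(g): _try(ttest_by_sex, y[groups == g],
                             table["sex"].to_numpy()[groups == g], equal_var)
                for g in range(6)
            },
            "group_summary": {
                str(g): {"n": int((groups == g).sum()),
                         "mean": float(np.mean(y[groups == g])) if (groups == g).any() else None,
                         "sd": float(np.std(y[groups == g], ddof=1)) if (groups == g).sum() > 1 else None}
                for g in range(6)
            },
        }
        if col == "caliber_um":
            entry["segmented_fit"] = _try(fit_segmented, age, y, breakpoint)
            entry["loess"] = _try(
                lambda: {"points": loess_smooth(age, y).tolist()})
        report["metrics"][col] = entry
    report["density_fd_correlation"] = _try(
        pearson_corr, table["density_fraction"].to_numpy(),
        table["fractal_dimension"].to_numpy())
    return report
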