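"""Group comparison across severity grades.

Descriptive summaries per grade, assumption checks (Shapiro-Wilk
normality, classic mean-centered Levene homogeneity), Welch's
heteroscedastic one-way ANOVA, and the Games-Howell pairwise post hoc
based on the studentized range distribution with Welch-Satterthwaite
degrees of freedom. Assumption checks are reported only -- the pipeline
always runs Welch/Games-Howell regardless of their outcome.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from hipcongruency.errors import DegenerateVarianceError, SampleSizeError
from hipcongruency.agreement import ci_mean_from_summary


@dataclass(frozen=True)
class GradeSummary:
    """Descriptive row for one grade: n, mean, SD, 95% CI, min, max."""

    grade: str
    n: int
    mean: float
    sd: float
    ci_lower: float
    ci_upper: float
    min: float
    max: float


@dataclass(frozen=True)
class WelchAnovaResult:
    f_value: float
    df1: float
    df2: float
    p_value: float


@dataclass(frozen=True)
class PosthocCell:
    """One Games-Howell pairwise comparison."""

    grade_i: str
    grade_j: str
    mean_diff: float
    se: float
    t_statistic: float
    welch_df: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class AssumptionReport:
    shapiro_p: dict[str, float]  # per-grade normality p (NaN when skipped)
    levene_p: float
    levene_statistic: float


def _as_groups(g: Mapping[str, Sequence[float]], min_n: int = 2) -> dict[str, np.ndarray]:
    groups = {}
    for grade, values in g.items():
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            warnings.warn(f"group {grade!r} is empty and was excluded")
            continue
        groups[str(grade)] = arr
    if len(groups) < 2:
        raise SampleSizeError(f"need >= 2 non-empty groups, got {len(groups)}")
    for grade, arr in groups.items():
        if arr.size < min_n:
            raise SampleSizeError(f"group {grade!r} has n={arr.size} < {min_n}")
    return groups


def describe_groups(g: Mapping[str, Sequence[float]], level: float = 0.95) -> list[GradeSummary]:
    """Per-grade descriptives; SD uses the n-1 denominator, CI is t-based."""
    out = []
    for grade in sorted(g):
        arr = np.asarray(g[grade], dtype=float)
        if arr.size == 0:
            warnings.warn(f"group {grade!r} is empty and was excluded")
            continue
        n = int(arr.size)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if n > 1 else 0.0
        lo, hi = ci_mean_from_summary(mean, sd, n, level) if n > 1 else (mean, mean)
        out.append(GradeSummary(grade, n, mean, sd, lo, hi, float(arr.min()), float(arr.max())))
    return out


def welch_anova(g: Mapping[str, Sequence[float]]) -> WelchAnovaResult:
    """Welch's heteroscedastic one-way ANOVA.

    Weights each group by n_i / s_i^2; the denominator correction and the
    Satterthwaite-style df2 follow the standard Welch (1951) formulation.
    """
    groups = _as_groups(g)
    k = len(groups)
    ns = np.array([arr.size for arr in groups.values()], dtype=float)
    means = np.array([arr.mean() for arr in groups.values()])
    variances = np.array([arr.var(ddof=1) for arr in groups.values()])
    if np.any(variances == 0.0):
        bad = [grade for grade, arr in groups.items() if arr.var(ddof=1) == 0.0]
        raise DegenerateVarianceError(f"zero-variance group(s): {', '.join(bad)}")
    w = ns / variances
    W = w.sum()
    grand = float(np.sum(w * means) / W)
    lam = float(np.sum((1.0 - w / W) ** 2 / (ns - 1.0)))
    num = float(np.sum(w * (means - grand) ** 2)) / (k - 1)
    den = 1.0 + (2.0 * (k - 2) / (k * k - 1.0)) * lam
    f = num / den
    df1 = k - 1
    df2 = (k * k - 1.0) / (3.0 * lam)
    p = float(stats.f.sf(f, df1, df2))
    return WelchAnovaResult(float(f), float(df1), float(df2), p)


def games_howell(g: Mapping[str, Sequence[float]], alpha: float = 0.05) -> list[PosthocCell]:
    """Games-Howell pairwise comparisons for unequal variances and sizes.

    For each pair: se = sqrt(s_i^2/n_i + s_j^2/n_j), Welch-Satterthwaite
    df, and p from the studentized range distribution with the total
    number of groups k and q = |mean_i - mean_j| / (se / sqrt(2)).
    """
    groups = _as_groups(g)
    k = len(groups)
    stats_by_grade = {
        grade: (arr.size, arr.mean(), arr.var(ddof=1)) for grade, arr in groups.items()
    }
    for grade, (_, _, v) in stats_by_grade.items():
        if v == 0.0:
            raise DegenerateVarianceError(f"zero-variance group: {grade}")
    cells = []
    for gi, gj in combinations(sorted(groups), 2):
        ni, mi, vi = stats_by_grade[gi]
        nj, mj, vj = stats_by_grade[gj]
        se = math.sqrt(vi / ni + vj / nj)
        diff = mi - mj
        t = diff / se
        df = (vi / ni + vj / nj) ** 2 / (
            (vi / ni) ** 2 / (ni - 1) + (vj / nj) ** 2 / (nj - 1)
        )
        q = abs(t) * math.sqrt(2.0)
        p = float(stats.studentized_range.sf(q, k, df))
        p = min(max(p, 0.0), 1.0)
        cells.append(
            PosthocCell(
                grade_i=gi,
                grade_j=gj,
                mean_diff=float(diff),
                se=float(se),
                t_statistic=float(t),
                welch_df=float(df),
                p_value=p,
                significant=bool(p < alpha),
            )
        )
    return cells


def assumption_checks(g: Mapping[str, Sequence[float]]) -> AssumptionReport:
    """Shapiro-Wilk normality per group and classic (mean-centered) Levene.

    Groups with n < 3 get NaN normality p-values with a warning. The
    report is informational; it never switches the comparison method.
    """
    groups = _as_groups(g)
    shapiro_p: dict[str, float] = {}
    for grade, arr in groups.items():
        if arr.size < 3:
            warnings.warn(f"group {grade!r} has n < 3; normality check skipped")
            shapiro_p[grade] = math.nan
        else:
            shapiro_p[grade] = float(stats.shapiro(arr).pvalue)
    if all(np.ptp(arr) == 0 for arr in groups.values()):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.levene(*groups.values(), center="mean")
    return AssumptionReport(shapiro_p=shapiro_p, levene_p=float(p), levene_statistic=float(stat))
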