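"""Paired agreement and reliability statistics.

Implements the preliminary-study battery for duplicate measurements:
paired t-test, Bland-Altman limits of agreement (mean difference
+/- 1.96 SD, with a t-based 95% CI of the mean difference), and the
two-way mixed, single-measure, consistency intraclass correlation
ICC(3,1) in the Shrout-Fleiss convention, with its F-based confidence
interval and a verbal interpretation scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from hipcongruency.errors import IncompleteDataError, ParameterError, SampleSizeError

#: multiplier for 95% limits of agreement (fixed constant, not a t quantile)
LOA_Z = 1.96

ICC_BANDS = (
    (0.5, "poor"),
    (0.75, "moderate"),
    (0.9, "good"),
    (1.0, "excellent"),
)


@dataclass(frozen=True)
class PairedSeries:
    """Two aligned measurement vectors over the same units (hips)."""

    values_a: tuple[float, ...]
    values_b: tuple[float, ...]
    unit_ids: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if len(self.values_a) != len(self.values_b):
            raise SampleSizeError(
                f"paired series lengths differ: {len(self.values_a)} vs {len(self.values_b)}"
            )
        if len(self.values_a) < 2:
            raise SampleSizeError(f"need n >= 2 pairs, got {len(self.values_a)}")
        if self.unit_ids is not None and len(self.unit_ids) != len(self.values_a):
            raise SampleSizeError("unit_ids length does not match values")

    @classmethod
    def from_arrays(cls, a: Sequence[float], b: Sequence[float], ids: Optional[Sequence[str]] = None):
        return cls(tuple(float(x) for x in a), tuple(float(x) for x in b), tuple(ids) if ids else None)

    @property
    def n(self) -> int:
        return len(self.values_a)

    def differences(self) -> np.ndarray:
        return np.asarray(self.values_a) - np.asarray(self.values_b)


@dataclass(frozen=True)
class PairedTResult:
    mean_diff: float
    sd_diff: float
    ci_lower: float
    ci_upper: float
    t_statistic: float  # nan when the differences are constant
    df: int
    p_value: float  # nan when degenerate
    n: int
    degenerate: bool


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_mean_lower: float
    ci_mean_upper: float
    n: int
    averages: tuple[float, ...]  # per-pair means, for plotting
    differences: tuple[float, ...]  # per-pair differences, for plotting


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_lower: float
    ci_upper: float
    f_value: float
    df1: int
    df2: int
    p_value: float
    interpretation: str


def ci_mean_from_summary(mean: float, sd: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Two-sided t-based confidence interval of a mean from (mean, SD, n)."""
    if n < 2:
        raise SampleSizeError(f"need n >= 2, got {n}")
    if sd < 0:
        raise ParameterError(f"sd must be >= 0, got {sd}")
    half = stats.t.ppf(0.5 + level / 2.0, n - 1) * sd / math.sqrt(n)
    return mean - half, mean + half


def loa_from_summary(mean_diff: float, sd_diff: float) -> tuple[float, float]:
    """95% limits of agreement: mean difference +/- 1.96 SD."""
    if sd_diff < 0:
        raise ParameterError(f"sd must be >= 0, got {sd_diff}")
    return mean_diff - LOA_Z * sd_diff, mean_diff + LOA_Z * sd_diff


def paired_t_test(s: PairedSeries) -> PairedTResult:
    """Two-sided paired t-test on the differences a - b.

    Zero-variance differences yield a degenerate result: the t statistic
    and p-value are NaN and the CI collapses to the mean difference.
    """
    d = s.differences()
    n = s.n
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        return PairedTResult(mean, 0.0, mean, mean, math.nan, n - 1, math.nan, n, True)
    se = sd / math.sqrt(n)
    t = mean / se
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    lo, hi = ci_mean_from_summary(mean, sd, n)
    return PairedTResult(mean, sd, lo, hi, t, n - 1, p, n, False)


def bland_altman(s: PairedSeries) -> BlandAltmanResult:
    """Bland-Altman agreement summary plus per-pair plot coordinates."""
    d = s.differences()
    avg = (np.asarray(s.values_a) + np.asarray(s.values_b)) / 2.0
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_lo, loa_hi = loa_from_summary(mean, sd)
    if sd == 0.0:
        ci_lo = ci_hi = mean
    else:
        ci_lo, ci_hi = ci_mean_from_summary(mean, sd, s.n)
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_lower=loa_lo,
        loa_upper=loa_hi,
        ci_mean_lower=ci_lo,
        ci_mean_upper=ci_hi,
        n=s.n,
        averages=tuple(float(x) for x in avg),
        differences=tuple(float(x) for x in d),
    )


def interpret_icc(icc_value: float) -> str:
    """Verbal reliability band for an ICC value.

    0 is "random" and 1 is "perfect"; the open bands are
    inclusive-lower/exclusive-upper: [0, 0.5) poor, [0.5, 0.75) moderate,
    [0.75, 0.9) good, [0.9, 1) excellent.
    """
    if icc_value == 0.0:
        return "random"
    if icc_value == 1.0:
        return "perfect"
    for upper, label in ICC_BANDS:
        if icc_value < upper:
            return label
    return "perfect"


def adequate_reliability(icc_ci_lower: float) -> bool:
    """Adequate reliability: the lower 95% CI bound of the ICC exceeds 0.75."""
    return icc_ci_lower > 0.75


def icc_3_1(ratings: np.ndarray, level: float = 0.95) -> IccResult:
    """ICC(3,1): two-way mixed effects, single measure, consistency.

    ``ratings`` is an n-units x k-raters matrix with no missing cells.
    From the two-way ANOVA decomposition (rows = units, columns = raters):

        ICC = (MS_R - MS_E) / (MS_R + (k - 1) MS_E)

    with F = MS_R / MS_E on (n-1, (n-1)(k-1)) degrees of freedom; the CI
    uses the standard F-bound construction. A constant-residual matrix
    (MS_E = 0) degenerates to ICC 1 with a point CI.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ParameterError(f"ratings must be 2-D, got shape {x.shape}")
    n, k = x.shape
    if n < 5:
        raise SampleSizeError(f"need at least 5 units, got {n}")
    if k < 2:
        raise SampleSizeError(f"need at least 2 raters, got {k}")
    if not np.all(np.isfinite(x)):
        raise IncompleteDataError("ratings matrix has missing or non-finite cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((x - grand) ** 2))
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    ms_r = ss_rows / df1
    ms_e = ss_err / df2

    if ms_e == 0.0:
        icc = 1.0
        return IccResult(icc, 1.0, 1.0, math.inf, df1, df2, 0.0, interpret_icc(icc))

    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    f = ms_r / ms_e
    p = float(stats.f.sf(f, df1, df2))
    alpha = 1.0 - level
    fl = f / stats.f.ppf(1.0 - alpha / 2.0, df1, df2)
    fu = f * stats.f.ppf(1.0 - alpha / 2.0, df2, df1)
    lower = (fl - 1.0) / (fl + k - 1.0)
    upper = (fu - 1.0) / (fu + k - 1.0)
    return IccResult(icc, float(lower), float(upper), float(f), df1, df2, p, interpret_icc(icc))
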