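"""Descriptive and inferential statistics for the screening cascade.

The analysis cascade: patients are grouped by the three-dimensional outcomes
(SASN: A_min < 80 mm^2; RSAV: V_PAS < 12 cm^3, both strict); descriptives are
normality-gated (mean +/- SD when a Lilliefors-corrected Kolmogorov-Smirnov
test does not reject, median +/- IQR otherwise); group differences use the
pooled-variance two-sample t-test, gender ratios the Pearson chi-squared test
without continuity correction; associations use Pearson correlation with
effect-size bands (weak |r| < 0.20, medium 0.20..0.30, strong > 0.30);
multiple testing is controlled per table family with the Benjamini-Hochberg
step-up adjustment; and rater reliability uses the intraclass correlation
ICC(A,1) — two-way model, absolute agreement, single rater — with its
F-based 95% confidence interval and the conventional reliability bands
(poor < 0.50, moderate < 0.75, good < 0.90, very good >= 0.90).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateSampleError,
    DegenerateTableError,
    MissingCellError,
    SchemaError,
)
from .reference import RSAV_VPAS_CUT, SASN_AMIN_CUT

ALPHA = 0.05


# --------------------------------------------------------------------------
# grouping
# --------------------------------------------------------------------------

@dataclass
class GroupAssignment:
    """Per-patient outcome flags and the thresholds that produced them."""

    sasn: pd.Series       # True: A_min < amin_cut
    rsav: pd.Series       # True: V_PAS < vpas_cut
    amin_cut: float
    vpas_cut: float

    @property
    def counts(self) -> dict[str, int]:
        return {
            "A1": int(self.sasn.sum()), "A2": int((~self.sasn).sum()),
            "B1": int(self.rsav.sum()), "B2": int((~self.rsav).sum()),
        }


def assign_groups(cohort: pd.DataFrame, amin_cut: float = SASN_AMIN_CUT,
                  vpas_cut: float = RSAV_VPAS_CUT) -> GroupAssignment:
    """Flag SASN (A_min < cut) and RSAV (V_PAS < cut), strict inequalities."""
    for col in ("A_min", "V_PAS"):
        if col not in cohort.columns:
            raise SchemaError(f"cohort table lacks required column {col!r}")
        if not np.all(np.isfinite(cohort[col].to_numpy(dtype=float))):
            raise SchemaError(f"column {col!r} contains non-finite values")
    return GroupAssignment(
        sasn=cohort["A_min"] < amin_cut,
        rsav=cohort["V_PAS"] < vpas_cut,
        amin_cut=amin_cut,
        vpas_cut=vpas_cut,
    )


# --------------------------------------------------------------------------
# normality and descriptives
# --------------------------------------------------------------------------

def ks_normality(x) -> float:
    """Lilliefors-corrected one-sample KS p-value against a fitted normal."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise DegenerateSampleError("normality test needs n >= 4")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("constant sample has no defined distribution")
    _, p = lilliefors(x, dist="norm")
    return float(p)


@dataclass
class Descriptive:
    """Normality-gated descriptive: mean+/-SD or median+/-IQR."""

    center: float
    spread: float | None
    kind: str              # "mean±SD" or "median±IQR"
    n: int
    normal_p: float | None

    def __str__(self) -> str:
        if self.spread is None:
            return f"{self.center:.1f}"
        return f"{self.center:.1f} ± {self.spread:.1f}"


def describe(x, force_normal: bool | None = None) -> Descriptive:
    """Describe a sample as mean+/-SD when normal, median+/-IQR when not.

    ``force_normal`` overrides the gate (used when a table reports a uniform
    format). Both raw statistics remain recomputable from the data.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise DegenerateSampleError("cannot describe an empty sample")
    if x.size == 1:
        return Descriptive(float(x[0]), None, "mean±SD", 1, None)
    if force_normal is None:
        try:
            p = ks_normality(x)
            normal = p >= ALPHA
        except DegenerateSampleError:
            p, normal = None, True
    else:
        p, normal = None, force_normal
    if normal:
        return Descriptive(float(np.mean(x)), float(np.std(x, ddof=1)),
                           "mean±SD", int(x.size), p)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return Descriptive(float(med), float(q3 - q1), "median±IQR", int(x.size), p)


# --------------------------------------------------------------------------
# intergroup tests
# --------------------------------------------------------------------------

@dataclass
class TestResult:
    statistic: float
    df: float
    p_raw: float
    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    p_fdr: float | None = None


def students_t(x1, x2) -> TestResult:
    """Pooled-variance (Student) two-sample t-test, two-sided."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x1, x2 = x1[np.isfinite(x1)], x2[np.isfinite(x2)]
    if x1.size < 2 or x2.size < 2:
        raise DegenerateSampleError("t-test needs n >= 2 per group")
    if np.ptp(x1) == 0 and np.ptp(x2) == 0:
        raise DegenerateSampleError("zero pooled variance")
    t, p = sps.ttest_ind(x1, x2, equal_var=True)
    return TestResult(
        statistic=float(t), df=float(x1.size + x2.size - 2), p_raw=float(p),
        n1=int(x1.size), n2=int(x2.size),
        mean1=float(np.mean(x1)), sd1=float(np.std(x1, ddof=1)),
        mean2=float(np.mean(x2)), sd2=float(np.std(x2, ddof=1)),
    )


def chi_squared_2x2(counts) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, df=1, no continuity correction."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0) or np.any(table != np.round(table)):
        raise DegenerateTableError("counts must be a 2x2 table of nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateTableError("chi-squared table has a zero margin")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


# --------------------------------------------------------------------------
# correlation
# --------------------------------------------------------------------------

def correlation_category(r: float) -> str:
    """Effect-size band for |r|: weak < 0.20 <= medium <= 0.30 < strong."""
    a = abs(r)
    if a < 0.20:
        return "weak"
    if a <= 0.30:
        return "medium"
    return "strong"


@dataclass
class CorrelationResult:
    r: float
    p_raw: float
    n: int
    category: str
    p_fdr: float | None = None


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with pairwise deletion of absent values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise DegenerateSampleError("Pearson correlation needs n >= 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSampleError("zero variance in a correlation input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), int(x.size),
                             correlation_category(float(r)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one family per call)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


# --------------------------------------------------------------------------
# intraclass correlation
# --------------------------------------------------------------------------

def icc_category(icc: float) -> str:
    """Reliability band: poor < 0.50 <= moderate < 0.75 <= good < 0.90 <= very good."""
    if icc < 0.50:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.90:
        return "good"
    return "very good"


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str
    category: str
    n_subjects: int
    n_raters: int


def icc_a1(table, alpha: float = ALPHA) -> IccResult:
    """ICC(A,1): two-way model, absolute agreement, single rater.

    From the two-way ANOVA mean squares (MSR subjects, MSC raters, MSE
    residual)::

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with the F-based confidence interval using a Satterthwaite
    denominator-degrees-of-freedom approximation.
    """
    y = np.asarray(table, dtype=float)
    if y.ndim != 2:
        raise MissingCellError("rater table must be 2-dimensional (subjects x raters)")
    if not np.all(np.isfinite(y)):
        raise MissingCellError("rater table has missing cells")
    n, k = y.shape
    if n < 2 or k < 2:
        raise DegenerateSampleError("ICC needs >= 2 subjects and >= 2 raters")

    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise DegenerateSampleError("degenerate rater table (no variance)")
    icc = (msr - mse) / denom

    if mse == 0 and msc == 0:  # perfect agreement
        lo = hi = 1.0
    else:
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        if np.isinf(a) or np.isinf(b):
            lo = hi = 1.0
        else:
            num_v = (a * msc + b * mse) ** 2
            den_v = ((a * msc) ** 2 / (k - 1.0)
                     + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0)))
            v = num_v / den_v if den_v > 0 else 1.0
            f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (n * (msr - f_l * mse)
                  / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
            hi = (n * (f_u * msr - mse)
                  / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
    lo, hi = float(min(lo, icc)), float(max(hi, icc))
    return IccResult(
        icc=float(icc), ci_low=max(lo, -1.0), ci_high=min(hi, 1.0),
        model="two-way mixed, absolute agreement, single rater",
        category=icc_category(float(icc)), n_subjects=n, n_raters=k,
    )
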