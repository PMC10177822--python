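"""Reader-agreement and group-comparison statistics.

Agreement between readers scoring images on a Likert scale is quantified by
the intraclass correlation in its two-way mixed, consistency form — ICC(3,1)
in the Shrout–Fleiss taxonomy — with the average-measure ICC(3,k) available
behind a flag, and by Cohen's kappa for two readers on categorical scores.
Group comparisons use the Wilcoxon–Mann–Whitney rank test (exact enumeration
for small samples, tie-corrected normal approximation otherwise), Welch's
t-test, and a Kolmogorov–Smirnov check against a normal with the sample's
own mean/SD (the classical KS p-value is conservative when parameters are
estimated — the Lilliefors caveat).

Agreement bands: poor < 0.5, moderate 0.5–0.75, good 0.76–0.9, excellent
> 0.9. The printed band edges leave 0.75–0.76 unassigned; the boundary is
resolved at 0.755 (good iff ICC >= 0.755).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from .errors import ConfigError, UndefinedStatisticError

__all__ = [
    "RaterTable",
    "AgreementResult",
    "DescriptiveSummary",
    "icc_consistency",
    "agreement_band",
    "cohens_kappa",
    "kappa_from_confusion",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "welch_t",
    "ks_normality",
    "describe",
]


@dataclass(frozen=True)
class RaterTable:
    """Items x raters grid of scores on a bounded ordinal scale."""

    scores: np.ndarray
    scale_min: float = 1
    scale_max: float = 5
    parameter: str = ""

    def __post_init__(self) -> None:
        sc = np.asarray(self.scores, dtype=np.float64)
        if sc.ndim != 2:
            raise ConfigError("scores must be an items x raters 2D array")
        if sc.shape[0] < 2 or sc.shape[1] < 2:
            raise ConfigError("need at least 2 items and 2 raters")
        if sc.min() < self.scale_min or sc.max() > self.scale_max:
            raise ConfigError("scores fall outside the declared scale")
        object.__setattr__(self, "scores", sc)

    @property
    def n_items(self) -> int:
        return self.scores.shape[0]

    @property
    def n_raters(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class AgreementResult:
    """ICC value with its qualitative band; ``undefined`` flags degenerate
    tables (zero between-item variance) where no number is meaningful."""

    icc_value: float | None
    band: str | None
    form: str = "ICC(3,1)"
    kappa: float | None = None
    undefined: bool = False


def agreement_band(icc: float) -> str:
    """Map an ICC value to poor/moderate/good/excellent."""
    if icc < 0.5:
        return "poor"
    if icc < 0.755:
        return "moderate"
    if icc <= 0.9:
        return "good"
    return "excellent"


def icc_consistency(table: RaterTable, average_measures: bool = False
                    ) -> AgreementResult:
    """Two-way mixed-effects, consistency ICC from the ANOVA decomposition.

    Single-rater ICC(3,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E); with
    ``average_measures`` the ICC(3,k) = (MS_R - MS_E) / MS_R of the k-rater
    mean is returned. Consistency ignores systematic per-rater offsets by
    construction. Tables with zero between-item variance yield an
    undefined-flagged result, not a number.
    """
    y = table.scores
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    scale = max(ss_total, 1.0)
    if ss_rows <= 1e-12 * scale:
        return AgreementResult(None, None, undefined=True,
                               form="ICC(3,k)" if average_measures else "ICC(3,1)")
    if average_measures:
        icc = (ms_rows - ms_err) / ms_rows
        form = "ICC(3,k)"
    else:
        icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
        form = "ICC(3,1)"
    return AgreementResult(float(icc), agreement_band(float(icc)), form=form)


def cohens_kappa(rater_a, rater_b) -> float:
    """Cohen's kappa for two raters on categorical (integer Likert) scores.

    kappa = (p_o - p_e) / (1 - p_e), with expected agreement p_e from the
    product of the two raters' marginal category frequencies.
    """
    a = np.asarray(rater_a).ravel()
    b = np.asarray(rater_b).ravel()
    if a.shape != b.shape or a.size == 0:
        raise ConfigError("raters must score the same non-empty item set")
    cats = np.union1d(a, b)
    p_o = np.mean(a == b)
    fa = np.array([np.mean(a == c) for c in cats])
    fb = np.array([np.mean(b == c) for c in cats])
    p_e = float(fa @ fb)
    if p_e >= 1.0 - 1e-12:
        raise UndefinedStatisticError(
            "kappa undefined: both raters constant and equal (p_e = 1)")
    return float((p_o - p_e) / (1.0 - p_e))


def kappa_from_confusion(confusion) -> float:
    """Cohen's kappa from a square confusion-count matrix."""
    m = np.asarray(confusion, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConfigError("confusion matrix must be square")
    total = m.sum()
    p_o = np.trace(m) / total
    p_e = float(m.sum(axis=1) @ m.sum(axis=0)) / total**2
    if p_e >= 1.0 - 1e-12:
        raise UndefinedStatisticError("kappa undefined: p_e = 1")
    return float((p_o - p_e) / (1.0 - p_e))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample ``a``: #(a > b) pairs + half-ties."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney(a, b, exact_max_n: int = 8) -> tuple[float, float]:
    """Wilcoxon–Mann–Whitney test; returns (U of the first sample, two-sided p).

    When both samples have at most ``exact_max_n`` observations the p-value
    is the exact permutation tail Pr(|U' - nm/2| >= |U - nm/2|) over all
    C(n+m, n) group assignments (valid under ties). Larger samples use the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ConfigError("both samples must be non-empty")
    n, m = a.size, b.size
    u = _u_statistic(a, b)
    if n <= exact_max_n and m <= exact_max_n:
        pooled = np.concatenate([a, b])
        half = n * m / 2.0
        obs = abs(u - half) - 1e-12
        hits = 0
        idx = np.arange(n + m)
        for pick in combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(pick)] = True
            u_p = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u_p - half) >= obs:
                hits += 1
        return u, hits / comb(n + m, n)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)


def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Paired signed-rank test for matched designs (e.g. the same patients
    scored under two protocols); zero differences are dropped (Wilcoxon's
    convention). Offered alongside the unpaired rank test because reader
    scores of paired examinations are a matched sample."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape or a.size == 0:
        raise ConfigError("paired samples must be non-empty and equal length")
    if np.all(a == b):
        raise UndefinedStatisticError(
            "signed-rank undefined: all paired differences are zero")
    res = sps.wilcoxon(a, b, zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)


def welch_t(a, b) -> tuple[float, float]:
    """Welch's unequal-variance t-test (two-sided)."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size < 2 or b.size < 2:
        raise ConfigError("t-test needs at least 2 observations per sample")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def ks_normality(x) -> tuple[float, float]:
    """Kolmogorov–Smirnov distance and p of the sample against a normal with
    the sample mean and SD. Because the parameters are estimated from the
    same data, the p-value is conservative (Lilliefors caveat)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < 2:
        raise ConfigError("KS normality check needs at least 2 observations")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise UndefinedStatisticError("KS against a normal undefined at SD 0")
    d, p = sps.kstest(x, "norm", args=(float(np.mean(x)), sd))
    return float(d), float(p)


@dataclass(frozen=True)
class DescriptiveSummary:
    """Both reporting conventions plus which one the normality rule selects."""

    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    normal: bool

    @property
    def preferred(self) -> str:
        return "mean_sd" if self.normal else "median_iqr"

    def formatted(self, decimals: int = 2) -> str:
        if self.normal:
            return f"{self.mean:.{decimals}f} ± {self.sd:.{decimals}f}"
        return (f"{self.median:.{decimals}f} "
                f"[{self.q1:.{decimals}f}–{self.q3:.{decimals}f}]")


def describe(x, alpha: float = 0.05) -> DescriptiveSummary:
    """Mean±SD and median/IQR (linear-interpolation quartiles), choosing the
    reporting convention by the KS normality rule at level ``alpha``.
    Constant samples are reported as non-normal with zero spread."""
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size < 2:
        raise ConfigError("describe needs at least 2 observations")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        normal = False
    else:
        _, p = ks_normality(x)
        normal = p > alpha
    return DescriptiveSummary(mean=float(np.mean(x)), sd=sd,
                              median=float(med), q1=float(q1), q3=float(q3),
                              normal=normal)
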