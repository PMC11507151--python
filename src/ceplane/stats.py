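"""Nonparametric sex comparison, FDR correction, and boxplot summaries.

Window-level quantifier values are pooled across channels and patients of
each sex and compared with the two-sided Mann-Whitney U test.  The binary
``h`` indicator is 1 iff p < alpha (strict).  Families of tests across
regions are corrected with the Benjamini-Hochberg step-up FDR procedure.
Boxplot summaries follow the Tukey convention, with the notch
median +/- 1.57*IQR/sqrt(n) approximating a 95% confidence interval for
the median.

Pooling window-level values treats windows as exchangeable observations
and ignores within-patient correlation (pseudo-replication); see the
methods documentation for the implications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .quantifiers import QuantifierPoint

__all__ = [
    "RegionComparison",
    "BoxplotSummary",
    "mann_whitney_u",
    "h_index",
    "bh_fdr",
    "compare_region",
    "boxplot_summary",
]


@dataclass
class RegionComparison:
    """One row of a per-region sex-comparison table."""

    region: str
    hemisphere: str
    quantifier: str  # "H" or "C"
    D: int
    mean_f: float
    median_f: float
    sd_f: float
    n_f: int
    mean_m: float
    median_m: float
    sd_m: float
    n_m: int
    U: float
    p_value: float
    h: int
    p_corrected: float | None = None
    h_corrected: int | None = None


@dataclass(frozen=True)
class BoxplotSummary:
    """Tukey boxplot statistics of one sample."""

    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray
    notch_lo: float
    notch_hi: float
    n: int


def mann_whitney_u(
    a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Two-sample Mann-Whitney U test.

    Uses the exact null distribution when the smaller sample has at most
    8 observations and the pooled data are tie-free; otherwise the normal
    approximation with tie and continuity corrections.  Returns
    ``(U_min, p)`` where ``U_min = min(U_a, U_b)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Mann-Whitney U requires two non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = sstats.mannwhitneyu(a, b, alternative=alternative, method=method)
    u_a = float(res.statistic)
    u_min = min(u_a, len(a) * len(b) - u_a)
    return u_min, float(res.pvalue)


def h_index(p: float, alpha: float = 0.05) -> int:
    """Rejection indicator: 1 iff p < alpha (strict inequality)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    return int(p < alpha)


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns ``(adjusted, decisions)``; ``decisions[i]`` is True iff the
    adjusted p-value is below ``q`` (strict, consistent with h_index).
    Adjusted values are monotone non-decreasing in the order of the sorted
    raw p-values and never smaller than the raw values.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.ndim != 1 or len(pvals) == 0:
        raise ValueError("pvals must be a non-empty 1-D vector")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = sstats.false_discovery_control(pvals, method="bh")
    return adjusted, adjusted < q


def _values(points: list[QuantifierPoint], quantifier: str) -> np.ndarray:
    if quantifier not in ("H", "C"):
        raise ValueError(f"quantifier must be 'H' or 'C', got {quantifier!r}")
    return np.array([getattr(p, quantifier) for p in points], dtype=float)


def compare_region(
    points_f: list[QuantifierPoint],
    points_m: list[QuantifierPoint],
    quantifier: str,
    alpha: float = 0.05,
    region: str = "",
    hemisphere: str = "",
) -> RegionComparison:
    """Sex comparison of one quantifier in one region.

    Pools window-level values across all channels/patients of each sex,
    summarizes them (mean, median, sample sd), and tests F vs M with the
    two-sided Mann-Whitney U test.
    """
    if not points_f or not points_m:
        raise ValueError("compare_region requires non-empty point lists for both sexes")
    vf = _values(points_f, quantifier)
    vm = _values(points_m, quantifier)
    U, p = mann_whitney_u(vf, vm)
    return RegionComparison(
        region=region,
        hemisphere=hemisphere,
        quantifier=quantifier,
        D=points_f[0].D,
        mean_f=float(vf.mean()),
        median_f=float(np.median(vf)),
        sd_f=float(vf.std(ddof=1)) if len(vf) > 1 else 0.0,
        n_f=len(vf),
        mean_m=float(vm.mean()),
        median_m=float(np.median(vm)),
        sd_m=float(vm.std(ddof=1)) if len(vm) > 1 else 0.0,
        n_m=len(vm),
        U=U,
        p_value=p,
        h=h_index(p, alpha),
    )


def boxplot_summary(sample: np.ndarray) -> BoxplotSummary:
    """Tukey boxplot statistics with a notched-median interval.

    Quartiles use linear interpolation; whiskers extend to the most
    extreme observations within 1.5*IQR of the quartiles; points beyond
    are outliers; the notch is median +/- 1.57*IQR/sqrt(n).
    """
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 1 or len(sample) == 0:
        raise ValueError("boxplot_summary requires a non-empty 1-D sample")
    q1, med, q3 = np.percentile(sample, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = sample[(sample >= lo_fence) & (sample <= hi_fence)]
    whisker_lo = float(inside.min())
    whisker_hi = float(inside.max())
    outliers = np.sort(sample[(sample < lo_fence) | (sample > hi_fence)])
    half_notch = 1.57 * iqr / np.sqrt(len(sample))
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=whisker_lo,
        whisker_hi=whisker_hi,
        outliers=outliers,
        notch_lo=float(med - half_notch),
        notch_hi=float(med + half_notch),
        n=len(sample),
    )
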