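"""The pipeline's statistical comparisons as thin, auditable wrappers.

Distribution differences use the two-sample Kolmogorov-Smirnov test.
Paired before/after comparisons use a paired t-test when the paired
differences pass a Lilliefors normality test (alpha = 0.05), otherwise a
Wilcoxon signed-rank test; the branch taken is reported.  Tests are
two-sided unless a directional hypothesis is explicitly configured.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

LILLIEFORS_ALPHA = 0.05


def ks_two_sample(dist_a, dist_b) -> tuple[float, float]:
    """Two-sample KS statistic and p-value."""
    a = np.asarray(dist_a, float)
    b = np.asarray(dist_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class PairedTestResult:
    test_used: str            # "paired_t" or "wilcoxon"
    statistic: float
    p_value: float
    n: int
    normal: bool              # Lilliefors verdict on the differences
    lilliefors_p: float
    alternative: str = "two-sided"
    degenerate: bool = False  # zero-variance differences


def paired_compare(before, after, alpha: float = LILLIEFORS_ALPHA,
                   alternative: str = "two-sided") -> PairedTestResult:
    """Paired t or Wilcoxon signed-rank on after-minus-before differences,
    gated by a Lilliefors normality test at `alpha`."""
    b = np.asarray(before, float)
    a = np.asarray(after, float)
    if b.shape != a.shape or b.ndim != 1:
        raise ValueError("paired samples must be 1-D arrays of equal length")
    if b.size < 4:
        raise ValueError("need >= 4 pairs (Lilliefors minimum)")
    diff = a - b
    if np.all(diff == diff[0]):
        return PairedTestResult(test_used="degenerate", statistic=float("nan"),
                                p_value=float("nan"), n=diff.size,
                                normal=False, lilliefors_p=float("nan"),
                                alternative=alternative, degenerate=True)
    _, lp = lilliefors(diff, dist="norm")
    normal = lp > alpha
    if normal:
        res = sps.ttest_rel(a, b, alternative=alternative)
        name = "paired_t"
    else:
        res = sps.wilcoxon(diff, alternative=alternative)
        name = "wilcoxon"
    return PairedTestResult(test_used=name, statistic=float(res.statistic),
                            p_value=float(res.pvalue), n=diff.size,
                            normal=normal, lilliefors_p=float(lp),
                            alternative=alternative)


def pearson(x, y) -> float:
    """Pearson correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-D samples of size >= 2")
    return float(sps.pearsonr(x, y).statistic)
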