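"""Normality-gated paired comparison and Bland–Altman agreement.

For each anatomical quantity the predicted values are compared with the
gold standard over paired scans:

* the Shapiro–Wilk test is applied to the paired differences; if the
  differences look normal (p ≥ α, default α = 0.05) a two-sided paired
  t-test is used, otherwise a two-sided Wilcoxon signed-rank test
  (zero differences dropped, the standard convention);
* Bland–Altman agreement reports the bias (mean difference), the 95%
  limits of agreement bias ± 1.96·SD (sample SD, n−1 denominator), and
  the fraction of differences inside the closed LoA interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["PairedStatsResult", "BlandAltmanResult", "paired_comparison",
           "bland_altman"]


@dataclass(frozen=True)
class PairedStatsResult:
    """Outcome of the Shapiro-gated paired comparison."""

    n: int
    mean_pred: float
    sd_pred: float
    mean_gold: float
    sd_gold: float
    shapiro_p: float
    test_used: str  # "paired-t" or "wilcoxon"
    p_value: float
    note: str | None = None


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    within_loa_fraction: float
    n: int


def paired_comparison(pred, gold, alpha: float = 0.05) -> PairedStatsResult:
    """Compare predicted against gold values over pairs.

    The normality gate acts on the paired differences, not on either
    arm.  Degenerate data (all differences zero, or constant
    differences where Shapiro is undefined) are reported with p = 1
    and an explanatory note rather than an exception.
    """
    pred = np.asarray(pred, dtype=float)
    gold = np.asarray(gold, dtype=float)
    if pred.shape != gold.shape or pred.ndim != 1:
        raise ValueError("pred and gold must be equal-length 1-D sequences")
    n = pred.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diff = pred - gold

    note = None
    if np.allclose(diff, diff[0]):
        # constant differences: Shapiro undefined; a zero constant means
        # identical samples (p = 1), a nonzero constant is a pure offset
        shapiro_p = float("nan")
        if diff[0] == 0:
            test_used, p_value = "wilcoxon", 1.0
            note = "all differences zero; comparison degenerate"
        else:
            test_used, p_value = "wilcoxon", float(
                sps.wilcoxon(diff, alternative="two-sided").pvalue)
            note = "constant nonzero differences"
    else:
        shapiro_p = float(sps.shapiro(diff).pvalue)
        if shapiro_p >= alpha:
            test_used = "paired-t"
            p_value = float(sps.ttest_rel(pred, gold).pvalue)
        else:
            test_used = "wilcoxon"
            nz = diff[diff != 0]
            if nz.size == 0:
                p_value, note = 1.0, "all differences zero"
            else:
                p_value = float(
                    sps.wilcoxon(nz, alternative="two-sided").pvalue)

    return PairedStatsResult(
        n=n,
        mean_pred=float(pred.mean()), sd_pred=float(pred.std(ddof=1)),
        mean_gold=float(gold.mean()), sd_gold=float(gold.std(ddof=1)),
        shapiro_p=shapiro_p, test_used=test_used, p_value=p_value, note=note,
    )


def bland_altman(pred, gold) -> BlandAltmanResult:
    """Bland–Altman agreement of predicted versus gold values.

    With zero spread of the differences the limits collapse onto the
    bias and the within-LoA fraction is 1 by convention.
    """
    pred = np.asarray(pred, dtype=float)
    gold = np.asarray(gold, dtype=float)
    if pred.shape != gold.shape or pred.ndim != 1 or pred.size < 2:
        raise ValueError("pred and gold must be equal-length 1-D, n >= 2")
    d = pred - gold
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0 or math.isnan(sd):
        return BlandAltmanResult(bias=bias, loa_low=bias, loa_high=bias,
                                 within_loa_fraction=1.0, n=d.size)
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    frac = float(((d >= lo) & (d <= hi)).mean())
    return BlandAltmanResult(bias=bias, loa_low=lo, loa_high=hi,
                             within_loa_fraction=frac, n=d.size)
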