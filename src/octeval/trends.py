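"""Treatment-response trend classification and its accuracy metrics.

A predicted post-therapeutic scan is judged against the real one by
comparing each anatomical quantity to its pre-therapeutic baseline and
classifying the change on a three-level scale:

* **increase** — the post value exceeds the pre value by more than the
  relative threshold (default 10%): ``post > pre * 1.10``;
* **decrease** — the pre value exceeds the post value by the same
  relative margin: ``pre > post * 1.10``, i.e. ``post < pre / 1.10``;
* otherwise the pair falls in the **tie zone**: the change is within the
  threshold and the case is flagged for adjudication (in the original
  clinical protocol two specialists decided; here the flag is surfaced
  and a configurable default label is assigned).

The two margins are deliberately asymmetric around ``pre`` — each
direction applies the 10% margin to its own reference value.  For fluid
quantities, absence both before and after therapy (both areas zero) is
"no change" outright, with no adjudication flag.

Agreement between the trend of the synthetic scan and the trend of the
real scan (both versus the same pre-therapeutic baseline) is
cross-tabulated; accuracy is the agreement proportion, and presence /
absence dichotomies additionally yield sensitivity and specificity with
exact (Clopper–Pearson) binomial confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DECREASE",
    "NO_CHANGE",
    "INCREASE",
    "THICKNESS_LABELS",
    "FLUID_LABELS",
    "TrendRule",
    "TrendLabel",
    "ConfusionTable",
    "BinaryMetrics",
    "classify_trend",
    "classify_presence",
    "build_trend_table",
    "build_presence_table",
    "table_accuracy",
    "binary_metrics",
    "clopper_pearson",
]

DECREASE = "decrease"
NO_CHANGE = "no_change"
INCREASE = "increase"

#: 2-level scale used for thickness quantities and 3-level for fluid areas
THICKNESS_LABELS = (DECREASE, INCREASE)
FLUID_LABELS = (DECREASE, NO_CHANGE, INCREASE)


@dataclass(frozen=True)
class TrendRule:
    """Parameters of the trend classification.

    ``tie_policy`` controls the label assigned inside the tie zone:
    ``"no_change-default"`` labels it no-change and raises the
    adjudication flag; ``"adjudicate-flag"`` raises the flag and leaves
    the label no-change as well but callers can hard-fail on the flag.
    """

    rel_threshold: float = 0.10
    tie_policy: str = "no_change-default"

    def __post_init__(self) -> None:
        if not 0.0 < self.rel_threshold < 1.0:
            raise ValueError("rel_threshold must lie in (0, 1)")
        if self.tie_policy not in ("no_change-default", "adjudicate-flag"):
            raise ValueError(f"unknown tie_policy {self.tie_policy!r}")


@dataclass(frozen=True)
class TrendLabel:
    value: str
    adjudication_needed: bool = False

    def __post_init__(self) -> None:
        if self.value not in FLUID_LABELS:
            raise ValueError(f"unknown trend label {self.value!r}")


def classify_trend(
    pre_value: float,
    post_value: float,
    rule: TrendRule = TrendRule(),
    is_fluid: bool = False,
) -> TrendLabel:
    """Classify the change of one quantity from pre to post.

    Both values must be non-negative.  For fluid quantities a (0, 0)
    pair is genuine no-change; a positive post value against a zero pre
    value is an increase (any positive value exceeds a zero baseline by
    more than 10%).
    """
    if pre_value < 0 or post_value < 0:
        raise ValueError("trend inputs must be non-negative")
    if is_fluid and pre_value == 0 and post_value == 0:
        return TrendLabel(NO_CHANGE)
    theta = rule.rel_threshold
    if post_value > pre_value * (1.0 + theta):
        return TrendLabel(INCREASE)
    if pre_value > post_value * (1.0 + theta):
        return TrendLabel(DECREASE)
    # tie zone: relative change within the threshold in both directions
    return TrendLabel(NO_CHANGE, adjudication_needed=True)


def classify_presence(area: float, min_area: float = 0.0) -> bool:
    """Presence dichotomy for a fluid area: present iff area > min_area."""
    if area < 0:
        raise ValueError("area must be non-negative")
    return area > min_area


@dataclass(frozen=True)
class ConfusionTable:
    """Cross-tabulation of synthetic-vs-pre against real-vs-pre outcomes.

    Rows index the synthetic (predicted) label, columns the real label.
    """

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self, margins: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.row_labels),
                          columns=list(self.col_labels))
        if margins:
            df["total"] = df.sum(axis=1)
            df.loc["total"] = df.sum(axis=0)
        df.index.name = "synthetic"
        df.columns.name = "real"
        return df


def build_trend_table(
    pairs, label_set=FLUID_LABELS
) -> ConfusionTable:
    """Cross-tabulate (synthetic_label, real_label) pairs.

    ``pairs`` is an iterable of 2-tuples of label strings (or
    :class:`TrendLabel`).  Unknown labels raise; an empty list raises.
    """
    label_set = tuple(label_set)
    index = {lab: i for i, lab in enumerate(label_set)}
    counts = np.zeros((len(label_set), len(label_set)), dtype=int)
    n = 0
    for syn, real in pairs:
        syn = syn.value if isinstance(syn, TrendLabel) else syn
        real = real.value if isinstance(real, TrendLabel) else real
        if syn not in index or real not in index:
            raise ValueError(f"label pair ({syn!r}, {real!r}) outside "
                             f"label set {label_set}")
        counts[index[syn], index[real]] += 1
        n += 1
    if n == 0:
        raise ValueError("no pairs to tabulate")
    return ConfusionTable(counts, label_set, label_set)


def build_presence_table(pairs) -> ConfusionTable:
    """Cross-tabulate (synthetic_present, real_present) boolean pairs."""
    labels = ("absent", "present")
    counts = np.zeros((2, 2), dtype=int)
    n = 0
    for syn, real in pairs:
        counts[int(bool(syn)), int(bool(real))] += 1
        n += 1
    if n == 0:
        raise ValueError("no pairs to tabulate")
    return ConfusionTable(counts, labels, labels)


def table_accuracy(table: ConfusionTable) -> float:
    """Agreement proportion: trace over total."""
    if table.total == 0:
        raise ValueError("cannot compute accuracy of an empty table")
    if table.row_labels != table.col_labels:
        raise ValueError("accuracy requires identical row and column labels")
    return float(np.trace(table.counts)) / table.total


def clopper_pearson(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval.

    Beta-quantile form: the lower bound is the ``alpha/2`` quantile of
    ``Beta(x, n - x + 1)`` (0 when x = 0) and the upper bound the
    ``1 - alpha/2`` quantile of ``Beta(x + 1, n - x)`` (1 when x = n).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    low = 0.0 if successes == 0 else float(
        sps.beta.ppf(alpha / 2, successes, trials - successes + 1))
    high = 1.0 if successes == trials else float(
        sps.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return low, high


@dataclass(frozen=True)
class BinaryMetrics:
    """Accuracy/sensitivity/specificity with exact 95% CIs.

    An undefined rate (no real positives, or no real negatives) is
    ``nan`` and its CI entry is absent.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def binary_metrics(
    table: ConfusionTable, positive_label: str, level: float = 0.95
) -> BinaryMetrics:
    """Score a 2×2 table with rows = synthetic, columns = real.

    Sensitivity is recovery of real positives, specificity of real
    negatives; accuracy is overall agreement.  CIs are exact binomial.
    """
    if table.counts.shape != (2, 2):
        raise ValueError("binary_metrics requires a 2×2 table")
    if table.total == 0:
        raise ValueError("empty table")
    if positive_label not in table.row_labels or table.row_labels != table.col_labels:
        raise ValueError("positive_label must be one of the shared labels")
    p = table.row_labels.index(positive_label)
    n = 1 - p
    tp = int(table.counts[p, p])
    tn = int(table.counts[n, n])
    fp = int(table.counts[p, n])
    fn = int(table.counts[n, p])
    total = table.total

    ci: dict[str, tuple[float, float]] = {
        "accuracy": clopper_pearson(tp + tn, total, level)}
    accuracy = (tp + tn) / total
    pos = tp + fn
    neg = tn + fp
    if pos > 0:
        sensitivity = tp / pos
        ci["sensitivity"] = clopper_pearson(tp, pos, level)
    else:
        sensitivity = math.nan
    if neg > 0:
        specificity = tn / neg
        ci["specificity"] = clopper_pearson(tn, neg, level)
    else:
        specificity = math.nan
    return BinaryMetrics(accuracy=accuracy, sensitivity=sensitivity,
                         specificity=specificity, ci=ci)
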