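"""Bundled reference confusion tables for a 37-image GAN evaluation.

These counts describe a held-out clinical test set of 37 predicted
post-therapeutic OCT B-scans from eyes with retinal vein occlusion,
cross-tabulating the treatment trend (or fluid presence) seen in each
synthetic scan against the trend seen in the corresponding real scan,
both relative to the pre-therapeutic baseline.  They serve two
purposes: regression-testing the metric pipeline against independently
reported headline values, and acting as format templates for cohort
reports.

Rows are always the synthetic (predicted) outcome, columns the real
outcome.  Thickness trends use the 2-level decrease/increase scale;
fluid-area trends use the 3-level scale including no-change; fluid
presence uses absent/present.
"""

from __future__ import annotations

import pandas as pd

from .trends import (
    DECREASE,
    INCREASE,
    NO_CHANGE,
    THICKNESS_LABELS,
    FLUID_LABELS,
    BinaryMetrics,
    ConfusionTable,
    binary_metrics,
    table_accuracy,
)

__all__ = ["REFERENCE_TREND_TABLES", "REFERENCE_QUALITY_COUNTS",
           "qualified_percentage", "summarize_reference_tables"]

_PRESENCE = ("absent", "present")

#: reference cross-tabulations, n = 37 pairs each
REFERENCE_TREND_TABLES: dict[str, ConfusionTable] = {
    "crt_trend": ConfusionTable(
        [[23, 4], [7, 3]], THICKNESS_LABELS, THICKNESS_LABELS),
    "max_thickness_trend": ConfusionTable(
        [[24, 6], [5, 2]], THICKNESS_LABELS, THICKNESS_LABELS),
    "srf_presence": ConfusionTable(
        [[32, 4], [1, 0]], _PRESENCE, _PRESENCE),
    "srf_trend": ConfusionTable(
        [[10, 0, 0], [0, 24, 3], [0, 0, 0]], FLUID_LABELS, FLUID_LABELS),
    "irc_presence": ConfusionTable(
        [[19, 10], [3, 5]], _PRESENCE, _PRESENCE),
    "irc_trend": ConfusionTable(
        [[23, 1, 5], [0, 5, 1], [1, 0, 1]], FLUID_LABELS, FLUID_LABELS),
}

#: reference image-quality triage: qualified scans out of all generated,
#: with the unqualified ones broken down by discontinuity type
REFERENCE_QUALITY_COUNTS: dict[str, int] = {
    "total": 237,
    "qualified": 208,
    "neuroepithelium_discontinuity": 16,
    "rpe_discontinuity": 8,
    "entire_discontinuity": 5,
}


def qualified_percentage(qualified: int, total: int) -> float:
    """Percentage of generated scans passing the quality triage."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= qualified <= total:
        raise ValueError("qualified must lie in [0, total]")
    return 100.0 * qualified / total


def summarize_reference_tables() -> pd.DataFrame:
    """Recompute every headline metric from the bundled counts.

    One row per table: agreement accuracy for trend tables; accuracy,
    sensitivity and specificity (with exact 95% CIs) for the presence
    dichotomies.
    """
    rows = []
    for name, table in REFERENCE_TREND_TABLES.items():
        row: dict[str, object] = {"table": name, "n": table.total,
                                  "accuracy": table_accuracy(table)}
        if name.endswith("_presence"):
            bm: BinaryMetrics = binary_metrics(table, "present")
            row["sensitivity"] = bm.sensitivity
            row["specificity"] = bm.specificity
            for metric, (lo, hi) in bm.ci.items():
                row[f"{metric}_ci_low"] = lo
                row[f"{metric}_ci_high"] = hi
        rows.append(row)
    return pd.DataFrame(rows).set_index("table")
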