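"""Cohort measurement and full evaluation-report assembly.

The report mirrors the structure of a clinical structural evaluation of
predicted post-therapeutic scans:

1. automated quality triage (band-discontinuity flags and the
   proportion of qualified scans);
2. per-quantity trend confusion tables (synthetic vs real outcome,
   both against the pre-therapeutic baseline) with agreement accuracy
   and tie-zone bookkeeping;
3. fluid presence dichotomies with sensitivity/specificity and exact
   binomial confidence intervals;
4. a normality-gated paired comparison and Bland–Altman agreement of
   predicted against gold values per quantity;
5. optional per-stratum segmentation metric tables.

Input is a long-form measurement table with one row per scan:
columns ``pair_id, role, crt, max_thickness, srf_area, irc_area`` with
``role`` in {pre, post_real, post_pred}; optional boolean flag columns
``neuroepithelium_discontinuity, rpe_discontinuity,
entire_discontinuity`` on predicted rows; optional ``stratum``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .anatomy import PIXEL_UNITS, PixelGeometry, continuity_flags, measure_masks
from .reference_tables import qualified_percentage
from .stats import bland_altman, paired_comparison
from .trends import (
    FLUID_LABELS,
    TrendRule,
    build_presence_table,
    build_trend_table,
    binary_metrics,
    classify_presence,
    classify_trend,
    table_accuracy,
)

__all__ = ["QUANTITIES", "measure_cohort", "build_report", "write_report"]

QUANTITIES = ("crt", "max_thickness", "srf_area", "irc_area")
FLUID_QUANTITIES = ("srf_area", "irc_area")
ROLES = ("pre", "post_real", "post_pred")


def measure_cohort(
    pairs: Sequence,
    backend: Callable | None = None,
    geometry: PixelGeometry = PIXEL_UNITS,
    min_gap_columns: int = 3,
) -> pd.DataFrame:
    """Measurement rows for a cohort of pre/post_real/post_pred triples.

    With ``backend=None`` the gold masks of each scene are measured
    directly; a segmentation backend (image → masks + fovea) switches
    measurement to inferred masks, exercising the whole chain from
    intensity images.  Continuity flags are always computed on the
    predicted scan's stratification mask.
    """
    rows = []
    for pair in pairs:
        for role in ROLES:
            scene = getattr(pair, role)
            if backend is None:
                strat, lesion, fovea = (scene.strat_mask, scene.lesion_mask,
                                        scene.fovea_x)
            else:
                strat, lesion, fovea = backend(scene.image)
            m = measure_masks(strat, lesion, fovea, geometry)
            row = {"pair_id": pair.pair_id, "role": role, **m.as_dict()}
            if role == "post_pred":
                flags = continuity_flags(scene.strat_mask, min_gap_columns)
                row.update({
                    "neuroepithelium_discontinuity":
                        flags.neuroepithelium_discontinuity,
                    "rpe_discontinuity": flags.rpe_discontinuity,
                    "entire_discontinuity": flags.entire_discontinuity,
                })
            rows.append(row)
    return pd.DataFrame(rows)


def _pivot(measurements: pd.DataFrame) -> tuple[dict, list]:
    """Split measurement rows into complete pairs and exclusions."""
    complete: dict = {}
    excluded: list = []
    for pid, grp in measurements.groupby("pair_id"):
        roles = dict(zip(grp["role"], grp.index))
        if all(r in roles for r in ROLES):
            complete[pid] = {r: grp.loc[roles[r]] for r in ROLES}
        else:
            excluded.append(pid)
    return complete, excluded


def build_report(
    measurements: pd.DataFrame,
    rule: TrendRule = TrendRule(),
    seg_tables: dict[str, pd.DataFrame] | None = None,
    metadata: dict | None = None,
) -> dict:
    """Assemble the full evaluation bundle from measurement rows.

    Pairs missing any of the three roles are excluded and counted.
    Returns a JSON-serialisable dict; see :func:`write_report` for the
    on-disk layout.
    """
    required = {"pair_id", "role", *QUANTITIES}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns {sorted(missing)}")
    complete, excluded = _pivot(measurements)
    if not complete:
        raise ValueError("no complete pre/post_real/post_pred pairs")

    report: dict = {
        "n_pairs": len(complete),
        "n_excluded": len(excluded),
        "excluded_pair_ids": sorted(excluded),
        "trend_rule": {"rel_threshold": rule.rel_threshold,
                       "tie_policy": rule.tie_policy},
        "metadata": metadata or {},
    }

    flag_cols = ["neuroepithelium_discontinuity", "rpe_discontinuity",
                 "entire_discontinuity"]
    pred_rows = measurements[measurements["role"] == "post_pred"]
    if all(c in pred_rows.columns for c in flag_cols):
        flagged = pred_rows[flag_cols].astype("boolean").fillna(False).astype(bool)
        unqualified = int(flagged.any(axis=1).sum())
        total = len(pred_rows)
        report["quality"] = {
            "total": total,
            "qualified": total - unqualified,
            "qualified_percent": qualified_percentage(total - unqualified,
                                                      total),
            **{c: int(flagged[c].sum()) for c in flag_cols},
        }

    trends: dict = {}
    presence: dict = {}
    agreement: dict = {}
    for q in QUANTITIES:
        is_fluid = q in FLUID_QUANTITIES
        label_pairs = []
        ties = 0
        pred_vals, gold_vals = [], []
        for rec in complete.values():
            pre_v = float(rec["pre"][q])
            real_v = float(rec["post_real"][q])
            pred_v = float(rec["post_pred"][q])
            syn = classify_trend(pre_v, pred_v, rule, is_fluid)
            real = classify_trend(pre_v, real_v, rule, is_fluid)
            ties += int(syn.adjudication_needed or real.adjudication_needed)
            label_pairs.append((syn, real))
            pred_vals.append(pred_v)
            gold_vals.append(real_v)

        table = build_trend_table(label_pairs, FLUID_LABELS)
        trends[q] = {
            "table": table.to_frame().to_dict(),
            "accuracy": table_accuracy(table),
            "tie_zone_pairs": ties,
        }
        if is_fluid:
            ptab = build_presence_table(
                (classify_presence(p), classify_presence(g))
                for p, g in zip(pred_vals, gold_vals))
            bm = binary_metrics(ptab, "present")
            presence[q] = {
                "table": ptab.to_frame().to_dict(),
                "accuracy": bm.accuracy,
                "sensitivity": bm.sensitivity,
                "specificity": bm.specificity,
                "ci": {k: list(v) for k, v in bm.ci.items()},
            }
        if len(pred_vals) >= 3:
            agreement[q] = {
                "paired": dataclasses.asdict(
                    paired_comparison(pred_vals, gold_vals)),
                "bland_altman": dataclasses.asdict(
                    bland_altman(pred_vals, gold_vals)),
            }

    report["trends"] = trends
    report["presence"] = presence
    report["agreement"] = agreement
    if seg_tables:
        report["segmentation"] = {name: df.to_dict()
                                  for name, df in seg_tables.items()}
    return report


def _summary_text(report: dict) -> str:
    lines = [f"pairs evaluated: {report['n_pairs']} "
             f"(excluded: {report['n_excluded']})"]
    if "quality" in report:
        qual = report["quality"]
        lines.append(
            f"qualified predicted scans: {qual['qualified']}/{qual['total']} "
            f"({qual['qualified_percent']:.2f}%)")
    for q, t in report["trends"].items():
        lines.append(f"{q}: trend accuracy {t['accuracy']:.4f} "
                     f"(tie-zone pairs: {t['tie_zone_pairs']})")
    for q, p in report["presence"].items():
        lines.append(f"{q}: presence accuracy {p['accuracy']:.4f}, "
                     f"sensitivity {p['sensitivity']:.4f}, "
                     f"specificity {p['specificity']:.4f}")
    for q, a in report["agreement"].items():
        ba = a["bland_altman"]
        lines.append(f"{q}: bias {ba['bias']:.3f}, "
                     f"LoA [{ba['loa_low']:.3f}, {ba['loa_high']:.3f}], "
                     f"within-LoA {ba['within_loa_fraction']:.3f}; "
                     f"{a['paired']['test_used']} p={a['paired']['p_value']:.4f}")
    return "\n".join(lines) + "\n"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_report(report: dict, outdir: str | Path) -> Path:
    """Write report.json, tables/*.csv and summary.txt under ``outdir``."""
    outdir = Path(outdir)
    (outdir / "tables").mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(_jsonable(report), indent=2))
    for q, t in report["trends"].items():
        pd.DataFrame(t["table"]).to_csv(outdir / "tables" / f"trend_{q}.csv")
    for q, p in report["presence"].items():
        pd.DataFrame(p["table"]).to_csv(
            outdir / "tables" / f"presence_{q}.csv")
    (outdir / "summary.txt").write_text(_summary_text(report))
    return outdir
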