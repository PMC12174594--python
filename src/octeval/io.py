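"""Disk layout for phantom cohorts.

One scan is stored as three PNGs plus a JSON annotation file:

* ``<stem>_image.png`` — 8-bit grayscale intensity image;
* ``<stem>_strat.png`` / ``<stem>_lesion.png`` — single-channel PNGs
  holding the literal label values {0, 1, 2};
* ``<stem>_annotation.json`` — ``{"fovea_x": float, "ilm": [...],
  "rpe": [...], "choroid": [...]}`` with per-column boundary rows
  (−1 in columns without that band).

A cohort adds ``manifest.csv`` with one row per scan (pair id, role,
file stem, the four ground-truth measurements and the real-vs-pre
trend labels of its pair).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .anatomy import RETINA_BAND, SUBRETINAL_BAND, measure_masks
from .synthetic import CohortPair, RetinalScene

__all__ = ["save_scene", "load_scene", "save_cohort", "load_manifest"]


def _boundaries(strat: np.ndarray) -> dict[str, list[int]]:
    h, _ = strat.shape
    rows = np.arange(h)[:, None]
    is1 = strat == RETINA_BAND
    is2 = strat == SUBRETINAL_BAND
    big = h + 1
    ilm = np.where(is1, rows, big).min(axis=0)
    rpe = np.where(is2, rows, big).min(axis=0)
    cho = np.where(is2, rows, -1).max(axis=0) + 1
    ilm[~is1.any(axis=0)] = -1
    rpe[~is2.any(axis=0)] = -1
    cho[~is2.any(axis=0)] = -1
    return {"ilm": ilm.tolist(), "rpe": rpe.tolist(), "choroid": cho.tolist()}


def save_scene(scene: RetinalScene, outdir: str | Path, stem: str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img8 = np.clip(np.rint(scene.image * 255), 0, 255).astype(np.uint8)
    Image.fromarray(img8, mode="L").save(outdir / f"{stem}_image.png")
    Image.fromarray(scene.strat_mask.astype(np.uint8), mode="L").save(
        outdir / f"{stem}_strat.png")
    Image.fromarray(scene.lesion_mask.astype(np.uint8), mode="L").save(
        outdir / f"{stem}_lesion.png")
    annotation = {"fovea_x": scene.fovea_x, **_boundaries(scene.strat_mask)}
    (outdir / f"{stem}_annotation.json").write_text(
        json.dumps(annotation))


def load_scene(outdir: str | Path, stem: str) -> RetinalScene:
    outdir = Path(outdir)
    image = np.asarray(
        Image.open(outdir / f"{stem}_image.png"), dtype=float) / 255.0
    strat = np.asarray(Image.open(outdir / f"{stem}_strat.png"),
                       dtype=np.uint8)
    lesion = np.asarray(Image.open(outdir / f"{stem}_lesion.png"),
                        dtype=np.uint8)
    annotation = json.loads(
        (outdir / f"{stem}_annotation.json").read_text())
    fovea_x = float(annotation["fovea_x"])
    truth = measure_masks(strat, lesion, fovea_x)
    return RetinalScene(image=image, strat_mask=strat, lesion_mask=lesion,
                        fovea_x=fovea_x, truth=truth)


def save_cohort(pairs: Sequence[CohortPair], outdir: str | Path) -> Path:
    """Write every scene of a cohort plus its manifest."""
    outdir = Path(outdir)
    records = []
    for pair in pairs:
        for role in ("pre", "post_real", "post_pred"):
            scene: RetinalScene = getattr(pair, role)
            stem = f"pair{pair.pair_id:04d}_{role}"
            save_scene(scene, outdir, stem)
            records.append({
                "pair_id": pair.pair_id,
                "role": role,
                "stem": stem,
                **scene.truth.as_dict(),
                **{f"trend_{q}": lab.value
                   for q, lab in pair.true_trends.items()},
            })
    manifest = pd.DataFrame(records)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return outdir


def load_manifest(outdir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(outdir) / "manifest.csv")
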