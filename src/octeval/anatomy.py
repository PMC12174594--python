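"""Anatomical measurement of retinal B-scan masks.

Four quantities drive the structural evaluation of a predicted
post-therapeutic scan: central retinal thickness (CRT, the thickness of
the ILM→RPE band at the foveal center), maximal retinal thickness within
the scan, and the areas of subretinal fluid (SRF) and intraretinal
cystoid fluid (IRC).  All of them are derived from two per-pixel label
maps:

* a stratification mask with labels ``0`` (background), ``1`` (ILM upper
  bound to RPE upper bound) and ``2`` (RPE upper bound to choroid lower
  bound), and
* a lesion mask with labels ``0`` (background), ``1`` (SRF), ``2`` (IRC).

Thickness is the per-column count of label-1 pixels; areas are lesion
pixel counts.  Physical units are opt-in via :class:`PixelGeometry`; the
trend-classification framework downstream is relative and therefore
unit-free.

This module also provides the fovea-localization error helpers and the
automated structural-quality flags (band discontinuities) used to triage
generated scans.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PixelGeometry",
    "AnatomyMeasurements",
    "QualityFlags",
    "thickness_profile",
    "central_retinal_thickness",
    "maximal_retinal_thickness",
    "lesion_areas",
    "measure_masks",
    "fovea_displacement",
    "displacement_summary",
    "fovea_column",
    "continuity_flags",
]

#: stratification labels
BACKGROUND, RETINA_BAND, SUBRETINAL_BAND = 0, 1, 2
#: lesion labels
LESION_SRF, LESION_IRC = 1, 2


@dataclass(frozen=True)
class PixelGeometry:
    """Physical pixel pitch of a B-scan.

    Defaults follow a 9-mm lateral scan digitised at 1,024 columns
    (≈8.789 µm/px laterally) and leave the axial direction in pixel
    units, since the axial pitch of the source device is unspecified.
    """

    lateral_um_per_px: float = 9000.0 / 1024.0
    axial_um_per_px: float = 1.0

    def __post_init__(self) -> None:
        if self.lateral_um_per_px <= 0 or self.axial_um_per_px <= 0:
            raise ValueError("pixel pitches must be strictly positive")

    @property
    def area_um2_per_px(self) -> float:
        return self.lateral_um_per_px * self.axial_um_per_px


#: unit geometry: thickness in pixels, areas in pixel counts
PIXEL_UNITS = PixelGeometry(lateral_um_per_px=1.0, axial_um_per_px=1.0)


@dataclass(frozen=True)
class AnatomyMeasurements:
    """The four structural quantities for one scan."""

    crt: float
    max_thickness: float
    srf_area: float
    irc_area: float

    def __post_init__(self) -> None:
        for name in ("crt", "max_thickness", "srf_area", "irc_area"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {
            "crt": self.crt,
            "max_thickness": self.max_thickness,
            "srf_area": self.srf_area,
            "irc_area": self.irc_area,
        }


@dataclass(frozen=True)
class QualityFlags:
    """Automated structural-quality flags for one scan.

    A predicted scan is disqualified when the retina shows an abrupt
    structural rupture: a run of columns inside the retina's horizontal
    support where the neuroepithelium band (label 1), the RPE/choroid
    band (label 2), or both are missing.
    """

    neuroepithelium_discontinuity: bool = False
    rpe_discontinuity: bool = False
    entire_discontinuity: bool = False
    gap_columns: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def qualified(self) -> bool:
        return not (
            self.neuroepithelium_discontinuity
            or self.rpe_discontinuity
            or self.entire_discontinuity
        )


def _check_labels(mask: np.ndarray, what: str) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"{what} must be 2-D, got shape {mask.shape}")
    if mask.size and mask.max() > 2 or mask.size and mask.min() < 0:
        raise ValueError(f"{what} labels must lie in {{0, 1, 2}}")
    return mask


def thickness_profile(
    strat_mask: np.ndarray, geometry: PixelGeometry = PIXEL_UNITS
) -> np.ndarray:
    """Per-column retinal thickness: label-1 pixel count × axial pitch.

    Columns with no retina yield 0.  An entirely empty mask yields an
    all-zero profile and emits a warning.
    """
    strat_mask = _check_labels(strat_mask, "strat_mask")
    profile = (strat_mask == RETINA_BAND).sum(axis=0).astype(float)
    if not profile.any():
        warnings.warn("stratification mask contains no retina (label 1)",
                      stacklevel=2)
    return profile * geometry.axial_um_per_px


def fovea_column(fovea_x: float, width: int) -> int:
    """Image column of a normalized fovea abscissa.

    Rounds half away from zero on ``fovea_x * (width - 1)`` so the
    mapping is symmetric and deterministic.
    """
    if not 0.0 <= fovea_x <= 1.0:
        raise ValueError(f"fovea_x must lie in [0, 1], got {fovea_x}")
    return int(math.floor(fovea_x * (width - 1) + 0.5))


def central_retinal_thickness(
    strat_mask: np.ndarray,
    fovea_x: float,
    geometry: PixelGeometry = PIXEL_UNITS,
) -> float:
    """Retinal thickness at the foveal column (CRT)."""
    profile = thickness_profile(strat_mask, geometry)
    return float(profile[fovea_column(fovea_x, strat_mask.shape[1])])


def maximal_retinal_thickness(
    strat_mask: np.ndarray, geometry: PixelGeometry = PIXEL_UNITS
) -> float:
    """Maximum of the per-column thickness profile."""
    return float(thickness_profile(strat_mask, geometry).max(initial=0.0))


def lesion_areas(
    lesion_mask: np.ndarray, geometry: PixelGeometry | None = None
) -> tuple[float, float]:
    """(SRF area, IRC area) as pixel counts, or µm² if geometry given."""
    lesion_mask = _check_labels(lesion_mask, "lesion_mask")
    factor = 1.0 if geometry is None else geometry.area_um2_per_px
    srf = float((lesion_mask == LESION_SRF).sum()) * factor
    irc = float((lesion_mask == LESION_IRC).sum()) * factor
    return srf, irc


def measure_masks(
    strat_mask: np.ndarray,
    lesion_mask: np.ndarray,
    fovea_x: float,
    geometry: PixelGeometry = PIXEL_UNITS,
    area_geometry: PixelGeometry | None = None,
) -> AnatomyMeasurements:
    """All four quantities for one (stratification, lesion) mask pair."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        crt = central_retinal_thickness(strat_mask, fovea_x, geometry)
        mx = maximal_retinal_thickness(strat_mask, geometry)
    srf, irc = lesion_areas(lesion_mask, area_geometry)
    return AnatomyMeasurements(crt=crt, max_thickness=mx, srf_area=srf,
                               irc_area=irc)


def fovea_displacement(pred_x: float, gold_x: float) -> float:
    """Absolute normalized difference between predicted and gold fovea."""
    for name, v in (("pred_x", pred_x), ("gold_x", gold_x)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return abs(pred_x - gold_x)


def displacement_summary(
    pred_xs, gold_xs, tolerance: float = 0.02
) -> dict[str, float]:
    """Cohort fovea-localization summary.

    Returns the mean and sample SD of the absolute normalized
    displacement and the fraction within ``tolerance`` ("accuracy").
    The default tolerance of 0.02 of the image width is a configurable
    convention, not a clinical standard.
    """
    d = np.array([fovea_displacement(p, g) for p, g in zip(pred_xs, gold_xs)])
    if d.size == 0:
        raise ValueError("no displacements to summarize")
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return {
        "n": int(d.size),
        "mean": float(d.mean()),
        "sd": sd,
        "accuracy": float((d <= tolerance).mean()),
        "tolerance": tolerance,
    }


def _runs(missing: np.ndarray, offset: int) -> list[tuple[int, int]]:
    """Inclusive (start, end) column ranges of True runs."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, m in enumerate(missing):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start + offset, i - 1 + offset))
            start = None
    if start is not None:
        runs.append((start + offset, len(missing) - 1 + offset))
    return runs


def continuity_flags(
    strat_mask: np.ndarray, min_gap_columns: int = 3
) -> QualityFlags:
    """Detect band discontinuities inside the retina's horizontal support.

    A run of at least ``min_gap_columns`` consecutive columns lacking
    label 1 flags a neuroepithelium discontinuity, lacking label 2 an
    RPE discontinuity, and lacking both an entire-retina discontinuity.
    Columns outside the leftmost/rightmost tissue column are ignored.
    """
    if min_gap_columns < 1:
        raise ValueError("min_gap_columns must be >= 1")
    strat_mask = _check_labels(strat_mask, "strat_mask")
    has1 = (strat_mask == RETINA_BAND).any(axis=0)
    has2 = (strat_mask == SUBRETINAL_BAND).any(axis=0)
    support = np.nonzero(has1 | has2)[0]
    if support.size == 0:
        return QualityFlags()
    lo, hi = int(support[0]), int(support[-1])
    sl = slice(lo, hi + 1)

    gaps: dict[str, list[tuple[int, int]]] = {}
    flags = {}
    for kind, missing in (
        ("neuroepithelium", ~has1[sl]),
        ("rpe", ~has2[sl]),
        ("entire", ~(has1[sl] | has2[sl])),
    ):
        runs = [r for r in _runs(missing, lo) if r[1] - r[0] + 1 >= min_gap_columns]
        if runs:
            gaps[kind] = runs
        flags[kind] = bool(runs)

    return QualityFlags(
        neuroepithelium_discontinuity=flags["neuroepithelium"],
        rpe_discontinuity=flags["rpe"],
        entire_discontinuity=flags["entire"],
        gap_columns=gaps,
    )
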