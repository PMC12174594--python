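"""Training-free segmentation backend for phantom B-scans.

Recovers the stratification mask, the fovea position, and the lesion
mask from an intensity image alone, so the whole measurement and
trend-evaluation chain can be exercised end to end from images rather
than gold masks.  The approach is deliberately classical:

* **Layer tracing** — per column, the ILM is the first axial crossing
  into tissue-level reflectivity and the choroid lower bound the last;
  the RPE upper bound is placed by minimising a two-segment
  misclassification cost that assigns mid-reflectivity pixels to the
  outer band and bright/dark pixels to the inner band.  Boundary
  curves are median-smoothed across columns.
* **Fovea detection** — the minimum of the smoothed retinal thickness
  profile inside a search band (default: the central third), with ties
  broken toward the image centre.
* **Fluid segmentation** — hypo-reflective pixels inside the retinal
  band form connected components; components touching the bottom of
  the band (the RPE upper boundary) are subretinal fluid, interior
  components are intraretinal cysts.

Any trained model can stand in for this backend: downstream code only
consumes the ``(strat_mask, lesion_mask, fovea_x)`` triple (see
:class:`SegmentationBackend`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
from scipy import ndimage

from . import anatomy

__all__ = [
    "InferenceConfig",
    "SegmentationBackend",
    "FoveaDetectionError",
    "trace_layer_boundaries",
    "detect_fovea",
    "segment_fluid",
    "infer_scene_masks",
]


class FoveaDetectionError(RuntimeError):
    """Raised when no retina is present inside the fovea search band."""


@dataclass(frozen=True)
class InferenceConfig:
    """Tunable parameters of the classical backend.

    ``gradient_threshold`` is the intensity level separating background
    from tissue at the inner and outer surfaces (applied to the
    smoothed image); ``fluid_threshold`` separates hypo-reflective
    fluid from retinal tissue; ``min_component_px`` suppresses
    speckle-induced fluid specks.
    """

    smoothing_window: int = 9
    gradient_threshold: float = 0.30
    fluid_threshold: float = 0.33
    min_component_px: int = 8
    axial_sigma: float = 1.5
    lateral_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        for name in ("gradient_threshold", "fluid_threshold"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.min_component_px < 1:
            raise ValueError("min_component_px must be >= 1")


class SegmentationBackend(Protocol):
    """Anything that maps an image to (strat_mask, lesion_mask, fovea_x)."""

    def __call__(self, image: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        ...


def _smoothed(image: np.ndarray, config: InferenceConfig) -> np.ndarray:
    return ndimage.gaussian_filter(
        image.astype(float), sigma=(config.axial_sigma, config.lateral_sigma))


def trace_layer_boundaries(
    image: np.ndarray, config: InferenceConfig = InferenceConfig()
) -> np.ndarray:
    """Stratification mask (labels 0/1/2) from an intensity image.

    Columns without tissue are labelled background; no exception is
    raised for them.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if image.size and (image.min() < 0 or image.max() > 1):
        raise ValueError("image intensities must lie in [0, 1]")
    sm = _smoothed(image, config)
    h, w = sm.shape

    # mid-band (outer retina / RPE complex) reflectivity window: above
    # fluid, below inner-retina tissue
    mid_lo, mid_hi = 0.25, 0.45

    ilm = np.full(w, -1, dtype=int)
    rpe = np.full(w, -1, dtype=int)
    cho = np.full(w, -1, dtype=int)
    for c in range(w):
        col = sm[:, c]
        tissue = np.nonzero(col > config.gradient_threshold)[0]
        if tissue.size == 0:
            continue
        top, bottom_candidates = tissue[0], np.nonzero(col > 0.20)[0]
        bottom = bottom_candidates[-1] + 1
        seg = col[top:bottom]
        mid = ((seg > mid_lo) & (seg < mid_hi)).astype(int)
        # cost(r): mid pixels above the cut + non-mid pixels below it
        cum = np.concatenate(([0], np.cumsum(mid)))
        n = seg.size
        r = np.arange(n + 1)
        cost = cum[r] + ((n - r) - (cum[n] - cum[r]))
        split = int(np.argmax(cost == cost.min()))  # topmost minimiser
        ilm[c], rpe[c], cho[c] = top, top + split, bottom

    valid = ilm >= 0
    if valid.any():
        win = config.smoothing_window
        for curve in (ilm, rpe, cho):
            curve[valid] = np.rint(
                ndimage.median_filter(curve[valid].astype(float), size=win,
                                      mode="nearest")).astype(int)
        rpe[valid] = np.clip(rpe[valid], ilm[valid] + 1, None)
        cho[valid] = np.clip(cho[valid], rpe[valid], h)

    rows = np.arange(h)[:, None]
    strat = np.zeros((h, w), dtype=np.uint8)
    band1 = valid[None, :] & (rows >= ilm[None, :]) & (rows < rpe[None, :])
    band2 = valid[None, :] & (rows >= rpe[None, :]) & (rows < cho[None, :])
    strat[band1] = anatomy.RETINA_BAND
    strat[band2] = anatomy.SUBRETINAL_BAND
    return strat


def detect_fovea(
    strat_mask: np.ndarray,
    search_band: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0),
    smoothing_window: int = 9,
) -> float:
    """Normalized abscissa of the thinnest point of the retina.

    The thickness profile is mean-smoothed and minimised over the
    search band (normalized column range); ties break toward the image
    centre (leftmost on exact distance ties).  Raises
    :class:`FoveaDetectionError` when the band contains no retina.
    """
    lo, hi = search_band
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("search_band must satisfy 0 <= lo < hi <= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty band raises below instead
        profile = anatomy.thickness_profile(strat_mask)
    w = strat_mask.shape[1]
    c0 = int(round(lo * (w - 1)))
    c1 = int(round(hi * (w - 1)))
    band = profile[c0:c1 + 1]
    if not band.any():
        raise FoveaDetectionError("no retina inside the fovea search band")
    smooth = ndimage.uniform_filter1d(band, size=smoothing_window,
                                      mode="nearest")
    minima = np.nonzero(smooth == smooth.min())[0] + c0
    center = (w - 1) / 2.0
    col = int(minima[np.argmin(np.abs(minima - center))])
    return col / (w - 1)


def segment_fluid(
    image: np.ndarray,
    strat_mask: np.ndarray,
    config: InferenceConfig = InferenceConfig(),
) -> np.ndarray:
    """Lesion mask (0 background, 1 SRF, 2 IRC) from image + stratification.

    Hypo-reflective pixels inside the class-1 band are grouped into
    8-connected components; components below ``min_component_px`` are
    dropped; components reaching the bottom edge of the band (adjacent
    to the RPE upper boundary) are SRF, the rest IRC.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != strat_mask.shape:
        raise ValueError("image and strat_mask must share dimensions")
    # threshold the raw image: smoothing erodes small fluid regions,
    # while isolated speckle outliers are removed by the size filter
    in_band = strat_mask == anatomy.RETINA_BAND
    candidates = (image < config.fluid_threshold) & in_band

    lesion = np.zeros_like(strat_mask, dtype=np.uint8)
    labels, n = ndimage.label(candidates, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return lesion

    h, w = strat_mask.shape
    rows = np.arange(h)[:, None]
    bottom = np.where(in_band, rows, -1).max(axis=0)  # per-column band bottom
    near_bottom = in_band & (rows >= bottom[None, :] - 1)

    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    touches = ndimage.maximum(near_bottom.astype(int), labels,
                              index=np.arange(1, n + 1))
    for k in range(1, n + 1):
        if sizes[k - 1] < config.min_component_px:
            continue
        label = anatomy.LESION_SRF if touches[k - 1] > 0 else anatomy.LESION_IRC
        lesion[labels == k] = label
    return lesion


def infer_scene_masks(
    image: np.ndarray, config: InferenceConfig = InferenceConfig()
) -> tuple[np.ndarray, np.ndarray, float]:
    """Full classical inference: stratification, lesions, fovea.

    Returns ``(strat_mask, lesion_mask, fovea_x)``; fovea detection
    failure propagates as :class:`FoveaDetectionError`.
    """
    strat = trace_layer_boundaries(image, config)
    lesion = segment_fluid(image, strat, config)
    fovea = detect_fovea(strat)
    return strat, lesion, fovea


def make_backend(config: InferenceConfig = InferenceConfig()) -> Callable:
    """Bind a config into a :class:`SegmentationBackend` callable."""
    def backend(image: np.ndarray):
        return infer_scene_masks(image, config)
    return backend
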