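"""Paired pre/post retinal B-scan phantoms with known anatomy.

The generator builds single B-scans of a layered retina seen in raster
order (row 0 is the vitreous side, columns increase left to right):

* an inner retinal band between the ILM upper bound and the RPE upper
  bound (stratification class 1), locally depressed by a Gaussian
  foveal pit;
* an outer band between the RPE upper bound and the choroid lower
  bound (class 2);
* elliptical intraretinal cysts (IRC, lesion class 2) strictly inside
  the class-1 band, and subretinal fluid pockets (SRF, lesion class 1)
  rasterized immediately above the RPE — still inside the class-1 band,
  whose lower delimiter is the RPE upper edge;
* an intensity image rendering each band at a distinct mean
  reflectivity with fluid hypo-reflective, degraded by multiplicative
  unit-mean gamma speckle.

A treatment effect rescales edema (retinal thickening above a healthy
baseline thickness), cyst axes, and SRF pocket heights, so the true
direction of every anatomical change in a pre/post pair is known.  An
imperfect "predicted" post scan — standing in for the output of an
image-to-image translation model — is produced by jittering boundary
curves, dilating or eroding lesions, displacing the fovea estimate,
and optionally injecting a band discontinuity (neuroepithelium, RPE,
or the entire retina) over a column range.

Every scene carries ground-truth measurements recomputed directly from
its own masks, so downstream measurement code can be validated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import anatomy
from .anatomy import AnatomyMeasurements, measure_masks
from .trends import FLUID_LABELS, TrendLabel, TrendRule, classify_trend

__all__ = [
    "Cyst",
    "SrfPocket",
    "SceneParams",
    "RetinalScene",
    "TreatmentEffect",
    "PredictionNoise",
    "CohortSpec",
    "CohortPair",
    "make_scene_params",
    "generate_scene",
    "apply_treatment",
    "perturb_prediction",
    "generate_cohort",
    "DEFAULT_PARAM_RANGES",
    "DEFAULT_EFFECT_RANGES",
]

# mean reflectivities of the rendered bands; chosen so the classical
# inference backend faces distinct but overlapping (under speckle)
# intensity populations
REFLECTIVITY = {
    "background": 0.05,
    "retina": 0.55,
    "subretinal": 0.35,
    "fluid": 0.12,
}


@dataclass(frozen=True)
class Cyst:
    """Elliptical intraretinal cyst, axes in pixels."""

    center_x: float
    center_y: float
    semi_axis_x: float
    semi_axis_y: float


@dataclass(frozen=True)
class SrfPocket:
    """Subretinal fluid pocket spanning columns [x_start, x_end].

    The pocket's height profile is parabolic: zero at the endpoints and
    ``max_height_px`` at the midpoint, carved upward from the RPE.
    """

    x_start: int
    x_end: int
    max_height_px: float


@dataclass(frozen=True)
class SceneParams:
    """Full geometric description of one B-scan phantom."""

    width: int
    height: int
    ilm_curve: np.ndarray
    rpe_curve: np.ndarray
    choroid_curve: np.ndarray
    fovea_x: float
    fovea_depth: float = 0.0
    cysts: tuple[Cyst, ...] = ()
    srf_pockets: tuple[SrfPocket, ...] = ()
    speckle_level: float = 0.0
    baseline_thickness: float = 30.0

    def __post_init__(self) -> None:
        for name in ("ilm_curve", "rpe_curve", "choroid_curve"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ValueError("scene must be at least 8×8 pixels")
        for name in ("ilm_curve", "rpe_curve", "choroid_curve"):
            curve = getattr(self, name)
            if curve.shape != (self.width,):
                raise ValueError(f"{name} must have one entry per column")
        ilm, rpe, cho = (np.rint(self.ilm_curve), np.rint(self.rpe_curve),
                         np.rint(self.choroid_curve))
        bad = np.nonzero(~((ilm < rpe) & (rpe <= cho)))[0]
        if bad.size:
            raise ValueError(
                f"curve ordering ILM < RPE <= choroid violated at column "
                f"{int(bad[0])}")
        out = np.nonzero((ilm < 0) | (cho >= self.height))[0]
        if out.size:
            raise ValueError(
                f"curves leave the image at column {int(out[0])}")
        if not 0.0 <= self.fovea_x <= 1.0:
            raise ValueError("fovea_x must lie in [0, 1]")
        if self.speckle_level < 0:
            raise ValueError("speckle_level must be >= 0")
        if self.baseline_thickness <= 0:
            raise ValueError("baseline_thickness must be positive")


@dataclass(frozen=True)
class RetinalScene:
    """One rendered B-scan with masks and ground-truth measurements."""

    image: np.ndarray
    strat_mask: np.ndarray
    lesion_mask: np.ndarray
    fovea_x: float
    truth: AnatomyMeasurements
    params: SceneParams | None = None

    def __post_init__(self) -> None:
        if not (self.image.shape == self.strat_mask.shape
                == self.lesion_mask.shape):
            raise ValueError("image and masks must share dimensions")


@dataclass(frozen=True)
class TreatmentEffect:
    """Anatomical response to therapy, as multiplicative factors.

    ``thickness_scale`` acts on retinal thickening above the healthy
    baseline (so a scale of 0 restores the baseline, not a zero-thick
    retina); ``cyst_scale`` on cyst semi-axes; ``srf_scale`` on SRF
    pocket heights.  A factor of 1 leaves that component unchanged up
    to rasterization; 0 removes the corresponding fluid entirely.
    """

    thickness_scale: float = 1.0
    cyst_scale: float = 1.0
    srf_scale: float = 1.0
    jitter_seed: int = 0

    def __post_init__(self) -> None:
        if self.thickness_scale <= 0:
            raise ValueError("thickness_scale must be > 0")
        if self.cyst_scale < 0 or self.srf_scale < 0:
            raise ValueError("cyst_scale and srf_scale must be >= 0")


@dataclass(frozen=True)
class PredictionNoise:
    """Imperfection model for the predicted post-therapeutic scan.

    ``boundary_sd`` displaces each layer boundary by smoothed Gaussian
    offsets (pixels); ``lesion_dilate`` grows (positive) or shrinks
    (negative) each lesion by that many morphological iterations;
    ``fovea_sd`` jitters the reported fovea abscissa (normalized
    units); ``discontinuity`` zeroes a band over an inclusive column
    range: ("neuroepithelium" | "rpe" | "entire", col_start, col_end).
    """

    boundary_sd: float = 0.0
    boundary_smooth: int = 7
    lesion_dilate: int = 0
    fovea_sd: float = 0.0
    speckle_level: float = 0.15
    discontinuity: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        if self.boundary_sd < 0 or self.fovea_sd < 0 or self.speckle_level < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.boundary_smooth < 1:
            raise ValueError("boundary_smooth must be >= 1")
        if self.discontinuity is not None:
            kind, lo, hi = self.discontinuity
            if kind not in ("neuroepithelium", "rpe", "entire"):
                raise ValueError(f"unknown discontinuity kind {kind!r}")
            if not 0 <= lo <= hi:
                raise ValueError("discontinuity columns must satisfy 0 <= lo <= hi")


def make_scene_params(
    width: int = 256,
    height: int = 160,
    ilm_level: float = 45.0,
    thickness: float = 60.0,
    band2_thickness: float = 30.0,
    fovea_x: float = 0.5,
    fovea_depth: float = 12.0,
    pit_sigma: float = 14.0,
    cysts: tuple[Cyst, ...] = (),
    srf_pockets: tuple[SrfPocket, ...] = (),
    speckle_level: float = 0.15,
    baseline_thickness: float = 30.0,
) -> SceneParams:
    """Build layer curves for a flat retina with a Gaussian foveal pit.

    The RPE and choroid run flat at ``ilm_level + thickness`` and
    ``ilm_level + thickness + band2_thickness``; the ILM is depressed
    by ``fovea_depth`` pixels at the foveal column with lateral spread
    ``pit_sigma`` (the pit thins the retina, it does not move the RPE).
    """
    x = np.arange(width, dtype=float)
    fov_col = fovea_x * (width - 1)
    rpe = np.full(width, ilm_level + thickness)
    pit = fovea_depth * np.exp(-0.5 * ((x - fov_col) / pit_sigma) ** 2)
    ilm = rpe - thickness + pit
    choroid = rpe + band2_thickness
    return SceneParams(
        width=width, height=height,
        ilm_curve=ilm, rpe_curve=rpe, choroid_curve=choroid,
        fovea_x=fovea_x, fovea_depth=fovea_depth,
        cysts=tuple(cysts), srf_pockets=tuple(srf_pockets),
        speckle_level=speckle_level, baseline_thickness=baseline_thickness,
    )


def _rasterize_masks(params: SceneParams) -> tuple[np.ndarray, np.ndarray]:
    """Exact label masks from curves and lesion geometry."""
    h, w = params.height, params.width
    rows = np.arange(h)[:, None]
    ilm = np.rint(params.ilm_curve).astype(int)[None, :]
    rpe = np.rint(params.rpe_curve).astype(int)[None, :]
    cho = np.rint(params.choroid_curve).astype(int)[None, :]

    strat = np.zeros((h, w), dtype=np.uint8)
    strat[(rows >= ilm) & (rows < rpe)] = anatomy.RETINA_BAND
    strat[(rows >= rpe) & (rows < cho)] = anatomy.SUBRETINAL_BAND

    lesion = np.zeros((h, w), dtype=np.uint8)
    cols = np.arange(w)[None, :]
    for pocket in params.srf_pockets:
        x0, x1 = int(pocket.x_start), int(pocket.x_end)
        if x1 <= x0 or pocket.max_height_px <= 0:
            continue
        span = (cols >= x0) & (cols <= x1)
        t = (cols - x0) / max(x1 - x0, 1)
        hgt = np.rint(pocket.max_height_px * 4.0 * t * (1.0 - t)).astype(int)
        srf = span & (rows >= rpe - hgt) & (rows < rpe)
        lesion[srf & (strat == anatomy.RETINA_BAND)] = anatomy.LESION_SRF
    yy = rows.astype(float)
    xx = cols.astype(float)
    for cyst in params.cysts:
        if cyst.semi_axis_x <= 0 or cyst.semi_axis_y <= 0:
            continue
        inside = (((xx - cyst.center_x) / cyst.semi_axis_x) ** 2
                  + ((yy - cyst.center_y) / cyst.semi_axis_y) ** 2) <= 1.0
        lesion[inside & (strat == anatomy.RETINA_BAND) & (lesion == 0)] = \
            anatomy.LESION_IRC
    return strat, lesion


def _render_image(
    strat: np.ndarray,
    lesion: np.ndarray,
    speckle_level: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reflectivity rendering with multiplicative unit-mean gamma speckle."""
    image = np.full(strat.shape, REFLECTIVITY["background"])
    image[strat == anatomy.RETINA_BAND] = REFLECTIVITY["retina"]
    image[strat == anatomy.SUBRETINAL_BAND] = REFLECTIVITY["subretinal"]
    image[lesion > 0] = REFLECTIVITY["fluid"]
    if speckle_level > 0:
        shape = 1.0 / speckle_level**2
        image = image * rng.gamma(shape, 1.0 / shape, size=image.shape)
    return np.clip(image, 0.0, 1.0)


def _scene_from_masks(
    strat: np.ndarray,
    lesion: np.ndarray,
    fovea_x: float,
    speckle_level: float,
    rng: np.random.Generator,
    params: SceneParams | None = None,
) -> RetinalScene:
    image = _render_image(strat, lesion, speckle_level, rng)
    truth = measure_masks(strat, lesion, fovea_x)
    return RetinalScene(image=image, strat_mask=strat, lesion_mask=lesion,
                        fovea_x=fovea_x, truth=truth, params=params)


def generate_scene(params: SceneParams, seed: int = 0) -> RetinalScene:
    """Render a phantom B-scan; deterministic in (params, seed)."""
    params.validate()
    strat, lesion = _rasterize_masks(params)
    rng = np.random.default_rng(seed)
    return _scene_from_masks(strat, lesion, params.fovea_x,
                             params.speckle_level, rng, params=params)


def apply_treatment(
    scene_params: SceneParams, effect: TreatmentEffect
) -> SceneParams:
    """Post-therapeutic geometry from pre-therapeutic geometry.

    Thickening above ``baseline_thickness`` is multiplied by
    ``thickness_scale`` (columns already at or below baseline — e.g.
    the foveal pit — are untouched); the ILM moves toward the fixed RPE
    accordingly.  Cyst centers keep their relative depth within the
    band, cyst axes scale by ``cyst_scale``, SRF heights by
    ``srf_scale``.
    """
    p = scene_params
    t_pre = p.rpe_curve - p.ilm_curve
    excess = np.maximum(t_pre - p.baseline_thickness, 0.0)
    t_post = np.minimum(t_pre, p.baseline_thickness) \
        + excess * effect.thickness_scale
    ilm_post = p.rpe_curve - t_post

    cysts = []
    for cyst in p.cysts:
        col = int(np.clip(round(cyst.center_x), 0, p.width - 1))
        t0, t1 = t_pre[col], t_post[col]
        rel = (cyst.center_y - p.ilm_curve[col]) / t0 if t0 > 0 else 0.5
        cysts.append(Cyst(
            center_x=cyst.center_x,
            center_y=ilm_post[col] + rel * t1,
            semi_axis_x=cyst.semi_axis_x * effect.cyst_scale,
            semi_axis_y=cyst.semi_axis_y * effect.cyst_scale,
        ))
    pockets = [replace(pk, max_height_px=pk.max_height_px * effect.srf_scale)
               for pk in p.srf_pockets]
    return replace(p, ilm_curve=ilm_post, cysts=tuple(cysts),
                   srf_pockets=tuple(pockets))


def _extract_curves(strat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Recover integer ILM/RPE/choroid rows per column from a mask.

    Returns (ilm, rpe, choroid, tissue) where tissue marks columns
    containing both bands; other columns are left untouched by the
    boundary perturbation.
    """
    h, w = strat.shape
    is1 = strat == anatomy.RETINA_BAND
    is2 = strat == anatomy.SUBRETINAL_BAND
    tissue = is1.any(axis=0) & is2.any(axis=0)
    rows = np.arange(h)[:, None]
    big = h + 1
    ilm = np.where(is1, rows, big).min(axis=0)
    rpe = np.where(is2, rows, big).min(axis=0)
    cho = np.where(is2, rows, -1).max(axis=0) + 1
    return ilm, rpe, cho, tissue


def _smooth_offsets(
    rng: np.random.Generator, width: int, sd: float, window: int
) -> np.ndarray:
    if sd == 0:
        return np.zeros(width)
    raw = rng.normal(0.0, sd, size=width)
    smooth = ndimage.uniform_filter1d(raw, size=window, mode="nearest")
    # restore the per-column displacement SD the caller asked for
    # (uniform averaging over `window` samples divides variance by window)
    return smooth * np.sqrt(window)


def perturb_prediction(
    scene: RetinalScene,
    noise: PredictionNoise = PredictionNoise(),
    seed: int = 0,
) -> RetinalScene:
    """Degrade a scene into a plausible model prediction.

    With all noise magnitudes zero the output masks equal the input
    masks exactly; the intensity image is re-rendered (with
    ``noise.speckle_level`` speckle) and therefore carries its own
    noise realization.
    """
    rng = np.random.default_rng(seed)
    h, w = scene.strat_mask.shape
    ilm, rpe, cho, tissue = _extract_curves(scene.strat_mask)

    ilm_n = ilm + _smooth_offsets(rng, w, noise.boundary_sd, noise.boundary_smooth)
    rpe_n = rpe + _smooth_offsets(rng, w, noise.boundary_sd, noise.boundary_smooth)
    cho_n = cho + _smooth_offsets(rng, w, noise.boundary_sd, noise.boundary_smooth)
    # enforce ordering and image bounds after jitter
    cho_n = np.clip(np.rint(cho_n), 2, h).astype(int)
    rpe_n = np.clip(np.rint(rpe_n), 1, cho_n - 1).astype(int)
    ilm_n = np.clip(np.rint(ilm_n), 0, rpe_n - 1).astype(int)

    rows = np.arange(h)[:, None]
    strat = np.zeros((h, w), dtype=np.uint8)
    band1 = (rows >= ilm_n[None, :]) & (rows < rpe_n[None, :]) & tissue[None, :]
    band2 = (rows >= rpe_n[None, :]) & (rows < cho_n[None, :]) & tissue[None, :]
    strat[band1] = anatomy.RETINA_BAND
    strat[band2] = anatomy.SUBRETINAL_BAND

    lesion = scene.lesion_mask.copy()
    if noise.lesion_dilate != 0:
        out = np.zeros_like(lesion)
        it = abs(noise.lesion_dilate)
        op = (ndimage.binary_dilation if noise.lesion_dilate > 0
              else ndimage.binary_erosion)
        for label in (anatomy.LESION_SRF, anatomy.LESION_IRC):
            sel = lesion == label
            if sel.any():
                out[op(sel, iterations=it)] = label
        lesion = out
    lesion[strat != anatomy.RETINA_BAND] = 0

    if noise.discontinuity is not None:
        kind, lo, hi = noise.discontinuity
        sl = slice(lo, hi + 1)
        if kind in ("neuroepithelium", "entire"):
            strat[:, sl][strat[:, sl] == anatomy.RETINA_BAND] = 0
            lesion[:, sl] = 0
        if kind in ("rpe", "entire"):
            strat[:, sl][strat[:, sl] == anatomy.SUBRETINAL_BAND] = 0

    fovea_x = scene.fovea_x
    if noise.fovea_sd > 0:
        fovea_x = float(np.clip(fovea_x + rng.normal(0, noise.fovea_sd), 0, 1))

    return _scene_from_masks(strat, lesion, fovea_x, noise.speckle_level, rng)


# ---------------------------------------------------------------------------
# cohort generation

#: sampling ranges for random pre-therapeutic scenes (min, max)
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "ilm_level": (35.0, 55.0),
    "thickness": (45.0, 85.0),
    "band2_thickness": (24.0, 38.0),
    "fovea_x": (0.40, 0.60),
    "fovea_depth": (8.0, 16.0),
    "pit_sigma": (10.0, 18.0),
    "n_cysts": (0, 3),
    "cyst_semi_x": (4.0, 10.0),
    "cyst_semi_y": (3.0, 7.0),
    "n_srf": (0, 1),
    "srf_width": (30.0, 70.0),
    "srf_height": (6.0, 14.0),
}

#: sampling ranges for treatment effects; mostly resolution of edema,
#: occasionally mild worsening, mirroring anti-VEGF response variability
DEFAULT_EFFECT_RANGES: dict[str, tuple[float, float]] = {
    "thickness_scale": (0.3, 1.15),
    "cyst_scale": (0.0, 1.2),
    "srf_scale": (0.0, 1.15),
}


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a deterministic paired pre/post cohort.

    The default size of 37 pairs matches the scale of a held-out
    clinical test set; identical seeds yield bit-identical cohorts.
    """

    n_pairs: int = 37
    width: int = 256
    height: int = 192
    speckle_level: float = 0.15
    param_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PARAM_RANGES))
    effect_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_RANGES))
    predicted_noise: PredictionNoise = field(
        default_factory=lambda: PredictionNoise(
            boundary_sd=1.5, boundary_smooth=9, lesion_dilate=-1,
            fovea_sd=0.01, speckle_level=0.15))
    trend_rule: TrendRule = field(default_factory=TrendRule)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        for name, ranges in (("param_ranges", self.param_ranges),
                             ("effect_ranges", self.effect_ranges)):
            for key, (lo, hi) in ranges.items():
                if lo > hi:
                    raise ValueError(
                        f"{name}[{key!r}]: min {lo} exceeds max {hi}")


@dataclass(frozen=True)
class CohortPair:
    """One patient-like triple plus its ground-truth trend labels."""

    pair_id: int
    pre: RetinalScene
    post_real: RetinalScene
    post_pred: RetinalScene
    true_trends: dict[str, TrendLabel]


def _sample_scene_params(
    rng: np.random.Generator, spec: CohortSpec
) -> SceneParams:
    r = spec.param_ranges

    def u(key: str) -> float:
        lo, hi = r[key]
        return float(rng.uniform(lo, hi))

    base = make_scene_params(
        width=spec.width, height=spec.height,
        ilm_level=u("ilm_level"), thickness=u("thickness"),
        band2_thickness=u("band2_thickness"),
        fovea_x=u("fovea_x"), fovea_depth=u("fovea_depth"),
        pit_sigma=u("pit_sigma"), speckle_level=spec.speckle_level,
    )
    t = base.rpe_curve - base.ilm_curve

    cysts = []
    n_cysts = int(rng.integers(r["n_cysts"][0], r["n_cysts"][1] + 1))
    for _ in range(n_cysts):
        a, b = u("cyst_semi_x"), u("cyst_semi_y")
        col = int(rng.uniform(0.12, 0.88) * (spec.width - 1))
        margin = b + 2.0
        if t[col] <= 2 * margin:
            continue  # band locally too thin for this cyst
        cy = float(rng.uniform(base.ilm_curve[col] + margin,
                               base.rpe_curve[col] - margin))
        cysts.append(Cyst(center_x=float(col), center_y=cy,
                          semi_axis_x=a, semi_axis_y=b))

    pockets = []
    n_srf = int(rng.integers(r["n_srf"][0], r["n_srf"][1] + 1))
    for _ in range(n_srf):
        wdt = u("srf_width")
        x0 = int(rng.uniform(0.1, 0.9 - wdt / spec.width) * spec.width)
        x1 = min(x0 + int(wdt), spec.width - 1)
        hgt = min(u("srf_height"), float(t[x0:x1 + 1].min()) - 2.0)
        if hgt >= 2.0:
            pockets.append(SrfPocket(x_start=x0, x_end=x1, max_height_px=hgt))

    return replace(base, cysts=tuple(cysts), srf_pockets=tuple(pockets))


def _sample_effect(rng: np.random.Generator, spec: CohortSpec) -> TreatmentEffect:
    r = spec.effect_ranges
    return TreatmentEffect(
        thickness_scale=float(rng.uniform(*r["thickness_scale"])),
        cyst_scale=float(rng.uniform(*r["cyst_scale"])),
        srf_scale=float(rng.uniform(*r["srf_scale"])),
    )


def generate_cohort(spec: CohortSpec) -> list[CohortPair]:
    """Generate pre / real-post / predicted-post triples.

    Ground-truth trend labels (real post versus pre, from the rendered
    masks) are attached per pair for all four anatomical quantities.
    """
    pairs: list[CohortPair] = []
    for i in range(spec.n_pairs):
        rng = np.random.default_rng([spec.seed, i])
        params = _sample_scene_params(rng, spec)
        effect = _sample_effect(rng, spec)
        post_params = apply_treatment(params, effect)
        scene_seed = int(rng.integers(0, 2**31 - 1))
        pre = generate_scene(params, seed=scene_seed)
        post_real = generate_scene(post_params, seed=scene_seed + 1)
        post_pred = perturb_prediction(post_real, spec.predicted_noise,
                                       seed=scene_seed + 2)
        trends = {
            q: classify_trend(getattr(pre.truth, q),
                              getattr(post_real.truth, q),
                              spec.trend_rule,
                              is_fluid=q in ("srf_area", "irc_area"))
            for q in ("crt", "max_thickness", "srf_area", "irc_area")
        }
        pairs.append(CohortPair(pair_id=i, pre=pre, post_real=post_real,
                                post_pred=post_pred, true_trends=trends))
    return pairs
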