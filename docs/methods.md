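# Methods

## Scope and model

`octeval` quantifies how faithfully a predicted post-therapeutic
retinal B-scan reproduces the anatomy of the real post-therapeutic
scan. The pipeline has five stages: phantom generation, anatomical
measurement, (optional) image-based segmentation, trend classification,
and agreement statistics. Training of the generative model or of
neural segmentation networks is out of scope; those components enter
only through their outputs (a predicted scan, a predicted mask), for
which the package provides synthetic stand-ins with known ground truth.

## Coordinate and mask conventions

Row 0 is the vitreous (top) side of the B-scan; columns increase left
to right; indices are 0-based. The fovea abscissa is stored normalized
to `[0, 1]` and mapped to a column by rounding half away from zero on
`fovea_x · (width − 1)`. The stratification mask uses class 0
(background), class 1 (ILM upper bound to RPE upper bound) and class 2
(RPE upper bound to choroid lower bound); class-1 rows per column
satisfy `ilm ≤ r < rpe`, class-2 rows `rpe ≤ r < choroid`. SRF is
rasterized immediately above the RPE and carries stratification label
1: the class-1 band is delimited by the two uppermost edges, so
sub-neuroepithelial fluid above the RPE lies inside it. IRC ellipses
are clipped to the class-1 band and never overwrite SRF.

Thickness is the per-column count of class-1 pixels rather than a
geodesic distance between traced boundaries; for simply-connected
bands the two coincide, and pixel counting is robust to mask noise.

## Units

Areas default to pixel counts and thicknesses to pixels
(`PixelGeometry` converts to µm/µm² when an axial pitch is known; the
lateral default is 9000/1024 ≈ 8.789 µm/px, the axial default 1).
The relative 10% trend rule is invariant under any common rescaling of
the geometry, so the evaluation itself is unit-free; published CRT
values in µm for the source device could not be reconciled with its
geometry, which is why pixel units are the default rather than a
guessed axial pitch.

## Phantom generator

A scene is parameterized by three per-column curves (ILM, RPE upper,
choroid lower), a Gaussian foveal pit (depth 8–16 px, lateral sigma
10–18 px in the cohort sampler), 0–3 elliptical cysts (semi-axes
4–10 × 3–7 px) strictly inside the band, and 0–1 parabolic SRF pockets
(width 30–70 px, height 6–14 px, clipped to the band). Rendering uses
fixed mean reflectivities — background 0.05, inner retina 0.55, outer
band 0.35, fluid 0.12 — multiplied by unit-mean gamma speckle whose
relative SD is `speckle_level` (default 0.15; `1/speckle_level²` shape
parameter). These values are a deliberate compromise: distinct enough
that a classical backend can solve the scene, overlapping enough under
speckle that it must work for it.

The treatment effect rescales *edema*, not the retina: thickening
above a healthy baseline (default 30 px) is multiplied by
`thickness_scale` (cohort range 0.3–1.15, i.e. mostly resolution,
occasionally mild worsening), cyst semi-axes by `cyst_scale` (0–1.2)
and SRF heights by `srf_scale` (0–1.15). Columns at or below baseline
(the pit) are untouched, and the RPE stays fixed while the ILM moves —
matching the physiology of fluid resorption. Cyst centres keep their
relative depth in the band. True IRC area, SRF area and thicknesses
are therefore monotone in their respective scale factors, and every
scene carries ground truth recomputed directly from its own rasterized
masks, so "truth" is exact by construction rather than approximated
from the continuous geometry.

The predicted-scan stand-in degrades the real post scan: each boundary
curve is displaced by laterally smoothed Gaussian offsets whose
realized per-column SD equals `boundary_sd` (the smoothing average is
rescaled by √window so the nominal SD is honest), lesions are dilated
or eroded morphologically (`lesion_dilate` iterations; the cohort
default −1 mimics the systematic under-segmentation of fluid typical
of translation models), the reported fovea is jittered
(`fovea_sd = 0.01` of width), and a band discontinuity
(neuroepithelium / RPE / entire retina) can be injected over a column
range on demand for testing the quality triage. The cohort default is
37 pairs — the scale of a held-out clinical test set — and cohorts are
a pure function of the spec including its seed.

What the phantoms do **not** emulate: real speckle correlation and
shadowing, vessel artefacts, curved/tilted retinas, multi-lesion
pathology beyond cysts+SRF, radial scan geometry, or device
post-processing. Passing tests therefore demonstrate correctness of
the measurement/evaluation machinery, not clinical performance of any
segmentation or prediction model on real OCT.

## Classical segmentation backend

The backend exists so the chain can run from images; it replaces no
clinical claim. Layer tracing works per column on a Gaussian-smoothed
image (axial σ 1.5, lateral σ 1.0): the ILM is the first row above the
tissue threshold (0.30, the halfway crossing between background and
inner retina so symmetric blur preserves edge position), the choroid
lower bound the last supra-background row, and the RPE upper bound the
cut minimizing a two-segment cost that counts mid-reflectivity pixels
(0.25–0.45) above the cut and non-mid pixels below it — robust to both
bright retina and dark fluid above the RPE. Curves are median-filtered
over 9 columns. Fluid segmentation thresholds the *raw* image at 0.33
(halfway between fluid and retina) inside the inferred class-1 band:
smoothing before thresholding erodes small cysts by several boundary
pixels, while raw speckle outliers are removed by the
connected-component size filter (8-connectivity, minimum 8 px).
Components touching the bottom edge of the band (RPE contact) are SRF;
interior components are IRC — the anatomical definition of the two
fluid types. The fovea is the minimum of the smoothed thickness
profile within the central third, ties broken toward the image centre.

On noiseless phantoms this backend is exact to ±1 px boundary
quantization; at speckle 0.2 the cohort mean class-1 Dice stays above
0.99. Exact trend agreement between inferred and gold measurement can
still flip for pairs whose true pre/post ratio lies within quantization
distance of the 10% threshold; this is a property of any thresholded
classification, not of the backend.

## Trend classification

The 10% rule is applied asymmetrically, each direction measuring the
margin against its own reference: increase when `post > pre·1.1`,
decrease when `pre > post·1.1` (`post < pre/1.1`). The residual band
is a tie zone: the clinical protocol sent such cases to human
adjudicators, so the package labels them no-change, sets
`adjudication_needed`, and reports tie-zone counts separately rather
than silently folding them into accuracy. For fluid quantities a
both-zero pair is no-change without a flag, and fluid appearing from a
zero baseline is an increase. Presence dichotomies use strict
inequality against `min_area` (default 0). Thickness trends are
reported on the 2-level decrease/increase scale in the bundled
reference tables (as printed in the source counts) and on the full
3-level scale in cohort reports, where tie-zone cases exist.

## Statistics

Confidence intervals for accuracy, sensitivity and specificity are
exact Clopper–Pearson (beta-quantile form); the exact method is chosen
because it reproduces the published 0–0.60 bound for 0 successes in 4
trials, where asymptotic intervals collapse. The paired comparison
applies Shapiro–Wilk to the paired differences (not to either arm) and
branches at α = 0.05 to a two-sided paired *t* or Wilcoxon signed-rank
with zero differences dropped; constant differences are reported with
p = 1 (identical samples) or handled by Wilcoxon (pure offset) with an
explanatory note instead of an exception. All p-values are two-sided.
Bland–Altman uses the sample (n−1) SD and the 1.96 multiplier; with
zero spread the limits collapse onto the bias and the within-LoA
fraction is 1 by convention. Quality triage counts a predicted scan as
disqualified if any discontinuity run of ≥ 3 columns (configurable) is
found within the retina's horizontal support.

The "average" row of segmentation metric tables is the unweighted
macro mean over classes defined in gold or prediction (0/0 classes are
excluded); this convention is recorded in the table metadata because
pixel-weighted averaging is an equally common reading of published
tables.

## Problem sizes

Default cohorts are 37 pairs of 256 × 192 scans — large enough that
every lesion configuration and trend label occurs, small enough that a
full simulate–measure–report cycle takes seconds. Monte-Carlo checks
in the test suite use 150–400 replicates (branch rates, boundary-jitter
calibration), 2,000 binomial draws for CI coverage, and n = 5,000 for
the Bland–Altman normal-theory limit.

## Known limitations

* The phantom's intensity model is piecewise-constant with
  multiplicative speckle; backends tuned on it will not transfer to
  real OCT without retraining, by design.
* SRF resolution exchanges fluid for tissue within a fixed band
  (thickness is controlled solely by `thickness_scale`), a
  simplification of the coupled thinning seen clinically.
* The tie-zone handling surfaces adjudication flags but contains no
  human-in-the-loop mechanism; accuracies on cohorts with many
  tie-zone pairs depend on the no-change default.
* Fovea "accuracy" depends on an arbitrary tolerance (default 0.02 of
  image width); no standard clinical threshold exists.
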