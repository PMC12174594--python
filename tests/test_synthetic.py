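"""Phantom generator: geometry, ground-truth bookkeeping, determinism."""

import dataclasses

import numpy as np
import pytest

from octeval import anatomy
from octeval.synthetic import (CohortSpec, Cyst, PredictionNoise, SrfPocket,
                               TreatmentEffect, apply_treatment,
                               generate_cohort, generate_scene,
                               make_scene_params, perturb_prediction)


def brute_force_truth(strat, lesion, fovea_x):
    """Independent per-pixel measurement by exhaustive python loops."""
    h, w = strat.shape
    col = int(np.floor(fovea_x * (w - 1) + 0.5))
    crt = sum(1 for r in range(h) if strat[r, col] == 1)
    mx = max(sum(1 for r in range(h) if strat[r, c] == 1) for c in range(w))
    srf = sum(1 for r in range(h) for c in range(w) if lesion[r, c] == 1)
    irc = sum(1 for r in range(h) for c in range(w) if lesion[r, c] == 2)
    return crt, mx, srf, irc


class TestGenerateScene:
    def test_flat_layers_give_constant_band(self, flat_scene):
        profile = (flat_scene.strat_mask == 1).sum(axis=0)
        assert set(profile) == {40}
        assert flat_scene.truth.srf_area == 0
        assert flat_scene.truth.irc_area == 0
        assert flat_scene.truth.crt == 40
        assert flat_scene.truth.max_thickness == 40

    def test_irc_area_matches_exhaustive_ellipse_count(self):
        cyst = Cyst(center_x=70, center_y=72, semi_axis_x=6, semi_axis_y=4)
        params = make_scene_params(cysts=(cyst,), speckle_level=0.0)
        scene = generate_scene(params, seed=0)
        # oracle: exhaustive pixel test inside the rasterized band
        count = 0
        h, w = scene.strat_mask.shape
        for r in range(h):
            for c in range(w):
                inside = ((c - cyst.center_x) / cyst.semi_axis_x) ** 2 \
                    + ((r - cyst.center_y) / cyst.semi_axis_y) ** 2 <= 1.0
                if inside and scene.strat_mask[r, c] == 1:
                    count += 1
        assert scene.truth.irc_area == count
        assert count > 0

    def test_truth_equals_brute_force_measurement(self, lesion_scene):
        crt, mx, srf, irc = brute_force_truth(
            lesion_scene.strat_mask, lesion_scene.lesion_mask,
            lesion_scene.fovea_x)
        assert lesion_scene.truth.crt == crt
        assert lesion_scene.truth.max_thickness == mx
        assert lesion_scene.truth.srf_area == srf
        assert lesion_scene.truth.irc_area == irc

    def test_lesions_stay_inside_retina_band(self, lesion_scene):
        lesioned = lesion_scene.lesion_mask > 0
        assert (lesion_scene.strat_mask[lesioned] == 1).all()

    def test_deterministic_in_params_and_seed(self, lesion_params):
        a = generate_scene(lesion_params, seed=9)
        b = generate_scene(lesion_params, seed=9)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.strat_mask, b.strat_mask)
        assert np.array_equal(a.lesion_mask, b.lesion_mask)

    def test_invalid_curve_ordering_names_column(self):
        params = make_scene_params(width=64, height=96, ilm_level=30,
                                   thickness=20, fovea_depth=0.0)
        bad = dataclasses.replace(params,
                                  rpe_curve=params.rpe_curve.copy())
        bad.rpe_curve[5] = 10.0  # RPE above ILM
        with pytest.raises(ValueError, match="column 5"):
            bad.validate()


class TestApplyTreatment:
    def test_zero_fluid_scales_remove_all_fluid(self, lesion_params):
        effect = TreatmentEffect(cyst_scale=0.0, srf_scale=0.0)
        post = generate_scene(apply_treatment(lesion_params, effect), seed=0)
        assert post.truth.irc_area == 0
        assert post.truth.srf_area == 0

    def test_identity_effect_preserves_anatomy(self, lesion_params):
        pre = generate_scene(lesion_params, seed=0)
        post = generate_scene(
            apply_treatment(lesion_params, TreatmentEffect()), seed=0)
        assert abs(post.truth.crt - pre.truth.crt) <= 1
        assert abs(post.truth.max_thickness - pre.truth.max_thickness) <= 1
        assert post.truth.srf_area == pre.truth.srf_area
        assert post.truth.irc_area == pre.truth.irc_area

    def test_half_scale_halves_thickening_above_baseline(self):
        # 40 px of thickening above a 20 px baseline -> 20 px remains
        params = make_scene_params(width=96, height=128, ilm_level=30,
                                   thickness=60, fovea_depth=0.0,
                                   baseline_thickness=20.0,
                                   speckle_level=0.0)
        post_params = apply_treatment(
            params, TreatmentEffect(thickness_scale=0.5))
        post = generate_scene(post_params, seed=0)
        assert post.truth.max_thickness == 40  # 20 baseline + 20 residual

    @pytest.mark.parametrize("quantity,field,scales", [
        ("irc_area", "cyst_scale", (0.0, 0.4, 0.8, 1.0, 1.3)),
        ("srf_area", "srf_scale", (0.0, 0.4, 0.8, 1.0, 1.2)),
        ("max_thickness", "thickness_scale", (0.3, 0.7, 1.0, 1.2)),
    ])
    def test_scaling_is_monotone_in_true_quantity(self, lesion_params,
                                                  quantity, field, scales):
        values = []
        for s in scales:
            post = apply_treatment(lesion_params,
                                   TreatmentEffect(**{field: s}))
            values.append(getattr(generate_scene(post, seed=0).truth,
                                  quantity))
        assert values == sorted(values)


class TestPerturbPrediction:
    def test_zero_noise_is_identity_on_masks(self, lesion_scene):
        out = perturb_prediction(lesion_scene,
                                 PredictionNoise(speckle_level=0.0), seed=3)
        assert np.array_equal(out.strat_mask, lesion_scene.strat_mask)
        assert np.array_equal(out.lesion_mask, lesion_scene.lesion_mask)
        assert out.fovea_x == lesion_scene.fovea_x

    def test_entire_discontinuity_is_injected_and_detected(self, lesion_scene):
        noise = PredictionNoise(discontinuity=("entire", 50, 60))
        out = perturb_prediction(lesion_scene, noise, seed=0)
        assert not out.strat_mask[:, 50:61].any()
        flags = anatomy.continuity_flags(out.strat_mask, min_gap_columns=3)
        assert flags.entire_discontinuity
        assert any(lo <= 50 and hi >= 60
                   for lo, hi in flags.gap_columns["entire"])

    @pytest.mark.parametrize("kind,gone,kept", [
        ("neuroepithelium", 1, 2), ("rpe", 2, 1)])
    def test_single_band_discontinuity(self, lesion_scene, kind, gone, kept):
        out = perturb_prediction(
            lesion_scene, PredictionNoise(discontinuity=(kind, 30, 40)),
            seed=0)
        assert not (out.strat_mask[:, 30:41] == gone).any()
        assert (out.strat_mask[:, 30:41] == kept).any()

    def test_boundary_jitter_crt_error_is_calibrated(self):
        # sd = 2 px per boundary -> mean |CRT error| of a few pixels
        params = make_scene_params(speckle_level=0.0)
        noise = PredictionNoise(boundary_sd=2.0, speckle_level=0.0)
        errors = []
        for i in range(150):
            scene = generate_scene(params, seed=i)
            pred = perturb_prediction(scene, noise, seed=1000 + i)
            errors.append(abs(pred.truth.crt - scene.truth.crt))
        assert 1.0 <= np.mean(errors) <= 4.0


class TestGenerateCohort:
    def test_cohort_size_and_determinism(self):
        spec = CohortSpec(n_pairs=6, seed=11)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        assert len(a) == 6
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.pre.image, pb.pre.image)
            assert np.array_equal(pa.post_pred.strat_mask,
                                  pb.post_pred.strat_mask)
            assert pa.true_trends == pb.true_trends

    def test_trend_labels_cover_all_quantities(self):
        pairs = generate_cohort(CohortSpec(n_pairs=3, seed=0))
        for pair in pairs:
            assert set(pair.true_trends) == {
                "crt", "max_thickness", "srf_area", "irc_area"}

    def test_invalid_ranges_are_rejected(self):
        with pytest.raises(ValueError, match="thickness"):
            CohortSpec(param_ranges={**CohortSpec().param_ranges,
                                     "thickness": (80.0, 40.0)})

    def test_crt_never_exceeds_max_thickness(self):
        for pair in generate_cohort(CohortSpec(n_pairs=8, seed=2)):
            for role in ("pre", "post_real", "post_pred"):
                t = getattr(pair, role).truth
                assert t.crt <= t.max_thickness
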