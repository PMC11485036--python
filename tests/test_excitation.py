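import numpy as np
import pytest

from avicontrast.excitation import (
    ExcitationStack,
    adapt_to_background,
    naka_rushton,
    normalize_to_standard,
    render_false_color,
    roi_median_excitation,
    sample_background_patches,
    subtract_dark,
)
from avicontrast.scene import (
    MultispectralStack,
    SceneSpec,
    SpectrumCurve,
    leaf_litter_reflectance,
    render_scene,
)


def _stack(values_by_label, dark_rows=2, steps=("rendered",)):
    return MultispectralStack(
        channels={k: np.asarray(v, dtype=float) for k, v in values_by_label.items()},
        pixel_pitch_mm=0.05,
        dark_rows=dark_rows,
        steps=steps,
    )


class TestSubtractDark:
    def test_known_offset_removed_exactly(self, noiseless_scene, noiseless_spec):
        stack, rois = noiseless_scene
        corrected = subtract_dark(stack)
        for label in stack.channels:
            np.testing.assert_allclose(
                corrected.channels[label][rois["background"]],
                stack.channels[label][rois["background"]] - noiseless_spec.dark_offset,
                atol=1e-12,
            )

    def test_all_zero_stack_unchanged(self):
        stack = _stack({"U": np.zeros((8, 8))})
        out = subtract_dark(stack)
        np.testing.assert_array_equal(out.channels["U"], 0.0)

    def test_offset_only_stack_clips_to_zero(self):
        stack = _stack({"U": np.full((8, 8), 0.03)})
        out = subtract_dark(stack)
        np.testing.assert_array_equal(out.channels["U"], 0.0)

    def test_double_application_raises(self):
        stack = subtract_dark(_stack({"U": np.ones((8, 8))}))
        with pytest.raises(ValueError, match="already"):
            subtract_dark(stack)


class TestNormalization:
    def test_standard_region_maps_to_one(self, noiseless_scene):
        stack, rois = noiseless_scene
        catch = normalize_to_standard(subtract_dark(stack), rois["gray_standard"])
        for arr in catch.channels.values():
            assert arr[rois["gray_standard"]].mean() == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self, noiseless_scene):
        stack, rois = noiseless_scene
        dark = subtract_dark(stack)
        scaled = dark.with_channels(
            {k: 7.0 * v for k, v in dark.channels.items()}, "rescaled"
        )
        a = normalize_to_standard(dark, rois["gray_standard"])
        b = normalize_to_standard(scaled, rois["gray_standard"])
        for label in a.channels:
            np.testing.assert_allclose(a.channels[label], b.channels[label], atol=1e-12)

    def test_background_catch_equals_integral_ratio(
        self, noiseless_scene, noiseless_spec, system
    ):
        stack, rois = noiseless_scene
        catch = normalize_to_standard(subtract_dark(stack), rois["gray_standard"])
        grid = system.grid()
        bg = leaf_litter_reflectance(noiseless_spec.seed, grid).values
        gray = np.full(grid.shape, noiseless_spec.gray_reflectance)
        for label in system.labels:
            sens = system.sensitivities[label].values
            expected = np.trapezoid(bg * sens, grid) / np.trapezoid(gray * sens, grid)
            got = catch.channels[label][rois["background"]].mean()
            assert got == pytest.approx(expected, rel=1e-9)

    def test_adaptation_gives_unit_channel_means(self, noiseless_scene):
        stack, _ = noiseless_scene
        adapted = adapt_to_background(subtract_dark(stack))
        lit = adapted.illuminated_slice()
        for arr in adapted.channels.values():
            assert arr[lit, :].mean() == pytest.approx(1.0, abs=1e-9)

    def test_adaptation_constant_image_becomes_ones(self):
        stack = _stack({"U": np.full((10, 8), 0.5)})
        stack.channels["U"][-2:, :] = 0.1  # dark rows
        adapted = adapt_to_background(subtract_dark(stack))
        np.testing.assert_allclose(adapted.channels["U"][:8, :], 1.0, atol=1e-12)

    def test_von_kries_property(self):
        # rescaling one channel's illumination leaves its adapted image unchanged
        rng = np.random.default_rng(0)
        base = rng.uniform(0.2, 0.8, size=(10, 8))
        base[-2:, :] = 0.0
        a = adapt_to_background(subtract_dark(_stack({"U": base})))
        b = adapt_to_background(subtract_dark(_stack({"U": 3.0 * base})))
        np.testing.assert_allclose(a.channels["U"], b.channels["U"], atol=1e-12)

    def test_pipeline_order_enforced(self, noiseless_scene):
        stack, rois = noiseless_scene
        with pytest.raises(ValueError, match="dark"):
            normalize_to_standard(stack, rois["gray_standard"])
        with pytest.raises(ValueError, match="dark"):
            adapt_to_background(stack)
        with pytest.raises(ValueError, match="normalize or adapt"):
            naka_rushton(subtract_dark(stack))
        dark = subtract_dark(stack)
        adapted = adapt_to_background(dark)
        with pytest.raises(ValueError, match="already normalized"):
            adapt_to_background(adapted)
        with pytest.raises(ValueError, match="already normalized"):
            normalize_to_standard(adapted, rois["gray_standard"])


class TestNakaRushton:
    @pytest.mark.parametrize("p,expected", [(0.0, 0.0), (1.0, 0.5), (3.0, 0.75)])
    def test_formula(self, p, expected):
        stack = _stack({"U": np.full((6, 6), p)}, steps=("rendered", "dark_subtracted", "adapted:background"))
        exc = naka_rushton(stack)
        np.testing.assert_allclose(exc.channels["U"], expected)

    def test_negative_catch_signals_missing_dark_correction(self):
        stack = _stack(
            {"U": np.full((6, 6), -0.1)},
            steps=("rendered", "dark_subtracted", "adapted:background"),
        )
        with pytest.raises(ValueError, match="dark correction"):
            naka_rushton(stack)


class TestRoiMedian:
    def test_noise_free_scene_matches_material_value(self, noiseless_excitation):
        exc, rois = noiseless_excitation
        for name in ("red_perpendicular", "black_simulated", "gray_standard"):
            med = roi_median_excitation(exc, rois[name])
            for label, value in med.items():
                pixel_values = exc.channels[label][rois[name]]
                assert value == pytest.approx(pixel_values[0], abs=1e-12)
                assert pixel_values.max() - pixel_values.min() <= 1e-12

    def test_single_pixel_mask(self, noiseless_excitation):
        exc, _ = noiseless_excitation
        mask = np.zeros(exc.shape, dtype=bool)
        mask[5, 7] = True
        med = roi_median_excitation(exc, mask)
        for label, value in med.items():
            assert value == exc.channels[label][5, 7]

    def test_median_robust_to_outlier(self):
        arr = np.full((3, 3), 0.4)
        stack = ExcitationStack(
            channels={"U": arr.copy()},
            mode="background",
            pixel_pitch_mm=0.05,
            dark_rows=0,
            steps=("naka_rushton",),
        )
        mask = np.ones((3, 3), dtype=bool)
        clean = roi_median_excitation(stack, mask)["U"]
        stack.channels["U"][0, 0] = 0.999
        assert roi_median_excitation(stack, mask)["U"] == clean

    def test_empty_mask_errors(self, noiseless_excitation):
        exc, _ = noiseless_excitation
        with pytest.raises(ValueError, match="empty"):
            roi_median_excitation(exc, np.zeros(exc.shape, dtype=bool))


class TestBackgroundPatches:
    def test_count_within_tolerance_on_full_frame(self):
        mask = np.ones((60, 60), dtype=bool)
        patches = sample_background_patches(mask, n_target=20, tol=3, seed=1)
        assert 17 <= len(patches) <= 23

    def test_small_mask_errors(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[:5, :5] = True
        with pytest.raises(ValueError, match="too small"):
            sample_background_patches(mask, n_target=20)

    def test_deterministic(self, noiseless_excitation):
        exc, rois = noiseless_excitation
        a = sample_background_patches(rois["background"], seed=4)
        b = sample_background_patches(rois["background"], seed=4)
        assert a.centers == b.centers

    def test_patches_inside_mask_and_disjoint(self, noiseless_excitation):
        exc, rois = noiseless_excitation
        patches = sample_background_patches(rois["background"], seed=0, stack=exc)
        assert 17 <= len(patches) <= 23
        covered = np.zeros(exc.shape, dtype=int)
        for i in range(len(patches)):
            m = patches.mask_for(i, exc.shape)
            assert m.sum() == 9
            assert rois["background"][m].all()
            covered += m
        assert covered.max() == 1
        assert patches.medians is not None and len(patches.medians) == len(patches)


class TestFalseColor:
    def test_equal_channels_render_gray(self, noiseless_excitation):
        exc, _ = noiseless_excitation
        stack = ExcitationStack(
            channels={k: exc.channels["M"].copy() for k in ("L", "M", "S_U")},
            mode="background",
            pixel_pitch_mm=0.05,
            dark_rows=exc.dark_rows,
            steps=("naka_rushton",),
        )
        img, scale = render_false_color(stack)
        np.testing.assert_allclose(img[..., 0], img[..., 1])
        np.testing.assert_allclose(img[..., 1], img[..., 2])
        assert img.max() == pytest.approx(1.0)

    def test_red_patch_dominates_r_channel(self, noiseless_excitation):
        exc, rois = noiseless_excitation
        img, scale = render_false_color(exc)
        patch = img[rois["red_perpendicular"]]
        assert (patch[:, 0] > patch[:, 1]).all()
        assert (patch[:, 0] > patch[:, 2]).all()
        assert img.max() == pytest.approx(1.0)
        assert scale > 0

    def test_missing_channel_errors(self, noiseless_excitation):
        exc, _ = noiseless_excitation
        stack = ExcitationStack(
            channels={"L": exc.channels["L"], "M": exc.channels["M"]},
            mode="background",
            pixel_pitch_mm=0.05,
            dark_rows=exc.dark_rows,
            steps=("naka_rushton",),
        )
        with pytest.raises(ValueError, match="S_U"):
            render_false_color(stack)
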