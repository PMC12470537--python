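import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import naive_oracles as oracle
from conftest import structured_pixels
from ctiq.errors import DegenerateNoiseError, UndefinedMetricError, ZeroDynamicRangeError
from ctiq.io_formats import ImageGrid
from ctiq.metrics import (
    GradientMasks,
    MetricConstants,
    Roi,
    RoiSet,
    compute_cnr,
    compute_fsim,
    compute_gm_score,
    compute_gmsd,
    compute_gradient_map,
    compute_nrmse,
    compute_psnr,
    compute_snr,
    compute_ssim,
    compute_uqi,
)


def _roi_set_for(shape=(16, 16)):
    return RoiSet([
        Roi("sig", "signal", 0, 0, 8, 8),
        Roi("bg", "background", 8, 8, 8, 8),
    ])


def _alternating(mean, half_amp, shape=(8, 8)):
    """Pixels alternating mean +/- half_amp: exact mean and SD = half_amp."""
    base = np.indices(shape).sum(axis=0) % 2
    return mean + half_amp * (2.0 * base - 1.0)


class TestSNR:
    def test_equal_signal_and_noise_gives_zero(self):
        px = np.zeros((16, 16))
        px[:8, :8] = 10.0
        px[8:, 8:] = _alternating(0.0, 10.0)
        assert compute_snr(ImageGrid(px), _roi_set_for()).value == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        px = np.zeros((16, 16))
        px[:8, :8] = 100.0
        px[8:, 8:] = _alternating(0.0, 10.0)
        assert compute_snr(ImageGrid(px), _roi_set_for()).value == pytest.approx(20.0, abs=1e-12)

    def test_constant_background_is_degenerate(self):
        px = np.ones((16, 16))
        with pytest.raises(DegenerateNoiseError):
            compute_snr(ImageGrid(px), _roi_set_for())


class TestPSNR:
    def test_unit_offset_at_L255(self, rng):
        ref = ImageGrid(rng.normal(50, 20, (64, 64)))
        test = ImageGrid(ref.pixels + 1.0)
        got = compute_psnr(ref, test, MetricConstants(L=255.0))
        assert got.value == pytest.approx(20.0 * math.log10(255.0), abs=1e-10)

    def test_identical_images_yield_sentinel(self, structured_image):
        got = compute_psnr(structured_image, structured_image)
        assert math.isinf(got.value)
        assert got.flag == "identical_images"

    def test_doubling_error_drops_psnr_by_3dB(self, rng):
        ref = ImageGrid(rng.normal(0, 30, (64, 64)))
        delta = rng.normal(0, 1, (64, 64))
        a = compute_psnr(ref, ImageGrid(ref.pixels + delta), MetricConstants(L=255.0))
        b = compute_psnr(ref, ImageGrid(ref.pixels + math.sqrt(2) * delta),
                         MetricConstants(L=255.0))
        assert a.value - b.value == pytest.approx(10.0 * math.log10(2.0), abs=1e-10)

    def test_closed_form_relation_with_mse(self, rng):
        ref = ImageGrid(rng.normal(0, 30, (32, 32)))
        test = ImageGrid(ref.pixels + rng.normal(0, 3, (32, 32)))
        L = 4096.0
        got = compute_psnr(ref, test, MetricConstants(L=L)).value
        E = float(np.mean((ref.pixels - test.pixels) ** 2))
        assert got == pytest.approx(20 * math.log10(L) - 10 * math.log10(E), abs=1e-12)


class TestNRMSE:
    def test_identical_is_zero(self, structured_image):
        assert compute_nrmse(structured_image, structured_image).value == 0.0

    def test_offset_over_known_range(self):
        ref = ImageGrid(np.linspace(0, 100, 4096).reshape(64, 64))
        test = ImageGrid(ref.pixels + 5.0)
        assert compute_nrmse(ref, test).value == pytest.approx(0.05, abs=1e-12)

    def test_joint_affine_invariance(self, rng):
        ref = ImageGrid(rng.normal(0, 30, (32, 32)))
        test = ImageGrid(ref.pixels + rng.normal(0, 5, (32, 32)))
        base = compute_nrmse(ref, test).value
        scaled = compute_nrmse(ImageGrid(3.0 * ref.pixels - 40.0),
                               ImageGrid(3.0 * test.pixels - 40.0)).value
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_flat_reference_rejected(self, rng):
        with pytest.raises(ZeroDynamicRangeError):
            compute_nrmse(ImageGrid(np.ones((8, 8))),
                          ImageGrid(rng.normal(0, 1, (8, 8))))


class TestCNR:
    def test_equal_means_give_zero(self):
        px = np.zeros((16, 16))
        px[:8, :8] = _alternating(50.0, 5.0)
        px[8:, 8:] = _alternating(50.0, 5.0)
        rois = RoiSet([Roi("l", "lesion", 0, 0, 8, 8), Roi("b", "background", 8, 8, 8, 8)])
        (got,) = compute_cnr(ImageGrid(px), rois)
        assert got.value == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # It=120, Ib=20, sigma_t=sigma_b=10 -> 100/sqrt(200)
        px = np.zeros((16, 16))
        px[:8, :8] = _alternating(120.0, 10.0)
        px[8:, 8:] = _alternating(20.0, 10.0)
        rois = RoiSet([Roi("l", "lesion", 0, 0, 8, 8), Roi("b", "background", 8, 8, 8, 8)])
        (got,) = compute_cnr(ImageGrid(px), rois)
        assert got.value == pytest.approx(100.0 / math.sqrt(200.0), abs=1e-10)

    def test_linearity_layout_yields_five_values(self):
        from ctiq.noise_model import BMI_NOISE_PRESETS, inject_noise
        from ctiq.phantom_synth import default_spec, make_phantom
        from ctiq.pipeline import place_default_rois

        spec = default_spec("linearity")
        noisy = inject_noise(make_phantom(spec), BMI_NOISE_PRESETS["obese"], seed=4)
        rois = place_default_rois("linearity", spec)
        values = compute_cnr(noisy, rois)
        assert len(values) == 5
        assert all(v.value >= 0 for v in values)


class TestSSIM:
    def test_identity_is_one(self, structured_image):
        assert compute_ssim(structured_image, structured_image).value == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip_of_zero_mean_image_is_negative(self, rng):
        px = rng.normal(0, 20, (32, 32))
        px -= px.mean()
        got = compute_ssim(ImageGrid(px), ImageGrid(-px), MetricConstants(L=255.0))
        assert got.value < 0

    def test_windowed_variant_also_one_on_identity(self, structured_image):
        got = compute_ssim(structured_image, structured_image, windowed=True)
        assert got.value == pytest.approx(1.0, abs=1e-12)


class TestUQI:
    def test_doubled_image_gives_064(self, rng):
        x = ImageGrid(rng.normal(10, 3, (32, 32)))
        assert compute_uqi(x, ImageGrid(2 * x.pixels)).value == pytest.approx(0.64, abs=1e-10)

    def test_symmetry(self, rng):
        a = ImageGrid(rng.normal(10, 5, (32, 32)))
        b = ImageGrid(rng.normal(12, 4, (32, 32)))
        assert compute_uqi(a, b).value == pytest.approx(compute_uqi(b, a).value, abs=1e-14)

    def test_two_constants_undefined(self):
        with pytest.raises(UndefinedMetricError):
            compute_uqi(ImageGrid(np.ones((8, 8))), ImageGrid(np.ones((8, 8))))


class TestGradientMap:
    def test_constant_image_is_all_zero(self):
        gm = compute_gradient_map(ImageGrid(np.full((16, 16), 7.0)))
        np.testing.assert_allclose(gm, 0.0, atol=1e-12)

    def test_sobel_on_unit_ramp_is_eight_in_interior(self):
        ramp = ImageGrid(np.tile(np.arange(32, dtype=float), (32, 1)))
        gm = compute_gradient_map(ramp, GradientMasks.sobel())
        np.testing.assert_allclose(gm[2:-2, 2:-2], 8.0, atol=1e-12)

    def test_rotation_isotropy(self, rng):
        px = structured_pixels(rng, 32)
        gm = compute_gradient_map(ImageGrid(px))
        gm_rot = compute_gradient_map(ImageGrid(np.rot90(px).copy()))
        np.testing.assert_allclose(gm_rot, np.rot90(gm), atol=1e-12)

    def test_mask_invariants_enforced(self):
        with pytest.raises(ValueError):
            GradientMasks(hx=np.ones((3, 3)), hy=np.ones((3, 3)), name="bad")


class TestGMScore:
    def test_flat_image_scores_zero(self):
        got = compute_gm_score(ImageGrid(np.full((16, 16), 3.0)))
        assert got.value == 0.0
        assert got.flag == "flat_image"

    def test_affine_intensity_invariance(self, rng):
        px = structured_pixels(rng, 32)
        a = compute_gm_score(ImageGrid(px)).value
        b = compute_gm_score(ImageGrid(5.0 * px + 300.0)).value
        assert b == pytest.approx(a, rel=1e-12)

    def test_sharpening_raises_the_score(self):
        from ctiq.phantom_synth import DEFAULT_PRESETS, apply_preset

        step = np.zeros((64, 64))
        step[:, 32:] = 100.0
        img = ImageGrid(step)
        sharpened = apply_preset(img, DEFAULT_PRESETS["surrogate-sharper"])
        assert compute_gm_score(sharpened).value > compute_gm_score(img).value


class TestGMSD:
    def test_identity_is_zero(self, structured_image):
        assert compute_gmsd(structured_image, structured_image).value == 0.0

    def test_two_distinct_constants_give_zero(self):
        got = compute_gmsd(ImageGrid(np.full((16, 16), 1.0)), ImageGrid(np.full((16, 16), 9.0)))
        assert got.value == 0.0

    def test_blur_increases_gmsd(self, rng):
        from scipy import ndimage

        px = structured_pixels(rng, 64)
        ref = ImageGrid(px)
        mild = ImageGrid(ndimage.gaussian_filter(px, 1.0))
        strong = ImageGrid(ndimage.gaussian_filter(px, 3.0))
        a, b = compute_gmsd(ref, mild).value, compute_gmsd(ref, strong).value
        assert 0 < a < b


class TestFSIM:
    def test_identity_is_one(self, structured_image):
        assert compute_fsim(structured_image, structured_image).value == pytest.approx(1.0, abs=1e-9)

    def test_featureless_pair_undefined(self):
        with pytest.raises(UndefinedMetricError):
            compute_fsim(ImageGrid(np.full((32, 32), 2.0)), ImageGrid(np.full((32, 32), 5.0)))

    def test_strictly_decreasing_under_increasing_blur(self, rng):
        from scipy import ndimage

        px = structured_pixels(rng, 64)
        ref = ImageGrid(px)
        vals = [
            compute_fsim(ref, ImageGrid(ndimage.gaussian_filter(px, s))).value
            for s in (0.5, 1.5, 3.0)
        ]
        assert vals[0] > vals[1] > vals[2]


class TestOracleEquivalence:
    """Spot equivalence against the naive-loop oracles (the exhaustive sweep
    lives in the acceptance suite)."""

    def test_global_ssim_matches_naive_two_pass(self, rng):
        a = rng.normal(0, 20, (16, 16))
        b = a + rng.normal(0, 4, (16, 16))
        c = MetricConstants(L=255.0)
        c1, c2 = c.c1c2(255.0)
        got = compute_ssim(ImageGrid(a), ImageGrid(b), c).value
        assert got == pytest.approx(oracle.naive_ssim(a.tolist(), b.tolist(), c1, c2), abs=1e-12)

    def test_gmsd_matches_naive_loops(self, rng):
        from scipy import ndimage

        a = structured_pixels(rng, 16)
        b = ndimage.gaussian_filter(a, 1.0)
        c = MetricConstants()
        L = float(np.ptp(a))
        eps = c.resolve_eps_gmsd(L)
        masks = GradientMasks.prewitt()
        got = compute_gmsd(ImageGrid(a), ImageGrid(b), c).value
        want = oracle.naive_gmsd(a.tolist(), b.tolist(), masks.hx.tolist(), masks.hy.tolist(), eps)
        assert got == pytest.approx(want, abs=1e-12)


class TestRangeInvariants:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_similarity_metrics_stay_in_range(self, seed):
        r = np.random.default_rng(seed)
        a = ImageGrid(r.normal(r.uniform(-50, 50), r.uniform(1, 40), (16, 16)))
        b = ImageGrid(r.normal(r.uniform(-50, 50), r.uniform(1, 40), (16, 16)))
        assert -1.0 <= compute_ssim(a, b).value <= 1.0
        assert -1.0 <= compute_uqi(a, b).value <= 1.0
        assert compute_gmsd(a, b).value >= 0.0
        assert compute_nrmse(a, b).value >= 0.0

    @settings(max_examples=10, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_fsim_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        a = ImageGrid(structured_pixels(r, 32))
        b = ImageGrid(structured_pixels(r, 32))
        assert 0.0 <= compute_fsim(a, b).value <= 1.0
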