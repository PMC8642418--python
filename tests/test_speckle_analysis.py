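import numpy as np
import pytest

from specklemode.speckle_analysis import (
    FrameStack,
    background_subtracted_signal,
    delta_flow,
    exposure_energy_density,
    flow_index,
    line_profile,
    read_stack,
    roi_sbr,
    speckle_size,
    temporal_contrast,
    write_map,
    write_stack,
)
from specklemode.synthetic_speckle import (
    correlated_field,
    pupil_fraction_for_speckle_size,
)


def stack_of(arr, exposure_ms=20.0):
    return FrameStack(frames=np.asarray(arr, dtype=float), exposure_ms=exposure_ms)


class TestTemporalContrast:
    def test_constant_stack_is_exactly_zero(self):
        st = stack_of(np.ones((40, 8, 8)) * 3.7)
        assert np.all(temporal_contrast(st).values == 0.0)

    def test_two_frame_hand_computation(self):
        # one pixel with values {0, 2}: mean 1, sample std sqrt(2)
        st = stack_of([[[0.0]], [[2.0]]])
        assert temporal_contrast(st).values[0, 0] == pytest.approx(np.sqrt(2))

    def test_exponential_frames_give_unit_contrast(self, rng):
        """Fully developed speckle: sigma/mu = 1 for exponential intensities
        (finite-sample estimator bias keeps the 40-frame mean slightly low)."""
        st = stack_of(rng.exponential(1.0, (40, 100, 100)))
        k = temporal_contrast(st).values
        assert 0.95 < k.mean() < 1.01

    def test_scale_invariance_is_exact(self, rng):
        frames = rng.exponential(1.0, (10, 16, 16))
        k1 = temporal_contrast(stack_of(frames)).values
        k2 = temporal_contrast(stack_of(4.0 * frames)).values  # power of two
        np.testing.assert_array_equal(k1, k2)
        k3 = temporal_contrast(stack_of(3.0 * frames)).values
        np.testing.assert_allclose(k1, k3, rtol=1e-12)

    def test_zero_mean_pixels_flagged_invalid(self):
        frames = np.ones((5, 2, 2))
        frames[:, 0, 0] = 0.0
        k = temporal_contrast(stack_of(frames)).values
        assert np.isnan(k[0, 0]) and k[1, 1] == 0.0

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            temporal_contrast(stack_of(np.ones((1, 4, 4))))

    def test_population_variant(self, rng):
        frames = rng.exponential(1.0, (10, 8, 8))
        k_n = temporal_contrast(stack_of(frames), ddof=0).values
        k_n1 = temporal_contrast(stack_of(frames), ddof=1).values
        np.testing.assert_allclose(k_n, k_n1 * np.sqrt(9 / 10), rtol=1e-12)


class TestSpatialContrast:
    def test_constant_frame_is_zero(self):
        from specklemode.speckle_analysis import spatial_contrast

        np.testing.assert_allclose(spatial_contrast(np.full((32, 32), 5.0)), 0.0)

    def test_fully_developed_speckle_near_unity(self):
        from specklemode.speckle_analysis import spatial_contrast

        img = np.abs(correlated_field((256, 256), 1.0, np.random.default_rng(2))) ** 2
        ks = spatial_contrast(img, window=15)
        assert np.nanmean(ks) == pytest.approx(1.0, abs=0.1)


class TestFlowIndex:
    @pytest.mark.parametrize("k, expected", [(0.5, 4.0), (1.0, 1.0), (2.0, 0.25)])
    def test_inverse_square(self, k, expected):
        from specklemode.speckle_analysis import ContrastMap

        fm = flow_index(ContrastMap(values=np.array([[k]]), n_frames=40))
        assert fm.values[0, 0] == pytest.approx(expected)

    def test_zero_contrast_clamps_to_ceiling(self):
        from specklemode.speckle_analysis import ContrastMap

        fm = flow_index(ContrastMap(values=np.array([[0.0]]), n_frames=40), ceiling=1e4)
        assert fm.values[0, 0] == 1e4

    def test_nan_propagates(self):
        from specklemode.speckle_analysis import ContrastMap

        fm = flow_index(ContrastMap(values=np.array([[np.nan, 1.0]]), n_frames=40))
        assert np.isnan(fm.values[0, 0]) and fm.values[0, 1] == 1.0


class TestDeltaFlow:
    def test_equation(self):
        ts = delta_flow([10.0, 10.0, 10.0, 4.0, 20.0], baseline_window=slice(0, 3))
        assert ts.baseline == 10.0
        np.testing.assert_allclose(ts.delta_flow, [0, 0, 0, -0.6, 1.0])

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            delta_flow([0.0, 0.0, 1.0], baseline_window=slice(0, 2))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            delta_flow([1.0, 2.0], baseline_window=slice(0, 0))


class TestSpeckleSize:
    def test_iid_noise_is_one_pixel(self, rng):
        img = rng.standard_normal((128, 128))
        assert speckle_size(img) == pytest.approx(1.0, abs=0.15)

    def test_generator_cross_validation(self):
        """Pupil set for ~2.5-px grains measures back within 15%."""
        p = pupil_fraction_for_speckle_size(2.5, oversample=1)
        img = np.abs(correlated_field((256, 256), p, np.random.default_rng(3))) ** 2
        assert speckle_size(img) == pytest.approx(2.5, rel=0.15)

    def test_upsampling_doubles_size(self):
        p = pupil_fraction_for_speckle_size(2.5, oversample=1)
        img = np.abs(correlated_field((256, 256), p, np.random.default_rng(3))) ** 2
        s1 = speckle_size(img)
        s2 = speckle_size(np.kron(img, np.ones((2, 2))))
        assert s2 == pytest.approx(2 * s1, rel=0.15)

    def test_scale_and_offset_invariance(self, rng):
        img = np.abs(correlated_field((128, 128), 0.4, rng)) ** 2
        assert speckle_size(5.0 * img + 2.0) == pytest.approx(speckle_size(img), rel=1e-9)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            speckle_size(np.ones((64, 64)))


class TestRoiQuantification:
    def test_background_subtraction(self):
        m = np.zeros((10, 10))
        m[:5] = 5.0
        m[5:] = 2.0
        assert background_subtracted_signal(m, (0, 0, 5, 10), (5, 0, 10, 10)) == 3.0

    def test_identical_statistics_give_zero_and_unity(self, rng):
        m = np.full((10, 10), 4.0)
        assert background_subtracted_signal(m, (0, 0, 5, 10), (5, 0, 10, 10)) == 0.0
        assert roi_sbr(m, (0, 0, 5, 10), (5, 0, 10, 10)) == 1.0

    def test_roi_sbr_ratio(self):
        m = np.zeros((10, 10))
        m[:5] = 8.0
        m[5:] = 2.0
        assert roi_sbr(m, (0, 0, 5, 10), (5, 0, 10, 10)) == 4.0

    def test_overlapping_rois_rejected(self):
        m = np.ones((10, 10))
        with pytest.raises(ValueError):
            roi_sbr(m, (0, 0, 6, 10), (5, 0, 10, 10))

    def test_out_of_bounds_roi_rejected(self):
        with pytest.raises(ValueError):
            roi_sbr(np.ones((10, 10)), (0, 0, 12, 10), (5, 0, 10, 10))


class TestLineProfile:
    def test_constant_map(self):
        prof = line_profile(np.full((20, 20), 7.0), (2, 2), (15, 18), n_samples=25)
        np.testing.assert_allclose(prof.values, 7.0)

    def test_linear_gradient_stays_linear(self):
        m = np.tile(np.arange(32, dtype=float), (32, 1))
        prof = line_profile(m, (0, 0), (31, 31), n_samples=30)
        np.testing.assert_allclose(np.diff(prof.values, 2), 0.0, atol=1e-9)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            line_profile(np.ones((10, 10)), (0, 0), (10, 5))


class TestEnergyDensity:
    def test_reference_acquisition_settings(self):
        assert exposure_energy_density(30, 5, 40) == 6.0
        assert exposure_energy_density(60, 20, 40) == 48.0


class TestIO:
    def test_stack_roundtrip(self, tmp_path, rng):
        stack = FrameStack(frames=rng.exponential(1.0, (5, 16, 16)))
        path = tmp_path / "stack.tif"
        write_stack(path, stack)
        back = read_stack(path, n_frames=4)
        assert back.frames.shape == (4, 16, 16)
        # 16-bit quantization preserves relative structure
        a = stack.frames[0].ravel()
        b = back.frames[0].ravel()
        assert np.corrcoef(a, b)[0, 1] > 0.999

    def test_map_roundtrip(self, tmp_path):
        import tifffile

        m = np.linspace(0, 1, 64).reshape(8, 8)
        path = tmp_path / "k.tif"
        write_map(path, m)
        back = tifffile.imread(path)
        assert back.dtype == np.float32
        np.testing.assert_allclose(back, m, atol=1e-6)
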