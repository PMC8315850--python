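import numpy as np
import pytest

from renalus import PCNNParams, enhance, init_thresholds, laplacian_convolve
from renalus import pcnn_enhance, run_pcnn
from renalus.errors import (
    InvalidImageError,
    InvalidParameterError,
    IterationCapError,
)

from .conftest import random_image
from .oracles import laplacian_kernel, naive_convolve3, uncoupled_firing_times


class TestLaplacianConvolve:
    def test_constant_field_zero_sum_kernel(self):
        img = np.full((3, 3), 50, dtype=np.uint8)
        assert np.array_equal(laplacian_convolve(img, center=8), np.zeros((3, 3)))

    def test_constant_field_center_six(self):
        # kernel sums to -2, so a constant-50 field maps to -100 everywhere
        img = np.full((3, 3), 50, dtype=np.uint8)
        assert np.array_equal(
            laplacian_convolve(img, center=6), np.full((3, 3), -100.0)
        )

    def test_single_bright_pixel(self):
        img = np.zeros((5, 5), dtype=np.uint8)
        img[2, 2] = 100
        out = laplacian_convolve(img, center=8)
        expected = naive_convolve3(img, laplacian_kernel(8))
        assert np.array_equal(out, expected)
        assert out[2, 2] == 800
        assert out[1, 1] == out[1, 2] == out[3, 3] == -100
        assert out[0, 0] == 0

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("center", [6, 8])
    def test_matches_naive_sliding_window(self, seed, center):
        rng = np.random.default_rng(seed)
        img = random_image(rng, shape=(7, 9))
        assert np.allclose(
            laplacian_convolve(img, center),
            naive_convolve3(img, laplacian_kernel(center)),
        )

    def test_rejects_non_2d(self):
        with pytest.raises(InvalidImageError):
            laplacian_convolve(np.zeros((2, 2, 3), dtype=np.uint8))


class TestInitThresholds:
    def test_constant_image(self, default_params):
        img = np.full((4, 4), 50, dtype=np.uint8)
        assert np.array_equal(init_thresholds(img, default_params), np.full((4, 4), 50.0))

    def test_clamped_when_convolution_overshoots(self, default_params):
        # central pixel convolves far above the image max -> raw threshold < 0
        img = np.zeros((5, 5), dtype=np.uint8)
        img[2, 2] = 200
        field = init_thresholds(img, default_params)
        assert field[2, 2] == default_params.stimulus_floor
        assert (field > 0).all()

    def test_ramp_composes_with_convolution_oracle(self, default_params):
        img = np.arange(16, dtype=np.uint8).reshape(4, 4) * 10
        cpg = naive_convolve3(img, laplacian_kernel(8))
        expected = np.maximum(float(img.max()) - cpg, default_params.stimulus_floor)
        assert np.allclose(init_thresholds(img, default_params), expected)

    def test_all_zero_image_is_degenerate_but_defined(self, default_params):
        img = np.zeros((3, 3), dtype=np.uint8)
        field = init_thresholds(img, default_params)
        assert np.array_equal(field, np.full((3, 3), default_params.stimulus_floor))


class TestRunPCNN:
    def test_single_pixel_fires_first_iteration(self, default_params):
        # theta0 = 200 (reflect padding zeroes the Laplacian); after one decay
        # 200*exp(-0.7) ~ 99.3 < stimulus 200, so S = 1.
        img = np.array([[200]], dtype=np.uint8)
        assert np.array_equal(run_pcnn(img, default_params), [[1]])

    def test_constant_image_fires_synchronously(self, default_params):
        img = np.full((6, 6), 120, dtype=np.uint8)
        firing = run_pcnn(img, default_params)
        assert len(np.unique(firing)) == 1

    def test_fire_once(self, default_params):
        rng = np.random.default_rng(42)
        img = random_image(rng, shape=(12, 12))
        firing = run_pcnn(img, default_params)
        assert firing.min() >= 1
        assert firing.max() <= default_params.max_iters
        # every neuron has exactly one firing time, none left at zero
        assert (firing > 0).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_uncoupled_equals_scalar_recurrence(self, seed, uncoupled_params):
        rng = np.random.default_rng(seed)
        img = random_image(rng, shape=(8, 8))
        expected = uncoupled_firing_times(
            img,
            uncoupled_params.laplacian_center,
            uncoupled_params.tau,
            uncoupled_params.stimulus_floor,
            uncoupled_params.max_iters,
        )
        assert np.array_equal(run_pcnn(img, uncoupled_params), expected)

    def test_monotone_in_intensity_for_equal_thresholds(self, uncoupled_params):
        rng = np.random.default_rng(3)
        img = random_image(rng, shape=(10, 10))
        firing = run_pcnn(img, uncoupled_params)
        theta0 = init_thresholds(img, uncoupled_params)
        flat_v = img.ravel().astype(int)
        flat_t = theta0.ravel()
        flat_s = firing.ravel()
        checked = 0
        for a in range(len(flat_v)):
            for b in range(len(flat_v)):
                if flat_t[a] == flat_t[b] and flat_v[a] > flat_v[b]:
                    assert flat_s[a] <= flat_s[b]
                    checked += 1
        assert checked > 0

    def test_iteration_cap_error_names_unfired_count(self):
        img = np.zeros((5, 5), dtype=np.uint8)
        img[2, 2] = 255
        params = PCNNParams(max_iters=1, alpha=0.0)
        with pytest.raises(IterationCapError) as excinfo:
            run_pcnn(img, params)
        assert excinfo.value.unfired > 0
        assert str(excinfo.value.unfired) in str(excinfo.value)

    def test_linking_never_delays_firing(self, default_params, uncoupled_params):
        rng = np.random.default_rng(11)
        img = random_image(rng, shape=(10, 10))
        coupled = run_pcnn(img, default_params)
        uncoupled = run_pcnn(img, uncoupled_params)
        assert (coupled <= uncoupled).all()


class TestEnhance:
    def test_first_firing_maps_to_brightest(self, default_params):
        img = np.array([[10, 200]], dtype=np.uint8)
        firing = np.array([[1, 2]])
        out = enhance(img, firing, default_params)
        assert out[0, 0] == 255
        assert out[0, 1] == 0

    def test_single_firing_class_maps_to_mid_gray(self, default_params):
        img = np.full((3, 3), 80, dtype=np.uint8)
        firing = np.full((3, 3), 2)
        assert np.array_equal(enhance(img, firing, default_params), np.full((3, 3), 127))

    def test_toy_closed_form(self, default_params):
        # raw = 100 * exp(-0.7 * (S-1)) = (100, 49.66, 24.66) -> (255, 85, 0)
        img = np.array([[100, 50, 20]], dtype=np.uint8)
        firing = np.array([[1, 2, 3]])
        assert np.array_equal(enhance(img, firing, default_params), [[255, 85, 0]])

    def test_rejects_firing_below_one(self, default_params):
        img = np.full((2, 2), 10, dtype=np.uint8)
        firing = np.array([[0, 1], [1, 1]])
        with pytest.raises(InvalidImageError):
            enhance(img, firing, default_params)

    def test_anti_monotone_in_firing_time(self, default_params):
        img = np.full((1, 6), 100, dtype=np.uint8)
        firing = np.array([[1, 2, 3, 4, 5, 6]])
        out = enhance(img, firing, default_params)[0]
        assert (np.diff(out.astype(int)) < 0).all()

    def test_log_form_is_order_equivalent(self):
        img = np.full((1, 5), 100, dtype=np.uint8)
        firing = np.array([[3, 1, 4, 2, 5]])
        out_exp = enhance(img, firing, PCNNParams(enhance_form="exp"))
        out_log = enhance(img, firing, PCNNParams(enhance_form="log"))
        assert np.array_equal(np.argsort(out_exp[0]), np.argsort(out_log[0]))


class TestPCNNEnhance:
    def test_deterministic(self, phantom, default_params):
        first = pcnn_enhance(phantom, default_params)
        second = pcnn_enhance(phantom, default_params)
        assert np.array_equal(first, second)

    def test_constant_input_gives_constant_output(self, default_params):
        img = np.full((5, 5), 90, dtype=np.uint8)
        out = pcnn_enhance(img, default_params)
        assert len(np.unique(out)) == 1

    def test_phantom_output_spans_full_range(self, phantom, default_params):
        out = pcnn_enhance(phantom, default_params)
        assert out.min() == 0
        assert out.max() == 255

    def test_propagates_iteration_cap(self):
        img = np.zeros((5, 5), dtype=np.uint8)
        img[2, 2] = 255
        with pytest.raises(IterationCapError):
            pcnn_enhance(img, PCNNParams(max_iters=1, alpha=0.0))


class TestPCNNParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tau": 0.0},
            {"tau": -1.0},
            {"w_f": 0.0},
            {"max_iters": 0},
            {"stimulus_floor": 0.0},
            {"enhance_form": "sqrt"},
            {"linking_kernel": -np.ones((3, 3))},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            PCNNParams(**kwargs)

    def test_reference_defaults(self, default_params):
        assert default_params.alpha == 0.2
        assert default_params.tau == 0.7
        assert default_params.w_l == 1.0
        assert default_params.w_f == 278.0
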