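"""Pixel-history background subtraction: differencing, SDPH statistics,
dual-threshold masks, automatic threshold selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermopad import (
    DifferenceModel,
    ForegroundMask,
    SdphThresholds,
    TemperatureScale,
    ThermalFrame,
    ThermalSequence,
    apply_mask,
    auto_thresholds,
    difference_mask,
    frame_difference,
    pixel_history_stats,
    sdph_mask,
    update_background,
)
from oracles import naive_pixel_history


def _frame(arr, t=0.0, depth=8):
    return ThermalFrame(
        pixels=np.asarray(arr, dtype=np.int64),
        scale=TemperatureScale(bit_depth=depth),
        timestamp=t,
    )


def _seq(stack, depth=8):
    frames = tuple(_frame(a, t=5.0 * i, depth=depth) for i, a in enumerate(stack))
    return ThermalSequence(frames=frames, interval=5.0)


class TestFrameDifference:
    @pytest.mark.parametrize(
        "cur, bg, expected",
        [(200, 180, 20), (100, 130, 30), (150, 150, 0)],
    )
    def test_absolute_difference(self, cur, bg, expected):
        model = DifferenceModel(background=np.full((3, 3), float(bg)))
        d = frame_difference(_frame(np.full((3, 3), cur)), model)
        assert np.all(d == expected)

    def test_shape_mismatch(self):
        model = DifferenceModel(background=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            frame_difference(_frame(np.zeros((3, 3))), model)


class TestDifferenceMask:
    def test_boundary_equality_is_foreground(self):
        d = np.array([[4.9, 5.0], [5.1, 0.0]])
        m = difference_mask(d, tau_f=5.0)
        assert m.mask.tolist() == [[0, 1], [1, 0]]

    def test_zero_threshold_all_ones(self):
        assert difference_mask(np.zeros((4, 4)), 0.0).area() == 16

    def test_zero_difference_positive_threshold_all_zero(self):
        assert difference_mask(np.zeros((4, 4)), 1.0).area() == 0


class TestBackgroundLearning:
    def test_alpha_zero_is_identity(self):
        model = DifferenceModel(background=np.full((2, 2), 50.0), learning_rate=0.0)
        out = update_background(model, _frame(np.full((2, 2), 200)))
        assert np.array_equal(out.background, model.background)

    def test_alpha_one_replaces_background(self):
        model = DifferenceModel(background=np.full((2, 2), 50.0), learning_rate=1.0)
        out = update_background(model, _frame(np.full((2, 2), 200)))
        assert np.all(out.background == 200.0)

    def test_halfway_blend(self):
        model = DifferenceModel(background=np.full((2, 2), 100.0), learning_rate=0.5)
        out = update_background(model, _frame(np.full((2, 2), 200)))
        assert np.all(out.background == 150.0)

    def test_iteration_converges_geometrically_to_current_frame(self):
        model = DifferenceModel(background=np.zeros((2, 2)), learning_rate=0.1)
        target = _frame(np.full((2, 2), 100))
        for _ in range(200):
            model = update_background(model, target)
        assert np.allclose(model.background, 100.0, atol=1e-6)

    def test_invalid_learning_rate(self):
        with pytest.raises(ValueError):
            DifferenceModel(background=np.zeros((2, 2)), learning_rate=1.5)


class TestPixelHistoryStats:
    def test_hand_computed_window(self):
        # history (0, 2, 4): mean 2, population variance (0+4+16)/3 - 4 = 8/3
        seq = _seq([np.full((2, 2), v) for v in (0, 2, 4)])
        stats = pixel_history_stats(seq, t_index=2, window_n=3)
        assert np.allclose(stats.mean_image, 2.0)
        assert np.allclose(stats.var_image, 8.0 / 3.0)

    def test_constant_history_zero_variance(self):
        seq = _seq([np.full((3, 3), 7)] * 5)
        stats = pixel_history_stats(seq, t_index=4, window_n=5)
        assert np.all(stats.var_image == 0)

    def test_single_frame_window(self):
        seq = _seq([np.arange(4).reshape(2, 2)])
        stats = pixel_history_stats(seq, t_index=0, window_n=1)
        assert np.array_equal(stats.mean_image, [[0, 1], [2, 3]])
        assert np.all(stats.var_image == 0)

    def test_window_uses_trailing_frames_only(self):
        # frames 0..4 hold values 0,0,0,10,10; window of 2 at the end sees only 10s
        seq = _seq([np.full((2, 2), v) for v in (0, 0, 0, 10, 10)])
        stats = pixel_history_stats(seq, t_index=4, window_n=2)
        assert np.all(stats.mean_image == 10.0)
        assert np.all(stats.var_image == 0.0)

    def test_insufficient_history_names_minimum(self):
        seq = _seq([np.zeros((2, 2))] * 3)
        with pytest.raises(ValueError, match="at least 5"):
            pixel_history_stats(seq, t_index=2, window_n=5)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(11)
        vol = rng.integers(0, 256, size=(10, 8, 8))
        seq = _seq(list(vol))
        for n in (1, 3, 10):
            stats = pixel_history_stats(seq, t_index=9, window_n=n)
            mean, var = naive_pixel_history(vol.astype(float), n)
            assert np.allclose(stats.mean_image, mean, atol=1e-9)
            assert np.allclose(stats.var_image, var, atol=1e-9)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(shift=st.integers(min_value=0, max_value=200), seed=st.integers(0, 2**16))
    def test_shift_invariance_of_variance(self, shift, seed):
        """Adding a constant to every frame shifts the mean image and
        leaves the variance image unchanged."""
        rng = np.random.default_rng(seed)
        vol = rng.integers(0, 50, size=(5, 6, 6))
        base = pixel_history_stats(_seq(list(vol)), 4, 5)
        moved = pixel_history_stats(_seq(list(vol + shift), depth=10), 4, 5)
        assert np.allclose(moved.mean_image, base.mean_image + shift, atol=1e-6)
        assert np.allclose(moved.var_image, base.var_image, atol=1e-6)


class TestSdphMask:
    def _stats(self, mean, var):
        from thermopad import PixelHistoryStats

        return PixelHistoryStats(
            mean_image=np.asarray(mean, float),
            var_image=np.asarray(var, float),
            window_n=3,
        )

    def test_intersection_requires_both_conditions(self):
        stats = self._stats(np.full((2, 2), 200.0), np.zeros((2, 2)))
        m = sdph_mask(stats, SdphThresholds(tau_mean=150, tau_var=10))
        assert m.area() == 0  # hot but static: background

    def test_hot_and_warming_pixel_is_foreground(self):
        stats = self._stats([[200.0]], [[50.0]])
        m = sdph_mask(stats, SdphThresholds(tau_mean=150, tau_var=10))
        assert m.mask[0, 0] == 1

    def test_zero_thresholds_all_ones(self):
        stats = self._stats(np.zeros((3, 3)), np.zeros((3, 3)))
        assert sdph_mask(stats, SdphThresholds(0, 0)).area() == 9

    def test_thresholds_above_maxima_all_zeros(self):
        rng = np.random.default_rng(3)
        stats = self._stats(rng.uniform(0, 100, (5, 5)), rng.uniform(0, 9, (5, 5)))
        m = sdph_mask(stats, SdphThresholds(tau_mean=101, tau_var=10))
        assert m.area() == 0

    def test_stddev_mode_thresholds_root_dispersion(self):
        stats = self._stats([[100.0, 100.0]], [[16.0, 4.0]])
        m = sdph_mask(stats, SdphThresholds(tau_mean=0, tau_var=3, mode="stddev"))
        assert m.mask.tolist() == [[1, 0]]  # stddevs 4 and 2 vs threshold 3

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        tau1=st.floats(0, 120),
        tau2=st.floats(0, 120),
        dtau=st.floats(0, 50),
        seed=st.integers(0, 2**16),
    )
    def test_mask_shrinks_monotonically_in_thresholds(self, tau1, tau2, dtau, seed):
        rng = np.random.default_rng(seed)
        stats = self._stats(
            rng.uniform(0, 100, (6, 6)), rng.uniform(0, 100, (6, 6))
        )
        base = sdph_mask(stats, SdphThresholds(tau1, tau2))
        tighter = sdph_mask(stats, SdphThresholds(tau1 + dtau, tau2 + dtau))
        assert np.all(tighter.mask <= base.mask)


class TestApplyMask:
    def test_all_one_mask_keeps_every_pixel(self):
        frame = _frame(np.arange(16).reshape(4, 4))
        fg = apply_mask(ForegroundMask(mask=np.ones((4, 4), np.uint8)), frame)
        assert fg.n_included == 16

    def test_all_zero_mask_excludes_everything(self):
        frame = _frame(np.arange(16).reshape(4, 4))
        fg = apply_mask(ForegroundMask(mask=np.zeros((4, 4), np.uint8)), frame)
        assert fg.n_included == 0

    def test_checkerboard_includes_half(self):
        m = np.indices((4, 4)).sum(axis=0) % 2
        fg = apply_mask(ForegroundMask(mask=m.astype(np.uint8)), _frame(np.zeros((4, 4))))
        assert fg.n_included == 8

    def test_excluded_pixels_never_reach_statistics(self):
        frame = _frame([[0, 255], [255, 255]])
        m = ForegroundMask(mask=np.array([[0, 1], [1, 1]], np.uint8))
        fg = apply_mask(m, frame)
        assert fg.included_values().min() == 45.0  # the cold pixel is excluded


class TestAutoThresholds:
    def test_two_level_image_threshold_falls_between_levels(self):
        from thermopad import PixelHistoryStats

        mean = np.full((20, 20), 50.0)
        mean[5:15, 5:15] = 200.0
        var = np.full((20, 20), 1.0)
        var[5:15, 5:15] = 80.0
        stats = PixelHistoryStats(mean_image=mean, var_image=var, window_n=3)
        thr = auto_thresholds(stats)
        assert 50.0 < thr.tau_mean < 200.0
        assert 1.0 < thr.tau_var < 80.0

    def test_constant_image_raises_with_instruction(self):
        from thermopad import PixelHistoryStats

        stats = PixelHistoryStats(
            mean_image=np.full((4, 4), 5.0),
            var_image=np.full((4, 4), 2.0),
            window_n=3,
        )
        with pytest.raises(ValueError, match="manual"):
            auto_thresholds(stats)

    def test_recovers_ground_truth_up_to_boundary(self, ellipse_sequence):
        seq, truth = ellipse_sequence
        stats = pixel_history_stats(seq, t_index=len(seq) - 1, window_n=10)
        mask = sdph_mask(stats, auto_thresholds(stats))
        disagreement = np.logical_xor(mask.as_bool(), truth.as_bool()).sum()
        assert disagreement <= 0.02 * truth.area()
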