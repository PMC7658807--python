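"""Frame-correlation and per-pixel-difference metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rhizoquant.dynamics import (
    TimeLapseStack,
    ZeroVarianceError,
    corr2d,
    correlation_by_lag,
    framewise_dynamics,
    mean_abs_diff,
    overlay_rgb,
)

A = np.array([[1.0, 2.0], [3.0, 4.0]])


class TestCorr2d:
    def test_self_correlation_is_one(self):
        assert corr2d(A, A) == pytest.approx(1.0, abs=1e-12)

    def test_positive_affine_gives_one(self):
        assert corr2d(A, 3.0 * A + 7.0) == pytest.approx(1.0, abs=1e-12)

    def test_negation_gives_minus_one(self):
        assert corr2d(A, -A + 10.0) == pytest.approx(-1.0, abs=1e-12)

    def test_hand_summed_pearson(self):
        # x=(1,2,3,4), y=(1,2,4,3): cov*n=4, sx*sy*n=5 -> r=0.8
        b = np.array([[1.0, 2.0], [4.0, 3.0]])
        assert corr2d(A, b) == pytest.approx(0.8, abs=1e-12)

    def test_constant_input_raises_not_zero(self):
        with pytest.raises(ZeroVarianceError):
            corr2d(A, np.full((2, 2), 5.0))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            corr2d(A, np.ones((3, 3)))

    def test_mask_restricts_selection(self):
        a = np.array([[1.0, 2.0], [3.0, 100.0]])
        b = np.array([[1.0, 2.0], [3.0, -50.0]])
        mask = np.array([[True, True], [True, False]])
        assert corr2d(a, b, mask) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_and_bounds_on_random_pairs(self, rng):
        for _ in range(1000):
            a = rng.normal(size=(6, 6))
            b = rng.normal(size=(6, 6))
            r = corr2d(a, b)
            assert r == pytest.approx(corr2d(b, a), abs=1e-12)
            assert -1.0 <= r <= 1.0


class TestMeanAbsDiff:
    def test_self_difference_zero(self):
        assert mean_abs_diff(A, A) == 0.0

    def test_unit_offset(self):
        assert mean_abs_diff(np.zeros((3, 3)), np.ones((3, 3))) == 1.0

    def test_enumerated_case(self):
        a = np.array([[0.0, 2.0], [4.0, 6.0]])
        assert mean_abs_diff(a, np.ones((2, 2))) == pytest.approx(2.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        arrays(np.float64, (4, 4), elements=st.floats(-100, 100)),
        arrays(np.float64, (4, 4), elements=st.floats(-100, 100)),
        arrays(np.float64, (4, 4), elements=st.floats(-100, 100)),
    )
    def test_triangle_inequality(self, a, b, c):
        lhs = mean_abs_diff(a, c)
        rhs = mean_abs_diff(a, b) + mean_abs_diff(b, c)
        assert lhs <= rhs + 1e-9


class TestFramewiseDynamics:
    def test_identical_frames_is_static_limit(self):
        frames = np.tile(A, (4, 1, 1))
        stack = TimeLapseStack(frames=frames)
        res = framewise_dynamics(stack)
        assert np.allclose(res.per_frame_correlation, 1.0)
        assert np.all(res.per_frame_difference == 0.0)
        assert res.stack_correlation == pytest.approx(1.0)
        assert res.stack_difference == 0.0

    def test_three_frame_enumeration(self):
        # frames (A, A, A+5): correlations all 1 (affine invariance);
        # differences per frame {2.5, 2.5, 5.0}
        stack = TimeLapseStack(frames=np.stack([A, A, A + 5.0]))
        res = framewise_dynamics(stack)
        assert np.allclose(res.per_frame_correlation, 1.0)
        assert res.per_frame_difference == pytest.approx([2.5, 2.5, 5.0])
        assert res.stack_difference == pytest.approx(10.0 / 3.0)

    def test_constant_frame_error_names_index(self):
        frames = np.stack([A, np.full((2, 2), 3.0), A])
        with pytest.raises(ZeroVarianceError, match="frame 1"):
            framewise_dynamics(TimeLapseStack(frames=frames))

    def test_time_reversal_reverses_per_frame_lists(self, rng):
        frames = rng.normal(size=(6, 8, 8))
        fwd = framewise_dynamics(TimeLapseStack(frames=frames))
        rev = framewise_dynamics(TimeLapseStack(frames=frames[::-1]))
        assert np.allclose(fwd.per_frame_correlation,
                           rev.per_frame_correlation[::-1])
        assert np.allclose(fwd.per_frame_difference,
                           rev.per_frame_difference[::-1])
        assert fwd.stack_correlation == pytest.approx(rev.stack_correlation)
        assert fwd.stack_difference == pytest.approx(rev.stack_difference)

    def test_independent_noise_has_null_correlation(self, rng):
        # Monte-Carlo null: grand mean over 100 pure-noise stacks ~ 0
        means = []
        for _ in range(100):
            frames = rng.normal(size=(25, 64, 64))
            means.append(framewise_dynamics(TimeLapseStack(frames=frames))
                         .stack_correlation)
        assert abs(np.mean(means)) < 0.02

    def test_mean_normalized_mode_recorded(self):
        stack = TimeLapseStack(frames=np.stack([A, A + 1.0]))
        res = framewise_dynamics(stack, normalize=True)
        assert res.difference_mode == "absolute_mean_normalized"
        res_sq = framewise_dynamics(stack, squared=True)
        assert res_sq.difference_mode == "squared_raw"

    def test_correlation_by_lag_decays_with_interval(self):
        from rhizoquant.synthgen import (FilamentNetworkParams,
                                         make_filament_timelapse)

        stack, _ = make_filament_timelapse(
            FilamentNetworkParams(remodeling_rate=0.3, seed=7))
        lags, corr = correlation_by_lag(stack)
        assert lags[0] == pytest.approx(stack.frame_interval)
        assert corr[0] > corr[-1]


class TestOverlayRgb:
    def test_identical_frames_give_gray_overlay(self, static_stack):
        rgb = overlay_rgb(static_stack, (0, 1, 2))
        assert np.allclose(rgb[..., 0], rgb[..., 1])
        assert np.allclose(rgb[..., 1], rgb[..., 2])
        assert rgb.max() == pytest.approx(1.0)

    def test_single_channel_is_pure_color(self):
        frames = np.stack([A, np.zeros((2, 2)), np.zeros((2, 2))])
        rgb = overlay_rgb(TimeLapseStack(frames=frames), (0, 1, 2))
        assert rgb[..., 0].max() == 1.0
        assert rgb[..., 1:].max() == 0.0

    def test_zero_range_frames_map_to_black(self):
        frames = np.zeros((3, 4, 4))
        rgb = overlay_rgb(TimeLapseStack(frames=frames), (0, 1, 2))
        assert rgb.max() == 0.0

    def test_out_of_range_index_raises(self, static_stack):
        with pytest.raises(IndexError):
            overlay_rgb(static_stack, (0, 1, 99))


def test_stack_validation():
    with pytest.raises(ValueError):
        TimeLapseStack(frames=A[None])  # single frame
    with pytest.raises(ValueError):
        TimeLapseStack(frames=np.stack([A, A]),
                       cell_mask=np.zeros((2, 2), bool))  # <2 mask px
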