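"""Temporal preprocessing: volume discard, FD, filtering, nuisance regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gfcdmap.preprocess import (
    BoldSeries,
    MotionTrace,
    compute_fd,
    detrend_and_bandpass,
    discard_initial,
    extract_tissue_signal,
    nuisance_regress,
)
from conftest import make_series


class TestDiscardInitial:
    @pytest.mark.parametrize("n_frames,n_discard,expected", [(140, 10, 130), (11, 10, 1)])
    def test_frame_counts(self, rng, n_frames, n_discard, expected):
        series = make_series(rng.normal(size=(2, 2, 2, n_frames)))
        assert discard_initial(series, n_discard).n_frames == expected

    def test_zero_discard_is_identity(self, rng):
        series = make_series(rng.normal(size=(2, 2, 2, 5)))
        out = discard_initial(series, 0)
        np.testing.assert_array_equal(out.data, series.data)

    def test_discarding_everything_errors(self, rng):
        series = make_series(rng.normal(size=(2, 2, 2, 5)))
        with pytest.raises(ValueError):
            discard_initial(series, 5)


class TestFramewiseDisplacement:
    def test_zero_trace_gives_zero_fd(self):
        fd = compute_fd(MotionTrace(np.zeros((20, 6))))
        assert fd.mean_fd == 0.0
        assert np.all(fd.values == 0.0)

    def test_hand_computed_step(self):
        # one step of +0.1 mm translation and +0.01 rad rotation:
        # FD = 0.1 + 50 * 0.01 = 0.6 mm
        params = np.zeros((3, 6))
        params[1:, 0] = 0.1
        params[1:, 3] = 0.01
        fd = compute_fd(MotionTrace(params))
        assert fd.values[0] == 0.0
        assert fd.values[1] == pytest.approx(0.6, abs=1e-12)
        assert fd.values[2] == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_sign_flip_leaves_fd_unchanged(self, seed):
        params = np.random.default_rng(seed).normal(size=(10, 6))
        fd_pos = compute_fd(MotionTrace(params)).values
        fd_neg = compute_fd(MotionTrace(-params)).values
        np.testing.assert_allclose(fd_pos, fd_neg, atol=1e-12)

    @given(st.integers(0, 5), st.floats(-10, 10, allow_nan=False))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_constant_offset_invariance(self, column, offset):
        params = np.random.default_rng(3).normal(size=(10, 6))
        shifted = params.copy()
        shifted[:, column] += offset
        np.testing.assert_allclose(
            compute_fd(MotionTrace(params)).values,
            compute_fd(MotionTrace(shifted)).values,
            atol=1e-9,
        )

    def test_single_frame_errors(self):
        with pytest.raises(ValueError):
            compute_fd(MotionTrace(np.zeros((1, 6))))


class TestDetrendBandpass:
    def test_in_band_sinusoid_preserved(self):
        t = np.arange(128) * 3.0
        sig = np.sin(2 * np.pi * 0.05 * t)
        series = make_series(np.broadcast_to(sig, (2, 2, 2, 128)).copy(), tr=3.0)
        out = detrend_and_bandpass(series, 0.01, 0.1)
        in_power = np.sum(sig**2)
        np.testing.assert_allclose(
            np.sum(out.data[0, 0, 0] ** 2), in_power, rtol=0.05
        )

    def test_linear_ramp_removed(self):
        ramp = np.linspace(0, 10, 100)
        series = make_series(np.broadcast_to(ramp, (2, 2, 2, 100)).copy())
        out = detrend_and_bandpass(series, 0.01, 0.1)
        assert np.max(np.abs(out.data)) < 1e-10

    def test_out_of_band_sinusoid_suppressed(self):
        # 0.2 Hz at TR = 2 s (Nyquist 0.25 Hz): outside the 0.01-0.1 Hz band.
        # Oracle: compare DFT power of output to input.
        t = np.arange(120) * 2.0
        sig = np.sin(2 * np.pi * 0.2 * t)
        series = make_series(np.broadcast_to(sig, (1, 1, 1, 120)).copy(), tr=2.0)
        out = detrend_and_bandpass(series, 0.01, 0.1)
        in_power = np.abs(np.fft.rfft(sig)) ** 2
        out_power = np.abs(np.fft.rfft(out.data[0, 0, 0])) ** 2
        assert out_power.sum() < 0.01 * in_power.sum()

    def test_idempotent(self, rng):
        series = make_series(rng.normal(size=(3, 3, 3, 60)))
        once = detrend_and_bandpass(series)
        twice = detrend_and_bandpass(once)
        np.testing.assert_allclose(twice.data, once.data, rtol=1e-8, atol=1e-10)

    def test_zero_temporal_mean(self, rng):
        out = detrend_and_bandpass(make_series(rng.normal(size=(3, 3, 3, 50))))
        np.testing.assert_allclose(out.data.mean(axis=3), 0.0, atol=1e-10)

    def test_band_outside_nyquist_errors(self, rng):
        series = make_series(rng.normal(size=(2, 2, 2, 50)), tr=3.0)
        with pytest.raises(ValueError):
            detrend_and_bandpass(series, 0.01, 0.3)


class TestNuisanceRegression:
    def test_voxel_equal_to_regressor_is_annihilated(self, rng):
        reg = rng.normal(size=(50, 1))
        data = np.broadcast_to(reg[:, 0], (2, 2, 2, 50)).copy()
        out = nuisance_regress(make_series(data), reg)
        assert np.max(np.abs(out.data)) < 1e-10

    def test_zero_regressors_equal_demeaning(self, rng):
        data = rng.normal(size=(2, 2, 2, 30))
        out = nuisance_regress(make_series(data), np.zeros((30, 0)))
        np.testing.assert_allclose(out.data, data - data.mean(axis=3, keepdims=True), atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        data = rng.normal(size=(3, 2, 2, 40))
        reg = rng.normal(size=(40, 4))
        out = nuisance_regress(make_series(data), reg)
        x = np.column_stack([np.ones(40), reg])
        beta = np.linalg.inv(x.T @ x) @ x.T @ data.reshape(-1, 40).T
        expected = data.reshape(-1, 40) - (x @ beta).T
        np.testing.assert_allclose(out.data.reshape(-1, 40), expected, atol=1e-8)

    def test_residuals_orthogonal_to_regressors(self, rng):
        data = rng.normal(size=(2, 2, 2, 40))
        reg = rng.normal(size=(40, 3))
        out = nuisance_regress(make_series(data), reg)
        dots = out.data.reshape(-1, 40) @ reg
        scale = np.linalg.norm(data) * np.linalg.norm(reg)
        assert np.max(np.abs(dots)) / scale < 1e-8

    def test_collinear_regressors_error(self, rng):
        reg = rng.normal(size=(30, 2))
        reg = np.column_stack([reg, reg[:, 0] + reg[:, 1]])
        with pytest.raises(ValueError, match="collinear"):
            nuisance_regress(make_series(rng.normal(size=(2, 2, 2, 30))), reg)


class TestTissueSignal:
    def test_constant_series(self):
        series = make_series(np.full((2, 2, 2, 5), 7.0))
        mask = np.ones((2, 2, 2), dtype=bool)
        np.testing.assert_array_equal(extract_tissue_signal(series, mask), np.full(5, 7.0))

    def test_single_and_two_voxel_masks(self, rng):
        data = rng.normal(size=(2, 1, 1, 6))
        series = make_series(data)
        one = np.zeros((2, 1, 1), dtype=bool)
        one[0, 0, 0] = True
        np.testing.assert_allclose(extract_tissue_signal(series, one), data[0, 0, 0])
        both = np.ones((2, 1, 1), dtype=bool)
        np.testing.assert_allclose(
            extract_tissue_signal(series, both), (data[0, 0, 0] + data[1, 0, 0]) / 2
        )

    def test_empty_mask_errors(self, rng):
        with pytest.raises(ValueError):
            extract_tissue_signal(
                make_series(rng.normal(size=(2, 2, 2, 4))), np.zeros((2, 2, 2), bool)
            )


def test_bold_series_validation():
    with pytest.raises(ValueError):
        BoldSeries(np.zeros((2, 2, 2)), np.eye(4), 3.0)  # not 4D
    with pytest.raises(ValueError):
        BoldSeries(np.full((2, 2, 2, 3), np.nan), np.eye(4), 3.0)
    singular = np.eye(4)
    singular[0, 0] = 0.0
    with pytest.raises(ValueError):
        BoldSeries(np.zeros((2, 2, 2, 3)), singular, 3.0)
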