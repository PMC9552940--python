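"""Waveform averaging, normalization, outlier rejection, Kalman smoothing."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulseicp.acpw import (
    ACPW,
    N_POINTS,
    filter_icp_range,
    kalman_smooth,
    normalize,
    read_acpws,
    sliding_average,
    write_acpws,
    zscore_reject,
)
from pulseicp.beats import Beat
from pulseicp.synthgen import GeneratorParams, pulse_template


def _acpw(y, idx=0, icp=12.0):
    return ACPW(y, mean_icp=icp, mean_map=80.0, modality="dHbT",
                subject_id="S00", trial_id="t00", window_index=idx)


def _template66(icp=12.0):
    return normalize(pulse_template(icp, 120, GeneratorParams()))


class TestNormalize:
    def test_fixed_point_for_already_normalized_waveform(self):
        y = _template66()
        np.testing.assert_allclose(normalize(y), y, atol=1e-12)

    @pytest.mark.parametrize("n", [5, 17, 66, 200])
    def test_linear_ramp_of_any_length_maps_to_unit_ramp(self, n):
        out = normalize(np.linspace(-3.0, 9.0, n))
        np.testing.assert_allclose(out, np.linspace(0, 1, N_POINTS), atol=1e-9)

    def test_half_sine_matches_analytic_resampling(self):
        coarse = np.sin(np.pi * np.linspace(0, 1, 33))
        out = normalize(coarse)
        np.testing.assert_allclose(out, np.sin(np.pi * np.linspace(0, 1, N_POINTS)), atol=1e-3)

    def test_constant_input_degenerates_to_zeros(self):
        with pytest.warns(UserWarning):
            out = normalize(np.full(30, 2.5))
        assert not out.any()

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            normalize(np.array([1.0, 2.0, 3.0]))


def _brute_force_window_count(n, window, step):
    count = 0
    while count * step + window <= n:
        count += 1
    return count


class TestSlidingAverage:
    def test_identical_beats_average_to_the_normalized_beat(self):
        tpl = pulse_template(10.0, 120, GeneratorParams())
        beats = [Beat(tpl, start_index=25 * k) for k in range(120)]
        out = sliding_average(beats, window=120, step=20)
        assert len(out) == 1
        np.testing.assert_allclose(out[0].y, normalize(tpl), atol=1e-12)

    def test_window_count_example(self):
        tpl = pulse_template(10.0, 120, GeneratorParams())
        beats = [Beat(tpl, start_index=25 * k) for k in range(200)]
        assert len(sliding_average(beats, window=120, step=20)) == 5

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        n=st.integers(min_value=0, max_value=400),
        window=st.integers(min_value=2, max_value=150),
        step=st.integers(min_value=1, max_value=149),
    )
    def test_window_count_formula_matches_brute_force(self, n, window, step):
        if step >= window:
            return
        tpl = pulse_template(10.0, 120, GeneratorParams())
        beats = [Beat(tpl, start_index=25 * k) for k in range(n)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = len(sliding_average(beats, window=window, step=step))
        assert got == _brute_force_window_count(n, window, step)

    def test_every_acpw_is_66_samples_in_unit_range(self):
        rng = np.random.default_rng(0)
        tpl = pulse_template(10.0, 120, GeneratorParams())
        beats = [
            Beat(tpl + 0.05 * rng.standard_normal(len(tpl)), start_index=25 * k)
            for k in range(180)
        ]
        for a in sliding_average(beats):
            assert len(a.y) == N_POINTS
            assert a.y.min() == pytest.approx(0.0)
            assert a.y.max() == pytest.approx(1.0)

    def test_window_labels_are_member_means(self):
        tpl = pulse_template(10.0, 120, GeneratorParams())
        beats = [
            Beat(tpl, start_index=25 * k, mean_icp_raw=float(k), mean_map_raw=2.0 * k)
            for k in range(120)
        ]
        (a,) = sliding_average(beats)
        assert a.mean_icp == pytest.approx(np.mean(np.arange(120)))
        assert a.mean_map == pytest.approx(2 * np.mean(np.arange(120)))


class TestZscoreReject:
    def test_identical_waveforms_none_rejected(self):
        acpws = [_acpw(_template66(), i) for i in range(20)]
        kept, rejected = zscore_reject(acpws)
        assert len(kept) == 20 and not rejected

    def test_planted_shape_outliers_rejected_without_false_alarms(self, rng):
        tpl = _template66()
        inliers = []
        for i in range(100):
            y = tpl + 0.03 * rng.standard_normal(N_POINTS)
            inliers.append(_acpw((y - y.min()) / np.ptp(y), i))
        outliers = []
        for j in range(5):
            y = np.clip(tpl * 3.0, 0, 1.0)  # saturated 3x-amplitude distortion
            outliers.append(_acpw((y - y.min()) / np.ptp(y), 100 + j))
        kept, rejected = zscore_reject(inliers + outliers)
        rejected_idx = {a.window_index for a in rejected}
        assert len(rejected_idx & set(range(100, 105))) >= 5 * 0.95
        assert not rejected_idx & set(range(100))

    def test_infinite_threshold_keeps_all(self, rng):
        acpws = [_acpw(rng.random(N_POINTS), i) for i in range(10)]
        kept, rejected = zscore_reject(acpws, thresh=np.inf)
        assert len(kept) == 10 and not rejected

    def test_fewer_than_three_all_kept_with_warning(self):
        acpws = [_acpw(_template66(), i) for i in range(2)]
        with pytest.warns(UserWarning):
            kept, rejected = zscore_reject(acpws)
        assert len(kept) == 2 and not rejected


class TestKalmanSmooth:
    def test_huge_process_noise_returns_input(self, rng):
        tpl = _template66()
        acpws = []
        for i in range(10):
            y = tpl + 0.05 * rng.standard_normal(N_POINTS)
            acpws.append(_acpw((y - y.min()) / np.ptp(y), i))
        out = kalman_smooth(acpws, q=1e12, r=1e-2)
        for a, b in zip(acpws, out):
            np.testing.assert_allclose(b.y, a.y, atol=1e-9)

    def test_identical_inputs_are_fixed_point(self):
        acpws = [_acpw(_template66(), i) for i in range(8)]
        out = kalman_smooth(acpws)
        for a, b in zip(acpws, out):
            np.testing.assert_allclose(b.y, a.y, atol=1e-12)

    def test_noise_rmse_reduced_at_least_20_percent(self, rng):
        """Smoothing against the trial's ideal pulse must cut RMSE to the
        noiseless template by >=20% at noise SD 0.1."""
        tpl = _template66()
        acpws = [_acpw(tpl + 0.1 * rng.standard_normal(N_POINTS), i) for i in range(50)]
        rmse = lambda ys: np.mean([np.sqrt(np.mean((y - tpl) ** 2)) for y in ys])
        before = rmse([a.y for a in acpws])
        after = rmse([a.y for a in kalman_smooth(acpws)])
        assert after <= 0.8 * before

    def test_empty_list(self):
        assert kalman_smooth([]) == []

    def test_invalid_noise_parameters_rejected(self):
        with pytest.raises(ValueError):
            kalman_smooth([_acpw(_template66())], q=-1.0)


class TestFilterIcpRange:
    def test_identity_when_all_below_ceiling(self):
        acpws = [_acpw(_template66(), i, icp=10.0 + i) for i in range(5)]
        assert filter_icp_range(acpws) == acpws

    def test_threshold_count(self):
        acpws = [_acpw(_template66(), i, icp=v) for i, v in enumerate([10, 29, 31, 45])]
        with pytest.warns(UserWarning):
            kept = filter_icp_range(acpws, max_icp=30.0)
        assert [a.mean_icp for a in kept] == [10, 29]

    def test_zero_ceiling_empties(self):
        acpws = [_acpw(_template66(), i, icp=5.0) for i in range(3)]
        with pytest.warns(UserWarning):
            assert filter_icp_range(acpws, max_icp=0.0) == []


def test_acpw_serialization_roundtrip(tmp_path, rng):
    acpws = [_acpw(_template66(icp=5.0 + i), i, icp=5.0 + i) for i in range(4)]
    path = tmp_path / "acpws.csv"
    write_acpws(acpws, path)
    back = read_acpws(path)
    assert len(back) == 4
    for a, b in zip(acpws, back):
        np.testing.assert_allclose(b.y, a.y, atol=1e-12)
        assert (b.modality, b.subject_id, b.trial_id, b.window_index) == (
            a.modality, a.subject_id, a.trial_id, a.window_index
        )
        assert b.mean_icp == pytest.approx(a.mean_icp)


def test_acpw_wrong_length_rejected():
    with pytest.raises(ValueError):
        ACPW(np.zeros(65), 10.0, 80.0, "dHbT")
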