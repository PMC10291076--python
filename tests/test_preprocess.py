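"""Conditioning pipeline: repair, segmentation, resampling, filtering,
normalisation, windowing and time-domain features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikemyo import preprocess as pp
from spikemyo import synth


def _rec(signal, layout=None):
    layout = layout or synth.ElectrodeLayout(arrays=((3, 3, 10.0),))
    return synth.EmgRecording(signal=np.asarray(signal, dtype=float),
                              sampling_rate=1000.0, subject=0, trial=0,
                              gesture=0, repetition=0, layout=layout)


class TestRepairChannels:
    def test_clean_recording_unchanged(self, toy_grid_recording):
        out = pp.repair_channels(toy_grid_recording)
        np.testing.assert_array_equal(out.signal, toy_grid_recording.signal)

    def test_interior_outlier_replaced_by_4_neighbour_mean(self):
        sig = np.ones((9, 500)) * np.arange(1, 10)[:, None]
        sig[4] = 1e6                       # centre of the 3x3 grid
        out = pp.repair_channels(_rec(sig), max_fraction=0.15)
        # neighbours of channel 4 on the grid: 1, 3, 5, 7
        expected = sig[[1, 3, 5, 7]].mean(axis=0)
        np.testing.assert_allclose(out.signal[4], expected)
        np.testing.assert_array_equal(out.signal[:4], sig[:4])

    def test_corner_outlier_uses_its_2_neighbours(self):
        sig = np.ones((9, 500)) * np.arange(1, 10)[:, None]
        sig[0] = 1e6                       # corner (0, 0): neighbours 1 and 3
        out = pp.repair_channels(_rec(sig), max_fraction=0.15)
        np.testing.assert_allclose(out.signal[0], sig[[1, 3]].mean(axis=0))

    def test_unrepairable_when_all_neighbours_flagged(self):
        sig = np.ones((9, 500))
        for ch in (0, 1, 3):               # corner plus both its neighbours
            sig[ch] = 1e6
        with pytest.raises(ValueError, match="cannot repair|repair cap"):
            pp.repair_channels(_rec(sig), max_fraction=0.5)


class TestSegmentActive:
    def test_rectangular_burst_located_within_smoothing_window(self):
        sig = np.zeros((2, 8000))
        sig[:, 1000:6000] = 1.0
        start, end = pp.segment_active(_rec(sig))
        assert abs(start - 1000) <= 200
        assert abs(end - 6000) <= 200

    def test_all_zero_signal_raises(self):
        with pytest.raises(pp.NoActivityError):
            pp.segment_active(_rec(np.zeros((2, 5000))))

    def test_triangular_envelope_crossings_near_10_percent(self):
        n = 4001
        tri = 1.0 - np.abs(np.linspace(-1, 1, n))
        sig = np.tile(tri, (2, 1))
        start, end = pp.segment_active(_rec(sig), smooth_ms=10)
        assert abs(start - 200) <= 30
        assert abs(end - 3800) <= 30


class TestResample:
    def test_same_length_is_identity(self, rng):
        x = rng.random((3, 5000))
        np.testing.assert_array_equal(pp.resample_segment(x), x)

    def test_linear_ramp_keeps_endpoints_and_linearity(self):
        ramp = np.linspace(0.0, 1.0, 2500)[None, :]
        out = pp.resample_segment(ramp, 5000)
        assert out.shape == (1, 5000)
        assert out[0, 0] == 0.0 and out[0, -1] == 1.0
        np.testing.assert_allclose(out[0], np.linspace(0, 1, 5000), atol=1e-12)

    def test_constant_signal_stays_constant(self):
        out = pp.resample_segment(np.full((2, 123), 3.7), 5000)
        np.testing.assert_allclose(out, 3.7)

    def test_too_short_segment_raises(self):
        with pytest.raises(ValueError):
            pp.resample_segment(np.ones((1, 1)))


class TestBandpassFilter:
    def test_dc_attenuated_by_at_least_20_db(self):
        x = np.ones((1, 5000))
        y = pp.bandpass_filter(x)
        assert np.abs(y[0, 1000:]).max() <= 0.1

    def test_100hz_tone_within_3_db(self):
        t = np.arange(5000) / 1000.0
        x = np.sin(2 * np.pi * 100 * t)[None, :]
        y = pp.bandpass_filter(x)
        amp = np.abs(y[0, 1000:]).max()
        assert 10 ** (-3 / 20) <= amp <= 10 ** (3 / 20)

    def test_linearity(self, rng):
        x = rng.standard_normal((2, 1000))
        y = rng.standard_normal((2, 1000))
        lhs = pp.bandpass_filter(2.5 * x - 1.5 * y)
        rhs = 2.5 * pp.bandpass_filter(x) - 1.5 * pp.bandpass_filter(y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


class TestMinMax:
    def test_direct_example(self):
        out = pp.minmax_normalize([[2.0, 4.0, 6.0]])
        np.testing.assert_allclose(out, [[0.0, 0.5, 1.0]])

    def test_idempotent(self, rng):
        x = rng.random((4, 200))
        once = pp.minmax_normalize(x)
        np.testing.assert_allclose(pp.minmax_normalize(once), once, atol=1e-15)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           offset=st.floats(min_value=-10, max_value=10))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, scale, offset):
        rng = np.random.default_rng(0)
        x = rng.random((2, 50))
        a = pp.minmax_normalize(x)
        b = pp.minmax_normalize(scale * x + offset)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_constant_channel_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = pp.minmax_normalize(np.ones((1, 10)))
        np.testing.assert_array_equal(out, 0.0)


class TestWindows:
    def test_steady_region_yields_39_windows(self, rng):
        seg = rng.random((4, 5000))
        wins = pp.extract_windows(seg)
        assert len(wins) == 39
        assert wins[0].window.shape == (4, 100)

    def test_single_window_boundary_case(self, rng):
        wins = pp.extract_windows(rng.random((2, 100)), region=(0, 100))
        assert len(wins) == 1

    def test_offsets_enumerated(self, rng):
        seg = rng.random((1, 250))
        wins = pp.extract_windows(seg, region=(0, 250))
        assert len(wins) == 4
        for i, w in enumerate(wins):
            np.testing.assert_array_equal(w.window, seg[:, 50 * i:50 * i + 100])

    def test_region_shorter_than_window_raises(self, rng):
        with pytest.raises(ValueError):
            pp.extract_windows(rng.random((1, 60)), region=(0, 60))

    @given(region_len=st.integers(min_value=1, max_value=10_000),
           win=st.integers(min_value=1, max_value=500),
           step=st.integers(min_value=1, max_value=500))
    @settings(max_examples=100, deadline=None)
    def test_count_formula_matches_brute_force(self, region_len, win, step):
        brute = sum(1 for off in range(0, region_len + 1, step)
                    if off + win <= region_len)
        if region_len < win:
            with pytest.raises(ValueError):
                pp.window_count(region_len, win, step)
        else:
            assert pp.window_count(region_len, win, step) == brute


class TestTdFeatures:
    def _feat(self, window):
        s = pp.RealSample(window=np.asarray(window, dtype=float), labels={})
        return pp.compute_td_features(s).features

    def test_constant_window_all_zero(self):
        f = self._feat([[0.5] * 10])
        np.testing.assert_allclose(f, [[0, 0, 0, 0]], atol=1e-15)

    def test_waveform_length_direct(self):
        f = self._feat([[0.0, 1.0, 0.0, 1.0]])
        assert f[0, 2] == pytest.approx(3.0)

    def test_mav_and_zc_on_centred_square_wave(self):
        f = self._feat([[0.2, 0.8, 0.2, 0.8]])
        assert f[0, 0] == pytest.approx(0.3)      # MAV of [-.3,.3,-.3,.3]
        assert f[0, 3] == 3                       # three sign changes

    def test_feature_signs(self, rng):
        f = self._feat(rng.random((5, 100)))
        assert (f[:, :3] >= 0).all()
        assert (f[:, 3] >= 0).all()
        np.testing.assert_array_equal(f[:, 3], f[:, 3].astype(int))


def test_pipeline_samples_in_unit_interval(tiny_recordings):
    samples = pp.preprocess_recording(tiny_recordings[0])
    assert len(samples) == 39
    for s in samples[:3]:
        assert s.window.shape[1] == 100
        assert s.window.min() >= 0.0 and s.window.max() <= 1.0
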