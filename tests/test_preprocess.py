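"""Optical density, MBLL forward/inverse, DPF sensitivity, motion
correction, and band-pass filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fnirskit as fk
from fnirskit.preprocess import (
    bandpass_filter,
    correct_motion_spline,
    dpf_sensitivity,
    intensity_to_od,
    mbll_forward,
    mbll_invert,
    preprocess_subject,
)


def _rec_from_intensity(x):
    return fk.RawRecording("s", "HEALTHY", x, 5.0, np.array([150]))


class TestOpticalDensity:
    def test_baseline_intensity_gives_zero_od(self):
        x = np.full((40, 2, 750), 2.0)
        od = intensity_to_od(_rec_from_intensity(x), (0, 150))
        np.testing.assert_allclose(od.od, 0.0, atol=1e-15)

    def test_tenfold_drop_gives_od_of_one(self):
        x = np.ones((40, 2, 750))
        x[0, 0, 200] = 0.1
        od = intensity_to_od(_rec_from_intensity(x), (0, 150))
        # the baseline mean is unaffected (sample 200 is outside the window)
        assert od.od[0, 0, 200] == pytest.approx(1.0, abs=1e-12)

    def test_matches_elementwise_log_ratio_loop(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0.5, 2.0, size=(3, 2, 60))
        od = intensity_to_od(_rec_from_intensity(x[:3]), (0, 10)).od
        for ch in range(3):
            for wl in range(2):
                base = x[ch, wl, :10].mean()
                for t in range(60):
                    expected = -np.log10(x[ch, wl, t] / base)
                    assert od[ch, wl, t] == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_intensity_is_rejected_with_location(self):
        x = np.ones((40, 2, 750))
        x[2, 1, 5] = -1.0
        with pytest.raises(ValueError, match="CH3"):
            intensity_to_od(_rec_from_intensity(x), (0, 150))


class TestMBLL:
    def test_zero_concentrations_give_zero_od(self, config):
        od = mbll_forward(0.0, 0.0, config.extinction)
        np.testing.assert_allclose(od, 0.0)

    def test_forward_is_homogeneous(self, config):
        od1 = mbll_forward(1.0, -0.3, config.extinction)
        od2 = mbll_forward(2.0, -0.6, config.extinction)
        np.testing.assert_allclose(od2, 2 * od1, rtol=1e-12)

    def test_forward_matches_hand_multiplied_product(self, config):
        hbo2, hb = 1.7, -0.4
        d, dpf = 2.5, (6.0, 5.0)
        od = mbll_forward(hbo2, hb, config.extinction, d, dpf)
        for wl in range(2):
            expected = (
                config.extinction[wl, 0] * hbo2 + config.extinction[wl, 1] * hb
            ) * 1e-6 * d * dpf[wl]
            assert od[wl] == pytest.approx(expected, rel=1e-12)

    def test_invert_of_zero_od_is_zero(self, config):
        hbo2, hb = mbll_invert(np.zeros((2, 5)), config.extinction)
        np.testing.assert_allclose(hbo2, 0.0)
        np.testing.assert_allclose(hb, 0.0)

    def test_forward_then_invert_is_identity(self, config):
        od = mbll_forward(1.0, -0.3, config.extinction)
        hbo2, hb = mbll_invert(od, config.extinction)
        assert hbo2 == pytest.approx(1.0, abs=1e-10)
        assert hb == pytest.approx(-0.3, abs=1e-10)

    def test_proportional_rows_are_singular(self):
        eps = np.array([[1.0, 2.0], [2.0, 4.0]])
        with pytest.raises(ValueError):
            mbll_invert(np.zeros((2, 3)), eps)

    @settings(max_examples=30, deadline=None)
    @given(
        hbo2=st.floats(-5, 5, allow_nan=False),
        hb=st.floats(-5, 5, allow_nan=False),
    )
    def test_round_trip_property(self, hbo2, hb):
        eps = fk.EXTINCTION_760_850
        out = mbll_invert(mbll_forward(hbo2, hb, eps), eps)
        assert out[0] == pytest.approx(hbo2, abs=1e-9)
        assert out[1] == pytest.approx(hb, abs=1e-9)


@pytest.fixture(scope="module")
def od(config):
    rng = np.random.default_rng(0)
    return mbll_forward(rng.normal(size=200), 0.3 * rng.normal(size=200), config.extinction)


class TestDPFSensitivity:

    def test_identical_dpfs_give_zero_error(self, od):
        res = dpf_sensitivity(od, 6.0, 6.0)
        assert res.scaling_error == 0.0
        assert res.empirical_error == pytest.approx(0.0, abs=1e-12)

    def test_dpf_6_for_5_gives_20_percent(self, od):
        res = dpf_sensitivity(od, 6.0, 5.0)
        assert res.scaling_error == pytest.approx(0.20, abs=1e-12)
        assert res.empirical_error == pytest.approx(0.20, rel=1e-9)

    def test_dpf_5_for_4_gives_25_percent(self, od):
        assert dpf_sensitivity(od, 5.0, 4.0).scaling_error == pytest.approx(0.25, abs=1e-12)

    def test_zero_dpf_is_rejected(self, od):
        with pytest.raises(ValueError):
            dpf_sensitivity(od, 6.0, 0.0)


class TestMotionCorrection:
    fs = 5.0

    def test_smooth_sinusoid_passes_unchanged(self):
        t = np.arange(750) / self.fs
        x = np.sin(2 * np.pi * 0.05 * t)
        out, mask = correct_motion_spline(x, self.fs)
        np.testing.assert_array_equal(out, x)
        assert not mask.any()

    def test_injected_spike_is_suppressed(self):
        rng = np.random.default_rng(4)
        t = np.arange(750) / self.fs
        clean = np.sin(2 * np.pi * 0.05 * t) + 0.1 * rng.normal(size=750)
        x = clean.copy()
        x[400] += 10 * clean.std()
        out, mask = correct_motion_spline(x, self.fs)
        before = np.abs(x - clean).max()
        after = np.abs(out - clean).max()
        assert mask[400]
        assert after <= 0.2 * before

    def test_baseline_step_is_relevelled(self):
        rng = np.random.default_rng(5)
        clean = 0.1 * rng.normal(size=750)
        sd = clean.std()
        x = clean.copy()
        x[500:] += 5 * sd
        out, _ = correct_motion_spline(x, self.fs)
        assert abs(out[520:].mean() - out[:480].mean()) < 0.1 * sd

    def test_window_longer_than_series_is_rejected(self):
        with pytest.raises(ValueError):
            correct_motion_spline(np.ones(5), self.fs, window_s=10.0)


class TestBandpass:
    fs = 5.0

    def test_dc_is_rejected(self):
        out = bandpass_filter(np.ones(750), fs=self.fs)
        assert np.abs(out[50:-50]).max() < 1e-6

    def test_passband_amplitude_preserved_at_0p05_hz(self):
        t = np.arange(3000) / self.fs
        x = np.sin(2 * np.pi * 0.05 * t)
        out = bandpass_filter(x, fs=self.fs)
        amp = np.abs(out[1000:2000]).max()
        assert 0.95 <= amp <= 1.05

    def test_cardiac_band_is_stopped(self):
        t = np.arange(3000) / self.fs
        x = np.sin(2 * np.pi * 1.0 * t)
        out = bandpass_filter(x, fs=self.fs)
        assert np.abs(out[1000:2000]).max() < 0.05

    def test_filter_is_linear(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=(2, 750))
        lhs = bandpass_filter(2.0 * x + 3.0 * y, fs=self.fs)
        rhs = 2.0 * bandpass_filter(x, fs=self.fs) + 3.0 * bandpass_filter(y, fs=self.fs)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_invalid_band_is_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.ones(100), band_hz=(0.1, 0.01), fs=self.fs)


class TestFullChain:
    def test_thb_equals_hbo2_plus_hb_exactly(self, noisy_subject, layout, paradigm, config):
        rec, _ = noisy_subject
        hemo, _ = preprocess_subject(rec, layout, paradigm, config)
        np.testing.assert_allclose(hemo.thb, hemo.hbo2 + hemo.hb, atol=1e-12)

    def test_noiseless_mbll_inversion_recovers_generated_traces(self, quiet_subject, paradigm, config):
        rec, truth = quiet_subject
        od = intensity_to_od(rec, paradigm.baseline_window)
        hbo2, hb = mbll_invert(np.moveaxis(od.od, 1, 0), config.extinction, 2.5, config.dpf)
        assert np.abs(hbo2 - truth.clean_hbo2).max() < 1e-9
        assert np.abs(hb - (-0.3 * truth.clean_hbo2)).max() < 1e-9

    def test_noiseless_chain_correlates_with_evoked_trace(self, quiet_subject, layout, paradigm, config):
        rec, truth = quiet_subject
        hemo, _ = preprocess_subject(rec, layout, paradigm, config)
        task = slice(*paradigm.task_window)
        for ch in range(0, 40, 7):
            r = np.corrcoef(
                hemo.hbo2[ch, task],
                bandpass_filter(truth.clean_hbo2[ch], config.band_hz, config.filter_order, 5.0)[task],
            )[0, 1]
            assert r > 0.99
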