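import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ecgdrift as ed
from ecgdrift.adaptive_notch import (
    DC_MODE,
    POWERLINE_60HZ,
    beta,
    design_bandwidth,
    stability_limit,
    steady_state_skip,
)

FS = 500.0


def _sig(x, fs=FS):
    return ed.Signal(np.asarray(x, dtype=float), fs)


class TestLmsCancel:
    def test_zero_reference_passes_primary_through(self):
        rng = np.random.default_rng(0)
        d = _sig(rng.standard_normal(1000))
        ref = _sig(np.zeros(1000))
        res = ed.lms_cancel(d, ref, n_taps=16, step=0.01)
        np.testing.assert_array_equal(res.output.samples, d.samples)
        np.testing.assert_array_equal(res.final_weights, np.zeros(16))

    def test_step_zero_is_identity(self):
        rng = np.random.default_rng(1)
        d = _sig(rng.standard_normal(500))
        ref = _sig(np.cos(2 * np.pi * 60 * np.arange(500) / FS))
        res = ed.lms_cancel(d, ref, n_taps=8, step=0.0)
        np.testing.assert_array_equal(res.output.samples, d.samples)

    def test_matched_sinusoid_is_cancelled(self):
        # primary == reference == unit sinusoid: steady-state error < 1e-3
        t = np.arange(int(10 * FS)) / FS
        s = np.cos(2 * np.pi * 60 * t)
        res = ed.lms_cancel(_sig(s), _sig(s), n_taps=32, step=0.01)
        assert np.max(np.abs(res.output.samples[-int(FS) :])) < 1e-3

    def test_output_plus_interference_is_primary_exactly(self):
        rng = np.random.default_rng(2)
        d = _sig(rng.standard_normal(2000))
        t = np.arange(2000) / FS
        ref = _sig(0.5 * np.cos(2 * np.pi * 50 * t))
        res = ed.lms_cancel(d, ref, n_taps=64, step=0.005)
        np.testing.assert_allclose(
            res.output.samples + res.interference_estimate.samples,
            d.samples,
            rtol=0,
            atol=1e-12,
        )

    def test_unstable_step_raises_divergence_error(self):
        t = np.arange(4000) / FS
        ref = _sig(np.cos(2 * np.pi * 60 * t))  # strong reference, C=1
        rng = np.random.default_rng(3)
        d = _sig(rng.standard_normal(4000))
        limit = stability_limit(ref, 256)
        with pytest.warns(UserWarning, match="stability bound"):
            with pytest.raises(ed.DivergenceError) as exc:
                ed.lms_cancel(d, ref, n_taps=256, step=10 * limit)
        assert exc.value.index >= 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ed.InputError, match="length"):
            ed.lms_cancel(_sig(np.zeros(10) + 1), _sig(np.ones(9)), 4, 0.01)

    def test_stability_limit_matches_dc_closed_form(self):
        # constant reference C: correlation matrix is C^2 * ones -> lambda = N C^2
        ref = _sig(np.full(5000, 0.1))
        lim = stability_limit(ref, 1000)
        assert lim == pytest.approx(1.0 / (1000 * 0.01), rel=0.15)


class TestMakeReference:
    @pytest.mark.parametrize(
        "cfg,expected_first",
        [
            (ed.NotchConfig(4, 0.01, amplitude=0.1, omega=0.0), 0.1),
            (ed.NotchConfig(4, 0.01, amplitude=1.0, omega=2 * np.pi * 60), 1.0),
        ],
    )
    def test_first_sample(self, cfg, expected_first):
        ref = ed.make_reference(8, FS, cfg)
        assert ref.samples[0] == pytest.approx(expected_first)

    def test_dc_reference_is_constant(self):
        cfg = ed.NotchConfig(4, 0.01, amplitude=0.1, omega=0.0, phase=0.0)
        np.testing.assert_allclose(ed.make_reference(100, FS, cfg).samples, 0.1)

    @given(
        amp=st.floats(0.01, 10),
        freq=st.floats(0, 250),
        phase=st.floats(-np.pi, np.pi),
    )
    def test_amplitude_bound(self, amp, freq, phase):
        cfg = ed.NotchConfig(4, 0.01, amplitude=amp, omega=2 * np.pi * freq, phase=phase)
        ref = ed.make_reference(64, FS, cfg)
        assert np.max(np.abs(ref.samples)) <= amp * (1 + 1e-12)


class TestAnalytics:
    def test_transfer_zero_at_notch_frequency(self):
        assert ed.transfer_magnitude(POWERLINE_60HZ, FS, 60.0) < 1e-9

    def test_transfer_unity_when_adaptation_product_vanishes(self):
        cfg = ed.NotchConfig(2048, 0.0, amplitude=0.1, omega=2 * np.pi * 60)
        freqs = np.linspace(0, FS / 2, 201)
        np.testing.assert_allclose(ed.transfer_magnitude(cfg, FS, freqs), 1.0, atol=1e-13)

    def test_transfer_near_unity_far_from_notch(self):
        bw_hz = design_bandwidth(POWERLINE_60HZ, 1 / FS) / (2 * np.pi)
        freqs = np.linspace(0, FS / 2, 1001)
        far = np.abs(freqs - 60.0) > 5 * bw_hz
        mags = ed.transfer_magnitude(POWERLINE_60HZ, FS, freqs)
        assert np.all(np.abs(mags[far] - 1.0) < 0.05)

    @pytest.mark.parametrize(
        "n,x,expected",
        [(3, np.pi / 6, 2.0), (1, 0.7, 1.0), (5, 1e-12, 5.0)],
    )
    def test_beta_values(self, n, x, expected):
        assert beta(n, x * FS, 1 / FS) == pytest.approx(expected, rel=1e-6)

    def test_beta_limit_is_continuous_near_zero(self):
        # closed form just outside the guard matches the limit inside it
        assert beta(64, 2e-9 * FS, 1 / FS) == pytest.approx(beta(64, 1e-13 * FS, 1 / FS), rel=1e-4)

    def test_design_bandwidth_printed_parameters(self):
        assert design_bandwidth(POWERLINE_60HZ, 1 / FS) == pytest.approx(5.12)

    def test_design_bandwidth_scales_with_amplitude_squared(self):
        cfg1 = ed.NotchConfig(100, 0.01, amplitude=0.1)
        cfg2 = ed.NotchConfig(100, 0.01, amplitude=0.2)
        assert design_bandwidth(cfg2, 1 / FS) == pytest.approx(
            4 * design_bandwidth(cfg1, 1 / FS)
        )

    def test_design_bandwidth_zero_amplitude(self):
        assert design_bandwidth(ed.NotchConfig(100, 0.01, amplitude=0.0), 1 / FS) == 0.0


class TestNotchFilter:
    def test_dc_mode_removes_constant(self):
        sig = _sig(np.full(int(30 * FS), 5.0))
        res = ed.notch_filter(sig, DC_MODE)
        skip = steady_state_skip(DC_MODE, FS)
        assert np.max(np.abs(res.output.samples[skip:])) < 0.05  # < 1% of 5

    def test_60hz_mode_attenuates_pure_tone_by_20db(self):
        t = np.arange(int(30 * FS)) / FS
        sig = _sig(np.cos(2 * np.pi * 60 * t))
        res = ed.notch_filter(sig, POWERLINE_60HZ)
        skip = steady_state_skip(POWERLINE_60HZ, FS)
        out_rms = np.sqrt(np.mean(res.output.samples[skip:] ** 2))
        assert 20 * np.log10(np.sqrt(0.5) / out_rms) >= 20.0

    def test_dc_mode_preserves_clean_ecg(self, zero_wander_record):
        rec = zero_wander_record
        res = ed.notch_filter(rec.mixture, DC_MODE)
        skip = steady_state_skip(DC_MODE, FS)
        rmse = np.sqrt(np.mean((res.output.samples - rec.mixture.samples)[skip:] ** 2))
        assert rmse < 0.05 * rec.spec.r_amplitude

    def test_short_signal_warns(self):
        with pytest.warns(UserWarning, match="below the tap count"):
            ed.notch_filter(_sig(np.random.default_rng(0).standard_normal(1000)), DC_MODE)
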