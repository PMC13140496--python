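import numpy as np
import pytest

from respmech.io import SampledSignal
from respmech.preprocess import (
    EnvelopeSpec,
    FilterSpec,
    apply_filters,
    breath_emg_integral,
    design_filters,
    envelope,
)

RATE = 20000.0


@pytest.fixture(scope="module")
def bank():
    return design_filters(FilterSpec(), RATE)


def _tone(freq, amp=1.0, duration=2.0, rate=RATE):
    t = np.arange(int(duration * rate)) / rate
    return SampledSignal(amp * np.sin(2 * np.pi * freq * t), rate, "dia", "uV")


def _mid_amplitude(sig):
    n = sig.samples.size
    return np.max(np.abs(sig.samples[n // 4 : 3 * n // 4]))


class TestDesign:
    def test_default_design_is_stable_without_fallback(self, bank):
        assert not bank.notch.used_sos_fallback
        assert not bank.bandpass.used_sos_fallback

    def test_dc_gain_blocked(self, bank):
        h = bank.frequency_response([0.01])
        assert 20 * np.log10(abs(h[0])) <= -60

    def test_band_edges_at_minus_3db(self, bank):
        # oracle: direct evaluation of the designed transfer function
        h = bank.bandpass.frequency_response([30.0, 1000.0], RATE)
        db = 20 * np.log10(np.abs(h))
        assert np.all(np.abs(db - (-3.0)) < 0.5)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            design_filters(FilterSpec(band_high=12000), RATE)

    def test_ill_conditioned_spec_falls_back_to_sos(self):
        # an 8th-order prototype bandpass at 20 kHz is unstable in (b, a) form
        bank = design_filters(FilterSpec(order=8), RATE)
        assert bank.bandpass.used_sos_fallback
        h = bank.bandpass.frequency_response([300.0], RATE)
        assert abs(20 * np.log10(abs(h[0]))) < 1.0  # SOS form still correct

    def test_odd_order_rejected(self):
        with pytest.raises(ValueError, match="order"):
            FilterSpec(order=3)


class TestApply:
    def test_zero_in_zero_out(self, bank):
        sig = SampledSignal(np.zeros(5000), RATE, "dia", "uV")
        out = apply_filters(sig, bank)
        np.testing.assert_allclose(out.samples, 0.0)
        assert out.samples.size == sig.samples.size

    def test_50hz_tone_attenuated_20db(self, bank):
        out = apply_filters(_tone(50.0), bank)
        assert _mid_amplitude(out) <= 0.1  # >= 20 dB down

    def test_300hz_tone_passes_within_1db(self, bank):
        out = apply_filters(_tone(300.0), bank)
        db = 20 * np.log10(_mid_amplitude(out))
        assert abs(db) < 1.0

    def test_passband_idempotence_within_2db(self, bank):
        once = apply_filters(_tone(300.0), bank)
        twice = apply_filters(once, bank)
        ratio_db = 20 * np.log10(_mid_amplitude(twice) / _mid_amplitude(once))
        assert abs(ratio_db) < 2.0

    def test_short_signal_rejected(self, bank):
        sig = SampledSignal(np.zeros(10), RATE, "dia", "uV")
        with pytest.raises(ValueError, match="too short"):
            apply_filters(sig, bank)

    def test_rate_mismatch_rejected(self, bank):
        sig = SampledSignal(np.zeros(5000), 1000.0, "dia", "uV")
        with pytest.raises(ValueError, match="designed for"):
            apply_filters(sig, bank)


class TestEnvelope:
    def test_constant_input_gives_constant_envelope(self):
        for c in (+2.0, -2.0):  # rectification: sign-symmetric
            sig = SampledSignal(np.full(2000, c), 1000.0, "dia", "uV")
            env = envelope(sig, EnvelopeSpec(window=0.05))
            np.testing.assert_allclose(env.samples[100:-100], 2.0, rtol=1e-12)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        sig = SampledSignal(x, 1000.0, "dia", "uV")
        flipped = SampledSignal(-x, 1000.0, "dia", "uV")
        np.testing.assert_array_equal(
            envelope(sig).samples, envelope(flipped).samples
        )

    def test_square_burst_plateau(self):
        x = np.zeros(3000)
        x[1000:2000] = 3.0  # 1 s burst >> 50 ms window
        env = envelope(SampledSignal(x, 1000.0, "dia", "uV"))
        plateau = env.samples[1200:1800]
        np.testing.assert_allclose(plateau, 3.0, rtol=0.01)

    def test_subsample_window_rejected(self):
        sig = SampledSignal(np.zeros(100), 10.0, "dia", "uV")
        with pytest.raises(ValueError, match="window"):
            envelope(sig, EnvelopeSpec(window=0.01))


class TestBreathIntegral:
    def test_rectangle(self):
        sig = SampledSignal(np.full(10000, 2.0), 10000.0, "dia", "uV")
        assert breath_emg_integral(sig, 0.1, 0.2) == pytest.approx(0.2, rel=1e-3)

    def test_zero_signal(self):
        sig = SampledSignal(np.zeros(10000), 10000.0, "dia", "uV")
        assert breath_emg_integral(sig, 0.1, 0.2) == 0.0

    def test_half_sine_closed_form(self):
        # integral of |A sin(pi t / d)| over one burst = (2/pi) A d
        rate, a, d = 20000.0, 5.0, 0.1
        t = np.arange(int(0.3 * rate)) / rate
        x = np.where((t >= 0.1) & (t < 0.2), a * np.sin(np.pi * (t - 0.1) / d), 0.0)
        sig = SampledSignal(x, rate, "dia", "uV")
        expected = (2 / np.pi) * a * d
        assert breath_emg_integral(sig, 0.1, 0.2) == pytest.approx(expected, rel=0.005)

    def test_homogeneity_under_amplitude_scaling(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(4000)
        sig = SampledSignal(x, 2000.0, "dia", "uV")
        half = SampledSignal(0.5 * x, 2000.0, "dia", "uV")
        assert breath_emg_integral(half, 0.2, 1.8) == pytest.approx(
            0.5 * breath_emg_integral(sig, 0.2, 1.8), rel=1e-12
        )

    def test_empty_interval_rejected(self):
        sig = SampledSignal(np.zeros(1000), 1000.0, "dia", "uV")
        with pytest.raises(ValueError, match="empty"):
            breath_emg_integral(sig, 0.5, 0.5)
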