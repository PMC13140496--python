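import numpy as np
import pytest

from respmech.entropy import (
    EntropyParams,
    approximate_entropy,
    clean_for_entropy,
    entropy_summary,
    sample_entropy,
    sample_entropy_counts,
    shannon_entropy,
)
from respmech.io import SampledSignal

from .oracles import apen_bruteforce, sampen_bruteforce, sampen_counts_bruteforce


class TestClean:
    def test_nonfinite_removed(self):
        x = np.ones(300)
        x[[5, 50, 100, 150, 200]] = np.nan
        sig = SampledSignal(x, 1000.0, "dia", "uV")
        assert clean_for_entropy(sig).samples.size == 295

    def test_linear_ramp_detrended_to_zero(self):
        sig = SampledSignal(np.linspace(0, 10, 500), 1000.0, "dia", "uV")
        out = clean_for_entropy(sig).samples
        assert abs(np.mean(out)) < 1e-9
        slope = np.polyfit(np.arange(500), out, 1)[0]
        assert abs(slope) < 1e-12

    def test_trendless_data_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000)
        x -= np.polyval(np.polyfit(np.arange(1000), x, 1), np.arange(1000))
        out = clean_for_entropy(SampledSignal(x, 1000.0, "dia", "uV")).samples
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_all_nonfinite_rejected(self):
        sig = SampledSignal(np.full(100, np.nan), 1000.0, "dia", "uV")
        with pytest.raises(ValueError, match="non-finite"):
            clean_for_entropy(sig)


class TestShannon:
    def test_constant_signal_is_zero_bits(self):
        assert shannon_entropy(np.full(100, 3.7)) == 0.0

    def test_two_equiprobable_levels_one_bit(self):
        x = np.tile([0.000, 0.001], 50)
        assert shannon_entropy(x) == pytest.approx(1.0, abs=1e-12)

    def test_four_levels_two_bits(self):
        x = np.tile([0.000, 0.001, 0.002, 0.003], 50)
        assert shannon_entropy(x) == pytest.approx(2.0, abs=1e-12)

    def test_discretisation_collapses_fine_structure(self):
        # values differing only at the 4th decimal are one symbol
        x = np.tile([0.1001, 0.1004], 100)
        assert shannon_entropy(x, precision=3) == 0.0


class TestRegularityOracles:
    """Vectorised ApEn/SampEn must equal naive O(N^2) double loops."""

    def test_periodic_sequence_apen_matches_bruteforce(self):
        x = np.tile([1.0, 2.0, 3.0], 100)
        r = 0.25 * np.std(x, ddof=1)
        assert approximate_entropy(x, 2, r) == pytest.approx(
            apen_bruteforce(x, 2, r), abs=1e-9
        )

    def test_alternating_sequence_sampen_near_zero(self):
        x = np.tile([1.0, 2.0], 150)
        r = 0.25 * np.std(x, ddof=1)
        val = sample_entropy(x, 2, r)
        assert val == pytest.approx(sampen_bruteforce(x, 2, r), abs=1e-9)
        assert val <= 0.02

    def test_white_noise_matches_bruteforce(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(500)
        r = 0.25 * np.std(x, ddof=1)
        apen = approximate_entropy(x, 2, r)
        assert apen == pytest.approx(apen_bruteforce(x, 2, r), abs=1e-9)
        # noise is less regular than a periodic sequence
        x_per = np.tile([1.0, 2.0, 3.0], 167)[:500]
        r_per = 0.25 * np.std(x_per, ddof=1)
        assert apen > approximate_entropy(x_per, 2, r_per)

    def test_sampen_counts_match_bruteforce(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(300)
        r = 0.25 * np.std(x, ddof=1)
        assert sample_entropy_counts(x, 2, r) == sampen_counts_bruteforce(x, 2, r)


class TestProperties:
    def test_affine_invariance(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(400)
        y = 3.0 * x + 7.0
        assert approximate_entropy(x) == pytest.approx(approximate_entropy(y), abs=1e-9)
        assert sample_entropy(x) == pytest.approx(sample_entropy(y), abs=1e-9)

    def test_a_le_b_and_sampen_nonnegative(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            x = rng.standard_normal(300)
            a, b = sample_entropy_counts(x)
            assert a <= b
            assert -np.log(a / b) >= 0


class TestSummaryGating:
    def test_constant_signal_degenerate(self):
        sig = SampledSignal(np.full(300, 2.0), 1000.0, "dia", "uV")
        s = entropy_summary(sig, EntropyParams(decimate_to_hz=None))
        assert s.apen == 0.0 and s.sampen == 0.0
        assert s.degenerate
        assert s.shannon == 0.0

    def test_short_signal_flagged_invalid_not_raised(self):
        sig = SampledSignal(np.random.default_rng(0).standard_normal(100), 1000.0, "dia", "uV")
        s = entropy_summary(sig, EntropyParams(decimate_to_hz=None))
        assert s.valid_flags["shannon"]
        assert not s.valid_flags["apen"] and not s.valid_flags["sampen"]
        assert np.isnan(s.apen) and np.isnan(s.sampen)

    def test_below_shannon_minimum(self):
        sig = SampledSignal(np.arange(30, dtype=float), 1000.0, "dia", "uV")
        s = entropy_summary(sig, EntropyParams(decimate_to_hz=None))
        assert not s.valid_flags["shannon"]
        assert np.isnan(s.shannon)

    def test_summary_counts_recorded(self):
        rng = np.random.default_rng(3)
        sig = SampledSignal(rng.standard_normal(300), 1000.0, "dia", "uV")
        s = entropy_summary(sig, EntropyParams(decimate_to_hz=None))
        assert s.A > 0 and s.B >= s.A
        assert s.sampen == pytest.approx(-np.log(s.A / s.B))
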