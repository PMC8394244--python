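import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegad.features import (
    BiomarkerTable,
    amplitude_change_rate,
    approximate_entropy,
    band_power,
    extract_all,
    extract_record,
    higuchi_fd,
    higuchi_curve_length_mean,
    lempel_ziv_complexity,
    lempel_ziv_phrase_count,
    msc_coherence,
    ratio_feature,
    tsallis_entropy,
    zero_crossing_interval,
)
from eegad.io import EegRecord
from eegad.montage import MONTAGE_19, feature_count


# ---------------------------------------------------------------- oracles

def lz_exhaustive_history_oracle(s: str) -> int:
    """Brute-force LZ76 parser: build the exhaustive history phrase by
    phrase, closing a phrase as soon as the current word stops occurring
    in the data seen before its last symbol."""
    n = len(s)
    phrases = 0
    start = 0
    while start < n:
        end = start + 1
        # smallest end with s[start:end] not reproducible from s[:end-1];
        # the final phrase counts even if it stays reproducible
        while end <= n and s[start:end] in s[:end - 1]:
            end += 1
        start = min(end, n)
        phrases += 1
    return phrases


def apen_naive(x, m, r):
    """Quadratic double-loop ApEn with self-matches, Chebyshev distance."""
    x = np.asarray(x, dtype=float)
    n = len(x)

    def phi(mm):
        templates = np.array([x[i:i + mm] for i in range(n - mm + 1)])
        total = 0.0
        for i in range(len(templates)):
            cnt = 0
            for j in range(len(templates)):
                if np.max(np.abs(templates[i] - templates[j])) <= r:
                    cnt += 1
            total += np.log(cnt / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


# ------------------------------------------------------------- Tsallis

class TestTsallisEntropy:
    def test_constant_signal_is_zero(self):
        assert tsallis_entropy(np.full(100, 3.3), 2200, 0.5) == 0.0

    def test_two_equal_bins_closed_form(self):
        # half the mass in each of two occupied bins:
        # (1 - 2 * 0.5**q) / (q - 1)
        x = np.tile([0.0, 1.0], 50)
        q = 0.5
        expected = (1 - 2 * 0.5**q) / (q - 1)
        assert tsallis_entropy(x, k_states=2, q=q) == pytest.approx(expected)
        assert expected == pytest.approx(0.8284, abs=1e-4)

    def test_q_of_one_rejected(self):
        with pytest.raises(ValueError):
            tsallis_entropy(np.arange(10.0), 10, 1.0)

    def test_uniform_distribution_maximises(self):
        rng = np.random.default_rng(0)
        uniform = rng.uniform(size=5000)
        peaked = rng.normal(scale=0.05, size=5000)
        k, q = 50, 0.5
        assert tsallis_entropy(uniform, k, q) > tsallis_entropy(peaked, k, q)

    @given(st.floats(0.1, 0.9).filter(lambda q: abs(q - 1) > 1e-3))
    @settings(deadline=None, max_examples=25)
    def test_nonnegative_for_q_below_one(self, q):
        rng = np.random.default_rng(42)
        x = rng.normal(size=500)
        assert tsallis_entropy(x, 100, q) >= 0


# ------------------------------------------------------------- Higuchi

class TestHiguchiFd:
    def test_smooth_ramp_dimension_one(self):
        x = np.linspace(0, 1, 1000)
        assert higuchi_fd(x, 8) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_dimension_two(self):
        x = np.random.default_rng(1).normal(size=4096)
        assert higuchi_fd(x, 8) == pytest.approx(2.0, abs=0.15)

    def test_constant_signal_returns_one(self):
        assert higuchi_fd(np.zeros(100), 8) == 1.0

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            higuchi_fd(np.arange(10.0), 8)

    def test_dimension_ordering_smooth_below_rough(self):
        rng = np.random.default_rng(2)
        rough = rng.normal(size=2048)
        smooth = np.cumsum(rough)  # integrated noise is smoother
        assert higuchi_fd(smooth, 8) < higuchi_fd(rough, 8)

    def test_curve_length_variant_differs_from_slope(self):
        x = np.random.default_rng(3).normal(size=1024)
        assert higuchi_curve_length_mean(x) != pytest.approx(higuchi_fd(x))


# ------------------------------------------------------------- Lempel-Ziv

class TestLempelZiv:
    def test_constant_sequence(self):
        # one symbol: phrases "0", "000..." -> c=2, C = 2/(16/4) = 0.5
        x = np.full(16, 5.0)
        assert lempel_ziv_complexity(x) == pytest.approx(0.5)

    def test_known_parse_0100(self):
        assert lempel_ziv_phrase_count("0100") == 3

    def test_matches_exhaustive_oracle_all_short_strings(self):
        for n in range(1, 13):
            for bits in itertools.product("01", repeat=n):
                s = "".join(bits)
                assert lempel_ziv_phrase_count(s) == \
                    lz_exhaustive_history_oracle(s), s

    def test_random_sequence_complexity_near_one(self):
        # balanced +-1 so the median binarisation splits the two levels
        rng = np.random.default_rng(4)
        x = np.repeat([-1.0, 1.0], 5_000)
        rng.shuffle(x)
        assert 0.9 <= lempel_ziv_complexity(x) <= 1.2

    def test_scale_and_offset_invariant(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=400)
        assert lempel_ziv_complexity(x) == lempel_ziv_complexity(3 * x + 10)


# ------------------------------------------------------------- ApEn

class TestApproximateEntropy:
    def test_constant_sequence_zero(self):
        assert approximate_entropy(np.full(50, 2.0), 2, 0.1) == 0.0

    def test_alternating_sequence_near_zero(self):
        x = np.tile([0.0, 1.0], 50)
        v = approximate_entropy(x, 2, 0.1)
        assert abs(v) < 0.02

    def test_agrees_with_naive_oracle_on_noise(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=500)
        r = 0.15 * x.std()
        assert approximate_entropy(x, 2, r) == pytest.approx(
            apen_naive(x, 2, r), abs=1e-9)

    def test_agrees_with_naive_oracle_many_short_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            x = rng.normal(size=n)
            m = int(rng.integers(1, 3))
            r = float(rng.uniform(0.1, 0.5)) * x.std()
            assert approximate_entropy(x, m, r) == pytest.approx(
                apen_naive(x, m, r), abs=1e-9)

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            approximate_entropy(np.arange(30.0), 2, -0.1)

    def test_scale_invariant_with_relative_tolerance(self):
        x = np.random.default_rng(8).normal(size=300)
        assert approximate_entropy(x) == pytest.approx(
            approximate_entropy(5.0 * x), abs=1e-9)


# ------------------------------------------------------------- ZCI

class TestZeroCrossingInterval:
    @pytest.mark.parametrize("freq,expected", [(10, 0.1), (5, 0.2)])
    def test_sinusoid_period(self, freq, expected):
        fs = 128.0
        t = np.arange(int(2 * fs)) / fs
        x = np.sin(2 * np.pi * freq * t + 0.1)
        assert zero_crossing_interval(x, fs) == pytest.approx(
            expected, abs=1 / fs)

    def test_strictly_positive_signal_undefined(self):
        assert np.isnan(zero_crossing_interval(np.ones(100) + 0.1, 128))

    def test_direct_scan_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=1000)
        fs = 128.0
        times = [t for t in range(len(x) - 1) if x[t] > 0 and x[t + 1] < 0]
        expected = np.mean(np.diff(times)) / fs
        assert zero_crossing_interval(x, fs) == pytest.approx(expected)

    def test_exact_zeros_do_not_open_crossings(self):
        # zero samples: x>0 then x=0 then x<0 is NOT a (t, t+1) crossing
        x = np.array([1.0, 0.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        times = [t for t in range(len(x) - 1) if x[t] > 0 and x[t + 1] < 0]
        assert times == [3, 5]
        assert zero_crossing_interval(x, 1.0) == pytest.approx(2.0)


# ------------------------------------------------------------- amplitude rate

class TestAmplitudeChangeRate:
    def test_constant_signal_zero(self):
        assert amplitude_change_rate(np.full(256, 4.2), 128) == 0.0

    def test_ramp_slope_recovered(self):
        fs = 128
        x = 0.5 * np.arange(4 * fs, dtype=float)  # 0.5 uV per sample
        assert amplitude_change_rate(x, fs) == pytest.approx(0.5 * fs)

    def test_whole_cycle_sinusoid_cancels(self):
        fs = 128
        t = np.arange(4 * fs) / fs
        x = 40 * np.sin(2 * np.pi * 8 * t)
        assert abs(amplitude_change_rate(x, fs)) < 1e-6 * 40 * fs

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            amplitude_change_rate(np.arange(100.0), 128)


# ------------------------------------------------------------- band power

class TestBandPower:
    def test_zero_signal(self):
        assert band_power(np.zeros(1024), 128, "alpha") == 0.0

    def test_sinusoid_energy_concentrated_in_alpha(self):
        fs, n = 128, 1024
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 10 * t)
        spec = np.abs(np.fft.rfft(x)) ** 2 / n
        freqs = np.fft.rfftfreq(n, 1 / fs)
        total = spec[freqs > 0].sum()
        alpha = spec[(freqs >= 8) & (freqs < 12)].sum()
        assert alpha / total >= 0.99  # Parseval oracle
        assert band_power(x, fs, "alpha") > 100 * band_power(x, fs, "beta")

    def test_white_noise_flat_spectrum(self):
        rng = np.random.default_rng(10)
        ratios = [band_power(x, 128, "alpha") / band_power(x, 128, "theta")
                  for x in rng.normal(size=(50, 2048))]
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.2)

    def test_empty_band_rejected(self):
        from eegad.montage import BandDef
        with pytest.raises(ValueError):
            band_power(np.ones(64), 64, BandDef("x", 30.2, 30.8))


# ------------------------------------------------------------- coherence

class TestCoherence:
    def test_self_coherence_is_one(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=128 * 10)
        for band in ["delta", "theta", "alpha", "beta", "gamma"]:
            assert msc_coherence(x, x, 128, band) == pytest.approx(
                1.0, abs=1e-10)

    def test_independent_noise_low_coherence(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=128 * 180)
        b = rng.normal(size=128 * 180)
        assert msc_coherence(a, b, 128, "alpha") < 0.2

    def test_nearly_identical_signals_high_coherence(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=128 * 60)
        b = a + 0.01 * rng.normal(size=a.size)
        assert msc_coherence(a, b, 128, "alpha") > 0.95

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(14)
        a = rng.normal(size=128 * 8)
        b = 0.5 * a + rng.normal(size=a.size)
        for band in ["delta", "alpha", "gamma"]:
            v = msc_coherence(a, b, 128, band)
            assert 0.0 <= v <= 1.0

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            msc_coherence(np.ones(100), np.ones(100), 128, "alpha")


# ------------------------------------------------------------- ratios / table

class TestRatioFeature:
    def test_equal_values_unity(self):
        assert ratio_feature(3.3, 3.3) == 1.0

    def test_ordered_ratios_are_reciprocal(self):
        assert ratio_feature(2.0, 4.0) == 0.5
        assert ratio_feature(4.0, 2.0) == 2.0

    @pytest.mark.parametrize("num,den", [(1.0, 0.0), (np.nan, 1.0),
                                         (1.0, np.inf)])
    def test_degenerate_inputs_excluded(self, num, den):
        assert np.isnan(ratio_feature(num, den))


class TestExtractAll:
    def test_full_montage_column_count(self):
        rng = np.random.default_rng(15)
        recs = [EegRecord(f"s{i}", g, 128.0, list(MONTAGE_19),
                          10 * rng.normal(size=(19, 128 * 5)))
                for i, g in enumerate(["AD", "NOLD"])]
        table = extract_all(recs)
        assert table.values.shape == (2, 7600)
        assert feature_count(19) == 7600
        assert feature_count(2) == 375

    def test_two_channel_column_count(self):
        rng = np.random.default_rng(16)
        recs = [EegRecord("s0", "AD", 128.0, ["C3", "C4"],
                          10 * rng.normal(size=(2, 128 * 5)))]
        table = extract_all(recs)
        assert table.values.shape[1] == 7 * 25 * 2 + 25

    def test_empty_input_gives_empty_table(self):
        table = extract_all([])
        assert table.values.empty

    def test_mixed_montages_rejected(self):
        rng = np.random.default_rng(17)
        recs = [EegRecord("a", "AD", 128.0, ["C3"],
                          rng.normal(size=(1, 640))),
                EegRecord("b", "NOLD", 128.0, ["C4"],
                          rng.normal(size=(1, 640)))]
        with pytest.raises(ValueError, match="share"):
            extract_all(recs)

    def test_offset_invariance_where_expected(self):
        # TsEn, LZC, HFD, ApEn are invariant to amplitude offset; the
        # zero-crossing interval is not (documented behaviour)
        rng = np.random.default_rng(18)
        rec = EegRecord("s0", "AD", 128.0, ["C3"],
                        rng.normal(size=(1, 128 * 5)))
        shifted = EegRecord("s0", "AD", 128.0, ["C3"], rec.data + 50.0)
        a = extract_record(rec)
        b = extract_record(shifted)
        for method in ["TSEN", "LZC", "HFD", "APEN"]:
            col = f"{method}_alpha_C3"
            assert a[col] == pytest.approx(b[col], rel=1e-6), method

    def test_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(19)
        recs = [EegRecord(f"s{i}", g, 128.0, ["C3", "C4"],
                          10 * rng.normal(size=(2, 128 * 5)))
                for i, g in enumerate(["AD", "NOLD", "AD"])]
        table = extract_all(recs)
        path = tmp_path / "biomarkers.csv"
        table.to_csv(path)
        back = BiomarkerTable.from_csv(path)
        assert list(back.groups) == ["AD", "NOLD", "AD"]
        np.testing.assert_allclose(back.values.to_numpy(),
                                   table.values.to_numpy(), rtol=1e-9)
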