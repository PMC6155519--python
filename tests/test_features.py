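"""Feature formulas against identities and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hrvseizure as hs
from hrvseizure.features import (FEATURE_NAMES, band_powers, cosen,
                                 extract_features, gstft, katz_fd,
                                 make_windows, sampen, time_domain,
                                 znormalize)
from hrvseizure.records import RRSeries
from hrvseizure.rrcorrect import resample_rr

rr_windows = st.lists(st.floats(min_value=400, max_value=1500), min_size=20,
                      max_size=60).map(np.asarray)


# ---------------------------------------------------------------- oracles
def sampen_oracle(x, m, r):
    """O(n^2) double-loop template counting."""
    n = len(x)
    nt = n - m

    def matches(mm):
        c = 0
        for i in range(nt):
            for j in range(i + 1, nt):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
        return c

    b, a = matches(m), matches(m + 1)
    return float("nan") if (a == 0 or b == 0) else -math.log(a / b)


def katz_oracle(x):
    L = sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))
    d = max(abs(v - x[0]) for v in x)
    n = len(x) - 1
    return math.log10(n) / (math.log10(n) + math.log10(d / L))


# ------------------------------------------------------------------ tests
class TestWindows:
    @pytest.mark.parametrize("n,expected_starts", [
        (420, [0, 120, 240]),
        (180, [0]),
        (179, []),
        (300, [0, 120]),
    ])
    def test_window_starts(self, n, expected_starts):
        rr = RRSeries(np.full(n, 800.0))
        if n >= 180:
            ws = make_windows(rr)
        else:
            with pytest.warns(UserWarning):
                ws = make_windows(rr)
        assert [w.start_beat_index for w in ws] == expected_starts
        for w in ws:
            assert w.rr_ms.size == 180

    def test_window_count_formula(self):
        for n in (180, 299, 300, 419, 420, 1000):
            rr = RRSeries(np.full(n, 800.0))
            assert len(make_windows(rr)) == (n - 180) // 120 + 1

    def test_spans_match_beat_times(self):
        rr = RRSeries(np.full(300, 1000.0))
        ws = make_windows(rr)
        assert ws[0].time_span_s == (0.0, 180.0)
        assert ws[1].time_span_s == (120.0, 300.0)


class TestZNormalize:
    @given(rr_windows)
    @settings(max_examples=25, deadline=None)
    def test_output_has_zero_mean_unit_sd(self, x):
        z, flag = znormalize(x)
        if not flag:
            assert abs(z.mean()) < 1e-9
            assert abs(z.std() - 1) < 1e-9

    @given(rr_windows, st.floats(-100, 100), st.floats(0.5, 3))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, x, b, a):
        z1, f1 = znormalize(x)
        z2, f2 = znormalize(a * x + b)
        if not (f1 or f2):
            assert np.allclose(z1, z2, atol=1e-6)

    def test_constant_series_flagged(self):
        z, flag = znormalize(np.full(10, 800.0))
        assert flag and np.all(z == 0)


class TestTimeDomain:
    def test_constant_window(self):
        td = time_domain(np.full(180, 800.0))
        assert td["meanNN"] == 800.0
        assert td["SDNN"] == td["RMSSD"] == td["NN50"] == td["pNN50"] == 0

    def test_alternating_80ms_gives_full_pnn50(self):
        td = time_domain(np.tile([780.0, 860.0], 90))
        assert td["pNN50"] == 100.0

    def test_poincare_identities(self):
        rng = np.random.default_rng(0)
        x = 800 + 30 * rng.standard_normal(180)
        td = time_domain(x)
        assert td["VAR"] == pytest.approx(td["SDNN"] ** 2)
        assert td["SD1"] == pytest.approx(td["RMSSD"] / math.sqrt(2))
        assert td["SD1"] ** 2 + td["SD2"] ** 2 == pytest.approx(
            2 * td["SDNN"] ** 2)
        assert td["CSI"] == pytest.approx(td["SD2"] / td["SD1"])
        assert td["CSV"] == pytest.approx(math.log10(td["SD1"] * td["SD2"]))

    def test_equal_axes_give_unit_csi(self):
        # alternate so that RMSSD-derived SD1 equals SD2
        x = np.array([800.0, 850, 800, 850, 800, 850, 800, 850])
        td = time_domain(x)
        sd1, sd2 = td["SD1"], td["SD2"]
        if abs(sd1 - sd2) < 1e-9:
            assert td["CSI"] == pytest.approx(1.0)

    @given(rr_windows, st.floats(-50, 50))
    @settings(max_examples=25, deadline=None)
    def test_pnn50_shift_invariance(self, x, c):
        assert time_domain(x)["pNN50"] == pytest.approx(
            time_domain(x + c)["pNN50"])


class TestEntropy:
    def test_sampen_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        x = 800 + 40 * rng.standard_normal(100)
        r = 0.2 * x.std()
        assert sampen(x, m=1, r=r) == pytest.approx(
            sampen_oracle(list(x), 1, r), abs=1e-12)
        assert sampen(x, m=2, r=r) == pytest.approx(
            sampen_oracle(list(x), 2, r), abs=1e-12)

    def test_cosen_identity(self):
        rng = np.random.default_rng(2)
        x = 800 + 25 * rng.standard_normal(80)
        r = max(0.03 * x.std(), 3.0)
        assert cosen(x) == pytest.approx(
            sampen(x, 1, r) + math.log(2 * r) - math.log(x.mean()))

    def test_periodic_below_shuffled(self):
        rng = np.random.default_rng(3)
        periodic = np.tile([760.0, 840.0], 60)
        shuffled = rng.permutation(periodic)
        assert cosen(periodic) < cosen(shuffled)


class TestKatz:
    def test_monotone_series_gives_one(self):
        assert katz_fd(np.linspace(700, 900, 50)) == 1.0

    def test_constant_series_gives_one(self):
        assert katz_fd(np.full(30, 800.0)) == 1.0

    def test_random_walk_matches_formula(self):
        rng = np.random.default_rng(4)
        x = np.cumsum(rng.standard_normal(120))
        assert katz_fd(x) == pytest.approx(katz_oracle(list(x)), abs=1e-12)


class TestGSTFT:
    def test_pure_lf_tone_ridge_at_modulation_frequency(self):
        rate = 4.0
        t = np.arange(int(400 * rate)) / rate
        u = hs.UniformRRSeries(800 + 40 * np.sin(2 * np.pi * 0.1 * t))
        tf = gstft(u)
        core = (tf.times > 60) & (tf.times < t[-1] - 60)
        mean_p = tf.power[:, core].mean(axis=1)
        assert tf.freqs[np.argmax(mean_p)] == pytest.approx(0.1, abs=0.005)

    def test_zero_series_gives_zero_map(self):
        u = hs.UniformRRSeries(np.zeros(2000))
        tf = gstft(u)
        assert np.allclose(tf.power, 0.0)

    def test_white_noise_roughly_flat_across_bands(self):
        rng = np.random.default_rng(5)
        u = hs.UniformRRSeries(800 + 10 * rng.standard_normal(40000))
        tf = gstft(u)
        bp = band_powers(tf, (300.0, 9500.0))
        assert 0.5 <= bp["LF_HF"] * (0.25 / 0.11) <= 2.0  # bandwidth-scaled

    def test_short_series_rejected(self):
        u = hs.UniformRRSeries(np.zeros(40))
        with pytest.raises(ValueError):
            gstft(u)


class TestBandPowers:
    @pytest.mark.parametrize("freq,key", [(0.06, "LFn"), (0.1, "LFn"),
                                          (0.12, "LFn"), (0.2, "HFn"),
                                          (0.25, "HFn"), (0.32, "HFn")])
    def test_pure_modulation_lands_in_its_band(self, freq, key):
        rate = 4.0
        t = np.arange(int(500 * rate)) / rate
        u = hs.UniformRRSeries(800 + 40 * np.sin(2 * np.pi * freq * t))
        tf = gstft(u)
        bp = band_powers(tf, (80.0, t[-1] - 80.0))
        assert bp[key] > 0.9
        assert bp["LFn"] + bp["HFn"] == pytest.approx(1.0)

    def test_equal_amplitude_tones_give_moderate_ratio(self):
        rate = 4.0
        t = np.arange(int(600 * rate)) / rate
        x = 800 + 40 * np.sin(2 * np.pi * 0.1 * t) \
            + 40 * np.sin(2 * np.pi * 0.25 * t)
        u = hs.UniformRRSeries(x)
        bp = band_powers(gstft(u), (80.0, t[-1] - 80.0))
        assert 0.5 <= bp["LF_HF"] <= 2.0


class TestExtractFeatures:
    def test_matrix_shape_and_column_order(self, clean_rr):
        rr, _, _ = clean_rr
        mat = extract_features(RRSeries(rr[:420]))
        assert mat.shape[0] == 3
        assert list(mat.columns[2:22]) == list(FEATURE_NAMES)

    def test_repeat_runs_are_identical(self, clean_rr):
        rr, _, _ = clean_rr
        a = extract_features(RRSeries(rr[:420]))
        b = extract_features(RRSeries(rr[:420]))
        assert a.equals(b)

    def test_degenerate_window_flagged_invalid(self):
        rr = np.concatenate([np.full(180, 800.0),
                             800 + 30 * np.random.default_rng(0)
                             .standard_normal(240)])
        mat = extract_features(RRSeries(rr))
        assert not mat.iloc[0]["valid"]  # constant window: CSI undefined
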