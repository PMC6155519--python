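"""Recurrence analysis against an independent brute-force oracle.

The oracle re-derives every count with plain Python double loops and its
own run-length scan, sharing no code with the implementation.
"""

import numpy as np
import pytest

from hrvseizure.rqa import (EpsilonRule, embed, line_histograms,
                            recurrence_matrix, rqa_features, rqa_measures)


# ---------------------------------------------------------------- oracle
def oracle_runs(bits):
    """Maximal run lengths of 1s, by explicit scan."""
    runs, cur = [], 0
    for b in bits:
        if b:
            cur += 1
        elif cur:
            runs.append(cur)
            cur = 0
    if cur:
        runs.append(cur)
    return runs


def oracle_rqa(R):
    """All six measures from first principles on a binary matrix."""
    n = len(R)
    total = sum(int(R[i][j]) for i in range(n) for j in range(n))
    loi = sum(int(R[i][i]) for i in range(n))
    off = total - loi

    diag_runs = []
    for k in range(-(n - 1), n):
        if k == 0:
            continue
        line = [R[i][i + k] for i in range(max(0, -k), min(n, n - k))]
        diag_runs.extend(oracle_runs(line))
    vert_runs = []
    for j in range(n):
        vert_runs.extend(oracle_runs([R[i][j] for i in range(n)]))

    rec = 100.0 * total / n ** 2
    dpts = sum(r for r in diag_runs if r >= 2)
    det = 100.0 * dpts / off if off else 0.0
    lmax = max(diag_runs) if diag_runs else 0
    vpts = sum(r for r in vert_runs if r >= 2)
    lam = 100.0 * vpts / total if total else 0.0
    vlines = sum(1 for r in vert_runs if r >= 2)
    tt = vpts / vlines if vlines else float("nan")
    dlines = [r for r in diag_runs if r >= 2]
    if dlines:
        counts = {}
        for r in dlines:
            counts[r] = counts.get(r, 0) + 1
        tot = sum(counts.values())
        ent = -sum((c / tot) * np.log(c / tot) for c in counts.values())
    else:
        ent = float("nan")
    return {"REC": rec, "DET": det, "LMAX": float(lmax), "LAM": lam,
            "TT": tt, "ENT": ent}


def assert_measures_equal(got, want):
    for k in ("REC", "DET", "LMAX", "LAM", "TT", "ENT"):
        if np.isnan(want[k]):
            assert np.isnan(got[k]), k
        else:
            assert got[k] == pytest.approx(want[k], abs=1e-12), k


# ----------------------------------------------------------------- tests
class TestEmbed:
    def test_dimension_one_returns_series(self):
        s = np.arange(20.0)
        tr = embed(s, m=1, tau=1)
        assert np.array_equal(tr.states[:, 0], s)

    def test_state_count_arithmetic(self):
        tr = embed(np.zeros(180), m=3, tau=1)
        assert tr.N == 178

    def test_delay_two_states(self):
        tr = embed(np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13]),
                   m=2, tau=2)
        assert np.array_equal(tr.states[0], [1, 3])
        assert np.array_equal(tr.states[3], [4, 6])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            embed(np.zeros(10), m=3, tau=4)


class TestRecurrenceMatrix:
    def test_constant_states_give_all_ones(self):
        tr = embed(np.full(20, 5.0), m=2, tau=1)
        rm = recurrence_matrix(tr, rule=1.0)
        assert rm.R.all()

    def test_tiny_epsilon_gives_identity(self):
        rng = np.random.default_rng(0)
        tr = embed(rng.standard_normal(30), m=2, tau=1)
        rm = recurrence_matrix(tr, rule=1e-12)
        assert np.array_equal(rm.R, np.eye(tr.N, dtype=bool))

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        tr = embed(rng.standard_normal(52), m=3, tau=1)
        eps = 0.8
        rm = recurrence_matrix(tr, rule=eps)
        n = tr.N
        expected = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(n):
                d = np.sqrt(np.sum((tr.states[i] - tr.states[j]) ** 2))
                expected[i, j] = d <= eps
        assert np.array_equal(rm.R, expected)

    def test_nonpositive_epsilon_rejected(self):
        tr = embed(np.arange(20.0), m=2, tau=1)
        with pytest.raises(ValueError):
            recurrence_matrix(tr, rule=0.0)


class TestLineHistograms:
    def test_identity_matrix_has_no_diagonals_and_unit_verticals(self):
        h = line_histograms(np.eye(12, dtype=bool))
        assert h.P_l == {}
        assert h.P_v == {1: 12}

    def test_periodic_series_longest_diagonal(self):
        period, reps = 5, 8
        s = np.tile(np.arange(period, dtype=float), reps)
        tr = embed(s, m=2, tau=1)
        rm = recurrence_matrix(tr, rule=0.1)
        h = line_histograms(rm)
        assert max(h.P_l) == tr.N - period

    def test_random_matrix_matches_run_length_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(5, 31))
            R = rng.random((n, n)) < 0.3
            R = R | R.T
            np.fill_diagonal(R, True)
            h = line_histograms(R)
            diag_runs = []
            for k in range(-(n - 1), n):
                if k == 0:
                    continue
                line = [R[i][i + k] for i in range(max(0, -k), min(n, n - k))]
                diag_runs.extend(oracle_runs(line))
            expected_pl = {}
            for r in diag_runs:
                expected_pl[r] = expected_pl.get(r, 0) + 1
            assert h.P_l == expected_pl
            off_pts = int(R.sum()) - n
            assert sum(l * c for l, c in h.P_l.items()) == off_pts


class TestMeasures:
    def test_all_ones_matrix(self):
        n = 15
        m = rqa_measures(np.ones((n, n), dtype=bool))
        assert m["REC"] == 100.0
        # every off-LOI diagonal is a full line, but the two corner cells
        # are length-1 diagonals and cannot join a line of length >= 2
        assert m["DET"] == pytest.approx(100.0 * (n * n - n - 2) / (n * n - n))
        assert m["LMAX"] == n - 1
        assert m["LAM"] == 100.0

    def test_single_diagonal_line_has_zero_entropy(self):
        n = 10
        R = np.eye(n, dtype=bool)
        for d in range(5):  # one length-5 line on the first superdiagonal
            R[d, d + 1] = R[d + 1, d] = True
        m = rqa_measures(R)
        assert m["ENT"] == 0.0

    def test_periodic_more_deterministic_than_noise(self):
        rng = np.random.default_rng(3)
        periodic = np.tile([0.0, 1.0, 2.0, 1.0], 12)[:44]
        noise = rng.standard_normal(44)
        mp = rqa_features(periodic, m=2, tau=1, rule=EpsilonRule(fixed=0.3))
        mn = rqa_features(noise, m=2, tau=1, rule=EpsilonRule(fixed=0.3))
        assert mp["DET"] > mn["DET"]

    def test_oracle_equivalence_on_random_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(5, 61))
            R = rng.random((n, n)) < rng.uniform(0.05, 0.5)
            R = R | R.T
            np.fill_diagonal(R, True)
            assert_measures_equal(rqa_measures(R), oracle_rqa(R))

    def test_measure_ranges(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(10, 50))
            R = rng.random((n, n)) < 0.2
            R = R | R.T
            np.fill_diagonal(R, True)
            m = rqa_measures(R)
            assert 0 <= m["REC"] <= 100
            assert 0 <= m["DET"] <= 100
            assert 0 <= m["LAM"] <= 100
            assert np.isnan(m["TT"]) or m["TT"] >= 2
            assert np.isnan(m["ENT"]) or m["ENT"] >= 0

    def test_shuffling_never_raises_determinism_on_average(self):
        rng = np.random.default_rng(6)
        s = np.tile([0.0, 1.0, 0.5, 1.5], 15)
        det_p = rqa_features(s, rule=EpsilonRule(fixed=0.3))["DET"]
        dets = []
        for _ in range(10):
            sh = rng.permutation(s)
            dets.append(rqa_features(sh, rule=EpsilonRule(fixed=0.3))["DET"])
        assert np.mean(dets) <= det_p
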