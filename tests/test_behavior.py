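"""Behavioral phenotyping and Markov choice statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import stresspop as sp
from stresspop import behavior as bh


def _brute_silhouette(X, labels):
    """Textbook silhouette: s(i) = (b - a) / max(a, b), averaged."""
    n = len(X)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same]) if same else 0.0
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j]) for j in range(n) if labels[j] == c])
            for c in set(labels) if c != labels[i]
        )
        vals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(vals))


class TestClassifyMice:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(0)
        lo = np.column_stack([rng.normal(0.4, 0.03, 20), rng.normal(0.5, 0.05, 20)])
        hi = np.column_stack([rng.normal(0.8, 0.03, 20), rng.normal(1.2, 0.05, 20)])
        df = pd.DataFrame(np.vstack([lo, hi]), columns=["sucrose_pref", "si_ratio"])
        res = bh.classify_mice(df, seed=0)
        assert res.k == 2
        # low-preference blob labeled susceptible
        expected = np.array(["susceptible"] * 20 + ["resilient"] * 20)
        assert np.mean(res.labels.to_numpy() == expected) >= 0.95

    def test_three_blobs_silhouette_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        centers = [(0.2, 0.3), (0.5, 1.0), (0.9, 0.3)]
        pts = np.vstack([
            np.column_stack([rng.normal(cx, 0.01, 12), rng.normal(cy, 0.01, 12)])
            for cx, cy in centers])
        df = pd.DataFrame(pts, columns=["sucrose_pref", "si_ratio"])
        res = bh.classify_mice(df, seed=0)
        assert res.k == 3
        from sklearn.preprocessing import StandardScaler
        Z = StandardScaler().fit_transform(pts)
        assert res.silhouette_by_k[3] == pytest.approx(
            _brute_silhouette(Z, res.cluster_ids), abs=1e-9)

    def test_degenerate_identical_points_rejected(self):
        df = pd.DataFrame({"sucrose_pref": [0.5] * 5, "si_ratio": [1.0] * 5})
        with pytest.raises(ValueError, match="degenerate"):
            bh.classify_mice(df)

    def test_too_few_mice_rejected(self):
        df = pd.DataFrame({"sucrose_pref": [0.5, 0.6], "si_ratio": [1.0, 0.4]})
        with pytest.raises(ValueError, match="at least 3"):
            bh.classify_mice(df)

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "sucrose_pref": np.concatenate([rng.normal(0.3, 0.02, 10),
                                            rng.normal(0.8, 0.02, 10)]),
            "si_ratio": np.concatenate([rng.normal(0.4, 0.05, 10),
                                        rng.normal(1.2, 0.05, 10)])})
        res1 = bh.classify_mice(df, seed=0)
        perm = np.random.default_rng(3).permutation(len(df))
        res2 = bh.classify_mice(df.iloc[perm], seed=0)
        assert res1.k == res2.k
        assert res2.labels.sort_index().equals(res1.labels.sort_index())


class TestDiscriminationIndex:
    @pytest.mark.parametrize("s,w,expected", [(4, 4, 0.0), (2, 0, 1.0), (3, 1, 0.5)])
    def test_closed_forms(self, s, w, expected):
        assert bh.lick_discrimination_index(s, w) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        assert np.isnan(bh.lick_discrimination_index(0.0, 0.0))

    @given(st.floats(0, 100), st.floats(0, 100))
    def test_antisymmetry(self, s, w):
        if s + w == 0:
            return
        assert bh.lick_discrimination_index(s, w) == pytest.approx(
            -bh.lick_discrimination_index(w, s), abs=1e-12)


class TestMarkovStats:
    def test_alternating_sequence(self):
        p = bh.markov_transition_probs(list("WSWSWS"))
        assert (p["P_WS"], p["P_SW"], p["P_WW"], p["P_SS"]) == (1.0, 1.0, 0.0, 0.0)

    def test_all_sucrose_missing_water_row(self):
        p = bh.markov_transition_probs(list("SSSSS"))
        assert p["P_SS"] == 1.0 and p["P_SW"] == 0.0
        assert np.isnan(p["P_WW"]) and p["missing_rows"] == ["W"]

    def test_row_normalization_on_generated_sequence(self):
        T = np.array([[0.3, 0.7], [0.2, 0.8]])
        seq = sp.generate_choice_sequence(T, 5001, seed=6)
        p = bh.markov_transition_probs(seq)
        assert p["P_WW"] + p["P_WS"] == pytest.approx(1.0, abs=1e-12)
        assert p["P_SS"] + p["P_SW"] == pytest.approx(1.0, abs=1e-12)
        assert p["P_WS"] == pytest.approx(0.7, abs=0.03)

    def test_chance_removed_independent_sequence(self):
        rng = np.random.default_rng(7)
        seq = np.where(rng.random(20000) < 0.5, "S", "W").astype(object)
        cr = bh.chance_removed_proportions(seq)
        for v in cr.values():
            assert abs(v) < 0.01
        assert sum(cr.values()) == pytest.approx(0.0, abs=0.02)

    def test_chance_removed_deterministic_alternation(self):
        seq = list("WS" * 500)
        cr = bh.chance_removed_proportions(seq)
        assert cr["WS"] == pytest.approx(0.25, abs=0.01)

    def test_chance_removed_all_sucrose(self):
        cr = bh.chance_removed_proportions(list("S" * 50))
        assert cr["SS"] == pytest.approx(0.0)

    def test_proportions_sum_to_one(self):
        seq = sp.generate_choice_sequence(
            np.array([[0.4, 0.6], [0.3, 0.7]]), 200, seed=8)
        assert sum(bh.trial_type_proportions(seq).values()) == pytest.approx(1.0)


class TestRunLengths:
    def test_single_runs(self):
        r = bh.consecutive_run_lengths(list("SSSWW"))
        assert r["S"] == 3.0 and r["W"] == 2.0

    def test_alternating_all_ones(self):
        r = bh.consecutive_run_lengths(list("WSWSWS"))
        assert r["S"] == 1.0 and r["W"] == 1.0

    def test_sticky_sequence_geometric_mean(self):
        # mean sucrose-run length = 1 / (1 - P(S->S)) = 5
        T = np.array([[0.5, 0.5], [0.2, 0.8]])
        seq = sp.generate_choice_sequence(T, 20000, seed=9)
        r = bh.consecutive_run_lengths(seq)
        assert r["S"] == pytest.approx(5.0, rel=0.1)


class TestLickAnalysis:
    def test_single_lick_per_trial_rate_trace(self):
        trials = bh.make_trial_table(["S"] * 10, 100.0 + 9.0 * np.arange(10))
        licks = pd.DataFrame({
            "lick_time_s": trials["reward_time_s"] + 0.05, "spout": "S"})
        out = bh.lick_raster_and_rate(licks, trials)
        rate = out["S"]["rate_hz"]
        centers = out["rate_edges"][:-1]
        bin_at_zero = int(np.argmin(np.abs(centers - 0.0)))
        assert rate[bin_at_zero] == pytest.approx(10.0)
        assert rate.sum() == pytest.approx(10.0)  # all mass in one bin

    def test_empty_lick_table_zero_trace(self):
        trials = bh.make_trial_table(["W"] * 5, 50.0 + 9.0 * np.arange(5))
        out = bh.lick_raster_and_rate(trials.iloc[0:0], trials)
        assert np.all(out["W"]["rate_hz"] == 0)

    def test_homogeneous_poisson_rate_recovered(self):
        rng = np.random.default_rng(10)
        rts = 100.0 + 9.0 * np.arange(200)
        trials = bh.make_trial_table(["S"] * 200, rts)
        times = np.concatenate([
            rt - 4 + np.sort(rng.uniform(0, 8, rng.poisson(5 * 8))) for rt in rts])
        licks = pd.DataFrame({"lick_time_s": times, "spout": "S"})
        out = bh.lick_raster_and_rate(licks, trials)
        assert out["S"]["rate_hz"].mean() == pytest.approx(5.0, rel=0.05)
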