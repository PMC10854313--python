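"""State clustering, entropy criterion, intention-state analysis."""

import numpy as np
import pytest

import stresspop as sp
import stresspop.states as st


def _orthonormal_basis(n, k, seed=0):
    """k mean-zero orthonormal vectors in R^n (columns)."""
    rng = np.random.default_rng(seed)
    M = rng.normal(size=(n, k + 1))
    M -= M.mean(axis=0)
    Q, _ = np.linalg.qr(M)
    cols = [q for q in Q.T if abs(q.mean()) < 1e-10][:k]
    return np.column_stack([c / np.linalg.norm(c) for c in cols])


def _vectors_with_correlations(rho12, rho13, rho23, n=200, seed=0):
    """Three vectors whose exact sample Pearson correlations are as given."""
    B = _orthonormal_basis(n, 3, seed)
    u, v, w = B.T
    x1 = u
    x2 = rho12 * u + np.sqrt(1 - rho12**2) * v
    a = rho13
    b = (rho23 - rho12 * rho13) / np.sqrt(1 - rho12**2)
    c = np.sqrt(max(1 - a**2 - b**2, 0.0))
    x3 = a * u + b * v + c * w
    return np.column_stack([x1, x2, x3])


def _brute_complete_linkage(D):
    """All-pairs farthest-point agglomeration; returns sorted merge heights."""
    clusters = [[i] for i in range(D.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(D[p, q] for p in clusters[i] for q in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return np.array(heights)


class TestClusterStates:
    def test_identical_states_merge_at_zero(self):
        v = np.random.default_rng(0).normal(size=20)
        clus = sp.cluster_states(np.column_stack([v, v]))
        assert clus.merge_heights[0] == pytest.approx(0.0, abs=1e-12)
        assert clus.n_clusters_at(0.1) == 1

    def test_anticorrelated_states_stay_apart(self):
        v = np.random.default_rng(1).normal(size=20)
        clus = sp.cluster_states(np.column_stack([v, -v]))
        assert clus.merge_heights[0] == pytest.approx(2.0)
        for t in (0.1, 0.5, 1.0):
            assert clus.n_clusters_at(t) == 2

    def test_hand_computed_merge_heights(self):
        # pairwise rho = (0.9, 0.5, 0.4) -> D = (0.1, 0.5, 0.6);
        # complete linkage merges the 0.1 pair first, then joins the third
        # state at max(0.5, 0.6) = 0.6
        R = _vectors_with_correlations(0.9, 0.5, 0.4)
        clus = sp.cluster_states(R)
        assert np.allclose(np.sort(clus.merge_heights), [0.1, 0.6], atol=1e-9)

    def test_matches_bruteforce_linkage_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(10):
            k = rng.integers(3, 7)
            R = rng.normal(size=(15, k))
            clus = sp.cluster_states(R)
            brute = _brute_complete_linkage(clus.distance)
            assert np.allclose(np.sort(clus.merge_heights), np.sort(brute),
                               atol=1e-10)

    def test_threshold_curve_nonincreasing_and_bounds(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            R = rng.normal(size=(12, int(rng.integers(2, 8))))
            clus = sp.cluster_states(R)
            n = [clus.n_clusters_at(t) for t in np.linspace(0, 1, 11)]
            assert all(a >= b for a, b in zip(n, n[1:]))
            assert clus.n_clusters_at(2.1) == 1  # everything merged eventually

    def test_zero_variance_state_warns(self):
        R = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            clus = sp.cluster_states(R)
        assert clus.correlation[0, 1] == 0.0

    def test_single_state_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            sp.cluster_states(np.ones((5, 1)))


class TestEntropy:
    def test_exclusive_state_zero_entropy(self):
        h, sel = sp.state_entropy(7, 0)
        assert h == 0.0 and sel

    def test_maximum_entropy_at_half(self):
        h, sel = sp.state_entropy(5, 5)
        assert h == pytest.approx(np.log(2))
        assert not sel

    def test_worked_value_point_eight(self):
        h, _ = sp.state_entropy(8, 2)
        assert h == pytest.approx(-(0.8 * np.log(0.8) + 0.2 * np.log(0.2)))
        assert h == pytest.approx(0.5004, abs=1e-4)

    def test_symmetric_under_class_swap(self):
        for a, b in [(3, 9), (1, 0), (5, 5), (2, 13)]:
            assert sp.state_entropy(a, b)[0] == pytest.approx(
                sp.state_entropy(b, a)[0])

    def test_zero_occurrences_rejected(self):
        with pytest.raises(ValueError, match="zero occurrences"):
            sp.state_entropy(0, 0)


class TestThresholdSelection:
    def test_argmax_with_tie_to_smallest(self):
        assert sp.select_intention_threshold([2, 3, 3, 1]) == 0.2

    def test_all_zero_returns_none(self):
        assert sp.select_intention_threshold([0, 0, 0, 0]) is None


class TestIntentionReport:
    def test_planted_states_recovered(self, planted_intention_mouse):
        rep = planted_intention_mouse["report"]
        assert rep.chosen_threshold is not None
        assert rep.n_selective.max() >= 1

    def test_flagged_trials_match_ground_truth(self, planted_intention_mouse):
        coh = planted_intention_mouse["cohort"]
        flags = planted_intention_mouse["trial_flags"]
        gt = set(coh.ground_truth["mice"]["m000"]["regions"]["BLA"]["intention_trials"])
        # trial index offset: analyses drop the history-less first trial
        found = set(int(i) + 1 for i in np.flatnonzero(flags))
        jaccard = len(found & gt) / len(found | gt)
        assert jaccard >= 0.7

    def test_control_spec_without_planting_has_no_intention_states(self):
        specs = [sp.GroupSpec("control", 1, np.array([[0.3, 0.7], [0.2, 0.8]]),
                              n_neurons=12, n_hidden_states=4,
                              intention_state_fraction=0.0)]
        coh = sp.generate_cohort(specs, task_n_trials=80, pretask_len_s=60, seed=1)
        res = st.fit_prereward_states(coh.spikes, coh.trials, "m000", "BLA",
                                      k_range=(2, 6), n_restarts=3, seed=1)
        clus = sp.cluster_states(res["model"].rates_)
        rep = sp.intention_state_report(res["viterbi"], res["intention"], clus)
        assert rep.n_selective.max() == 0
        assert rep.chosen_threshold is None


class TestPretaskClusterCount:
    def test_orthogonal_states_counted(self):
        # 3 states with near-orthogonal rate patterns across 12 neurons
        rng = np.random.default_rng(4)
        rates = np.zeros((12, 3))
        rates[0:4, 0] = 20.0
        rates[4:8, 1] = 20.0
        rates[8:12, 2] = 20.0
        rates += 1.0
        T = np.full((3, 3), 0.05)
        np.fill_diagonal(T, 0.9)
        counts, _ = sp.generate_poisson_hmm_session(
            rates, T, np.full(3, 1 / 3), 360, 1.0, seed=5)
        res = sp.count_distinct_state_clusters_pretask(
            counts.T, k_range=(2, 5), n_restarts=3, seed=5)
        assert res["clustering"].n_clusters_at(0.5) == 3

    def test_single_effective_state_collapses(self):
        # one true state with a heterogeneous rate profile: any extra fitted
        # states copy that profile, so their activity vectors correlate highly
        rates = np.linspace(2, 20, 8).reshape(8, 1)
        counts, _ = sp.generate_poisson_hmm_session(
            rates, np.ones((1, 1)), np.ones(1), 360, 1.0, seed=6)
        res = sp.count_distinct_state_clusters_pretask(
            counts.T, k_range=(2, 3), n_restarts=2, seed=6)
        # fitted states carve up one true state; their activity vectors are
        # near-identical, so they merge at a low threshold
        assert res["clustering"].n_clusters_at(0.3) == 1
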