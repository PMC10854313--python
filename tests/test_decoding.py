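"""History-balanced pseudo-population decoding."""

import numpy as np
import pytest

from stresspop._utils import TRIAL_TYPES
from stresspop.decoding import (PseudoPopulation, SCHEMES, balance_trials,
                                cross_time_decode, decode, shuffle_chance)

N_BINS = 16  # 0.5 s bins over +-4 s
BIN_CENTERS = np.arange(-4, 4, 0.5) + 0.25
POST_BINS = (BIN_CENTERS >= 0) & (BIN_CENTERS < 1)


def make_pseudo(n_neurons, counts_per_type, rng, sucrose_shift=0.0,
                shifted_fraction=1.0, shift_bins=POST_BINS, base_rate=5.0,
                noise_sd=1.0):
    """Synthetic pseudo-population with an optional planted sucrose code."""
    rates, labels = [], []
    n_shifted = int(round(shifted_fraction * n_neurons))
    for n in range(n_neurons):
        lab = np.concatenate([[t] * c for t, c in zip(TRIAL_TYPES, counts_per_type)])
        lab = np.array(lab, dtype=object)
        r = base_rate + rng.normal(0, noise_sd, size=(len(lab), N_BINS))
        if n < n_shifted and sucrose_shift != 0.0:
            is_sucrose = np.isin(lab, ["WS", "SS"])
            r[np.ix_(is_sucrose, shift_bins)] += sucrose_shift
        rates.append(r)
        labels.append(lab)
    edges = np.arange(-4, 4.25, 0.5)
    return PseudoPopulation(rates, labels, edges, [("m0", "BLA", n) for n in range(n_neurons)])


class TestBalancing:
    def test_equal_counts_forced_composition(self):
        pseudo = make_pseudo(3, (8, 8, 8, 8), np.random.default_rng(0))
        bal = balance_trials(pseudo, "current", seed=0)
        assert bal["n_per_type"] == 8
        for cls, types in SCHEMES["current"].items():
            for per_neuron in bal["classes"][cls]:
                assert set(per_neuron) == set(types)
                assert all(len(v) == 8 for v in per_neuron.values())

    def test_min_count_subsampling(self):
        pseudo = make_pseudo(2, (20, 8, 8, 20), np.random.default_rng(0))
        bal = balance_trials(pseudo, "current", seed=0)
        assert bal["n_per_type"] == 8  # limited by the rarest history type

    def test_intention_scheme_composition(self):
        pseudo = make_pseudo(2, (20, 8, 8, 20), np.random.default_rng(0))
        bal = balance_trials(pseudo, "intention", seed=0)
        assert set(SCHEMES["intention"]["stay"]) == {"SS", "WW"}
        assert set(SCHEMES["intention"]["switch"]) == {"SW", "WS"}
        for per_neuron in bal["classes"]["stay"]:
            assert sum(len(v) for v in per_neuron.values()) == 16

    def test_unknown_scheme_rejected(self):
        pseudo = make_pseudo(2, (8, 8, 8, 8), np.random.default_rng(0))
        with pytest.raises(ValueError, match="unknown scheme"):
            balance_trials(pseudo, "outcome", seed=0)

    def test_empty_population_rejected(self):
        empty = PseudoPopulation([], [], np.arange(-4, 4.25, 0.5), [])
        with pytest.raises(ValueError, match="empty"):
            balance_trials(empty, "current")


class TestDecode:
    def test_structureless_population_at_chance(self):
        rng = np.random.default_rng(1)
        pseudo = make_pseudo(20, (12, 12, 12, 12), rng)
        res = decode(pseudo, "current", n_neuron_subsample=20, n_cell_draws=2,
                     n_trial_draws=3, seed=0)
        chance = shuffle_chance(pseudo, "current", n_shuffles=20,
                                n_neuron_subsample=20, seed=1)
        # window-averaged accuracy stays inside the shuffle band
        for lo, hi in ((-4, -3), (0, 1)):
            sel = (BIN_CENTERS >= lo) & (BIN_CENTERS < hi)
            acc = res.mean[sel].mean()
            assert 0.5 - 2 * chance["sd"][sel].mean() <= acc <= 0.5 + 2 * chance["sd"][sel].mean()

    def test_planted_post_reward_code(self):
        rng = np.random.default_rng(2)
        # half the neurons carry a +2 sd sucrose shift after reward
        pseudo = make_pseudo(40, (12, 12, 12, 12), rng, sucrose_shift=2.0,
                             shifted_fraction=0.5)
        res = decode(pseudo, "current", n_neuron_subsample=40, n_cell_draws=2,
                     n_trial_draws=3, seed=0)
        assert res.window_mean(0, 1) >= 0.9
        assert abs(res.window_mean(-4, -3) - 0.5) < 0.15

    def test_perfectly_separated_classes(self):
        rng = np.random.default_rng(3)
        pseudo = make_pseudo(10, (10, 10, 10, 10), rng, sucrose_shift=100.0,
                             shift_bins=np.ones(N_BINS, dtype=bool))
        res = decode(pseudo, "current", n_neuron_subsample=10, n_cell_draws=2,
                     n_trial_draws=2, seed=0)
        assert np.all(res.accuracy_draws == 1.0)

    def test_two_level_averaging_contract(self):
        rng = np.random.default_rng(4)
        pseudo = make_pseudo(6, (8, 8, 8, 8), rng, sucrose_shift=1.0,
                             shifted_fraction=0.5)
        res = decode(pseudo, "current", n_neuron_subsample=6, n_cell_draws=2,
                     n_trial_draws=3, seed=7)
        # reported per-cell-draw value is the flat mean over its trial draws
        for c in range(2):
            assert np.allclose(res.per_cell_draw[c],
                               res.accuracy_draws[c].mean(axis=0))
        # and the whole computation is reproducible under the same seed
        res2 = decode(pseudo, "current", n_neuron_subsample=6, n_cell_draws=2,
                      n_trial_draws=3, seed=7)
        assert np.array_equal(res.accuracy_draws, res2.accuracy_draws)

    def test_invariance_to_neuron_order_and_rate_scaling(self):
        rng = np.random.default_rng(5)
        pseudo = make_pseudo(8, (9, 9, 9, 9), rng, sucrose_shift=1.5,
                             shifted_fraction=0.5)
        res = decode(pseudo, "current", n_neuron_subsample=8, n_cell_draws=1,
                     n_trial_draws=2, seed=3)
        perm = np.random.default_rng(6).permutation(8)
        pseudo_perm = PseudoPopulation([pseudo.rates[i] for i in perm],
                                       [pseudo.labels[i] for i in perm],
                                       pseudo.bin_edges,
                                       [pseudo.neuron_info[i] for i in perm])
        res_perm = decode(pseudo_perm, "current", n_neuron_subsample=8,
                          n_cell_draws=1, n_trial_draws=2, seed=3)
        assert np.allclose(res.accuracy_draws, res_perm.accuracy_draws)
        pseudo_scaled = PseudoPopulation([3.0 * r for r in pseudo.rates],
                                         pseudo.labels, pseudo.bin_edges,
                                         pseudo.neuron_info)
        res_scaled = decode(pseudo_scaled, "current", n_neuron_subsample=8,
                            n_cell_draws=1, n_trial_draws=2, seed=3)
        assert np.allclose(res.accuracy_draws, res_scaled.accuracy_draws)


class TestCrossTime:
    def test_diagonal_matches_within_bin_decoding(self):
        rng = np.random.default_rng(7)
        pseudo = make_pseudo(6, (8, 8, 8, 8), rng, sucrose_shift=1.5,
                             shifted_fraction=0.5)
        within = decode(pseudo, "current", n_neuron_subsample=6, n_cell_draws=1,
                        n_trial_draws=2, seed=5)
        cross = cross_time_decode(pseudo, "current", n_neuron_subsample=6,
                                  n_cell_draws=1, n_trial_draws=2, seed=5)
        assert np.allclose(np.diag(cross.matrix), within.mean)

    def test_post_reward_only_code_block_structure(self):
        rng = np.random.default_rng(8)
        pseudo = make_pseudo(30, (10, 10, 10, 10), rng, sucrose_shift=3.0,
                             shifted_fraction=0.5)
        cross = cross_time_decode(pseudo, "current", n_neuron_subsample=30,
                                  n_cell_draws=1, n_trial_draws=2, seed=5)
        post = np.flatnonzero(POST_BINS)
        pre = np.flatnonzero((BIN_CENTERS >= -4) & (BIN_CENTERS < -3))
        assert cross.matrix[np.ix_(post, post)].mean() >= 0.9
        assert abs(cross.matrix[np.ix_(pre, pre)].mean() - 0.5) < 0.15
        assert abs(cross.matrix[np.ix_(post, pre)].mean() - 0.5) < 0.15

    def test_time_stationary_code_generalizes(self):
        rng = np.random.default_rng(9)
        pseudo = make_pseudo(30, (10, 10, 10, 10), rng, sucrose_shift=3.0,
                             shifted_fraction=0.5,
                             shift_bins=np.ones(N_BINS, dtype=bool))
        cross = cross_time_decode(pseudo, "current", n_neuron_subsample=30,
                                  n_cell_draws=1, n_trial_draws=2, seed=5)
        assert cross.matrix.min() >= 0.8


class TestShuffleChance:
    def test_band_centered_on_half(self):
        rng = np.random.default_rng(10)
        pseudo = make_pseudo(12, (10, 10, 10, 10), rng)
        ch = shuffle_chance(pseudo, "previous", n_shuffles=15,
                            n_neuron_subsample=12, seed=2)
        assert abs(ch["mean"].mean() - 0.5) < 0.1
        assert np.allclose(ch["band_hi"] - 0.5, 0.5 - ch["band_lo"])

    def test_shuffle_sd_shrinks_with_trial_count(self):
        rng = np.random.default_rng(11)
        small = make_pseudo(10, (10, 10, 10, 10), rng)
        big = make_pseudo(10, (50, 50, 50, 50), rng)
        sd_small = shuffle_chance(small, "current", n_shuffles=25,
                                  n_neuron_subsample=10, seed=3)["sd"].mean()
        sd_big = shuffle_chance(big, "current", n_shuffles=25,
                                n_neuron_subsample=10, seed=3)["sd"].mean()
        assert sd_big < sd_small

    def test_planted_code_outside_band_shuffle_inside(self):
        rng = np.random.default_rng(12)
        pseudo = make_pseudo(30, (12, 12, 12, 12), rng, sucrose_shift=3.0,
                             shifted_fraction=0.5)
        res = decode(pseudo, "current", n_neuron_subsample=30, n_cell_draws=2,
                     n_trial_draws=2, seed=4)
        ch = shuffle_chance(pseudo, "current", n_shuffles=20,
                            n_neuron_subsample=30, seed=4)
        sel = POST_BINS
        assert res.mean[sel].mean() > 0.5 + 2 * ch["sd"][sel].mean()
        assert abs(ch["mean"][sel].mean() - 0.5) < 2 * ch["sd"][sel].mean() + 0.05
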