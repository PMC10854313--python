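"""Pseudo-population linear decoding with outcome-history balancing.

Neurons recorded in the same region are pooled across mice; surrogate
("pseudo") trials are assembled by sampling each neuron's trials
independently within a class.  Classes are balanced over the four
previous/current reward history types, so decoding current reward, previous
reward, or switch/stay intention is never confounded by trial history.
Decoders are linear SVMs evaluated per 0.5 s bin with an 80/20
cross-validation split, a two-level subsampling scheme (cells, then trials),
label-shuffle chance bands, and cross-temporal generalization.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._utils import TRIAL_TYPES, spawn_rngs
from .single_unit import bin_trial_spikes

#: class -> constituent history types (previous/current), per decoding scheme
SCHEMES = {
    "current": {"water": ("WW", "SW"), "sucrose": ("SS", "WS")},
    "previous": {"water": ("WW", "WS"), "sucrose": ("SW", "SS")},
    "intention": {"stay": ("SS", "WW"), "switch": ("SW", "WS")},
}


@dataclass
class PseudoPopulation:
    """Pooled neurons with per-trial binned rates and history labels."""

    rates: list[np.ndarray]          # per neuron: (n_trials, n_bins) spikes/s
    labels: list[np.ndarray]         # per neuron: trial_type per trial
    bin_edges: np.ndarray
    neuron_info: list[tuple]         # (mouse_id, region, neuron_id)

    @property
    def n_neurons(self) -> int:
        return len(self.rates)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_edges[:-1] + np.diff(self.bin_edges) / 2

    def type_counts(self) -> np.ndarray:
        """(n_neurons, 4) trial counts in TRIAL_TYPES order."""
        return np.array([[np.sum(lab == t) for t in TRIAL_TYPES] for lab in self.labels])


def build_pseudopopulation(spikes: pd.DataFrame, trials: pd.DataFrame, region: str,
                           mice=None, bin_s: float = 0.5,
                           window: tuple[float, float] = (-4.0, 4.0),
                           min_trials_per_type: int = 8) -> PseudoPopulation:
    """Pool all eligible neurons of one region into a pseudo-population.

    Neurons lacking ``min_trials_per_type`` trials of any of the four history
    types are dropped.  First trials (no history) are never used.
    """
    spk = spikes[spikes["region"] == region]
    if mice is not None:
        spk = spk[spk["mouse_id"].isin(mice)]
    edges = np.arange(window[0], window[1] + bin_s / 2, bin_s)
    rates, labels, info = [], [], []
    for (mouse_id, neuron_id), grp in spk.groupby(["mouse_id", "neuron_id"]):
        tr = trials[(trials["mouse_id"] == mouse_id) & (trials["trial_type"] != "")]
        tr = tr.sort_values("trial_id")
        lab = tr["trial_type"].to_numpy(dtype=object)
        if min(np.sum(lab == t) for t in TRIAL_TYPES) < min_trials_per_type:
            continue
        counts = bin_trial_spikes(grp["spike_time_s"].to_numpy(),
                                  tr["reward_time_s"].to_numpy(dtype=float),
                                  window=window, bin_s=bin_s)
        rates.append(counts / bin_s)
        labels.append(lab)
        info.append((mouse_id, region, neuron_id))
    return PseudoPopulation(rates, labels, np.asarray(edges), info)


def balance_trials(pseudo: PseudoPopulation, scheme: str, seed=None) -> dict:
    """Balanced per-class trial composition under a decoding scheme.

    Per class, equal numbers are drawn from its two constituent history
    types; the common count is the minimum trial count over the four history
    types across all neurons, so both classes end up exactly the same size.
    Returns per-neuron index sets (class -> type -> indices).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; options: {sorted(SCHEMES)}")
    if pseudo.n_neurons == 0:
        raise ValueError("empty pseudo-population")
    rng = np.random.default_rng(seed)
    m = int(pseudo.type_counts().min())
    out = {"n_per_type": m, "classes": {}}
    for cls, types in SCHEMES[scheme].items():
        per_neuron = []
        for lab in pseudo.labels:
            sel = {t: rng.permutation(np.flatnonzero(lab == t))[:m] for t in types}
            per_neuron.append(sel)
        out["classes"][cls] = per_neuron
    return out


def _neuron_stream(base_seed: int, info) -> np.random.Generator:
    """Per-neuron RNG keyed to the neuron's identity (order-invariant draws)."""
    h = int.from_bytes(hashlib.md5(repr(info).encode()).digest()[:8], "little")
    return np.random.default_rng((base_seed, h))


def _assemble(pseudo, scheme, neuron_idx, base_seed: int):
    """Sample one set of balanced pseudo-trials.

    Each pseudo-trial of history type t takes, from every neuron
    independently, the rate vector of one of its type-t trials (drawn
    without replacement).  Each neuron's draws come from a stream keyed to
    its identity, so the assembly is invariant to neuron ordering.  Returns
    X (trials, neurons, bins), class labels y, and the constituent-type
    label used for stratified splitting.
    """
    counts = pseudo.type_counts()[neuron_idx]
    m = int(counts.min())
    if m < 1:
        raise ValueError("a selected neuron has no trials of some history type")
    streams = [_neuron_stream(base_seed, pseudo.neuron_info[n]) for n in neuron_idx]
    X_parts, y_parts, strat = [], [], []
    for cls, types in SCHEMES[scheme].items():
        for t in types:
            block = np.empty((m, len(neuron_idx), pseudo.rates[0].shape[1]))
            for j, n in enumerate(neuron_idx):
                idx = streams[j].permutation(np.flatnonzero(pseudo.labels[n] == t))[:m]
                block[:, j, :] = pseudo.rates[n][idx]
            X_parts.append(block)
            y_parts.extend([cls] * m)
            strat.extend([t] * m)
    return np.concatenate(X_parts), np.array(y_parts), np.array(strat)


@dataclass
class DecodingResult:
    """Cross-validated accuracies per time bin with shuffle chance bands."""

    bin_centers: np.ndarray
    accuracy_draws: np.ndarray        # (n_cell_draws, n_trial_draws, n_bins)
    matrix: np.ndarray | None = None  # (bins, bins) train x test generalization
    shuffle_mean: np.ndarray | None = None
    shuffle_sd: np.ndarray | None = None
    n_neurons_subsampled: int = 0
    scheme: str = ""

    @property
    def per_cell_draw(self) -> np.ndarray:
        """Per-cell-draw accuracy: mean over trial draws (two-level scheme)."""
        return self.accuracy_draws.mean(axis=1)

    @property
    def mean(self) -> np.ndarray:
        return self.per_cell_draw.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.per_cell_draw.std(axis=0)

    def window_mean(self, lo: float, hi: float) -> float:
        """Mean accuracy over bins whose centers fall in [lo, hi)."""
        sel = (self.bin_centers >= lo) & (self.bin_centers < hi)
        return float(self.mean[sel].mean())

    @property
    def chance_band(self) -> tuple[float, np.ndarray] | None:
        """Theoretical chance (0.5) and 2-sd half-width of the shuffle band."""
        if self.shuffle_sd is None:
            return None
        return 0.5, 2.0 * self.shuffle_sd


def _fit_eval(X_train, y_train, X_test, y_test, C=1.0):
    scaler = StandardScaler().fit(X_train)
    clf = SVC(kernel="linear", C=C).fit(scaler.transform(X_train), y_train)
    return clf.score(scaler.transform(X_test), y_test), (scaler, clf)


def _decode_core(pseudo, scheme, n_neuron_subsample, n_cell_draws, n_trial_draws,
                 test_size, seed, cross_time=False, shuffle_labels=False):
    if pseudo.n_neurons == 0:
        raise ValueError("empty pseudo-population")
    n_sub = min(n_neuron_subsample, pseudo.n_neurons)
    if n_sub < n_neuron_subsample:
        warnings.warn(f"only {pseudo.n_neurons} eligible neurons; subsampling all of them")
    n_bins = pseudo.rates[0].shape[1]
    acc = np.zeros((n_cell_draws, n_trial_draws, n_bins))
    mat = np.zeros((n_cell_draws, n_trial_draws, n_bins, n_bins)) if cross_time else None
    cell_rngs = spawn_rngs(seed, n_cell_draws)
    for c in range(n_cell_draws):
        crng = cell_rngs[c]
        neuron_idx = crng.choice(pseudo.n_neurons, size=n_sub, replace=False)
        for t in range(n_trial_draws):
            X, y, strat = _assemble(pseudo, scheme, neuron_idx,
                                    int(crng.integers(2**31)))
            if len(np.unique(y)) < 2:
                raise ValueError("fewer than 2 classes after balancing")
            if shuffle_labels:
                y = crng.permutation(y)
            idx_train, idx_test = train_test_split(
                np.arange(len(y)), test_size=test_size, stratify=strat,
                random_state=int(crng.integers(2**31)))
            for b in range(n_bins):
                score, (scaler, clf) = _fit_eval(X[idx_train, :, b], y[idx_train],
                                                 X[idx_test, :, b], y[idx_test])
                acc[c, t, b] = score
                if cross_time:
                    for b2 in range(n_bins):
                        mat[c, t, b, b2] = clf.score(
                            scaler.transform(X[idx_test, :, b2]), y[idx_test])
    return acc, mat, n_sub


def decode(pseudo: PseudoPopulation, scheme: str, n_neuron_subsample: int = 60,
           n_cell_draws: int = 10, n_trial_draws: int = 10,
           test_size: float = 0.2, seed=0) -> DecodingResult:
    """Cross-validated per-bin linear decoding of a balanced binary label.

    Two-level subsampling: for each of ``n_cell_draws`` random neuron
    subsamples, accuracy is averaged over ``n_trial_draws`` random balanced
    pseudo-trial sets; the distribution over cell draws is reported.
    """
    acc, _, n_sub = _decode_core(pseudo, scheme, n_neuron_subsample, n_cell_draws,
                                 n_trial_draws, test_size, seed)
    return DecodingResult(pseudo.bin_centers, acc, n_neurons_subsampled=n_sub,
                          scheme=scheme)


def cross_time_decode(pseudo: PseudoPopulation, scheme: str,
                      n_neuron_subsample: int = 60, n_cell_draws: int = 10,
                      n_trial_draws: int = 10, test_size: float = 0.2,
                      seed=0) -> DecodingResult:
    """Train on one time bin, test on every bin; diagonal = within-bin decoding."""
    acc, mat, n_sub = _decode_core(pseudo, scheme, n_neuron_subsample, n_cell_draws,
                                   n_trial_draws, test_size, seed, cross_time=True)
    return DecodingResult(pseudo.bin_centers, acc, matrix=mat.mean(axis=(0, 1)),
                          n_neurons_subsampled=n_sub, scheme=scheme)


def shuffle_chance(pseudo: PseudoPopulation, scheme: str, n_shuffles: int = 10,
                   n_neuron_subsample: int = 60, test_size: float = 0.2,
                   seed=0) -> dict:
    """Label-shuffle chance distribution per bin.

    Labels are permuted within the balanced pseudo-trial set before
    training.  The significance band is the theoretical chance level (0.5
    for balanced binary labels) +- 2 sd of the shuffle accuracies.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    accs = []
    for s, rng_seed in enumerate(ss.spawn(n_shuffles)):
        acc, _, _ = _decode_core(pseudo, scheme, n_neuron_subsample, 1, 1,
                                 test_size, rng_seed, shuffle_labels=True)
        accs.append(acc[0, 0])
    accs = np.array(accs)
    sd = accs.std(axis=0)
    return {"shuffle_accuracies": accs, "mean": accs.mean(axis=0), "sd": sd,
            "band_lo": 0.5 - 2 * sd, "band_hi": 0.5 + 2 * sd}
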