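"""Hidden-state structure: clustering, intention selectivity, ablation decoding.

Fitted HMM states are characterized by their emission-rate vectors.  States
are agglomeratively clustered with complete (farthest-point) linkage on the
correlation distance D = 1 - rho, and the number of clusters retained is
tracked across merge thresholds.  A state (or state cluster) whose
pre-reward occurrences are confined to one intention class (switch or stay)
has zero Shannon entropy over the two classes and is called
intention-selective.  Switch/stay decoding from posterior-smoothed activity
is re-run with intention-state trials removed, retained exclusively, or
randomly thinned, to test whether those states carry the intention signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._utils import as_rng, spawn_rngs
from .hmm import PoissonHMMStates
from .single_unit import bin_trial_spikes

CLUSTER_THRESHOLDS = (0.1, 0.2, 0.3, 0.4, 0.5)   # group-decoder features
INTENTION_THRESHOLDS = (0.1, 0.2, 0.3, 0.4)


@dataclass
class StateClustering:
    """Complete-linkage hierarchy over HMM states in activity space."""

    correlation: np.ndarray
    distance: np.ndarray
    linkage_: np.ndarray
    thresholds: tuple

    @property
    def n_states(self) -> int:
        return self.distance.shape[0]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_[:, 2]

    def cluster_ids_at(self, threshold: float) -> np.ndarray:
        """Flat cluster label per state with all merges <= threshold applied."""
        return fcluster(self.linkage_, t=threshold, criterion="distance")

    def n_clusters_at(self, threshold: float) -> int:
        return int(len(np.unique(self.cluster_ids_at(threshold))))

    @property
    def n_clusters(self) -> np.ndarray:
        return np.array([self.n_clusters_at(t) for t in self.thresholds])

    @property
    def proportion_retained(self) -> np.ndarray:
        """Clusters retained / total states, at each probed threshold."""
        return self.n_clusters / self.n_states


def cluster_states(state_rates, thresholds=CLUSTER_THRESHOLDS) -> StateClustering:
    """Agglomerate HMM states by complete linkage on correlation distance.

    ``state_rates`` is (n_neurons, K): column j is state j's emission-rate
    vector.  Pairwise Pearson correlations rho give the distance D = 1 - rho
    (D can exceed 1 when rho < 0; thresholds are only probed in [0, 1]).
    A zero-variance state vector has undefined correlations; its rho is set
    to 0 with a warning.
    """
    R = np.asarray(state_rates, dtype=float)
    if R.ndim != 2 or R.shape[1] < 2:
        raise ValueError("need at least 2 states (neurons x states matrix)")
    K = R.shape[1]
    sd = R.std(axis=0)
    corr = np.eye(K)
    for i in range(K):
        for j in range(i + 1, K):
            if sd[i] == 0 or sd[j] == 0:
                warnings.warn("zero-variance state activity vector: correlation set to 0")
                rho = 0.0
            else:
                rho = float(np.corrcoef(R[:, i], R[:, j])[0, 1])
            corr[i, j] = corr[j, i] = rho
    D = 1.0 - corr
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="complete")
    return StateClustering(corr, D, Z, tuple(thresholds))


def state_entropy(n_switch: float, n_stay: float):
    """Shannon entropy of a state's occurrences over intention classes.

    P_switch = n_switch / (n_switch + n_stay); H = -(p ln p + q ln q) with
    0 ln 0 = 0 by continuity (natural log).  H = 0 exactly iff the state
    occurs exclusively in one class; such states are intention-selective.
    Returns (H, intention_selective).
    """
    total = n_switch + n_stay
    if total <= 0:
        raise ValueError("state has zero occurrences")
    p = n_switch / total
    h = 0.0
    for q in (p, 1.0 - p):
        if q > 0:
            h -= q * np.log(q)
    return float(h), bool(h == 0.0)


def select_intention_threshold(counts, thresholds=INTENTION_THRESHOLDS):
    """Threshold yielding the most intention-selective states (ties: smallest).

    Returns None when no threshold yields any.
    """
    counts = np.asarray(counts)
    if counts.max() == 0:
        return None
    return float(np.asarray(thresholds)[int(np.argmax(counts))])


@dataclass
class IntentionStateReport:
    thresholds: tuple
    n_selective: np.ndarray         # intention-selective clusters per threshold
    n_clusters: np.ndarray          # total clusters per threshold
    fraction_selective: np.ndarray
    chosen_threshold: float | None
    state_table: pd.DataFrame       # per cluster at the chosen threshold
    bin_flags: np.ndarray           # (trials, bins) True where an intention state occurs


def intention_state_report(state_path: np.ndarray, intention, clustering: StateClustering,
                           thresholds=INTENTION_THRESHOLDS) -> IntentionStateReport:
    """Identify intention-selective states at each clustering threshold.

    ``state_path`` is (n_trials, n_bins) of Viterbi state ids over the
    pre-reward bins; ``intention`` per trial in {'stay','switch'}.  At each
    threshold, states merged into the same cluster pool their occurrences;
    clusters occurring pre-reward in exactly one class (entropy 0) are
    counted.  The chosen threshold maximizes that count; per-bin flags mark
    occurrences of the chosen threshold's intention-selective clusters.
    """
    state_path = np.asarray(state_path)
    intention = np.asarray(intention, dtype=object)
    is_switch = intention == "switch"
    n_sel, n_tot, tables = [], [], []
    for t in thresholds:
        ids = clustering.cluster_ids_at(t)
        rows = []
        for c in np.unique(ids):
            member = np.isin(state_path, np.flatnonzero(ids == c))
            occ_switch = int(member[is_switch].sum())
            occ_stay = int(member[~is_switch].sum())
            if occ_switch + occ_stay == 0:
                continue  # state cluster never occurs pre-reward: skipped
            h, sel = state_entropy(occ_switch, occ_stay)
            rows.append({"cluster": int(c), "occ_switch": occ_switch,
                         "occ_stay": occ_stay,
                         "P_switch": occ_switch / (occ_switch + occ_stay),
                         "entropy": h, "intention_selective": sel})
        tab = pd.DataFrame(rows)
        n_sel.append(int(tab["intention_selective"].sum()) if len(tab) else 0)
        n_tot.append(len(np.unique(ids)))
        tables.append(tab)
    n_sel = np.array(n_sel)
    n_tot = np.array(n_tot)
    chosen = select_intention_threshold(n_sel, thresholds)
    if chosen is None:
        flags = np.zeros_like(state_path, dtype=bool)
        table = pd.DataFrame()
    else:
        i = int(np.argmax(n_sel))
        table = tables[i]
        ids = clustering.cluster_ids_at(thresholds[i])
        sel_clusters = table.loc[table["intention_selective"], "cluster"].to_numpy() \
            if len(table) else np.empty(0, int)
        sel_states = np.flatnonzero(np.isin(ids, sel_clusters))
        flags = np.isin(state_path, sel_states)
    return IntentionStateReport(tuple(thresholds), n_sel, n_tot,
                                n_sel / np.maximum(n_tot, 1), chosen, table, flags)


def intention_trial_flags(bin_flags: np.ndarray, min_bins: int = 3) -> np.ndarray:
    """Trials containing intention-selective states in >= min_bins pre-reward bins."""
    return np.asarray(bin_flags).sum(axis=1) >= min_bins


def fit_prereward_states(spikes: pd.DataFrame, trials: pd.DataFrame, mouse_id: str,
                         region: str, bin_s: float = 1.0,
                         window: tuple[float, float] = (-4.0, 0.0),
                         k_range=(2, 10), n_restarts: int = 5, max_iter: int = 100,
                         seed=0, min_neurons: int = 5) -> dict:
    """Fit a Poisson HMM on one mouse/region's pre-reward spike counts.

    Trials are concatenated (each trial's chain restarts from the initial
    distribution); first trials with no history are dropped.  Returns the
    fitted model, per-trial counts, Viterbi paths, posteriors, and smoothed
    activity, all shaped (n_trials, n_bins, ...).
    """
    spk = spikes[(spikes["mouse_id"] == mouse_id) & (spikes["region"] == region)]
    n_neurons = spk["neuron_id"].nunique()
    if n_neurons < min_neurons:
        raise ValueError(f"{mouse_id}/{region}: only {n_neurons} neurons (< {min_neurons})")
    tr = trials[(trials["mouse_id"] == mouse_id) & (trials["trial_type"] != "")]
    tr = tr.sort_values("trial_id")
    rts = tr["reward_time_s"].to_numpy(dtype=float)
    n_bins = int(round((window[1] - window[0]) / bin_s))
    neuron_ids = np.sort(spk["neuron_id"].unique())
    counts = np.stack([
        bin_trial_spikes(spk[spk["neuron_id"] == nid]["spike_time_s"].to_numpy(),
                         rts, window=window, bin_s=bin_s)
        for nid in neuron_ids
    ], axis=-1)  # (n_trials, n_bins, n_neurons)
    M = counts.shape[0]
    flat = counts.reshape(M * n_bins, len(neuron_ids))
    lengths = [n_bins] * M
    model = PoissonHMMStates(k_range=k_range, n_restarts=n_restarts,
                             max_iter=max_iter, bin_s=bin_s, random_state=seed)
    model.fit(flat, lengths=lengths)
    viterbi = model.predict(flat, lengths=lengths).reshape(M, n_bins)
    gamma = model.predict_proba(flat, lengths=lengths)
    smoothed = model.smooth(flat, lengths=lengths).reshape(M, n_bins, -1)
    return {"model": model, "counts": counts, "viterbi": viterbi,
            "posterior": gamma.reshape(M, n_bins, -1), "smoothed": smoothed,
            "intention": tr["intention"].to_numpy(dtype=object),
            "neuron_ids": neuron_ids}


def decode_intention_from_states(smoothed: np.ndarray, intention, trial_flags,
                                 mode: str = "all", n_cv: int = 100,
                                 n_train: int = 100, n_test: int = 20,
                                 n_shuffles: int = 100, seed=0) -> dict:
    """Linear switch/stay decoding from HMM-smoothed activity, with ablation.

    ``smoothed`` is (n_trials, n_bins, n_neurons); ``trial_flags`` marks
    trials containing intention-selective states in >= 3 pre-reward bins.
    Modes: 'all' uses every trial; 'remove_intention' drops flagged trials;
    'keep_intention' keeps, within each class that has any flagged trials,
    only the flagged ones (a class with none keeps all its trials, so the
    binary problem stays well posed); 'remove_random' drops an equal number
    of randomly chosen trials.

    Per CV iteration each class's real trials are split 80/20 into
    train/test sets, and pseudo trials (per-neuron resampling within class)
    are built separately from each split, so no real trial contributes to
    both.  ``n_train`` / ``n_test`` are the total pseudo-trial counts per
    CV.  Chance band: 0.5 +- 2 sd over ``n_shuffles`` label-shuffle
    accuracies (real-trial labels permuted before pseudo-trial generation).
    """
    rng = as_rng(seed)
    smoothed = np.asarray(smoothed, dtype=float)
    intention = np.asarray(intention, dtype=object)
    trial_flags = np.asarray(trial_flags, dtype=bool)
    M = len(intention)
    keep = np.ones(M, dtype=bool)
    if mode == "remove_intention":
        keep = ~trial_flags
    elif mode == "keep_intention":
        for c in ("stay", "switch"):
            in_c = intention == c
            if np.any(trial_flags & in_c):
                keep[in_c & ~trial_flags] = False
    elif mode == "remove_random":
        drop = rng.choice(M, size=int(trial_flags.sum()), replace=False)
        keep[drop] = False
    elif mode != "all":
        raise ValueError(f"unknown mode {mode!r}")

    cls_idx = {c: np.flatnonzero(keep & (intention == c)) for c in ("stay", "switch")}
    if any(len(v) < 2 for v in cls_idx.values()):
        raise ValueError(
            f"mode={mode!r}: not enough trials survive filtering for class(es) "
            f"{[c for c, v in cls_idx.items() if len(v) < 2]}")

    n_bins, n_neurons = smoothed.shape[1], smoothed.shape[2]

    def _pseudo(real_idx, n_pseudo, r):
        draws = real_idx[r.integers(len(real_idx), size=(n_pseudo, n_neurons))]
        block = np.empty((n_pseudo, n_bins, n_neurons))
        for n in range(n_neurons):
            block[:, :, n] = smoothed[draws[:, n], :, n]
        return block.reshape(n_pseudo, -1)

    def _one_cv(class_indices, r):
        X_tr, y_tr, X_te, y_te = [], [], [], []
        for c, idx in class_indices.items():
            order = r.permutation(idx)
            n_te_real = max(int(round(0.2 * len(order))), 1)
            test_real, train_real = order[:n_te_real], order[n_te_real:]
            X_tr.append(_pseudo(train_real, n_train // 2, r))
            y_tr.extend([c] * (n_train // 2))
            X_te.append(_pseudo(test_real, n_test // 2, r))
            y_te.extend([c] * (n_test // 2))
        X_tr, X_te = np.concatenate(X_tr), np.concatenate(X_te)
        scaler = StandardScaler().fit(X_tr)
        clf = SVC(kernel="linear", C=1.0).fit(scaler.transform(X_tr), np.array(y_tr))
        return clf.score(scaler.transform(X_te), np.array(y_te))

    pooled = np.concatenate(list(cls_idx.values()))
    sizes = {c: len(v) for c, v in cls_idx.items()}

    def _shuffled_classes(r):
        perm = r.permutation(pooled)
        out, k = {}, 0
        for c, n in sizes.items():
            out[c] = perm[k:k + n]
            k += n
        return out

    cv_rngs = spawn_rngs(rng.integers(2**31), n_cv + n_shuffles)
    cv_acc = np.array([_one_cv(cls_idx, cv_rngs[i]) for i in range(n_cv)])
    shuf_acc = np.array([
        _one_cv(_shuffled_classes(cv_rngs[n_cv + s]), cv_rngs[n_cv + s])
        for s in range(n_shuffles)
    ])
    sd = shuf_acc.std()
    return {"mode": mode, "accuracy": float(cv_acc.mean()),
            "cv_accuracies": cv_acc, "shuffle_accuracies": shuf_acc,
            "band_lo": 0.5 - 2 * sd, "band_hi": 0.5 + 2 * sd,
            "n_trials_used": int(keep.sum())}


def count_distinct_state_clusters_pretask(counts, k_range=(2, 10), n_restarts: int = 5,
                                          max_iter: int = 100, bin_s: float = 1.0,
                                          thresholds=CLUSTER_THRESHOLDS, seed=0) -> dict:
    """Pre-task state-cluster curve: fit HMM on 1 s bins, cluster, count.

    ``counts`` is (n_bins, n_neurons) spike counts over the pre-task window
    (the 6 min pre-task analysis uses 360 one-second bins).  Returns the
    fitted model, the clustering, and the proportion of clusters retained at
    the probed thresholds.
    """
    model = PoissonHMMStates(k_range=k_range, n_restarts=n_restarts,
                             max_iter=max_iter, bin_s=bin_s, random_state=seed)
    model.fit(counts)
    clustering = cluster_states(model.rates_, thresholds=thresholds)
    return {"model": model, "clustering": clustering,
            "n_clusters": clustering.n_clusters,
            "proportion_retained": clustering.proportion_retained,
            "thresholds": tuple(thresholds)}
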