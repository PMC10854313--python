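"""Single-neuron firing-rate processing and selectivity classification.

Reward-aligned PSTHs; reward-modulated neurons (post- vs. pre-reward
rank-sum with Benjamini-Hochberg FDR across neurons); intention-modulated
neurons (switch vs. stay pre-reward rates); and reward-choice selectivity by
auROC against a label-shuffle threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PRE_WINDOW = (-4.0, -3.0)    # 1 s pre-reward baseline for reward modulation
POST_WINDOW = (0.0, 1.0)     # 1 s post-reward
INTENTION_WINDOW = (-4.0, 0.0)


def bin_trial_spikes(spike_times, reward_times, window=(-4.0, 4.0), bin_s=0.5) -> np.ndarray:
    """Reward-aligned spike counts, one row per trial (half-open bins)."""
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    lo, hi = window
    edges = np.arange(lo, hi + bin_s / 2, bin_s)
    out = np.empty((len(reward_times), len(edges) - 1), dtype=np.int64)
    for i, rt in enumerate(np.asarray(reward_times, dtype=float)):
        out[i] = np.histogram(spike_times - rt, bins=edges)[0]
    return out


def window_rates(spike_times, reward_times, window) -> np.ndarray:
    """Per-trial firing rate (spikes/s) in a reward-aligned half-open window."""
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    lo, hi = window
    rts = np.asarray(reward_times, dtype=float)
    counts = (np.searchsorted(spike_times, rts + hi, side="left")
              - np.searchsorted(spike_times, rts + lo, side="left"))
    return counts / (hi - lo)


def psth(trial_counts: np.ndarray, bin_s: float = 0.01,
         window: tuple[float, float] = (-4.0, 4.0),
         baseline: tuple[float, float] = (-1.0, 0.0),
         smooth_s: float = 0.05):
    """z-scored, smoothed trial-averaged PSTH.

    ``trial_counts`` is trials x bins at ``bin_s`` resolution over ``window``.
    The trial-averaged trace is z-scored against the mean/sd of its own
    baseline bins, then smoothed with a moving-average filter of width
    ``smooth_s``.  A zero-variance baseline makes the trace unscorable:
    returns (None, False).
    """
    trial_counts = np.asarray(trial_counts, dtype=float)
    if trial_counts.ndim != 2 or trial_counts.shape[0] < 1:
        raise ValueError("trial_counts must be trials x bins with >= 1 trial")
    mean_trace = trial_counts.mean(axis=0) / bin_s
    edges = np.arange(window[0], window[1] + bin_s / 2, bin_s)
    centers = edges[:-1] + bin_s / 2
    in_base = (centers >= baseline[0]) & (centers < baseline[1])
    mu, sd = mean_trace[in_base].mean(), mean_trace[in_base].std()
    if sd == 0:
        return None, False
    z = (mean_trace - mu) / sd
    w = max(int(round(smooth_s / bin_s)), 1)
    kernel = np.ones(w) / w
    pad = np.pad(z, (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid"), True


def _ranksum_table(pre_rates, post_rates, neuron_ids, min_trials, alpha):
    """Shared machinery: per-neuron two-sided rank-sum + BH across neurons."""
    rows = []
    for nid, a, b in zip(neuron_ids, pre_rates, post_rates):
        a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
        if len(a) < min_trials or len(b) < min_trials:
            rows.append((nid, np.nan, np.nan, False, 0.0, True))
            continue
        if np.ptp(np.concatenate([a, b])) == 0:  # all values tied
            rows.append((nid, 0.0, 1.0, False, 0.0, False))
            continue
        res = stats.mannwhitneyu(b, a, alternative="two-sided", method="asymptotic")
        rows.append((nid, float(res.statistic), float(res.pvalue), False,
                     float(np.sign(np.median(b) - np.median(a))), False))
    df = pd.DataFrame(rows, columns=["neuron_id", "statistic", "p_raw",
                                     "selective", "direction", "excluded"])
    tested = df["p_raw"].notna() & ~df["excluded"]
    df["p_adj"] = np.nan
    if tested.any():
        rej, p_adj, _, _ = multipletests(df.loc[tested, "p_raw"], alpha=alpha,
                                         method="fdr_bh")
        df.loc[tested, "p_adj"] = p_adj
        df.loc[tested, "selective"] = rej
    return df


def reward_modulated(pre_rates, post_rates, neuron_ids=None,
                     min_trials: int = 10, alpha: float = 0.05) -> pd.DataFrame:
    """Reward-modulated neurons: post-reward [0,1) vs. pre-reward [-4,-3) rates.

    ``pre_rates`` / ``post_rates`` are per-neuron sequences of per-trial
    firing rates.  Two-sided Wilcoxon rank-sum per neuron, BH-FDR across all
    tested neurons, selective iff adjusted p < ``alpha``.  Neurons with fewer
    than ``min_trials`` trials are excluded (flagged, not tested).
    """
    if neuron_ids is None:
        neuron_ids = np.arange(len(pre_rates))
    return _ranksum_table(pre_rates, post_rates, neuron_ids, min_trials, alpha)


def intention_modulated(stay_rates, switch_rates, neuron_ids=None,
                        min_trials: int = 10, alpha: float = 0.05) -> pd.DataFrame:
    """Intention-modulated neurons: 4 s pre-reward rates, switch vs. stay."""
    if neuron_ids is None:
        neuron_ids = np.arange(len(stay_rates))
    return _ranksum_table(stay_rates, switch_rates, neuron_ids, min_trials, alpha)


def fraction_comparison_fisher(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p for comparing two selective-neuron fractions."""
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def auroc(x, y) -> float:
    """Area under the ROC curve for separating ``y`` (positive) from ``x``.

    Computed by an explicit sweep over response thresholds (trapezoidal area
    under the TPR-FPR curve); for count data this equals the rank statistic
    U/(n1*n2) with ties counted 1/2.  Constant pooled data gives exactly 0.5.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    thresholds = np.unique(np.concatenate([x, y]))
    # sweep threshold from above the max down to below the min
    fpr = [0.0]
    tpr = [0.0]
    for thr in thresholds[::-1]:
        fpr.append(np.mean(x >= thr))
        tpr.append(np.mean(y >= thr))
    return float(np.trapezoid(tpr, fpr))


def auroc_selectivity(trial_counts: np.ndarray, labels, n_shuffles: int = 10,
                      seed=None, min_trials: int = 10) -> dict:
    """Per-bin auROC (sucrose vs. water) with a label-shuffle threshold.

    ``trial_counts`` is trials x bins (0.5 s bins); ``labels`` per-trial in
    {'W','S'} with 'S' the positive class.  A neuron is reward-choice
    selective if |auROC - 0.5| exceeds 2 sd of |shuffled auROC - 0.5| in any
    bin (shuffle sd computed per bin).
    """
    rng = np.random.default_rng(seed)
    trial_counts = np.asarray(trial_counts, dtype=float)
    labels = np.asarray(labels, dtype=object)
    pos, neg = labels == "S", labels == "W"
    if pos.sum() < min_trials or neg.sum() < min_trials:
        return {"auroc": None, "selective": False, "excluded": True}
    n_bins = trial_counts.shape[1]
    a = np.array([auroc(trial_counts[neg, b], trial_counts[pos, b]) for b in range(n_bins)])
    shuf = np.empty((n_shuffles, n_bins))
    for s in range(n_shuffles):
        perm = rng.permutation(len(labels))
        lp = labels[perm]
        pp, np_ = lp == "S", lp == "W"
        shuf[s] = [auroc(trial_counts[np_, b], trial_counts[pp, b]) for b in range(n_bins)]
    shuffle_sd = np.abs(shuf - 0.5).std(axis=0)
    selective_bins = np.abs(a - 0.5) > 2 * shuffle_sd
    return {"auroc": a, "shuffle_sd": shuffle_sd, "selective_bins": selective_bins,
            "selective": bool(selective_bins.any()), "excluded": False}


def selectivity_table(spikes: pd.DataFrame, trials: pd.DataFrame, region: str,
                      min_trials: int = 10, alpha: float = 0.05,
                      min_neurons: int = 5) -> pd.DataFrame:
    """Reward- and intention-modulation tests for all neurons of one region.

    Pools neurons across mice into a pseudo-population (per-mouse counts add
    up to the pooled count); mice with fewer than ``min_neurons`` neurons in
    the region are excluded.
    """
    spk = spikes[spikes["region"] == region]
    rows_pre, rows_post, rows_stay, rows_switch, ids = [], [], [], [], []
    for (mouse_id, neuron_id), grp in spk.groupby(["mouse_id", "neuron_id"]):
        if spk[spk["mouse_id"] == mouse_id]["neuron_id"].nunique() < min_neurons:
            continue
        tr = trials[trials["mouse_id"] == mouse_id].sort_values("trial_id")
        st = grp["spike_time_s"].to_numpy()
        rts = tr["reward_time_s"].to_numpy(dtype=float)
        intent = tr["intention"].to_numpy(dtype=object)
        ids.append((mouse_id, neuron_id))
        rows_pre.append(window_rates(st, rts, PRE_WINDOW))
        rows_post.append(window_rates(st, rts, POST_WINDOW))
        pre4 = window_rates(st, rts, INTENTION_WINDOW)
        rows_stay.append(pre4[intent == "stay"])
        rows_switch.append(pre4[intent == "switch"])
    reward = reward_modulated(rows_pre, rows_post, neuron_ids=range(len(ids)),
                              min_trials=min_trials, alpha=alpha)
    intent_df = intention_modulated(rows_stay, rows_switch, neuron_ids=range(len(ids)),
                                    min_trials=min_trials, alpha=alpha)
    reward["test"] = "reward"
    intent_df["test"] = "intention"
    out = pd.concat([reward, intent_df], ignore_index=True)
    out["mouse_id"] = [ids[int(i)][0] for i in out["neuron_id"]]
    out["unit_id"] = [ids[int(i)][1] for i in out["neuron_id"]]
    out["region"] = region
    return out
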