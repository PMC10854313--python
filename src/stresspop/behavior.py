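"""Behavioral phenotyping and choice-sequence statistics.

Classifies stressed mice into susceptible/resilient subtypes by K-means on
(sucrose preference, social-interaction ratio), and quantifies the structure
of reward-choice sequences: lick discrimination indices, row-normalized
first-order Markov transition probabilities, chance-removed trial-type
proportions, and consecutive-run lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

from ._utils import TRIAL_TYPES, intention_labels, trial_type_labels


def make_trial_table(choices, reward_times, mouse_id: str = "", session_id: str = "") -> pd.DataFrame:
    """Tidy trial table with previous-choice, trial-type and intention labels.

    The first trial has no history; it carries empty labels and is excluded
    from all history-conditioned analyses.
    """
    choices = np.asarray(choices, dtype=object)
    reward_times = np.asarray(reward_times, dtype=float)
    if len(choices) != len(reward_times):
        raise ValueError("choices and reward_times must have equal length")
    tt = trial_type_labels(choices)
    prev = np.concatenate(([""], choices[:-1]))
    return pd.DataFrame({
        "mouse_id": mouse_id, "session_id": session_id,
        "trial_id": np.arange(len(choices)),
        "reward_time_s": reward_times, "choice": choices,
        "prev_choice": prev, "trial_type": tt,
        "intention": intention_labels(choices),
    })


@dataclass
class ClassificationResult:
    labels: pd.Series          # 'susceptible' / 'resilient' per mouse
    k: int                     # silhouette-optimal number of clusters
    silhouette_by_k: dict[int, float]
    cluster_ids: np.ndarray


def classify_mice(metrics: pd.DataFrame, k_max: int = 10, n_restarts: int = 50,
                  seed: int = 0) -> ClassificationResult:
    """Split CSDS mice into susceptible vs. resilient by K-means.

    ``metrics`` needs columns ``sucrose_pref`` and ``si_ratio`` (one row per
    stressed mouse; controls must not be passed in).  Features are z-scored,
    K-means is run for k = 2..min(k_max, n-1), and the k maximizing the mean
    silhouette score is kept (ties to smaller k).  Clusters are ranked by
    mean sucrose preference; the lowest-preference cluster is labeled
    susceptible, all others resilient.
    """
    X = metrics[["sucrose_pref", "si_ratio"]].to_numpy(dtype=float)
    if len(X) < 3:
        raise ValueError("need at least 3 CSDS mice to classify")
    if not np.all(np.isfinite(X)):
        raise ValueError("behavioral metrics must be finite")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: all mice have identical metrics")
    Z = StandardScaler().fit_transform(X)

    best_k, best_score, scores, best_ids = None, -np.inf, {}, None
    for k in range(2, min(k_max, len(X) - 1) + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(Z)
        s = silhouette_score(Z, km.labels_, metric="euclidean")
        scores[k] = float(s)
        if s > best_score + 1e-12:  # strict improvement => ties go to smaller k
            best_k, best_score, best_ids = k, s, km.labels_

    pref_by_cluster = pd.Series(X[:, 0]).groupby(best_ids).mean()
    susceptible_cluster = pref_by_cluster.idxmin()
    labels = pd.Series(
        np.where(best_ids == susceptible_cluster, "susceptible", "resilient"),
        index=metrics.index, name="group",
    )
    return ClassificationResult(labels, best_k, scores, best_ids)


def lick_discrimination_index(lick_rate_sucrose, lick_rate_water):
    """DI = (S - W) / (S + W) in [-1, 1]; NaN when both rates are zero."""
    s = np.asarray(lick_rate_sucrose, dtype=float)
    w = np.asarray(lick_rate_water, dtype=float)
    if np.any(s < 0) or np.any(w < 0):
        raise ValueError("lick rates must be nonnegative")
    total = s + w
    with np.errstate(invalid="ignore", divide="ignore"):
        di = np.where(total > 0, (s - w) / total, np.nan)
    return float(di) if di.ndim == 0 else di


def _choice_sequence(trials) -> np.ndarray:
    if isinstance(trials, pd.DataFrame):
        return trials.sort_values("trial_id")["choice"].to_numpy(dtype=object) \
            if "trial_id" in trials else trials["choice"].to_numpy(dtype=object)
    return np.asarray(trials, dtype=object)


def markov_transition_probs(trials) -> dict:
    """Row-normalized transition probabilities of the choice sequence.

    Returns P_WW, P_WS, P_SW, P_SS with P_WW + P_WS = 1 and
    P_SS + P_SW = 1 where the source choice occurs; a source choice that
    never occurs leaves its row as NaN with ``missing_rows`` flagging it.
    """
    seq = _choice_sequence(trials)
    pairs = list(zip(seq[:-1], seq[1:]))
    counts = {t: 0 for t in TRIAL_TYPES}
    for a, b in pairs:
        counts[str(a) + str(b)] += 1
    out: dict = {"counts": counts, "missing_rows": []}
    for src in ("W", "S"):
        row_total = counts[src + "W"] + counts[src + "S"]
        if row_total == 0:
            out[f"P_{src}W"] = np.nan
            out[f"P_{src}S"] = np.nan
            out["missing_rows"].append(src)
        else:
            out[f"P_{src}W"] = counts[src + "W"] / row_total
            out[f"P_{src}S"] = counts[src + "S"] / row_total
    return out


def trial_type_proportions(trials) -> dict[str, float]:
    """Proportion of each history trial type among history-labeled trials."""
    seq = _choice_sequence(trials)
    if len(seq) < 2:
        raise ValueError("need at least 2 trials")
    tt = trial_type_labels(seq)[1:]
    n = len(tt)
    return {t: float(np.sum(tt == t)) / n for t in TRIAL_TYPES}


def chance_removed_proportions(trials) -> dict[str, float]:
    """Observed trial-type proportion minus the independence chance level.

    Chance for type XY is P(X) * P(Y) with P the marginal choice frequency,
    so a history-independent sequence gives ~0 for every type.
    """
    seq = _choice_sequence(trials)
    props = trial_type_proportions(seq)
    p = {c: float(np.mean(seq == c)) for c in ("W", "S")}
    return {t: props[t] - p[t[0]] * p[t[1]] for t in TRIAL_TYPES}


def consecutive_run_lengths(trials) -> dict[str, float]:
    """Mean length of maximal runs of identical choices, per choice.

    A choice that never occurs gets NaN.
    """
    seq = _choice_sequence(trials)
    if len(seq) == 0:
        raise ValueError("need at least 1 trial")
    runs: dict[str, list[int]] = {"W": [], "S": []}
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            runs[str(seq[start])].append(i - start)
            start = i
    return {c: float(np.mean(v)) if v else np.nan for c, v in runs.items()}


def lick_raster_and_rate(licks: pd.DataFrame, trials: pd.DataFrame,
                         window: tuple[float, float] = (-4.0, 4.0),
                         raster_bin_s: float = 0.02, rate_bin_s: float = 0.1) -> dict:
    """Reward-aligned lick rasters (20 ms bins) and rate traces (100 ms bins).

    Returns, per reward type ('S', 'W'): the raster count matrix
    (trials x raster bins), the trial-averaged rate trace in Hz, and the two
    bin-edge grids.  A type with no trials yields empty arrays; no licks
    yields an all-zero trace.
    """
    lick_times = licks["lick_time_s"].to_numpy(dtype=float) if len(licks) else np.empty(0)
    lo, hi = window
    raster_edges = np.arange(lo, hi + raster_bin_s / 2, raster_bin_s)
    rate_edges = np.arange(lo, hi + rate_bin_s / 2, rate_bin_s)
    out = {"raster_edges": raster_edges, "rate_edges": rate_edges}
    for rtype in ("S", "W"):
        sel = trials[trials["choice"] == rtype]
        rasters, rates = [], []
        for rt in sel["reward_time_s"].to_numpy(dtype=float):
            rel = lick_times[(lick_times >= rt + lo) & (lick_times < rt + hi)] - rt
            rasters.append(np.histogram(rel, bins=raster_edges)[0])
            rates.append(np.histogram(rel, bins=rate_edges)[0])
        n = len(sel)
        out[rtype] = {
            "raster": np.array(rasters) if n else np.empty((0, len(raster_edges) - 1), int),
            "rate_hz": (np.mean(rates, axis=0) / rate_bin_s) if n
                       else np.zeros(len(rate_edges) - 1),
            "n_trials": n,
        }
    return out


def lick_rates_in_window(licks, trials, window) -> dict[str, float]:
    """Mean lick rate (Hz) in a reward-aligned window, per reward type."""
    lick_times = licks["lick_time_s"].to_numpy(dtype=float) if len(licks) else np.empty(0)
    lo, hi = window
    out = {}
    for rtype in ("S", "W"):
        sel = trials[trials["choice"] == rtype]["reward_time_s"].to_numpy(dtype=float)
        if len(sel) == 0:
            out[rtype] = np.nan
            continue
        n_licks = sum(np.sum((lick_times >= rt + lo) & (lick_times < rt + hi)) for rt in sel)
        out[rtype] = n_licks / (len(sel) * (hi - lo))
    return out


def behavior_metrics(subjects: pd.DataFrame, trials: pd.DataFrame,
                     licks: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse behavioral feature table: DI pre/post, preference, SI ratio."""
    rows = []
    for mouse_id, subj in subjects.set_index("mouse_id").iterrows():
        tr = trials[trials["mouse_id"] == mouse_id]
        lk = licks[licks["mouse_id"] == mouse_id]
        pre = lick_rates_in_window(lk, tr, (-4.0, 0.0))
        post = lick_rates_in_window(lk, tr, (0.0, 4.0))
        rows.append({
            "mouse_id": mouse_id, "group": subj["group"],
            "sucrose_pref": subj["sucrose_pref"], "si_ratio": subj["si_ratio"],
            "lick_rate_pre_S": pre["S"], "lick_rate_pre_W": pre["W"],
            "lick_rate_post_S": post["S"], "lick_rate_post_W": post["W"],
            "DI_pre": lick_discrimination_index(max(pre["S"], 0) if np.isfinite(pre["S"]) else 0,
                                                max(pre["W"], 0) if np.isfinite(pre["W"]) else 0),
            "DI_post": lick_discrimination_index(max(post["S"], 0) if np.isfinite(post["S"]) else 0,
                                                 max(post["W"], 0) if np.isfinite(post["W"]) else 0),
        })
    return pd.DataFrame(rows)


def markov_stats_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse Markov choice statistics (transitions, chance-removed, runs)."""
    rows = []
    for mouse_id, tr in trials.groupby("mouse_id"):
        seq = tr.sort_values("trial_id")["choice"].to_numpy(dtype=object)
        probs = markov_transition_probs(seq)
        cr = chance_removed_proportions(seq)
        runs = consecutive_run_lengths(seq)
        rows.append({
            "mouse_id": mouse_id,
            **{k: probs[k] for k in ("P_WW", "P_WS", "P_SW", "P_SS")},
            **{f"chance_removed_{t}": cr[t] for t in TRIAL_TYPES},
            "mean_run_W": runs["W"], "mean_run_S": runs["S"],
        })
    return pd.DataFrame(rows)
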