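"""Trial-type-specific correlation between simultaneously recorded regions.

Population rates (10 ms bins) are averaged over each region's neurons;
Pearson correlation between the two region traces is computed within each
1 s window of the +-4 s trial (100 samples per window), averaged over
windows within a trial and then over trials of a type, and summarized per
mouse as delta = corr_sucrose - corr_water.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .single_unit import bin_trial_spikes


def region_mean_trace(spikes: pd.DataFrame, reward_times, window=(-4.0, 4.0),
                      fine_bin_s: float = 0.01) -> np.ndarray:
    """(n_trials, n_fine_bins) region-mean firing rate, reward-aligned."""
    neuron_ids = np.sort(spikes["neuron_id"].unique())
    if len(neuron_ids) == 0:
        raise ValueError("region has no neurons")
    traces = [
        bin_trial_spikes(spikes[spikes["neuron_id"] == nid]["spike_time_s"].to_numpy(),
                         reward_times, window=window, bin_s=fine_bin_s)
        for nid in neuron_ids
    ]
    return np.mean(traces, axis=0) / fine_bin_s


def interregional_correlation(spikes_a: pd.DataFrame, spikes_b: pd.DataFrame,
                              trials: pd.DataFrame, window=(-4.0, 4.0),
                              fine_bin_s: float = 0.01, corr_window_s: float = 1.0,
                              average: str = "windows_then_trials") -> dict:
    """Windowed Pearson correlation between two regions' mean-rate traces.

    Returns per-trial-type mean correlations, the per-window averages, and
    delta = corr_sucrose - corr_water.  Windows where either region's trace
    has zero variance are skipped (counted in ``n_skipped_windows``).
    ``average`` chooses whether windows are averaged within trials first
    ('windows_then_trials') or trials within windows first
    ('trials_then_windows'); both orders are exposed.
    """
    rts = trials["reward_time_s"].to_numpy(dtype=float)
    choice = trials["choice"].to_numpy(dtype=object)
    A = region_mean_trace(spikes_a, rts, window, fine_bin_s)
    B = region_mean_trace(spikes_b, rts, window, fine_bin_s)
    n_win = int(round((window[1] - window[0]) / corr_window_s))
    samples = int(round(corr_window_s / fine_bin_s))
    r = np.full((len(rts), n_win), np.nan)
    skipped = 0
    for i in range(len(rts)):
        for w in range(n_win):
            sl = slice(w * samples, (w + 1) * samples)
            a, b = A[i, sl], B[i, sl]
            if a.std() == 0 or b.std() == 0:
                skipped += 1
                continue
            r[i, w] = np.corrcoef(a, b)[0, 1]
    out = {"r_trial_window": r, "n_skipped_windows": skipped,
           "window_edges": np.arange(window[0], window[1] + corr_window_s / 2,
                                     corr_window_s)}
    means = {}
    for rtype in ("S", "W"):
        sel = r[choice == rtype]
        if sel.size == 0 or np.all(np.isnan(sel)):
            means[rtype] = np.nan
            continue
        if average == "windows_then_trials":
            per_trial = np.nanmean(sel, axis=1)
            means[rtype] = float(np.nanmean(per_trial))
        elif average == "trials_then_windows":
            per_window = np.nanmean(sel, axis=0)
            means[rtype] = float(np.nanmean(per_window))
        else:
            raise ValueError(f"unknown averaging order {average!r}")
    out["corr_sucrose"] = means["S"]
    out["corr_water"] = means["W"]
    out["delta_corr"] = means["S"] - means["W"]
    return out


def interregional_table(spikes: pd.DataFrame, trials: pd.DataFrame,
                        regions=("BLA", "vCA1"), **kwargs) -> pd.DataFrame:
    """Per-mouse interregional correlations and sucrose-water difference."""
    rows = []
    for mouse_id in sorted(trials["mouse_id"].unique()):
        spk = spikes[spikes["mouse_id"] == mouse_id]
        tr = trials[trials["mouse_id"] == mouse_id].sort_values("trial_id")
        a = spk[spk["region"] == regions[0]]
        b = spk[spk["region"] == regions[1]]
        if len(a) == 0 or len(b) == 0:
            continue
        res = interregional_correlation(a, b, tr, **kwargs)
        rows.append({"mouse_id": mouse_id, "corr_sucrose": res["corr_sucrose"],
                     "corr_water": res["corr_water"], "delta_corr": res["delta_corr"]})
    return pd.DataFrame(rows)
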