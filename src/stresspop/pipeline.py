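"""End-to-end orchestration of the cohort analyses.

Reads a cohort directory (subjects/spikes/trials/licks tables), runs the
enabled analysis modules with seeds derived from one master seed, writes
per-module tables plus a machine-readable ``report.json``, and never
mutates its inputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, decoding, geometry, interregional, states, subject
from ._utils import REGIONS
from .cohort import read_cohort
from .single_unit import bin_trial_spikes, selectivity_table

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """All pipeline tunables with their standard defaults.

    The defaults mirror the analysis conventions used throughout the
    package: +-4 s trial windows, pre-reward summary window [-4, -3) s and
    post-reward [0, 1) s, a pre-task analysis window of minutes 2-8, 0.5 s
    decoding bins, and the two-level decoding subsampling scheme.
    """

    input_dir: str = "."
    output_dir: str = "run_out"
    seed: int = 0
    modules: dict = field(default_factory=lambda: {
        "behavior": True, "single_unit": True, "decoding": True,
        "geometry": True, "states": True, "subject": True,
        "interregional": True,
    })
    pretask_window_s: tuple = (120.0, 480.0)
    trial_window_s: tuple = (-4.0, 4.0)
    prereward_window_s: tuple = (-4.0, -3.0)
    postreward_window_s: tuple = (0.0, 1.0)
    decode_bin_s: float = 0.5
    n_neuron_subsample: int = 60
    n_cell_draws: int = 10
    n_trial_draws: int = 10
    n_decode_shuffles: int = 10
    hmm_k_range: tuple = (2, 15)
    hmm_n_restarts: int = 5
    hmm_max_iter: int = 100
    geometry_n_subsamples: int = 1000
    subject_n_cv: int = 1000
    min_neurons: int = 5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("pretask_window_s", "trial_window_s", "prereward_window_s",
                     "postreward_window_s", "hmm_k_range"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def _pretask_counts(spikes: pd.DataFrame, mouse_id: str, region: str,
                    window: tuple, bin_s: float = 1.0) -> np.ndarray:
    """(n_neurons, n_bins) spike counts in the pre-task analysis window."""
    spk = spikes[(spikes["mouse_id"] == mouse_id) & (spikes["region"] == region)]
    edges = np.arange(window[0], window[1] + bin_s / 2, bin_s)
    return np.stack([
        np.histogram(grp["spike_time_s"].to_numpy(), bins=edges)[0]
        for _, grp in spk.groupby("neuron_id")
    ]) if len(spk) else np.empty((0, len(edges) - 1), dtype=int)


def run_all(config: RunConfig) -> dict:
    """Run every enabled module on the cohort; returns (and writes) the report."""
    cohort = read_cohort(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(
        ("decoding", "geometry", "states", "subject"), ss.spawn(4))}
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "seed": config.seed,
                    "n_mice": int(len(cohort.subjects))}
    groups = sorted(cohort.subjects["group"].unique())
    mice_by_group = {g: cohort.subjects.loc[cohort.subjects["group"] == g,
                                            "mouse_id"].tolist() for g in groups}

    metrics = behavior.behavior_metrics(cohort.subjects, cohort.trials, cohort.licks)
    if config.modules.get("behavior", True):
        metrics.to_csv(out / "behavior_metrics.tsv", sep="\t", index=False)
        markov = behavior.markov_stats_table(cohort.trials)
        markov.to_csv(out / "markov_stats.tsv", sep="\t", index=False)
        rep = {"per_group_DI_post": {
            g: float(metrics.loc[metrics["group"] == g, "DI_post"].mean())
            for g in groups}}
        csds = metrics[metrics["group"] != "control"]
        if len(csds) >= 3:
            cls = behavior.classify_mice(csds, seed=config.seed)
            rep["classification"] = {
                "k": cls.k,
                "silhouette_by_k": cls.silhouette_by_k,
                "agreement_with_truth": float(np.mean(
                    cls.labels.to_numpy() == csds["group"].to_numpy())),
            }
        report["behavior"] = rep

    if config.modules.get("single_unit", True):
        tabs = []
        for region in REGIONS:
            tab = selectivity_table(cohort.spikes, cohort.trials, region,
                                    min_neurons=config.min_neurons)
            tabs.append(tab)
        sel = pd.concat(tabs, ignore_index=True)
        sel.to_csv(out / "selectivity.tsv", sep="\t", index=False)
        frac = {}
        mouse_group = cohort.subjects.set_index("mouse_id")["group"]
        sel["group"] = sel["mouse_id"].map(mouse_group)
        for (region, test, group), grp in sel.groupby(["region", "test", "group"]):
            tested = grp[~grp["excluded"]]
            if len(tested):
                frac[f"{region}/{group}/{test}"] = float(tested["selective"].mean())
        report["single_unit"] = {"fraction_selective": frac}

    if config.modules.get("decoding", True):
        rep = {}
        for region in REGIONS:
            for g in groups:
                pseudo = decoding.build_pseudopopulation(
                    cohort.spikes, cohort.trials, region, mice=mice_by_group[g],
                    bin_s=config.decode_bin_s, window=config.trial_window_s)
                if pseudo.n_neurons == 0:
                    continue
                key = f"{region}/{g}"
                rep[key] = {}
                for s_i, scheme in enumerate(decoding.SCHEMES):
                    res = decoding.decode(
                        pseudo, scheme,
                        n_neuron_subsample=config.n_neuron_subsample,
                        n_cell_draws=config.n_cell_draws,
                        n_trial_draws=config.n_trial_draws,
                        seed=seeds["decoding"].spawn(1)[0])
                    chance = decoding.shuffle_chance(
                        pseudo, scheme, n_shuffles=config.n_decode_shuffles,
                        n_neuron_subsample=config.n_neuron_subsample,
                        seed=seeds["decoding"].spawn(1)[0])
                    rep[key][scheme] = {
                        "accuracy_by_bin": res.mean.tolist(),
                        "pre_reward": res.window_mean(*config.prereward_window_s),
                        "post_reward": res.window_mean(*config.postreward_window_s),
                        "shuffle_sd_by_bin": chance["sd"].tolist(),
                    }
        report["decoding"] = rep

    geo_rows = []
    if config.modules.get("geometry", True):
        for mouse_id in cohort.subjects["mouse_id"]:
            for region in REGIONS:
                counts = _pretask_counts(cohort.spikes, mouse_id, region,
                                         config.pretask_window_s)
                if counts.shape[0] < config.min_neurons:
                    continue
                feats = geometry.geometry_features(
                    counts, n_subsamples=config.geometry_n_subsamples,
                    seed=seeds["geometry"].spawn(1)[0])
                geo_rows.append({"mouse_id": mouse_id, "region": region, **feats})
        geo = pd.DataFrame(geo_rows)
        geo.to_csv(out / "geometry.tsv", sep="\t", index=False)
        if len(geo):
            geo["group"] = geo["mouse_id"].map(
                cohort.subjects.set_index("mouse_id")["group"])
            report["geometry"] = {
                "mean_PR_by_group": {
                    f"{r}/{g}": float(grp["participation_ratio"].mean())
                    for (r, g), grp in geo.groupby(["region", "group"])},
            }

    cluster_rows = []
    if config.modules.get("states", True):
        rep = {}
        for mouse_id in cohort.subjects["mouse_id"]:
            for region in REGIONS:
                counts = _pretask_counts(cohort.spikes, mouse_id, region,
                                         config.pretask_window_s)
                if counts.shape[0] < config.min_neurons:
                    continue
                res = states.count_distinct_state_clusters_pretask(
                    counts.T, k_range=config.hmm_k_range,
                    n_restarts=config.hmm_n_restarts,
                    max_iter=config.hmm_max_iter,
                    seed=seeds["states"].spawn(1)[0])
                cluster_rows.append({
                    "mouse_id": mouse_id, "region": region,
                    "n_states": res["model"].n_states_,
                    **{f"prop_clusters_{t}": float(p) for t, p in
                       zip(res["thresholds"], res["proportion_retained"])},
                })
        clusters = pd.DataFrame(cluster_rows)
        clusters.to_csv(out / "state_clusters.tsv", sep="\t", index=False)
        if len(clusters):
            clusters["group"] = clusters["mouse_id"].map(
                cohort.subjects.set_index("mouse_id")["group"])
            rep["mean_n_states_by_group"] = {
                f"{r}/{g}": float(grp["n_states"].mean())
                for (r, g), grp in clusters.groupby(["region", "group"])}
        report["states"] = rep

    if config.modules.get("subject", True):
        rep = {"behavioral": {}, "neural": {}}
        Xb = metrics[["DI_pre", "DI_post", "sucrose_pref", "si_ratio"]].to_numpy()
        yb = metrics["group"].to_numpy()
        finite = np.all(np.isfinite(Xb), axis=1)
        for a, b in [(x, y) for i, x in enumerate(groups) for y in groups[i + 1:]]:
            sel = finite & np.isin(yb, [a, b])
            if min(np.sum(yb[sel] == a), np.sum(yb[sel] == b)) < 3:
                continue
            res = subject.mahalanobis_binary_decode(
                Xb[sel], yb[sel], n_cv=config.subject_n_cv,
                seed=seeds["subject"].spawn(1)[0])
            rep["behavioral"][f"{a}_vs_{b}"] = res["accuracy"]
        if geo_rows and cluster_rows:
            geo = pd.DataFrame(geo_rows)
            clusters = pd.DataFrame(cluster_rows)
            feats = geo.merge(clusters, on=["mouse_id", "region"])
            feats["group"] = feats["mouse_id"].map(
                cohort.subjects.set_index("mouse_id")["group"])
            for region in REGIONS:
                fr = feats[feats["region"] == region]
                cols = subject.NEURAL_FEATURES
                if not set(cols) <= set(fr.columns):
                    continue
                Xn = fr[cols].to_numpy(dtype=float)
                yn = fr["group"].to_numpy()
                for a, b in [(x, y) for i, x in enumerate(groups) for y in groups[i + 1:]]:
                    sel = np.isin(yn, [a, b])
                    if min(np.sum(yn[sel] == a), np.sum(yn[sel] == b)) < 3:
                        continue
                    res = subject.mahalanobis_binary_decode(
                        Xn[sel], yn[sel], n_cv=config.subject_n_cv,
                        minmax_columns=[8, 9],
                        seed=seeds["subject"].spawn(1)[0])
                    rep["neural"][f"{region}/{a}_vs_{b}"] = res["accuracy"]
                if len(fr) >= 3:
                    coords = subject.mds_embed(Xn, group_labels=yn)
                    pd.DataFrame({"mouse_id": fr["mouse_id"], "region": region,
                                  "mds_x": coords[:, 0], "mds_y": coords[:, 1]}) \
                        .to_csv(out / f"mds_coords_{region}.tsv", sep="\t", index=False)
        report["subject"] = rep

    if config.modules.get("interregional", True):
        tab = interregional.interregional_table(cohort.spikes, cohort.trials,
                                                regions=REGIONS)
        tab.to_csv(out / "interregional.tsv", sep="\t", index=False)
        if len(tab):
            tab["group"] = tab["mouse_id"].map(
                cohort.subjects.set_index("mouse_id")["group"])
            report["interregional"] = {
                "mean_delta_corr_by_group": {
                    g: float(grp["delta_corr"].mean())
                    for g, grp in tab.groupby("group")},
            }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
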