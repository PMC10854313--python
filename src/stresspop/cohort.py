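"""Synthetic cohorts of stressed and control mice.

Emulates the data structure of a head-fixed two-spout sucrose/water choice
task with simultaneous two-region extracellular recordings: three groups
(control, susceptible, resilient), first-order Markov reward-choice
sequences, Poisson-HMM spiking with group-specific numbers of hidden states,
planted reward-modulated neurons, planted intention-selective states that
occur only pre-reward on one trial class, and a tunable correlation between
the two regions' population rates.  Ground truth (state paths, emission
rates, planted trials) is returned for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import (
    CHOICES,
    REGIONS,
    as_rng,
    check_probability_vector,
    check_row_stochastic,
    intention_labels,
    spawn_rngs,
    stationary_distribution,
    trial_type_labels,
)

STATE_BIN_S = 1.0   # hidden-state dwell resolution
GAIN_BIN_S = 0.05   # resolution of the shared inter-regional gain signal
ITI_SPACING_S = 9.0  # reward-to-reward spacing; > 8 s ITI so +-4 s windows never overlap
FIRST_REWARD_S = 10.0  # offset of first reward into the task epoch


@dataclass
class GroupSpec:
    """Generative parameters for one experimental group.

    ``choice_transition`` is row-stochastic over (water, sucrose) in that
    order.  ``intention_state_fraction`` of the hidden states are reserved as
    intention-only states planted in >= 3 of the 4 pre-reward 1-s bins on a
    fraction of trials of ``intention_trial_class``.
    ``interregional_coupling`` in [-1, 1] is the target correlation of the
    shared log-normal gain driving the two regions' population rates.
    """

    group_label: str
    n_mice: int
    choice_transition: np.ndarray
    sucrose_pref_mean: float = 0.7
    sucrose_pref_sd: float = 0.08
    si_ratio_mean: float = 1.0
    si_ratio_sd: float = 0.25
    n_hidden_states: int = 3
    state_rate_range: tuple[float, float] = (2.0, 20.0)
    intention_state_fraction: float = 0.0
    intention_trial_class: str = "switch"
    intention_trial_fraction: float = 0.9
    interregional_coupling: float = 0.3
    n_neurons: int = 12
    reward_mod_fraction: float = 0.4
    reward_gain: float = 2.5
    reward_gain_nonpref: float = 1.2
    lick_rate_sucrose: float = 6.0
    lick_rate_water: float = 3.0
    lick_rate_baseline: float = 0.5

    def __post_init__(self):
        self.choice_transition = check_row_stochastic(
            self.choice_transition, f"choice_transition[{self.group_label}]"
        )
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        lo, hi = self.state_rate_range
        if lo < 0 or hi < lo:
            raise ValueError("state_rate_range must be nonnegative and ordered")
        if not 0.0 <= self.intention_state_fraction <= 1.0:
            raise ValueError("intention_state_fraction must lie in [0, 1]")
        if not -1.0 <= self.interregional_coupling <= 1.0:
            raise ValueError("interregional_coupling must lie in [-1, 1]")
        if self.intention_trial_class not in ("switch", "stay"):
            raise ValueError("intention_trial_class must be 'switch' or 'stay'")
        if self.n_hidden_states < 1:
            raise ValueError("n_hidden_states must be >= 1")


def default_group_specs() -> list[GroupSpec]:
    """The cohort emulated by default: 15 control, 12 susceptible, 33 resilient.

    Susceptible mice get lower sucrose preference and social-interaction
    ratio, weaker lick discrimination, less history-dependent choice, more
    hidden states, planted intention-only states, and weaker inter-regional
    coupling; controls and resilient mice share strong sucrose-seeking
    defaults.  Effect sizes are package choices (see docs/methods.md).
    """
    return [
        GroupSpec(
            "control", 15,
            np.array([[0.3, 0.7], [0.2, 0.8]]),
            sucrose_pref_mean=0.75, si_ratio_mean=1.2,
            n_hidden_states=3, intention_state_fraction=0.0,
            interregional_coupling=0.35,
        ),
        GroupSpec(
            "susceptible", 12,
            np.array([[0.5, 0.5], [0.45, 0.55]]),
            sucrose_pref_mean=0.45, sucrose_pref_sd=0.10,
            si_ratio_mean=0.5, si_ratio_sd=0.2,
            n_hidden_states=5, intention_state_fraction=0.25,
            interregional_coupling=0.1,
            lick_rate_sucrose=4.0, lick_rate_water=3.5,
        ),
        GroupSpec(
            "resilient", 33,
            np.array([[0.2, 0.8], [0.15, 0.85]]),
            sucrose_pref_mean=0.75, si_ratio_mean=1.1,
            n_hidden_states=3, intention_state_fraction=0.0,
            interregional_coupling=0.35,
            lick_rate_sucrose=7.0, lick_rate_water=2.5,
        ),
    ]


def generate_choice_sequence(transition, n_trials: int, seed) -> np.ndarray:
    """First-order Markov sequence of reward choices in {'W', 'S'}.

    The first choice is drawn from the stationary distribution of the
    transition matrix; each subsequent choice from the row of its
    predecessor.
    """
    transition = check_row_stochastic(transition, "transition")
    if transition.shape != (2, 2):
        raise ValueError("choice transition must be 2x2 over (W, S)")
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    rng = as_rng(seed)
    pi = stationary_distribution(transition)
    seq = np.empty(n_trials, dtype=np.int64)
    seq[0] = rng.choice(2, p=pi)
    for t in range(1, n_trials):
        seq[t] = rng.choice(2, p=transition[seq[t - 1]])
    return np.array(CHOICES, dtype=object)[seq]


def generate_poisson_hmm_session(
    emission_rates, transition, initial, n_bins: int, bin_s: float, seed,
    n_neurons: int | None = None,
):
    """Sample a Poisson-HMM spike-count session.

    Parameters
    ----------
    emission_rates : (n_neurons, K) array of mean rates in spikes/s per state.
    transition, initial : K x K row-stochastic matrix and K-vector.
    n_bins, bin_s : number of time bins and bin width in seconds.

    Returns
    -------
    counts : (n_neurons, n_bins) int array; states : (n_bins,) int array.
    """
    emission_rates = np.asarray(emission_rates, dtype=float)
    if emission_rates.ndim != 2:
        raise ValueError("emission_rates must be 2-D (neurons x states)")
    if np.any(emission_rates < 0):
        raise ValueError("emission rates must be nonnegative")
    if n_neurons is not None and emission_rates.shape[0] != n_neurons:
        raise ValueError("emission_rates row count does not match n_neurons")
    K = emission_rates.shape[1]
    transition = check_row_stochastic(transition, "transition")
    initial = check_probability_vector(initial, "initial")
    if transition.shape != (K, K) or initial.shape != (K,):
        raise ValueError("transition/initial shapes inconsistent with emission_rates")
    rng = as_rng(seed)
    states = np.empty(n_bins, dtype=np.int64)
    states[0] = rng.choice(K, p=initial)
    for t in range(1, n_bins):
        states[t] = rng.choice(K, p=transition[states[t - 1]])
    counts = rng.poisson(emission_rates[:, states] * bin_s)
    return counts, states


@dataclass
class Cohort:
    """Generated cohort: tidy tables plus ground truth for recovery tests."""

    subjects: pd.DataFrame
    spikes: pd.DataFrame
    trials: pd.DataFrame
    licks: pd.DataFrame
    ground_truth: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
        self.spikes.to_csv(out / "spikes.tsv", sep="\t", index=False, float_format="%.4f")
        self.trials.to_csv(out / "trials.tsv", sep="\t", index=False)
        self.licks.to_csv(out / "licks.tsv", sep="\t", index=False, float_format="%.4f")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_cohort(in_dir) -> Cohort:
    """Load a cohort directory written by :meth:`Cohort.write`."""
    d = Path(in_dir)
    with open(d / "ground_truth.json") as fh:
        gt = json.load(fh)
    return Cohort(
        subjects=pd.read_csv(d / "subjects.tsv", sep="\t"),
        spikes=pd.read_csv(d / "spikes.tsv", sep="\t"),
        trials=pd.read_csv(d / "trials.tsv", sep="\t"),
        licks=pd.read_csv(d / "licks.tsv", sep="\t"),
        ground_truth=gt,
    )


def _ar1(n: int, phi: float, rng) -> np.ndarray:
    """Unit-variance AR(1) series."""
    x = np.empty(n)
    x[0] = rng.normal()
    innov = rng.normal(size=n, scale=np.sqrt(1.0 - phi**2))
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innov[t]
    return x


def generate_cohort(
    specs: list[GroupSpec] | None = None,
    task_n_trials: int = 100,
    pretask_len_s: float = 600.0,
    seed: int = 0,
) -> Cohort:
    """Generate a full synthetic cohort (pure function of specs and seed).

    Each mouse contributes one session per region (pre-task epoch of
    ``pretask_len_s`` seconds followed by the task epoch), a Markov choice
    sequence, licks, and behavioral metrics.  All randomness descends from
    ``seed`` through per-mouse child streams.
    """
    if specs is None:
        specs = default_group_specs()
    if not specs:
        raise ValueError("specs must be non-empty")
    n_total = sum(s.n_mice for s in specs)
    mouse_rngs = spawn_rngs(seed, n_total)

    subj_rows, spike_rows, trial_rows, lick_rows = [], [], [], []
    gt: dict = {"seed": int(seed), "pretask_len_s": float(pretask_len_s),
                "task_start_s": float(pretask_len_s), "mice": {}}

    midx = 0
    for spec in specs:
        for _ in range(spec.n_mice):
            rng = mouse_rngs[midx]
            mouse_id = f"m{midx:03d}"
            midx += 1
            _generate_mouse(
                mouse_id, spec, rng, task_n_trials, pretask_len_s,
                subj_rows, spike_rows, trial_rows, lick_rows, gt,
            )

    subjects = pd.DataFrame(subj_rows, columns=["mouse_id", "group", "sucrose_pref", "si_ratio"])
    spikes = pd.DataFrame(
        spike_rows, columns=["mouse_id", "session_id", "region", "neuron_id", "spike_time_s"]
    )
    trials = pd.DataFrame(
        trial_rows,
        columns=["mouse_id", "session_id", "trial_id", "reward_time_s", "choice",
                 "prev_choice", "trial_type", "intention"],
    )
    licks = pd.DataFrame(lick_rows, columns=["mouse_id", "session_id", "lick_time_s", "spout"])
    return Cohort(subjects, spikes, trials, licks, gt)


def _generate_mouse(mouse_id, spec, rng, n_trials, pretask_len_s,
                    subj_rows, spike_rows, trial_rows, lick_rows, gt):
    pref = float(np.clip(rng.normal(spec.sucrose_pref_mean, spec.sucrose_pref_sd), 0.01, 0.99))
    si = float(max(rng.normal(spec.si_ratio_mean, spec.si_ratio_sd), 0.0))
    subj_rows.append((mouse_id, spec.group_label, pref, si))

    choices = generate_choice_sequence(spec.choice_transition, n_trials, rng)
    tt = trial_type_labels(choices)
    intent = intention_labels(choices)
    task_start = pretask_len_s
    reward_times = task_start + FIRST_REWARD_S + ITI_SPACING_S * np.arange(n_trials)
    session_end = float(reward_times[-1] + 5.0)
    session_id = f"{mouse_id}_s0"

    for i in range(n_trials):
        trial_rows.append((mouse_id, session_id, i, reward_times[i], choices[i],
                           choices[i - 1] if i else "", tt[i], intent[i]))

    n_state_bins = int(np.ceil(session_end / STATE_BIN_S))
    n_sub = int(np.ceil(session_end / GAIN_BIN_S))
    sub_per_state = int(round(STATE_BIN_S / GAIN_BIN_S))

    # shared + per-region gain signals (50 ms grid, ~0.25 s correlation time)
    rho = spec.interregional_coupling
    sigma = 0.5
    shared = _ar1(n_sub, 0.8, rng)
    mouse_gt = {"group": spec.group_label, "choices": choices.tolist(),
                "trial_type": tt.tolist(), "intention": intent.tolist(),
                "reward_times_s": reward_times.tolist(), "regions": {}}

    for r_idx, region in enumerate(REGIONS):
        own = _ar1(n_sub, 0.8, rng)
        sgn = 1.0 if r_idx == 0 else np.sign(rho) if rho != 0 else 1.0
        log_gain = sigma * (np.sqrt(1.0 - abs(rho)) * own + np.sqrt(abs(rho)) * sgn * shared)
        region_gain = np.exp(log_gain - sigma**2 / 2.0)

        K = spec.n_hidden_states
        n_int = int(round(spec.intention_state_fraction * K))
        n_int = min(n_int, K - 1)  # keep at least one background state
        K_base = K - n_int
        lo, hi = spec.state_rate_range
        emission = rng.uniform(lo, hi, size=(spec.n_neurons, K))

        # sticky chain over the background states; intention states are planted
        if K_base == 1:
            base_T = np.ones((1, 1))
            base_pi = np.ones(1)
        else:
            base_T = np.full((K_base, K_base), 0.1 / (K_base - 1))
            np.fill_diagonal(base_T, 0.9)
            base_pi = np.full(K_base, 1.0 / K_base)
        _, states = generate_poisson_hmm_session(
            np.zeros((1, K_base)), base_T, base_pi, n_state_bins, STATE_BIN_S, rng
        )

        intention_trials = []
        if n_int > 0:
            planted = 0
            for i in range(1, len(choices)):
                if intent[i] != spec.intention_trial_class:
                    continue
                if rng.random() >= spec.intention_trial_fraction:
                    continue
                state_id = K_base + planted % n_int
                planted += 1
                b0 = int(reward_times[i] - 4.0)  # plant 3 of the 4 pre-reward 1-s bins
                states[b0:b0 + 3] = state_id
                intention_trials.append(i)

        # reward-modulated neurons: multiplicative gain in [reward, reward+1 s)
        n_mod = int(round(spec.reward_mod_fraction * spec.n_neurons))
        mod_ids = rng.choice(spec.n_neurons, size=n_mod, replace=False)
        prefers_sucrose = np.zeros(spec.n_neurons, dtype=bool)
        prefers_sucrose[mod_ids[: n_mod // 2]] = True
        is_mod = np.zeros(spec.n_neurons, dtype=bool)
        is_mod[mod_ids] = True

        reward_gain = np.ones((spec.n_neurons, n_sub))
        for i, rt in enumerate(reward_times):
            j0 = int(round(rt / GAIN_BIN_S))
            j1 = int(round((rt + 1.0) / GAIN_BIN_S))
            pref_gain = np.where(
                prefers_sucrose == (choices[i] == "S"),
                spec.reward_gain, spec.reward_gain_nonpref,
            )
            reward_gain[is_mod, j0:j1] = pref_gain[is_mod, None]

        state_of_sub = np.repeat(states, sub_per_state)[:n_sub]
        rates_sub = emission[:, state_of_sub] * reward_gain * region_gain[None, :]
        counts = rng.poisson(rates_sub * GAIN_BIN_S)

        for n_id in range(spec.n_neurons):
            c = counts[n_id]
            nz = np.nonzero(c)[0]
            t0 = np.repeat(nz * GAIN_BIN_S, c[nz])
            times = t0 + rng.uniform(0.0, GAIN_BIN_S, size=t0.size)
            times.sort()
            for t in times:
                spike_rows.append((mouse_id, session_id, region, n_id, float(t)))

        mouse_gt["regions"][region] = {
            "n_states": int(K),
            "states": states.tolist(),
            "emission_rates": emission.tolist(),
            "intention_state_ids": list(range(K_base, K)),
            "intention_trials": intention_trials,
            "reward_modulated_neurons": sorted(int(i) for i in mod_ids),
        }

    # licks: baseline Poisson pre-reward, consummatory burst post-reward
    for i, rt in enumerate(reward_times):
        post_rate = spec.lick_rate_sucrose if choices[i] == "S" else spec.lick_rate_water
        for lo_t, hi_t, rate in ((rt - 4.0, rt, spec.lick_rate_baseline),
                                 (rt, rt + 3.0, post_rate)):
            n_licks = rng.poisson(rate * (hi_t - lo_t))
            for t in np.sort(rng.uniform(lo_t, hi_t, size=n_licks)):
                lick_rows.append((mouse_id, f"{mouse_id}_s0", float(t), choices[i]))

    gt["mice"][mouse_id] = mouse_gt
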