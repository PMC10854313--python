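import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stresspop as sp

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Three tiny groups with short sessions; susceptible has planted
    intention states and more hidden states."""
    specs = [
        sp.GroupSpec("control", 3, np.array([[0.3, 0.7], [0.2, 0.8]]),
                     n_neurons=6, n_hidden_states=2),
        sp.GroupSpec("susceptible", 3, np.array([[0.5, 0.5], [0.45, 0.55]]),
                     n_hidden_states=4, intention_state_fraction=0.25, n_neurons=6,
                     sucrose_pref_mean=0.45, si_ratio_mean=0.5),
        sp.GroupSpec("resilient", 3, np.array([[0.2, 0.8], [0.15, 0.85]]),
                     n_neurons=6, n_hidden_states=2),
    ]
    return sp.generate_cohort(specs, task_n_trials=60, pretask_len_s=120, seed=11)


@pytest.fixture(scope="session")
def planted_intention_mouse():
    """One susceptible-like mouse with planted >=3-bin intention states,
    fitted pre-reward HMM, and intention-state report."""
    import stresspop.states as st

    specs = [sp.GroupSpec("susceptible", 1, np.array([[0.5, 0.5], [0.45, 0.55]]),
                          n_hidden_states=5, intention_state_fraction=0.25,
                          n_neurons=12, sucrose_pref_mean=0.45, si_ratio_mean=0.5)]
    coh = sp.generate_cohort(specs, task_n_trials=80, pretask_len_s=60, seed=0)
    res = st.fit_prereward_states(coh.spikes, coh.trials, "m000", "BLA",
                                  k_range=(2, 8), n_restarts=5, seed=0)
    clus = sp.cluster_states(res["model"].rates_)
    rep = sp.intention_state_report(res["viterbi"], res["intention"], clus)
    flags = st.intention_trial_flags(rep.bin_flags)
    return {"cohort": coh, "fit": res, "clustering": clus, "report": rep,
            "trial_flags": flags}
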