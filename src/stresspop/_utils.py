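"""Shared validation and RNG helpers."""

from __future__ import annotations

import numpy as np

#: canonical choice labels: water, sucrose
CHOICES = ("W", "S")
TRIAL_TYPES = ("WW", "WS", "SW", "SS")  # previous/current
REGIONS = ("BLA", "vCA1")


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rngs(seed, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent child generators from one master seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def check_row_stochastic(mat, name: str = "matrix", atol: float = 1e-8) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square, got shape {mat.shape}")
    if np.any(mat < -atol) or np.any(mat > 1 + atol):
        raise ValueError(f"{name} entries must lie in [0, 1]")
    rows = mat.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=atol):
        raise ValueError(f"{name} rows must sum to 1, got {rows}")
    return np.clip(mat, 0.0, None) / mat.sum(axis=1, keepdims=True)


def check_probability_vector(vec, name: str = "vector", atol: float = 1e-8) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if vec.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if np.any(vec < -atol):
        raise ValueError(f"{name} entries must be nonnegative")
    if not np.isclose(vec.sum(), 1.0, atol=atol):
        raise ValueError(f"{name} must sum to 1, got {vec.sum()}")
    return np.clip(vec, 0.0, None) / vec.sum()


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (principal left eigenvector)."""
    vals, vecs = np.linalg.eig(transition.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def trial_type_labels(choices: np.ndarray) -> np.ndarray:
    """Previous/current trial-type labels; first trial has no history -> ''."""
    choices = np.asarray(choices)
    out = np.empty(len(choices), dtype=object)
    out[0] = ""
    for i in range(1, len(choices)):
        out[i] = str(choices[i - 1]) + str(choices[i])
    return out


def intention_labels(choices: np.ndarray) -> np.ndarray:
    """'stay'/'switch' per trial based on the previous choice; first trial -> ''."""
    tt = trial_type_labels(choices)
    out = np.empty(len(tt), dtype=object)
    out[0] = ""
    for i in range(1, len(tt)):
        out[i] = "stay" if tt[i] in ("WW", "SS") else "switch"
    return out
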