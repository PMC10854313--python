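"""Population-geometry measures.

Embedding dimensionality of ensemble activity, treated as a cloud of
time-bin points in firing-rate space: cumulative PCA variance under random
5-neuron subsampling, the participation ratio PR = (sum lambda)^2 /
sum lambda^2 over covariance eigenvalues (scale-invariant, between 1 and N),
and the mean pairwise Pearson correlation of population vectors across time.
"""

from __future__ import annotations

import numpy as np

from ._utils import as_rng


def participation_ratio(eigenvalues) -> float:
    """PR = (sum lambda)^2 / sum lambda^2 of a covariance spectrum.

    Equals 1 when a single eigenvalue carries all the variance and N when
    all N eigenvalues are equal; invariant to scaling the spectrum.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < -1e-12):
        raise ValueError("eigenvalues must be nonnegative")
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total == 0:
        return np.nan
    return float(total**2 / np.sum(lam**2))


def zscore_rows(X: np.ndarray):
    """z-score each row (neuron) over time; rows with zero variance are flagged."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    Z = np.zeros_like(X)
    Z[ok] = (X[ok] - mu[ok]) / sd[ok]
    return Z, ok


def pca_cumulative_variance(counts: np.ndarray, subsample_size: int = 5,
                            n_subsamples: int = 1000, seed=0) -> dict:
    """Mean cumulative explained-variance curve under neuron subsampling.

    ``counts`` is (n_neurons, n_bins).  Each neuron is z-scored over the
    window (zero-variance neurons are excluded before subsampling); for each
    of ``n_subsamples`` random draws of ``subsample_size`` neurons, the
    covariance over time bins is eigendecomposed and the cumulative
    explained-variance fractions recorded; curves and participation ratios
    are averaged across subsamples.
    """
    Z, ok = zscore_rows(counts)
    Z = Z[ok]
    n_excluded = int(np.sum(~ok))
    if Z.shape[0] < subsample_size:
        raise ValueError(f"need >= {subsample_size} neurons with nonzero variance")
    rng = as_rng(seed)
    curves = np.empty((n_subsamples, subsample_size))
    prs = np.empty(n_subsamples)
    for s in range(n_subsamples):
        idx = rng.choice(Z.shape[0], size=subsample_size, replace=False)
        cov = np.cov(Z[idx])   # (T-1) normalizer
        lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
        lam = np.clip(lam, 0.0, None)
        curves[s] = np.cumsum(lam) / lam.sum()
        prs[s] = participation_ratio(lam)
    return {"cumulative_variance": curves.mean(axis=0),
            "participation_ratio": float(prs.mean()),
            "n_excluded_neurons": n_excluded}


def population_correlation_over_time(counts: np.ndarray) -> float:
    """Mean pairwise Pearson correlation of population vectors across bins.

    ``counts`` is (n_neurons, n_bins); each column is a population vector.
    Zero-variance columns are excluded; NaN when fewer than 2 usable bins.
    """
    X = np.asarray(counts, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 neurons")
    ok = X.std(axis=0) > 0
    X = X[:, ok]
    if X.shape[1] < 2:
        return np.nan
    corr = np.corrcoef(X.T)
    iu = np.triu_indices(corr.shape[0], k=1)
    return float(corr[iu].mean())


def geometry_features(pretask_counts: np.ndarray, subsample_size: int = 5,
                      n_subsamples: int = 1000, seed=0) -> dict:
    """Per-mouse geometry summary used downstream for group-identity decoding."""
    pca = pca_cumulative_variance(pretask_counts, subsample_size, n_subsamples, seed)
    return {
        **{f"cumvar_pc{i + 1}": float(v)
           for i, v in enumerate(pca["cumulative_variance"][:3])},
        "participation_ratio": pca["participation_ratio"],
        "mean_time_correlation": population_correlation_over_time(pretask_counts),
        "spike_count_mean": float(pretask_counts.mean()),
        "spike_count_sd": float(pretask_counts.std()),
    }
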