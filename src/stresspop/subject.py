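"""Per-mouse group-identity decoding and low-dimensional visualization.

A Mahalanobis-like nearest-centroid binary decoder: the test point's
Euclidean distance to each training group's centroid is divided by the
variance of that group's training points projected on the test-to-centroid
direction, and the smaller scaled distance wins.  Cross-validation balances
group sizes by subsampling and holds out one mouse per iteration.  Feature
importance is assessed by leave-one-feature-out re-decoding; classical MDS
embeds the feature-space dissimilarities for visualization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._utils import as_rng, spawn_rngs

#: the 4 behavioral and 10 neural features used for group-identity decoding
BEHAVIORAL_FEATURES = ["DI_pre", "DI_post", "sucrose_pref", "si_ratio"]
NEURAL_FEATURES = ["cumvar_pc1", "cumvar_pc2", "cumvar_pc3",
                   "prop_clusters_0.1", "prop_clusters_0.2", "prop_clusters_0.3",
                   "prop_clusters_0.4", "prop_clusters_0.5",
                   "spike_count_mean", "spike_count_sd"]


class MahalanobisNearestCentroid(BaseEstimator, ClassifierMixin):
    """Nearest-centroid classifier with direction-projected variance scaling.

    For test point x and group g with centroid mu_g, let u = (x - mu_g) /
    ||x - mu_g||; the decision distance is d_g = ||x - mu_g|| / s_g where
    s_g is the variance (or sd, with ``use_std=True``) of group g's training
    points projected on u.  x is assigned to argmin d_g.  A test point
    coinciding with a centroid has distance 0; a zero projected variance
    falls back to the pooled variance across both training groups; exact
    ties are broken uniformly at random.
    """

    def __init__(self, use_std: bool = False, random_state=None):
        self.use_std = use_std
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or not np.all(np.isfinite(X)):
            raise ValueError("X must be a finite 2-D array")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary decoder: exactly 2 classes required")
        self.X_ = {c: X[y == c] for c in self.classes_}
        for c in self.classes_:
            if len(self.X_[c]) < 2:
                raise ValueError("need at least 2 training mice per group")
        self.centroids_ = {c: self.X_[c].mean(axis=0) for c in self.classes_}
        self._rng = as_rng(self.random_state)
        return self

    def _distance(self, x, c):
        mu = self.centroids_[c]
        diff = x - mu
        norm = np.linalg.norm(diff)
        if norm == 0:
            return 0.0
        u = diff / norm
        proj = (self.X_[c] - mu) @ u
        spread = proj.std()
        if self.use_std:
            s = spread
        else:
            s = spread**2
        if s == 0:  # fallback: pooled spread across both training groups
            pooled = np.concatenate([
                (self.X_[cc] - self.centroids_[cc]) @ u for cc in self.classes_])
            s = pooled.std() if self.use_std else pooled.std()**2
            if s == 0:
                return norm  # fully degenerate: fall back to raw distance
        return norm / s

    def predict(self, X):
        check_is_fitted(self, "centroids_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = []
        for x in X:
            d = np.array([self._distance(x, c) for c in self.classes_])
            if d[0] == d[1]:
                out.append(self.classes_[self._rng.integers(2)])
            else:
                out.append(self.classes_[int(np.argmin(d))])
        return np.array(out)


def mahalanobis_binary_decode(X, y, n_cv: int = 1000, seed=0, use_std: bool = False,
                              minmax_columns=None, holdout_fraction: float | None = None) -> dict:
    """Cross-validated group-identity decoding accuracy for one group pair.

    Per CV iteration: groups are balanced by subsampling to the smaller
    size, one mouse (or a ``holdout_fraction`` of mice) is held out, the
    decoder is fit on the rest, and the held-out prediction(s) scored.
    ``minmax_columns`` are min-max scaled on the training mice only (the
    test mouse is transformed and clipped to [0, 1]).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("exactly 2 groups required")
    idx = {c: np.flatnonzero(y == c) for c in classes}
    m = min(len(v) for v in idx.values())
    if m < 2:
        raise ValueError("need at least 2 mice per group")
    rngs = spawn_rngs(seed, n_cv)
    correct = []
    for r in rngs:
        bal = np.concatenate([r.permutation(idx[c])[:m] for c in classes])
        if holdout_fraction is None:
            test = bal[r.integers(len(bal)):][:1]
        else:
            n_test = max(int(round(holdout_fraction * len(bal))), 1)
            test = r.permutation(bal)[:n_test]
        train = np.setdiff1d(bal, test)
        if len(np.unique(y[train])) < 2:
            continue
        Xtr, Xte = X[train].copy(), X[test].copy()
        if minmax_columns is not None:
            for j in minmax_columns:
                lo, hi = Xtr[:, j].min(), Xtr[:, j].max()
                span = hi - lo if hi > lo else 1.0
                Xtr[:, j] = (Xtr[:, j] - lo) / span
                Xte[:, j] = np.clip((Xte[:, j] - lo) / span, 0.0, 1.0)
        clf = MahalanobisNearestCentroid(use_std=use_std,
                                         random_state=r.integers(2**31)).fit(Xtr, y[train])
        correct.extend(clf.predict(Xte) == y[test])
    return {"accuracy": float(np.mean(correct)), "n_cv": len(correct),
            "classes": tuple(classes)}


def feature_importance_by_removal(X, y, n_cv: int = 1000, seed=0,
                                  feature_names=None, **kwargs) -> pd.DataFrame:
    """Decoding accuracy with each feature removed in turn.

    The accuracy drop relative to the full feature set measures that
    feature's importance.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("cannot remove features from a single-feature set")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    mm = kwargs.pop("minmax_columns", None)
    full = mahalanobis_binary_decode(X, y, n_cv=n_cv, seed=seed,
                                     minmax_columns=mm, **kwargs)["accuracy"]
    rows = []
    for j in range(X.shape[1]):
        keep = [k for k in range(X.shape[1]) if k != j]
        sub_mm = None if mm is None else [keep.index(c) for c in mm if c != j]
        acc = mahalanobis_binary_decode(X[:, keep], y, n_cv=n_cv, seed=seed,
                                        minmax_columns=sub_mm, **kwargs)["accuracy"]
        rows.append({"feature": feature_names[j], "accuracy": acc,
                     "drop": full - acc})
    out = pd.DataFrame(rows)
    out.attrs["full_accuracy"] = full
    return out


def mds_embed(X, n_components: int = 2, group_labels=None) -> np.ndarray:
    """Classical (Torgerson) MDS of Euclidean dissimilarities.

    Double-centers the squared Euclidean distance matrix and
    eigendecomposes it; coordinates are the top eigenvectors scaled by the
    square roots of their (nonnegative) eigenvalues.  With
    ``group_labels``, each group's rows are first normalized by the group's
    variance.  Orientation is unconstrained.  All-identical points yield a
    degenerate (all-zero) embedding with a warning.
    """
    import warnings

    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if group_labels is not None:
        X = X.copy()
        for g in np.unique(np.asarray(group_labels)):
            sel = np.asarray(group_labels) == g
            v = X[sel].var(axis=0).mean()
            if v > 0:
                X[sel] = X[sel] / v
    D2 = np.sum((X[:, None, :] - X[None, :, :])**2, axis=-1)
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    lam, vec = np.linalg.eigh(B)
    order = np.argsort(lam)[::-1][:n_components]
    lam_top = np.clip(lam[order], 0.0, None)
    if lam_top.max(initial=0.0) == 0.0:
        warnings.warn("degenerate MDS embedding: all points identical")
    return vec[:, order] * np.sqrt(lam_top)
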