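"""Poisson hidden Markov models of population spike counts.

A hidden state is a latent population activity pattern; given state j, the
N neurons' counts in a bin are independent Poisson with mean rates given by
column j of the emission matrix.  States evolve as a first-order Markov
chain (transition matrix T, initial distribution A).  Models are fit by
Baum-Welch EM with multiple restarts per candidate state count K, and the
model order is selected by the Akaike Information Criterion over a K range,
with n_params = K*N (emissions) + K*(K-1) (transitions) + (K-1) (initial).

The EM core is hmmlearn's PoissonHMM; this estimator owns initialization
(k-means on count vectors plus jitter, sticky transitions), restarts, AIC
selection, rate scaling by the bin width, and trial-boundary handling (each
trial's chain restarts from the initial distribution via sequence lengths).
"""

from __future__ import annotations

import warnings
from collections import deque

import numpy as np
from hmmlearn.hmm import PoissonHMM as _HmmlearnPoissonHMM
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans


class _FullHistoryMonitor:
    """Convergence monitor that records the full EM log-likelihood trace."""

    def __init__(self, tol, n_iter, verbose=False):
        self.tol = tol
        self.n_iter = n_iter
        self.verbose = verbose
        self.history = deque()
        self.iter = 0

    def _reset(self):
        self.history.clear()
        self.iter = 0

    def report(self, log_prob):
        self.history.append(log_prob)
        self.iter += 1

    @property
    def converged(self):
        if self.iter == self.n_iter:
            return True
        if len(self.history) >= 2:
            return (self.history[-1] - self.history[-2]) < self.tol
        return False


def _validate_counts(X) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("counts must be 2-D (bins x neurons)")
    if not np.issubdtype(X.dtype, np.integer):
        if not np.allclose(X, np.round(X)):
            raise ValueError("spike counts must be integers")
        X = np.round(X).astype(np.int64)
    if np.any(X < 0):
        raise ValueError("spike counts must be nonnegative")
    return X


class PoissonHMMStates(BaseEstimator):
    """Poisson-emission HMM with restarts and AIC model-order selection.

    Parameters
    ----------
    k_range : (int, int)
        Inclusive range of candidate state counts.  The desk-scale default
        (2, 15) can be widened to (2, 50).
    n_restarts : int
        EM restarts per K; the best log-likelihood wins.
    max_iter, tol : EM stopping rule.
    bin_s : bin width in seconds; fitted rates are reported in spikes/s.
    sticky : initial self-transition probability.

    Fitted attributes
    -----------------
    n_states_, startprob_, transmat_, rates_ (n_neurons x K, spikes/s),
    lambdas_ (K x n_neurons, counts/bin), log_likelihood_, aic_, n_params_,
    model_selection_ (per-K log-likelihood and AIC),
    log_likelihood_history_ (EM trace of the winning fit), degenerate_.
    """

    def __init__(self, k_range=(2, 15), n_restarts: int = 5, max_iter: int = 100,
                 tol: float = 1e-3, bin_s: float = 1.0, sticky: float = 0.9,
                 random_state=None):
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.bin_s = bin_s
        self.sticky = sticky
        self.random_state = random_state

    def _init_model(self, X, k, rng):
        lam = KMeans(n_clusters=k, n_init=1,
                     random_state=int(rng.integers(2**31))).fit(X).cluster_centers_
        lam = np.maximum(lam + rng.uniform(0.0, 0.5, size=lam.shape), 1e-3)
        if k == 1:
            trans = np.ones((1, 1))
        else:
            trans = np.full((k, k), (1.0 - self.sticky) / (k - 1))
            np.fill_diagonal(trans, self.sticky)
        m = _HmmlearnPoissonHMM(n_components=k, n_iter=self.max_iter, tol=self.tol,
                                init_params="", params="stl",
                                random_state=int(rng.integers(2**31)))
        m.monitor_ = _FullHistoryMonitor(self.tol, self.max_iter)
        m.startprob_ = np.full(k, 1.0 / k)
        m.transmat_ = trans
        m.lambdas_ = lam
        return m

    def fit(self, X, lengths=None):
        """Fit on counts X of shape (n_bins, n_neurons).

        ``lengths`` splits X into independent sequences (e.g. trials), each
        restarting from the initial state distribution.
        """
        X = _validate_counts(X)
        self.degenerate_ = bool(np.all(X == 0))
        if self.degenerate_:
            warnings.warn("all-zero spike counts: degenerate HMM fit")
        rng = np.random.default_rng(self.random_state)
        lo, hi = self.k_range
        hi = min(hi, X.shape[0])  # cannot support more states than bins
        rows = []
        best = None
        n_neurons = X.shape[1]
        for k in range(lo, hi + 1):
            k_best = None
            for _ in range(self.n_restarts):
                m = self._init_model(X, k, rng)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    m.fit(X, lengths=lengths)
                    ll = m.score(X, lengths=lengths)
                if k_best is None or ll > k_best[0]:
                    k_best = (ll, m)
            ll, m = k_best
            n_params = k * n_neurons + k * (k - 1) + (k - 1)
            aic = 2.0 * n_params - 2.0 * ll
            rows.append({"K": k, "log_likelihood": ll, "n_params": n_params, "aic": aic})
            if best is None or aic < best[0]:
                best = (aic, m, ll, n_params)
        aic, m, ll, n_params = best
        self.model_ = m
        self.n_states_ = m.n_components
        self.startprob_ = m.startprob_
        self.transmat_ = m.transmat_
        self.lambdas_ = m.lambdas_                 # (K, N) counts per bin
        self.rates_ = m.lambdas_.T / self.bin_s    # (N, K) spikes per second
        self.log_likelihood_ = float(ll)
        self.n_params_ = int(n_params)
        self.aic_ = float(aic)
        self.model_selection_ = rows
        self.log_likelihood_history_ = np.asarray(m.monitor_.history, dtype=float)
        return self

    def predict(self, X, lengths=None) -> np.ndarray:
        """Viterbi most-likely state path."""
        return self.model_.predict(_validate_counts(X), lengths=lengths)

    def predict_proba(self, X, lengths=None) -> np.ndarray:
        """Forward-backward posterior state probabilities (rows sum to 1)."""
        return self.model_.predict_proba(_validate_counts(X), lengths=lengths)

    def score(self, X, lengths=None) -> float:
        return float(self.model_.score(_validate_counts(X), lengths=lengths))

    def smooth(self, X, lengths=None) -> np.ndarray:
        """Posterior-smoothed activity (bins x neurons, spikes/s)."""
        gamma = self.predict_proba(X, lengths=lengths)
        return smooth_observations(gamma, self.rates_)


def smooth_observations(posterior, state_means) -> np.ndarray:
    """Posterior-weighted mixture of state emission means.

    ``posterior`` is (n_bins, K) with rows summing to 1; ``state_means`` is
    (n_neurons, K).  Bin t's smoothed activity is sum_j gamma_t(j) * mu_j, a
    convex combination of state mean vectors.
    """
    gamma = np.asarray(posterior, dtype=float)
    mu = np.atleast_2d(np.asarray(state_means, dtype=float))
    if gamma.ndim == 1:
        gamma = gamma[None, :]
    if not np.allclose(gamma.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("posterior rows must sum to 1")
    if np.any(gamma < -1e-12):
        raise ValueError("posterior entries must be nonnegative")
    return gamma @ mu.T


def match_states(true_rates, fitted_rates) -> np.ndarray:
    """Optimal fitted-to-true state assignment (evaluation helper).

    Hungarian assignment maximizing the correlation between emission-rate
    vectors; returns ``perm`` with ``perm[fitted_state] = true_state``.
    """
    from scipy.optimize import linear_sum_assignment

    true_rates = np.asarray(true_rates, dtype=float)    # (N, K_true)
    fitted_rates = np.asarray(fitted_rates, dtype=float)  # (N, K_fit)
    k_fit = fitted_rates.shape[1]
    cost = np.zeros((k_fit, true_rates.shape[1]))
    for i in range(k_fit):
        for j in range(true_rates.shape[1]):
            a, b = fitted_rates[:, i], true_rates[:, j]
            if a.std() == 0 or b.std() == 0:
                cost[i, j] = -np.mean(np.abs(a - b))
            else:
                cost[i, j] = np.corrcoef(a, b)[0, 1]
    row, col = linear_sum_assignment(-cost)
    perm = np.full(k_fit, -1, dtype=int)
    perm[row] = col
    return perm
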