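"""Latent class analysis for binary indicators.

A latent class model for D binary conditions is a K-component mixture of
conditionally independent Bernoulli variables:

    P(x) = sum_k pi_k prod_d theta_kd^x_d (1 - theta_kd)^(1 - x_d)

estimated by maximum likelihood via EM.  The E-step computes posterior
class-membership probabilities for each patient; the M-step re-estimates
class weights ``pi`` and item probabilities ``theta`` as posterior-weighted
means.  Patients are assigned to the class with the highest posterior
probability.

Model selection across K uses BIC, sample-size-adjusted BIC and the
relative-entropy diagnostic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import logsumexp, xlogy
from sklearn.base import BaseEstimator, ClusterMixin

from .cohort import validate_binary_matrix

_EPS = 1e-6  # flooring for item probabilities and class weights


def _log_bernoulli(X: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """(N, K) matrix of per-class conditional log-likelihoods."""
    log_t = np.log(theta)
    log_1mt = np.log1p(-theta)
    return X @ (log_t - log_1mt).T + log_1mt.sum(axis=1)


class LatentClassAnalysis(ClusterMixin, BaseEstimator):
    """Bernoulli-mixture latent class model fitted by EM.

    Parameters
    ----------
    n_classes : int, default=2
        Number of latent classes K.
    n_restarts : int, default=10
        Random restarts; the solution with the highest log-likelihood is
        kept (ties broken by lowest restart index).
    tol : float, default=1e-6
        Convergence threshold on the relative log-likelihood change.
    max_iter : int, default=500
        Maximum EM iterations per restart; non-convergence sets
        ``converged_ = False`` with a warning, it is not an error.
    random_state : int or None
        Seed for the restart initialisations.

    Attributes
    ----------
    weights_ : ndarray of shape (n_classes,)
        Class mixing proportions pi, summing to 1.
    item_probs_ : ndarray of shape (n_classes, n_conditions)
        Within-class condition probabilities theta.
    posterior_ : ndarray of shape (n_patients, n_classes)
        Posterior membership probabilities on the training data; rows sum
        to 1.
    labels_ : ndarray of shape (n_patients,)
        Modal class assignment (0-based).
    log_likelihood_ : float
        Maximised log-likelihood.
    log_likelihood_history_ : ndarray
        Per-iteration log-likelihood of the winning restart (non-decreasing).
    n_parameters_ : int
        (K - 1) + K * D free parameters.
    bic_, abic_, entropy_ : float
        Model-selection diagnostics (see :func:`lca_selection`).
    """

    def __init__(self, n_classes: int = 2, n_restarts: int = 10, tol: float = 1e-6,
                 max_iter: int = 500, random_state: int | None = None):
        self.n_classes = n_classes
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- EM core ----------------------------------------------------------
    def _em_once(self, X: np.ndarray, rng: np.random.Generator):
        n, d = X.shape
        k = self.n_classes
        pi = np.full(k, 1.0 / k)
        theta = rng.uniform(0.2, 0.8, size=(k, d))
        history = []
        ll_prev = -np.inf
        converged = False
        for _ in range(self.max_iter):
            # E-step
            log_joint = np.log(pi) + _log_bernoulli(X, theta)
            log_norm = logsumexp(log_joint, axis=1)
            resp = np.exp(log_joint - log_norm[:, None])
            ll = log_norm.sum()
            history.append(ll)
            if ll - ll_prev <= self.tol * (abs(ll_prev) + 1e-12) and np.isfinite(ll_prev):
                converged = True
                break
            ll_prev = ll
            # M-step, with flooring against degenerate classes
            nk = resp.sum(axis=0)
            pi = np.clip(nk / n, _EPS, None)
            pi = pi / pi.sum()
            theta = np.clip(resp.T @ X / np.maximum(nk, _EPS)[:, None],
                            _EPS, 1.0 - _EPS)
        return ll, pi, theta, np.asarray(history), converged

    def fit(self, X, y=None):
        X = validate_binary_matrix(X)
        n, d = X.shape
        if n <= self.n_classes:
            raise ValueError("need more patients than classes")
        rng = np.random.default_rng(self.random_state)
        best = None
        for restart in range(self.n_restarts):
            ll, pi, theta, history, converged = self._em_once(X, rng)
            if best is None or ll > best[0]:
                best = (ll, pi, theta, history, converged)
        ll, pi, theta, history, converged = best
        if not converged:
            warnings.warn("EM did not converge within max_iter", RuntimeWarning)
        self.converged_ = converged
        self.weights_ = pi
        self.item_probs_ = theta
        self.log_likelihood_ = float(ll)
        self.log_likelihood_history_ = history
        self.posterior_ = self.predict_proba(X)
        self.labels_ = self.posterior_.argmax(axis=1)
        k = self.n_classes
        self.n_parameters_ = (k - 1) + k * d
        self.bic_ = -2.0 * ll + self.n_parameters_ * np.log(n)
        self.abic_ = -2.0 * ll + self.n_parameters_ * np.log((n + 2.0) / 24.0)
        self.entropy_ = self._relative_entropy(self.posterior_)
        return self

    @staticmethod
    def _relative_entropy(posterior: np.ndarray) -> float:
        """1 - (sum of posterior Shannon entropies) / (N log K); 1 means
        perfectly certain classification.  Defined as 1 for K = 1."""
        n, k = posterior.shape
        if k == 1:
            return 1.0
        h = -xlogy(posterior, posterior).sum()
        return float(1.0 - h / (n * np.log(k)))

    def predict_proba(self, X) -> np.ndarray:
        X = validate_binary_matrix(X)
        log_joint = np.log(self.weights_) + _log_bernoulli(X, self.item_probs_)
        return np.exp(log_joint - logsumexp(log_joint, axis=1)[:, None])

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X, y=None) -> float:
        """Total log-likelihood of ``X`` under the fitted model."""
        X = validate_binary_matrix(X)
        log_joint = np.log(self.weights_) + _log_bernoulli(X, self.item_probs_)
        return float(logsumexp(log_joint, axis=1).sum())


def lca_selection(cohort, k_range, n_restarts: int = 10, tol: float = 1e-6,
                  max_iter: int = 500, random_state: int | None = None):
    """Fit one latent class model per K and tabulate selection diagnostics.

    Returns ``(table, models)`` where ``table`` has one row per K with
    columns ``k, log_likelihood, n_parameters, bic, abic, entropy`` and
    ``models`` maps K to the fitted :class:`LatentClassAnalysis`.
    """
    k_range = list(k_range)
    rows = []
    models = {}
    seeds = np.random.SeedSequence(random_state).generate_state(len(k_range))
    for i, k in enumerate(k_range):
        model = LatentClassAnalysis(
            n_classes=k, n_restarts=n_restarts, tol=tol, max_iter=max_iter,
            random_state=int(seeds[i]) & 0x7FFFFFFF).fit(cohort)
        models[k] = model
        rows.append({
            "k": k,
            "log_likelihood": model.log_likelihood_,
            "n_parameters": model.n_parameters_,
            "bic": model.bic_,
            "abic": model.abic_,
            "entropy": model.entropy_,
        })
    return pd.DataFrame(rows), models
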