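"""Compiled 2-D Gaussian-mixture EM used by the pairwise engine.

The all-pairs similarity pass fits mixtures with k = 1..max_k to every gene
pair, which makes the EM the computational bottleneck of the whole workflow.
This module is a small, dedicated implementation for the bivariate case:
full covariance matrices (closed-form 2x2 inverses), k-means++/Lloyd
initialisation, and convergence on the change in mean per-sample
log-likelihood. It is deterministic for a given seed.

Parameter count for the BIC is 6k - 1 per k-component model
(k-1 mixing weights, 2k means, 3k covariance entries).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

_LOG_2PI = math.log(2.0 * math.pi)


@njit(cache=True)
def _kmeans_labels(X, k, seed):
    """k-means++ seeding followed by at most 10 Lloyd iterations."""
    n = X.shape[0]
    np.random.seed(seed)
    centers = np.empty((k, 2))
    centers[0] = X[np.random.randint(0, n)]
    d2 = np.empty(n)
    for c in range(1, k):
        for i in range(n):
            best = 1e300
            for cc in range(c):
                dx = X[i, 0] - centers[cc, 0]
                dy = X[i, 1] - centers[cc, 1]
                v = dx * dx + dy * dy
                if v < best:
                    best = v
            d2[i] = best
        tot = d2.sum()
        if tot <= 0.0:
            centers[c] = X[np.random.randint(0, n)]
            continue
        r = np.random.random() * tot
        acc = 0.0
        pick = n - 1
        for i in range(n):
            acc += d2[i]
            if acc >= r:
                pick = i
                break
        centers[c] = X[pick]
    labels = np.zeros(n, np.int64)
    for _ in range(10):
        changed = False
        for i in range(n):
            best = 1e300
            bi = 0
            for cc in range(k):
                dx = X[i, 0] - centers[cc, 0]
                dy = X[i, 1] - centers[cc, 1]
                v = dx * dx + dy * dy
                if v < best:
                    best = v
                    bi = cc
            if labels[i] != bi:
                labels[i] = bi
                changed = True
        counts = np.zeros(k)
        sums = np.zeros((k, 2))
        for i in range(n):
            counts[labels[i]] += 1.0
            sums[labels[i], 0] += X[i, 0]
            sums[labels[i], 1] += X[i, 1]
        for cc in range(k):
            if counts[cc] > 0:
                centers[cc, 0] = sums[cc, 0] / counts[cc]
                centers[cc, 1] = sums[cc, 1] / counts[cc]
        if not changed:
            break
    return labels


@njit(cache=True, fastmath=True)
def _em_fit(X, k, seed, tol, max_iter, reg_covar):
    """EM for a k-component full-covariance bivariate Gaussian mixture.

    Returns (weights, means, covs[xx,yy,xy], responsibilities,
    total log-likelihood, converged flag, iterations used).
    """
    n = X.shape[0]
    labels0 = _kmeans_labels(X, k, seed)
    w = np.full(k, 1.0 / k)
    mu = np.zeros((k, 2))
    cov = np.zeros((k, 3))
    resp = np.zeros((n, k))
    for i in range(n):
        resp[i, labels0[i]] = 1.0
    ll_old = -1e300
    ll = -1e300
    converged = False
    it = 0
    for it in range(max_iter):
        # M step
        for c in range(k):
            nk = 0.0
            mx = 0.0
            my = 0.0
            for i in range(n):
                nk += resp[i, c]
                mx += resp[i, c] * X[i, 0]
                my += resp[i, c] * X[i, 1]
            if nk < 1e-10:
                nk = 1e-10
            mx /= nk
            my /= nk
            sxx = 0.0
            syy = 0.0
            sxy = 0.0
            for i in range(n):
                dx = X[i, 0] - mx
                dy = X[i, 1] - my
                sxx += resp[i, c] * dx * dx
                syy += resp[i, c] * dy * dy
                sxy += resp[i, c] * dx * dy
            w[c] = nk / n
            mu[c, 0] = mx
            mu[c, 1] = my
            cov[c, 0] = sxx / nk + reg_covar
            cov[c, 1] = syy / nk + reg_covar
            cov[c, 2] = sxy / nk
        # E step (log-sum-exp per sample)
        ll = 0.0
        for i in range(n):
            m = -1e300
            for c in range(k):
                det = cov[c, 0] * cov[c, 1] - cov[c, 2] * cov[c, 2]
                if det < 1e-300:
                    det = 1e-300
                dx = X[i, 0] - mu[c, 0]
                dy = X[i, 1] - mu[c, 1]
                q = (cov[c, 1] * dx * dx - 2.0 * cov[c, 2] * dx * dy
                     + cov[c, 0] * dy * dy) / det
                lp = math.log(w[c]) - 0.5 * (math.log(det) + q) - _LOG_2PI
                resp[i, c] = lp
                if lp > m:
                    m = lp
            s = 0.0
            for c in range(k):
                s += math.exp(resp[i, c] - m)
            lse = m + math.log(s)
            ll += lse
            for c in range(k):
                resp[i, c] = math.exp(resp[i, c] - lse)
        ll /= n
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    return w, mu, cov, resp, ll * n, converged, it + 1


@dataclass
class MixtureFit:
    """One fitted k-component mixture on a gene pair's 2-D scatter."""

    k: int
    weights: np.ndarray
    means: np.ndarray        # (k, 2)
    covariances: np.ndarray  # (k, 3) as [xx, yy, xy]
    responsibilities: np.ndarray
    log_likelihood: float
    converged: bool
    n_iter: int

    @property
    def n_parameters(self) -> int:
        return 6 * self.k - 1

    def bic(self, n: int) -> float:
        return -2.0 * self.log_likelihood + self.n_parameters * math.log(n)

    @property
    def labels(self) -> np.ndarray:
        """Hard assignment by maximum posterior responsibility."""
        return np.argmax(self.responsibilities, axis=1)


def fit_mixture(X: np.ndarray, k: int, seed: int, tol: float = 1e-5,
                max_iter: int = 300, reg_covar: float = 1e-6) -> MixtureFit:
    """Fit one k-component mixture; deterministic for a given seed."""
    X = np.ascontiguousarray(X, dtype=float)
    w, mu, cov, resp, ll, converged, n_iter = _em_fit(
        X, k, seed & 0x7FFFFFFF, tol, max_iter, reg_covar
    )
    return MixtureFit(k=k, weights=w, means=mu, covariances=cov,
                      responsibilities=resp, log_likelihood=ll,
                      converged=bool(converged), n_iter=int(n_iter))
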