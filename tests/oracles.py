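"""Independent re-implementations used as oracles by the test suite.

Each function computes the same quantity as the package by a deliberately
different route (sorting instead of percentile calls, bisection on erf
instead of scipy quantiles, explicit density sums instead of the EM's own
bookkeeping) so that agreement is informative.
"""

import math

import numpy as np
from scipy import stats
from scipy.special import logsumexp


def sorted_quantile(values, q):
    """Quantile by explicit sorting + linear interpolation (type 7)."""
    v = np.sort(np.asarray(values, float))
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def tukey_flags(values):
    q1 = sorted_quantile(values, 0.25)
    q3 = sorted_quantile(values, 0.75)
    iqr = q3 - q1
    v = np.asarray(values, float)
    return (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)


def normal_quantile(q, tol=1e-12):
    """Standard-normal quantile by bisection on erf (independent of scipy)."""
    lo, hi = -10.0, 10.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if 0.5 * (1.0 + math.erf(mid / math.sqrt(2.0))) < q:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def min_samples(r, alpha, power):
    z = normal_quantile(1 - alpha / 2) + normal_quantile(power)
    return math.ceil((z / math.atanh(r)) ** 2 + 3)


def mixture_bic(fit, X):
    """BIC of a fitted 2-D mixture, recomputed from its parameters."""
    n = len(X)
    comp_ll = np.empty((n, fit.k))
    for c in range(fit.k):
        cov = np.array([[fit.covariances[c, 0], fit.covariances[c, 2]],
                        [fit.covariances[c, 2], fit.covariances[c, 1]]])
        comp_ll[:, c] = np.log(fit.weights[c]) + \
            stats.multivariate_normal(fit.means[c], cov).logpdf(X)
    ll = logsumexp(comp_ll, axis=1).sum()
    return -2.0 * ll + (6 * fit.k - 1) * np.log(n), ll


def fisher_z_power_mc(rho, n, alpha, reps, seed):
    """Monte-Carlo power of the Fisher-z test of zero correlation."""
    rng = np.random.default_rng(seed)
    z_crit = stats.norm.ppf(1 - alpha / 2)
    x = rng.standard_normal((reps, n))
    e = rng.standard_normal((reps, n))
    y = rho * x + np.sqrt(1 - rho ** 2) * e
    x = x - x.mean(axis=1, keepdims=True)
    y = y - y.mean(axis=1, keepdims=True)
    r = (x * y).sum(axis=1) / np.sqrt((x ** 2).sum(axis=1)
                                      * (y ** 2).sum(axis=1))
    z = np.abs(np.arctanh(r)) * np.sqrt(n - 3)
    return float((z > z_crit).mean())


def fisher_z_power_theory(rho, n, alpha):
    z_crit = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(np.arctanh(rho) * np.sqrt(n - 3) - z_crit))
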