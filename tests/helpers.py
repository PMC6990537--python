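"""Independent oracles used by the test suite.

These deliberately avoid the package's model machinery: the Weibull
proportional-hazards fitter works on its own (log-scale, log-shape)
parameterization straight from the density, and the brute-force partial
likelihood enumerates risk sets directly from the written formula.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def weibull_ph_mle(t, d, X):
    """Maximum likelihood for h(t|x) = lam * p * t^(p-1) * exp(x beta).

    Independent of the spline machinery.  Returns (log lam, p, beta,
    loglik) from a direct maximization of
    sum d [ln lam + ln p + (p-1) ln t + x beta] - lam t^p exp(x beta).
    """
    t = np.asarray(t, float)
    d = np.asarray(d, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != t.size:
        X = X.T
    k = X.shape[1]
    logt = np.log(t)

    def negll(par):
        loglam, logp = par[0], par[1]
        beta = par[2:]
        p = np.exp(logp)
        lam = np.exp(loglam)
        eta = X @ beta
        H = lam * t**p * np.exp(eta)
        ll = np.sum(d * (loglam + logp + (p - 1) * logt + eta)) - np.sum(H)
        g = np.empty(2 + k)
        g[0] = np.sum(d) - np.sum(H)
        g[1] = p * (np.sum(d * (1 / p + logt)) - np.sum(H * logt))
        g[2:] = X.T @ (d - H)
        return -ll, -g

    x0 = np.zeros(2 + k)
    x0[0] = np.log(d.sum() / t.sum())
    res = optimize.minimize(negll, x0, jac=True, method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 1000})
    # Newton-ish polish via high-accuracy BFGS restart
    res = optimize.minimize(negll, res.x, jac=True, method="BFGS",
                            options={"gtol": 1e-11, "maxiter": 1000})
    loglam, logp = res.x[0], res.x[1]
    return loglam, float(np.exp(logp)), res.x[2:], -res.fun


def brute_force_cox_loglik(beta, start, stop, d, w, x):
    """Weighted Breslow partial log likelihood by direct risk-set
    enumeration (O(n^2); small fixtures only)."""
    beta = float(beta)
    ll = 0.0
    r = w * np.exp(x * beta)
    for i in np.nonzero(d > 0)[0]:
        t = stop[i]
        risk = (start < t) & (t <= stop)
        ll += w[i] * (x[i] * beta - np.log(np.sum(r[risk])))
    return ll


def empirical_cif(time, event, cause, t_eval):
    """Empirical CIF under no censoring: fraction failing from the cause
    by each evaluation time."""
    t_eval = np.atleast_1d(t_eval)
    return np.array([np.mean((time <= te) & (event == cause)) for te in t_eval])
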