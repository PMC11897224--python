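"""Independent brute-force oracles used by the test suite.

Deliberately written with naive enumeration / direct formulas, sharing no
code with the package implementation.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def efron_loglik(beta, X, entry, exit_, event):
    """Explicitly enumerated Efron partial log-likelihood with delayed entry."""
    beta = np.atleast_1d(beta)
    ll = 0.0
    for u in sorted(set(exit_[event == 1])):
        D = [i for i in range(len(entry)) if exit_[i] == u and event[i] == 1]
        R = [i for i in range(len(entry)) if entry[i] < u <= exit_[i]]
        d = len(D)
        sum_risk = sum(np.exp(X[i] @ beta) for i in R)
        sum_dead = sum(np.exp(X[i] @ beta) for i in D)
        for i in D:
            ll += float(X[i] @ beta)
        for l in range(d):
            ll -= np.log(sum_risk - (l / d) * sum_dead)
    return float(ll)


def maximize_efron(X, entry, exit_, event, p):
    """Numerically maximise the enumerated likelihood (Nelder-Mead, tight)."""
    res = optimize.minimize(
        lambda b: -efron_loglik(b, X, entry, exit_, event),
        x0=np.zeros(p), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000,
                 "maxfev": 20000},
    )
    # polish from the simplex optimum
    res2 = optimize.minimize(
        lambda b: -efron_loglik(b, X, entry, exit_, event),
        x0=res.x, method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 20000,
                 "maxfev": 20000},
    )
    return res2.x, -res2.fun


def bh_direct(p):
    """Direct step-up formula: p_(i) * n / i with trailing cumulative minimum."""
    p = list(map(float, p))
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj_sorted = [p[order[i]] * n / (i + 1) for i in range(n)]
    for i in range(n - 2, -1, -1):
        adj_sorted[i] = min(adj_sorted[i], adj_sorted[i + 1])
    out = [0.0] * n
    for i in range(n):
        out[order[i]] = min(adj_sorted[i], 1.0)
    return np.array(out)


def pca_eigh(X):
    """Eigendecomposition of the empirical correlation matrix.

    Returns (variance fractions, loading matrix with columns as components),
    ordered by decreasing eigenvalue, signs unconstrained.
    """
    R = np.corrcoef(X, rowvar=False)
    vals, vecs = np.linalg.eigh(R)
    idx = np.argsort(vals)[::-1]
    vals, vecs = vals[idx], vecs[:, idx]
    return vals / vals.sum(), vecs
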