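"""Gibbs sweep for the indicator-times-coefficient regression.

One systematic-scan Gibbs iteration updates, in order: the intercept, each
column's indicator then coefficient, the shared inclusion probability of
any uniform-prior marker type (conjugate Beta), any hierarchical slab
variance (conjugate inverse-Gamma), and the residual variance (conjugate
inverse-Gamma). Excluded coefficients are refreshed from their prior so
the indicator chain keeps mixing.

The inner loop is compiled with numba when available; the pure-Python
path is identical (same RNG stream) but slow, and exists as a fallback.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

# regime codes mirror model._REGIMES
_FIXED, _ALWAYS_IN, _ALWAYS_OUT, _UNIFORM = 0, 1, 2, 3


@njit(cache=False)
def _chain_kernel(
    X, y, type_idx, regime, pi0, tau2_fixed, t2_shape, t2_scale, a0, b0, n_iter, seed
):
    np.random.seed(seed)
    n, p = X.shape
    T = pi0.shape[0]

    xtx = np.empty(p)
    for l in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, l] * X[i, l]
        xtx[l] = s

    # --- initial state from priors (data-informed sigma2 start) ---
    pi = pi0.copy()
    for t in range(T):
        if regime[t] == _ALWAYS_IN:
            pi[t] = 1.0
        elif regime[t] == _ALWAYS_OUT:
            pi[t] = 0.0
        elif regime[t] == _UNIFORM:
            pi[t] = np.random.random()
    tau2 = np.empty(T)
    for t in range(T):
        if tau2_fixed[t] > 0.0:
            tau2[t] = tau2_fixed[t]
        else:
            tau2[t] = t2_scale[t] / (t2_shape[t] + 1.0)
    alpha = np.random.normal()
    beta = np.empty(p)
    ind = np.zeros(p, np.int8)
    for l in range(p):
        t = type_idx[l]
        beta[l] = np.random.normal() * np.sqrt(tau2[t])
        if np.random.random() < pi[t]:
            ind[l] = 1
    ybar = 0.0
    yvar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    for i in range(n):
        yvar += (y[i] - ybar) ** 2
    sigma2 = yvar / n if yvar > 0.0 else 1.0

    r = np.empty(n)
    for i in range(n):
        r[i] = y[i] - alpha
    for l in range(p):
        if ind[l] == 1:
            for i in range(n):
                r[i] -= X[i, l] * beta[l]

    out_alpha = np.empty(n_iter)
    out_beta = np.empty((n_iter, p))
    out_ind = np.empty((n_iter, p), np.int8)
    out_sigma2 = np.empty(n_iter)
    out_pi = np.empty((n_iter, T))
    out_tau2 = np.empty((n_iter, T))

    for it in range(n_iter):
        # intercept: N(0,1) prior
        s = 0.0
        for i in range(n):
            s += r[i] + alpha
        prec = n / sigma2 + 1.0
        new_alpha = (s / sigma2) / prec + np.random.normal() / np.sqrt(prec)
        d = alpha - new_alpha
        for i in range(n):
            r[i] += d
        alpha = new_alpha

        for l in range(p):
            t = type_idx[l]
            b = beta[l]
            if ind[l] == 1:  # lift column out of the residual
                for i in range(n):
                    r[i] += X[i, l] * b
            xr = 0.0
            for i in range(n):
                xr += X[i, l] * r[i]

            # indicator given current coefficient value
            if regime[t] == _ALWAYS_IN:
                ind[l] = 1
            elif regime[t] == _ALWAYS_OUT:
                ind[l] = 0
            elif pi[t] <= 0.0:
                ind[l] = 0
            elif pi[t] >= 1.0:
                ind[l] = 1
            else:
                delta = (2.0 * b * xr - b * b * xtx[l]) / (2.0 * sigma2)
                logit = np.log(pi[t] / (1.0 - pi[t])) + delta
                if logit > 35.0:
                    p1 = 1.0
                elif logit < -35.0:
                    p1 = 0.0
                else:
                    p1 = 1.0 / (1.0 + np.exp(-logit))
                ind[l] = 1 if np.random.random() < p1 else 0

            if ind[l] == 1:  # conjugate Normal full conditional
                v = 1.0 / (xtx[l] / sigma2 + 1.0 / tau2[t])
                m = v * xr / sigma2
                beta[l] = m + np.random.normal() * np.sqrt(v)
                for i in range(n):
                    r[i] -= X[i, l] * beta[l]
            else:  # prior refresh keeps the chain mixing
                beta[l] = np.random.normal() * np.sqrt(tau2[t])

        for t in range(T):
            if regime[t] == _UNIFORM:  # conjugate Beta(1 + s, 1 + k - s)
                k = 0
                s1 = 0
                for l in range(p):
                    if type_idx[l] == t:
                        k += 1
                        s1 += ind[l]
                pi[t] = np.random.beta(1.0 + s1, 1.0 + k - s1)
            if tau2_fixed[t] <= 0.0:
                k = 0
                ssb = 0.0
                for l in range(p):
                    if type_idx[l] == t:
                        k += 1
                        ssb += beta[l] * beta[l]
                if k > 0:
                    tau2[t] = 1.0 / np.random.gamma(
                        t2_shape[t] + 0.5 * k, 1.0 / (t2_scale[t] + 0.5 * ssb)
                    )

        ssr = 0.0
        for i in range(n):
            ssr += r[i] * r[i]
        sigma2 = 1.0 / np.random.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * ssr))

        if (it + 1) % 256 == 0:  # refresh residual against drift
            for i in range(n):
                acc = y[i] - alpha
                for l in range(p):
                    if ind[l] == 1:
                        acc -= X[i, l] * beta[l]
                r[i] = acc

        out_alpha[it] = alpha
        for l in range(p):
            out_beta[it, l] = beta[l]
            out_ind[it, l] = ind[l]
        out_sigma2[it] = sigma2
        for t in range(T):
            out_pi[it, t] = pi[t]
            out_tau2[it, t] = tau2[t]

    return out_alpha, out_beta, out_ind, out_sigma2, out_pi, out_tau2


def run_chain(
    X, y, type_idx, regime, pi0, tau2_fixed, t2_shape, t2_scale, a0, b0, n_iter, seed
):
    """Run one Gibbs chain; returns (alpha, beta, I, sigma2, pi, tau2) draws."""
    return _chain_kernel(
        np.ascontiguousarray(X, dtype=np.float64),
        np.ascontiguousarray(y, dtype=np.float64),
        np.ascontiguousarray(type_idx, dtype=np.int64),
        np.ascontiguousarray(regime, dtype=np.int64),
        np.ascontiguousarray(pi0, dtype=np.float64),
        np.ascontiguousarray(tau2_fixed, dtype=np.float64),
        np.ascontiguousarray(t2_shape, dtype=np.float64),
        np.ascontiguousarray(t2_scale, dtype=np.float64),
        float(a0),
        float(b0),
        int(n_iter),
        int(seed),
    )
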