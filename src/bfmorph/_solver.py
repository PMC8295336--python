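"""Coordinate-descent solver for the L1-penalized logistic model.

Minimizes, over (alpha, beta),

    f(alpha, beta) = (1/n) sum_i [ log(1 + exp(eta_i)) - y_i * eta_i ]
                     + lambda * ||beta||_1,        eta_i = alpha + x_i . beta

with an unpenalized intercept, via IRLS (local quadratic approximation)
with cyclic coordinate descent on the working weighted least squares,
warm starts along a decreasing lambda path, an ever-active feature set
with KKT screening of inactive features, and step-halving backtracking so
the objective never increases between IRLS iterations.

The kernel is compiled with numba; the design matrix must be
Fortran-ordered so column sweeps stream contiguous memory.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_WMIN = 1e-6
_ETA_CLIP = 30.0


@njit(cache=True)
def _objective(eta, y, beta, lam, n):
    f = 0.0
    for i in range(n):
        e = eta[i]
        if e > 0.0:
            f += np.log1p(np.exp(-e)) + e - y[i] * e
        else:
            f += np.log1p(np.exp(e)) - y[i] * e
    f /= n
    pen = 0.0
    for j in range(beta.shape[0]):
        pen += abs(beta[j])
    return f + lam * pen


@njit(cache=True)
def logistic_lasso_path(X, y, lambdas, tol, max_irls, max_cd):
    """Fit the lambda path; returns (alphas, betas, trace, trace_len, iters).

    ``trace`` holds the per-IRLS-iteration objective of the LAST lambda in
    the path (the fit a caller asking for a single lambda cares about).
    """
    n, p = X.shape
    L = lambdas.shape[0]
    out_alpha = np.zeros(L)
    out_beta = np.zeros((L, p))
    out_iters = np.zeros(L, dtype=np.int64)
    trace = np.zeros(max_irls + 1)
    trace_len = 0

    beta = np.zeros(p)
    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    alpha = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, alpha)
    active = np.zeros(p, dtype=np.bool_)

    w = np.empty(n)
    r = np.empty(n)
    resid = np.empty(n)
    beta_old = np.empty(p)
    eta_old = np.empty(n)

    for li in range(L):
        lam = lambdas[li]
        if lam <= 0.0:
            for j in range(p):
                active[j] = True
        is_last = li == L - 1
        if is_last:
            trace_len = 0
            trace[trace_len] = _objective(eta, y, beta, lam, n)
            trace_len += 1
        n_irls = 0
        for _kkt_round in range(100):
            # --- solve to tolerance on the current active set ---
            for _it in range(max_irls):
                n_irls += 1
                obj0 = _objective(eta, y, beta, lam, n)
                alpha_old = alpha
                for j in range(p):
                    beta_old[j] = beta[j]
                for i in range(n):
                    eta_old[i] = eta[i]
                    e = eta[i]
                    if e > _ETA_CLIP:
                        e = _ETA_CLIP
                    elif e < -_ETA_CLIP:
                        e = -_ETA_CLIP
                    pe = 1.0 / (1.0 + np.exp(-e))
                    wi = pe * (1.0 - pe)
                    if wi < _WMIN:
                        wi = _WMIN
                    w[i] = wi
                    r[i] = (y[i] - pe) / wi
                for _sweep in range(max_cd):
                    maxdel = 0.0
                    sw = 0.0
                    swr = 0.0
                    for i in range(n):
                        sw += w[i]
                        swr += w[i] * r[i]
                    da = swr / sw
                    alpha += da
                    for i in range(n):
                        r[i] -= da
                    if abs(da) > maxdel:
                        maxdel = abs(da)
                    for j in range(p):
                        if not active[j]:
                            continue
                        bj = beta[j]
                        num = 0.0
                        den = 0.0
                        for i in range(n):
                            xij = X[i, j]
                            wx = w[i] * xij
                            num += wx * (r[i] + xij * bj)
                            den += wx * xij
                        if den <= 0.0:
                            continue
                        u = num / n
                        d2 = den / n
                        if u > lam:
                            bn = (u - lam) / d2
                        elif u < -lam:
                            bn = (u + lam) / d2
                        else:
                            bn = 0.0
                        d = bn - bj
                        if d != 0.0:
                            beta[j] = bn
                            for i in range(n):
                                r[i] -= X[i, j] * d
                            if abs(d) > maxdel:
                                maxdel = abs(d)
                    if maxdel < tol:
                        break
                # refresh eta from the parameter change
                da = alpha - alpha_old
                for i in range(n):
                    eta[i] = eta_old[i] + da
                for j in range(p):
                    d = beta[j] - beta_old[j]
                    if d != 0.0:
                        for i in range(n):
                            eta[i] += X[i, j] * d
                # backtracking: never let the objective rise
                obj1 = _objective(eta, y, beta, lam, n)
                halvings = 0
                while obj1 > obj0 + 1e-12 and halvings < 20:
                    alpha = 0.5 * (alpha + alpha_old)
                    for j in range(p):
                        beta[j] = 0.5 * (beta[j] + beta_old[j])
                    for i in range(n):
                        eta[i] = 0.5 * (eta[i] + eta_old[i])
                    obj1 = _objective(eta, y, beta, lam, n)
                    halvings += 1
                if is_last:
                    trace[trace_len] = obj1
                    trace_len += 1
                    if trace_len >= trace.shape[0]:
                        trace_len = trace.shape[0] - 1
                maxch = abs(alpha - alpha_old)
                for j in range(p):
                    c = abs(beta[j] - beta_old[j])
                    if c > maxch:
                        maxch = c
                if maxch < tol:
                    break
            # --- KKT screen: activate violating inactive features ---
            for i in range(n):
                e = eta[i]
                if e > _ETA_CLIP:
                    e = _ETA_CLIP
                elif e < -_ETA_CLIP:
                    e = -_ETA_CLIP
                resid[i] = y[i] - 1.0 / (1.0 + np.exp(-e))
            violated = False
            for j in range(p):
                if active[j]:
                    continue
                g = 0.0
                for i in range(n):
                    g += X[i, j] * resid[i]
                g /= n
                if abs(g) > lam + 1e-12:
                    active[j] = True
                    violated = True
            if not violated:
                break
        out_alpha[li] = alpha
        for j in range(p):
            out_beta[li, j] = beta[j]
        out_iters[li] = n_irls
    return out_alpha, out_beta, trace, trace_len, out_iters
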