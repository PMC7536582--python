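"""Compiled inner loops for the coordinate-ascent sweep.

The per-SNP mixture updates are inherently sequential (each update changes
the running residual), so they are written as explicit loops and JIT-compiled
with numba. A pure-numpy fallback with identical semantics is used when numba
is unavailable; results agree to floating-point round-off dictated by
summation order, so the numba path performs dot products in plain serial
order as well (fastmath stays off for determinism).
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def snp_sweep(
    X,
    xtx,
    z2,
    r_lin,
    g,
    eta,
    eta2,
    eta_g,
    e2g,
    beta_resp,
    beta_mean1,
    beta_var1,
    beta_mean2,
    beta_var2,
    beta_bar,
    gamma_resp,
    gamma_mean1,
    gamma_var1,
    gamma_mean2,
    gamma_var2,
    gamma_bar,
    se2,
    sb1,
    sb2,
    sg1,
    sg2,
    logit_lb,
    logit_lg,
):
    """In-place (beta_j, gamma_j) pair updates in genome order.

    Returns 0 on success, j + 1 when the update for SNP j went non-finite.
    """
    n, m = X.shape
    for j in range(m):
        # ---- main effect beta_j
        lin = xtx[j] * beta_bar[j]
        for i in range(n):
            lin += X[i, j] * (r_lin[i] - eta_g[i])
        d1 = xtx[j] + 1.0 / sb1
        d2 = xtx[j] + 1.0 / sb2
        m1 = lin / d1
        m2 = lin / d2
        v1 = se2 / d1
        v2 = se2 / d2
        log_odds = (
            logit_lb
            - 0.5 * math.log1p(sb1 * xtx[j])
            + 0.5 * math.log1p(sb2 * xtx[j])
            + 0.5 * m1 * m1 / v1
            - 0.5 * m2 * m2 / v2
        )
        if not math.isfinite(log_odds):
            return j + 1
        resp = _sigmoid(min(max(log_odds, -700.0), 700.0))
        new_bar = resp * m1 + (1.0 - resp) * m2
        delta = new_bar - beta_bar[j]
        if delta != 0.0:
            for i in range(n):
                r_lin[i] -= X[i, j] * delta
        beta_resp[j] = resp
        beta_mean1[j] = m1
        beta_var1[j] = v1
        beta_mean2[j] = m2
        beta_var2[j] = v2
        beta_bar[j] = new_bar

        # ---- interaction effect gamma_j
        lin = z2[j] * gamma_bar[j]
        for i in range(n):
            lin += X[i, j] * (eta[i] * r_lin[i] - e2g[i])
        d1 = z2[j] + 1.0 / sg1
        d2 = z2[j] + 1.0 / sg2
        m1 = lin / d1
        m2 = lin / d2
        v1 = se2 / d1
        v2 = se2 / d2
        log_odds = (
            logit_lg
            - 0.5 * math.log1p(sg1 * z2[j])
            + 0.5 * math.log1p(sg2 * z2[j])
            + 0.5 * m1 * m1 / v1
            - 0.5 * m2 * m2 / v2
        )
        if not math.isfinite(log_odds):
            return j + 1
        resp = _sigmoid(min(max(log_odds, -700.0), 700.0))
        new_bar = resp * m1 + (1.0 - resp) * m2
        delta = new_bar - gamma_bar[j]
        if delta != 0.0:
            for i in range(n):
                xij = X[i, j]
                g[i] += xij * delta
                eta_g[i] += xij * eta[i] * delta
                e2g[i] += xij * eta2[i] * delta
        gamma_resp[j] = resp
        gamma_mean1[j] = m1
        gamma_var1[j] = v1
        gamma_mean2[j] = m2
        gamma_var2[j] = v2
        gamma_bar[j] = new_bar
    return 0
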