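"""Compiled likelihood kernels for the pairwise fits.

The objective evaluation is dominated by small-array work (pmf grids of
a few thousand entries and short convolutions) where interpreter
overhead outweighs the flops; these numba kernels keep a full
correlation matrix of fits affordable on one core.  They mirror the
numpy implementation in :mod:`bzinbnet.model` exactly (the test suite
cross-checks the two).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _lgamma_vec(x):
    out = np.empty(x.size)
    for i in range(x.size):
        out[i] = math.lgamma(x[i])
    return out


@njit(cache=True)
def _nb_pmf_vec(m, shape, beta):
    """NB(shape, 1/(1+beta)) pmf on 0..m."""
    out = np.empty(m + 1)
    lb = math.log(beta) - math.log1p(beta)
    base = -shape * math.log1p(beta) - math.lgamma(shape)
    for x in range(m + 1):
        out[x] = math.exp(
            math.lgamma(x + shape) - math.lgamma(x + 1.0) + base + x * lb
        )
    return out


@njit(cache=True)
def _bnb_grid(a0, a1, a2, b1, b2, m1, m2):
    """Joint BNB pmf grid on {0..m1} x {0..m2} (finite-sum form)."""
    delta = b2 / b1
    log_t = math.log1p(delta + 1.0 / b1)
    log_d = math.log(delta)
    smax = m1 + m2
    g = np.empty(smax + 1)
    for s in range(smax + 1):
        g[s] = (
            math.lgamma(a0 + s)
            - math.lgamma(a0)
            - a0 * math.log(b1)
            - (a0 + s) * log_t
        )
    lf = np.empty(max(m1, m2) + 1)  # log factorials
    lf[0] = 0.0
    for i in range(1, lf.size):
        lf[i] = lf[i - 1] + math.log(i)
    g0 = np.empty((m1 + 1, m2 + 1))
    for u1 in range(m1 + 1):
        for u2 in range(m2 + 1):
            g0[u1, u2] = math.exp(g[u1 + u2] + u2 * log_d - lf[u1] - lf[u2])
    nb1 = _nb_pmf_vec(m1, a1, b1)
    nb2 = _nb_pmf_vec(m2, a2, b2)
    # separable convolution with the two NB kernels
    tmp = np.zeros((m1 + 1, m2 + 1))
    for x1 in range(m1 + 1):
        for u1 in range(x1 + 1):
            c = nb1[x1 - u1]
            if c == 0.0:
                continue
            for u2 in range(m2 + 1):
                tmp[x1, u2] += c * g0[u1, u2]
    out = np.zeros((m1 + 1, m2 + 1))
    for x1 in range(m1 + 1):
        for x2 in range(m2 + 1):
            acc = 0.0
            for u2 in range(x2 + 1):
                acc += nb2[x2 - u2] * tmp[x1, u2]
            out[x1, x2] = acc
    return out


@njit(cache=True)
def nll_bzinb(theta, i1, i2, w, m1, m2):
    """Negative BZINB log-likelihood at packed coordinates.

    theta = (logit s, log A1, log A2, log b1, log b2, t1, t2, t3) with
    alpha0 = s * min(A1, A2) and pi = softmax(t1, t2, t3, 0); (i1, i2)
    are unique count pairs with multiplicities w.
    """
    s = 1.0 / (1.0 + math.exp(-min(max(theta[0], -16.0), 16.0)))
    tot1 = math.exp(min(max(theta[1], -18.4), 18.4))
    tot2 = math.exp(min(max(theta[2], -18.4), 18.4))
    b1 = math.exp(min(max(theta[3], -18.4), 18.4))
    b2 = math.exp(min(max(theta[4], -18.4), 18.4))
    a0 = max(s * min(tot1, tot2), 1e-8)
    a1 = max(tot1 - a0, 1e-8)
    a2 = max(tot2 - a0, 1e-8)
    mx = max(theta[5], max(theta[6], max(theta[7], 0.0)))
    e1 = math.exp(min(max(theta[5], -30.0), 30.0) - mx)
    e2 = math.exp(min(max(theta[6], -30.0), 30.0) - mx)
    e3 = math.exp(min(max(theta[7], -30.0), 30.0) - mx)
    e4 = math.exp(0.0 - mx)
    tot = e1 + e2 + e3 + e4
    p1, p2, p3, p4 = e1 / tot, e2 / tot, e3 / tot, e4 / tot

    grid = _bnb_grid(a0, a1, a2, b1, b2, m1, m2)
    f1 = _nb_pmf_vec(m1, a0 + a1, b1)
    f2 = _nb_pmf_vec(m2, a0 + a2, b2)
    ll = 0.0
    for idx in range(i1.size):
        x1 = i1[idx]
        x2 = i2[idx]
        mix = p1 * grid[x1, x2]
        if x2 == 0:
            mix += p2 * f1[x1]
        if x1 == 0:
            mix += p3 * f2[x2]
        if x1 == 0 and x2 == 0:
            mix += p4
        if mix < 1e-300:
            mix = 1e-300
        ll += w[idx] * math.log(mix)
    return -ll


@njit(cache=True)
def nll_bnb(theta, i1, i2, w, m1, m2):
    """Negative BNB log-likelihood (5 packed coordinates, no masking)."""
    s = 1.0 / (1.0 + math.exp(-min(max(theta[0], -16.0), 16.0)))
    tot1 = math.exp(min(max(theta[1], -18.4), 18.4))
    tot2 = math.exp(min(max(theta[2], -18.4), 18.4))
    b1 = math.exp(min(max(theta[3], -18.4), 18.4))
    b2 = math.exp(min(max(theta[4], -18.4), 18.4))
    a0 = max(s * min(tot1, tot2), 1e-8)
    a1 = max(tot1 - a0, 1e-8)
    a2 = max(tot2 - a0, 1e-8)
    grid = _bnb_grid(a0, a1, a2, b1, b2, m1, m2)
    ll = 0.0
    for idx in range(i1.size):
        v = grid[i1[idx], i2[idx]]
        if v < 1e-300:
            v = 1e-300
        ll += w[idx] * math.log(v)
    return -ll
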