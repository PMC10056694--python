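"""Bivariate (zero-inflated) negative binomial model: pmf, moments,
model-based correlations, sampling and maximum-likelihood fitting.

The joint mass of the BNB pair is computed by the finite-sum
decomposition: splitting each count into events generated by the shared
Gamma component and by the idiosyncratic component, the joint pmf is the
2D convolution of the shared-component grid

    G0[u1, u2] = delta^u2 / (u1! u2!) *
                 Gamma(alpha0 + u1 + u2) / (Gamma(alpha0) * beta^alpha0) /
                 (1 + delta + 1/beta)^(alpha0 + u1 + u2)

with the two idiosyncratic NB kernels ``NB(alpha1, 1/(1+beta1))`` and
``NB(alpha2, 1/(1+beta2))``.  The convolution is separable, so the full
grid of probabilities up to the maximum observed counts is obtained with
two lower-triangular Toeplitz matrix products (BLAS), which is what makes
large pairwise correlation matrices tractable.

Fitting maximizes the observed-data log-likelihood directly with
L-BFGS-B on margin-preserving coordinates: the correlation enters
through the shared-component share ``s = alpha0 / min(A1, A2)`` with the
total shapes ``A_j = alpha0 + alpha_j`` and scales held in their own
coordinates, so moving along the correlation direction leaves both
marginal distributions unchanged.  The zero-inflation simplex enters
through softmax coordinates (the mixture is concave in the simplex).
Objective evaluations run in compiled kernels (:mod:`bzinbnet._kernels`).
"""

from __future__ import annotations

import math
from typing import Optional, Tuple, Union

import numpy as np
from scipy.linalg import toeplitz
from scipy.optimize import minimize
from scipy.special import expit, gammaln

from . import _kernels
from .params import BNBParams, BZINBParams, FitResult, MomentSet

__all__ = [
    "bnb_pmf",
    "bzinb_pmf",
    "bnb_pmf_grid",
    "bzinb_pmf_grid",
    "rho_bnb",
    "rho_bzinb",
    "rho_naive_bzinb",
    "moments",
    "sample_bnb",
    "sample_bzinb",
    "fit_bnb",
    "fit_bzinb",
]

# Fitted parameters are floored here to keep the likelihood finite.
_PARAM_FLOOR = 1e-8
_PARAM_CEIL = 1e8
_LOG_BOUNDS = (math.log(_PARAM_FLOOR), math.log(_PARAM_CEIL))
# Finite-sum grids beyond this count are impractical; callers should
# downscale their counts first (correlation helpers do this).
MAX_COUNT = 5000


# ---------------------------------------------------------------------------
# pmf machinery
# ---------------------------------------------------------------------------

def _as_counts(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if not np.issubdtype(arr.dtype, np.number):
        raise TypeError(f"{name} must be numeric")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError(f"{name} must contain non-negative integers")
    if arr.size and arr.max() > MAX_COUNT:
        raise ValueError(
            f"{name} contains counts above {MAX_COUNT}; the finite-sum pmf "
            "grid would be impractically large -- rescale the counts first"
        )
    return arr.astype(np.int64)


def bnb_pmf_grid(params: BNBParams, m1: int, m2: int) -> np.ndarray:
    """Joint BNB probabilities on the grid ``{0..m1} x {0..m2}``."""
    a0, a1, a2, b1, b2 = params.as_array()
    delta = b2 / b1
    s = np.arange(m1 + m2 + 1, dtype=np.float64)
    # log of the shared-component partial mass, indexed by u1 + u2
    log_t = np.log1p(delta + 1.0 / b1)
    g = gammaln(a0 + s) - gammaln(a0) - a0 * np.log(b1) - (a0 + s) * log_t
    u1 = np.arange(m1 + 1)
    u2 = np.arange(m2 + 1)
    log_g0 = (
        g[u1[:, None] + u2[None, :]]
        + u2[None, :] * np.log(delta)
        - gammaln(u1 + 1.0)[:, None]
        - gammaln(u2 + 1.0)[None, :]
    )
    g0 = np.exp(log_g0)
    nb1 = _nb_marginal_pmf(u1, a1, b1)
    nb2 = _nb_marginal_pmf(u2, a2, b2)
    t1 = toeplitz(nb1, np.zeros(m1 + 1))
    t2 = toeplitz(nb2, np.zeros(m2 + 1))
    return t1 @ g0 @ t2.T


def _nb_marginal_pmf(x: np.ndarray, shape: float, beta: float) -> np.ndarray:
    """NB(shape, 1/(beta+1)) pmf (direct log-gamma form, avoids scipy
    distribution-object overhead in tight pairwise-fit loops)."""
    x = np.asarray(x, dtype=np.float64)
    return np.exp(
        gammaln(x + shape)
        - gammaln(x + 1.0)
        - gammaln(shape)
        - shape * np.log1p(beta)
        + x * (np.log(beta) - np.log1p(beta))
    )


def bnb_pmf(x1, x2, params: BNBParams) -> Union[float, np.ndarray]:
    """Joint pmf of the BNB pair at (possibly vector) counts."""
    a1 = _as_counts(x1, "x1")
    a2 = _as_counts(x2, "x2")
    scalar = a1.ndim == 0 and a2.ndim == 0
    a1, a2 = np.atleast_1d(a1), np.atleast_1d(a2)
    if a1.shape != a2.shape:
        raise ValueError("x1 and x2 must have the same shape")
    grid = bnb_pmf_grid(params, int(a1.max(initial=0)), int(a2.max(initial=0)))
    out = grid[a1, a2]
    return float(out[0]) if scalar else out


def bzinb_pmf_grid(params: BZINBParams, m1: int, m2: int) -> np.ndarray:
    """Joint BZINB probabilities on ``{0..m1} x {0..m2}``."""
    bnb = params.bnb
    f = bnb_pmf_grid(bnb, m1, m2)
    f1 = _nb_marginal_pmf(np.arange(m1 + 1), bnb.alpha0 + bnb.alpha1, bnb.beta1)
    f2 = _nb_marginal_pmf(np.arange(m2 + 1), bnb.alpha0 + bnb.alpha2, bnb.beta2)
    out = params.pi1 * f
    out[:, 0] += params.pi2 * f1
    out[0, :] += params.pi3 * f2
    out[0, 0] += params.pi4
    return out


def bzinb_pmf(y1, y2, params: BZINBParams) -> Union[float, np.ndarray]:
    """Joint pmf of the masked (zero-inflated) pair."""
    a1 = _as_counts(y1, "y1")
    a2 = _as_counts(y2, "y2")
    scalar = a1.ndim == 0 and a2.ndim == 0
    a1, a2 = np.atleast_1d(a1), np.atleast_1d(a2)
    if a1.shape != a2.shape:
        raise ValueError("y1 and y2 must have the same shape")
    grid = bzinb_pmf_grid(params, int(a1.max(initial=0)), int(a2.max(initial=0)))
    out = grid[a1, a2]
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# correlations and moments
# ---------------------------------------------------------------------------

def rho_bnb(params: BNBParams) -> float:
    """Model-based correlation of the BNB pair; always in [0, 1)."""
    a0, a1, a2, b1, b2 = params.as_array()
    return float(
        a0
        * math.sqrt(b1 * b2)
        / math.sqrt((a0 + a1) * (a0 + a2) * (b1 + 1.0) * (b2 + 1.0))
    )


def rho_bzinb(params: BZINBParams) -> float:
    """Underlying (masking-free) correlation of a BZINB pair.

    Applies the BNB correlation formula to the latent BNB component,
    ignoring the masking probabilities; this is the headline estimator.
    """
    return rho_bnb(params.bnb)


def moments(params: Union[BNBParams, BZINBParams]) -> MomentSet:
    """Closed-form moments of the latent pair and of the masked pair."""
    if isinstance(params, BNBParams):
        params = BZINBParams(params, 1.0, 0.0, 0.0, 0.0)
    a0, a1, a2, b1, b2 = params.bnb.as_array()
    mean1 = (a0 + a1) * b1
    mean2 = (a0 + a2) * b2
    var1 = (a0 + a1) * b1 * (b1 + 1.0)
    var2 = (a0 + a2) * b2 * (b2 + 1.0)
    cov = a0 * b1 * b2
    p1, p2, p3, _ = params.pi
    obs1 = p1 + p2  # P(margin 1 unmasked)
    obs2 = p1 + p3
    s12 = (a0 + (a0 + a1) * (a0 + a2)) * b1 * b2 * p1 - (a0 + a1) * (
        a0 + a2
    ) * b1 * b2 * obs1 * obs2
    s1 = (a0 + a1) ** 2 * b1**2 * obs1 * (1.0 - obs1) + var1 * obs1
    s2 = (a0 + a2) ** 2 * b2**2 * obs2 * (1.0 - obs2) + var2 * obs2
    return MomentSet(mean1, mean2, var1, var2, cov, s12, s1, s2)


def rho_naive_bzinb(params: BZINBParams) -> float:
    """Unconditional (masking-inclusive) correlation of the observed pair."""
    m = moments(params)
    if m.naive_sigma1sq <= 0 or m.naive_sigma2sq <= 0:
        raise ValueError("naive correlation undefined: a margin has zero variance")
    return float(m.naive_sigma12 / math.sqrt(m.naive_sigma1sq * m.naive_sigma2sq))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_bnb(params: BNBParams, n: int, seed=None) -> Tuple[np.ndarray, np.ndarray]:
    """Latent-variable draw of ``n`` BNB pairs."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    a0, a1, a2, b1, b2 = params.as_array()
    r0 = rng.gamma(a0, b1, n)
    r1 = rng.gamma(a1, b1, n)
    r2 = rng.gamma(a2, b1, n)
    delta = b2 / b1
    x1 = rng.poisson(r0 + r1)
    x2 = rng.poisson(delta * (r0 + r2))
    return x1, x2


def sample_bzinb(
    params: BZINBParams, n: int, seed=None, return_mask: bool = False
):
    """Draw ``n`` BZINB pairs: BNB draw plus a 4-category masking draw.

    With ``return_mask=True`` also returns the masking category per
    observation (0: none masked, 1: second masked, 2: first masked,
    3: both masked).
    """
    rng = _rng(seed)
    x1, x2 = sample_bnb(params.bnb, n, rng)
    cat = rng.choice(4, size=n, p=params.pi)
    y1 = np.where((cat == 0) | (cat == 1), x1, 0)
    y2 = np.where((cat == 0) | (cat == 2), x2, 0)
    if return_mask:
        return y1, y2, cat
    return y1, y2


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _aggregate_pairs(y1: np.ndarray, y2: np.ndarray):
    """Unique (y1, y2) pairs with multiplicities."""
    m2 = int(y2.max()) + 1
    codes = y1.astype(np.int64) * m2 + y2.astype(np.int64)
    uniq, w = np.unique(codes, return_counts=True)
    return (uniq // m2), (uniq % m2), w.astype(np.float64)


def _theta_from_moments(mu, var, cov):
    """Build the optimizer coordinates from moment estimates.

    The fit is parametrized as (logit s, log A1, log A2, log beta1,
    log beta2) with total shapes A_j = alpha0 + alpha_j and
    alpha0 = s * min(A1, A2): the first coordinate moves only the
    shared-component share (the correlation) while leaving both
    marginal distributions untouched, which conditions the likelihood
    far better than optimizing alpha0 directly.
    """
    beta = np.clip(var / np.maximum(mu, 1e-8) - 1.0, 0.05, 1e6)
    shape = np.clip(mu / beta, 1e-4, 1e6)
    a0 = np.clip(cov / (beta[0] * beta[1]), 0.02 * shape.min(), 0.95 * shape.min())
    s = np.clip(a0 / shape.min(), 0.02, 0.95)
    return np.array(
        [np.log(s / (1 - s)), np.log(shape[0]), np.log(shape[1]),
         np.log(beta[0]), np.log(beta[1])]
    )


def _moment_init_bnb(y1: np.ndarray, y2: np.ndarray) -> np.ndarray:
    mu = np.array([y1.mean(), y2.mean()])
    var = np.array([y1.var(ddof=1), y2.var(ddof=1)])
    return _theta_from_moments(mu, var, np.cov(y1, y2)[0, 1])


_THETA_BOUNDS = [(-16.0, 16.0)] + [_LOG_BOUNDS] * 4


def _params_from_theta(theta: np.ndarray) -> BNBParams:
    s = float(expit(theta[0]))
    total1, total2, b1, b2 = np.exp(np.clip(theta[1:5], *_LOG_BOUNDS))
    a0 = max(s * min(total1, total2), _PARAM_FLOOR)
    return BNBParams(
        a0, max(total1 - a0, _PARAM_FLOOR), max(total2 - a0, _PARAM_FLOOR), b1, b2
    )


def _fit_generic(nll, theta0, max_iter, tol, restarts, seed, bounds=None):
    """Shared L-BFGS driver with random restarts on failure.

    ``tol`` is an absolute tolerance on the log-likelihood change;
    scipy's ftol is relative, so it is rescaled by the starting
    objective (the likelihood surface has long flat valleys in the
    correlation direction where a loose relative tolerance stops far
    from the optimum).
    """
    rng = _rng(seed)
    if bounds is None:
        bounds = _THETA_BOUNDS
    last = {"f": np.inf}

    def tracked(theta):
        f = nll(theta)
        last["f"] = f
        return f

    best = None
    start = np.asarray(theta0, dtype=float)
    ftol = max(tol / max(1.0, abs(float(nll(start)))), 1e-15)
    for attempt in range(restarts + 1):
        trace_local: list = []

        def cb(theta):
            # the accepted iterate is the last point the line search evaluated
            trace_local.append(-last["f"])

        res = minimize(
            tracked,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            callback=cb,
            options={"maxiter": max_iter, "ftol": ftol, "maxfun": 50 * max_iter},
        )
        if best is None or res.fun < best[0].fun:
            best = (res, trace_local)
        if res.success:
            break
        start = np.asarray(theta0) + rng.normal(0.0, 0.7, size=start.size)
    res, trace = best
    return res, [float(t) for t in trace]


def fit_bnb(
    y1,
    y2,
    max_iter: int = 1000,
    tol: float = 1e-6,
    restarts: int = 3,
    seed: int = 0,
) -> FitResult:
    """Maximum-likelihood BNB fit of a pair of count vectors."""
    y1 = _as_counts(y1, "y1")
    y2 = _as_counts(y2, "y2")
    if y1.shape != y2.shape or y1.ndim != 1:
        raise ValueError("y1 and y2 must be 1-D vectors of equal length")
    if y1.size < 10:
        raise ValueError("need at least 10 paired observations")
    if not y1.any() or not y2.any():
        return FitResult(None, np.nan, 0, False, np.nan, status="degenerate")
    i1, i2, w = _aggregate_pairs(y1, y2)
    m1, m2 = int(y1.max()), int(y2.max())

    def nll(theta):
        return _kernels.nll_bnb(theta, i1, i2, w, m1, m2)

    theta0 = _moment_init_bnb(y1, y2)
    res, trace = _fit_generic(nll, theta0, max_iter, tol, restarts, seed)
    params = _params_from_theta(res.x)
    return FitResult(
        params,
        -float(res.fun),
        int(res.nit),
        bool(res.success),
        rho_bnb(params),
        trace=trace,
    )


def _moment_init_bzinb(y1, y2):
    """Moment/zero-fraction start: treat roughly half the observed zeros
    in each margin as structural."""
    z1 = float(np.mean(y1 == 0))
    z2 = float(np.mean(y2 == 0))
    z12 = float(np.mean((y1 == 0) & (y2 == 0)))
    pi4 = max(z12 / 2.0, 1e-3)
    pi3 = max(z1 / 2.0 - pi4, 1e-3)
    pi2 = max(z2 / 2.0 - pi4, 1e-3)
    pi1 = max(1.0 - pi2 - pi3 - pi4, 0.05)
    pi = np.array([pi1, pi2, pi3, pi4])
    pi /= pi.sum()
    # un-thin the moments by the implied observation probabilities
    keep1 = max(pi[0] + pi[1], 0.05)
    keep2 = max(pi[0] + pi[2], 0.05)
    mu = np.array([y1.mean() / keep1, y2.mean() / keep2])
    var = np.array([y1.var(ddof=1) / keep1, y2.var(ddof=1) / keep2])
    # the raw covariance is diluted by masked zeros; estimate the latent
    # covariance from the jointly nonzero subset instead
    both = (y1 > 0) & (y2 > 0)
    if both.sum() >= 10:
        cov = np.cov(y1[both], y2[both])[0, 1]
    else:
        cov = np.cov(y1, y2)[0, 1] / (keep1 * keep2)
    return _theta_from_moments(mu, var, cov), pi


def fit_bzinb(
    y1,
    y2,
    max_iter: int = 1000,
    tol: float = 1e-6,
    restarts: int = 3,
    seed: int = 0,
) -> FitResult:
    """Maximum-likelihood BZINB fit over all nine parameters.

    The shape/scale parameters are optimized through the
    margin-preserving coordinates (correlation share, total shapes,
    scales) and the masking simplex through softmax coordinates; the
    mixture likelihood is concave in the simplex, so the joint surface
    has no additional modes from the masking layer.
    """
    y1 = _as_counts(y1, "y1")
    y2 = _as_counts(y2, "y2")
    if y1.shape != y2.shape or y1.ndim != 1:
        raise ValueError("y1 and y2 must be 1-D vectors of equal length")
    if y1.size < 10:
        raise ValueError("need at least 10 paired observations")
    if not y1.any() or not y2.any():
        # a fully masked margin leaves the latent correlation unidentified
        return FitResult(None, np.nan, 0, False, np.nan, status="degenerate")

    i1, i2, w = _aggregate_pairs(y1, y2)
    m1, m2 = int(y1.max()), int(y2.max())
    theta_bnb, pi0 = _moment_init_bzinb(y1, y2)
    # masking simplex enters as softmax coordinates relative to pi4;
    # the mixture likelihood is concave in pi, so this adds no modes
    theta0 = np.concatenate([theta_bnb, np.log(pi0[:3] / pi0[3])])

    def pi_of(theta):
        t = np.concatenate([np.clip(theta[5:], -30.0, 30.0), [0.0]])
        e = np.exp(t - t.max())
        return e / e.sum()

    def nll(theta):
        return _kernels.nll_bzinb(theta, i1, i2, w, m1, m2)

    res, trace = _fit_generic(
        nll, theta0, max_iter, tol, restarts, seed,
        bounds=_THETA_BOUNDS + [(-30.0, 30.0)] * 3,
    )
    bnb = _params_from_theta(res.x)
    params = BZINBParams(bnb, *pi_of(res.x))
    return FitResult(
        params,
        -float(res.fun),
        int(res.nit),
        bool(res.success),
        rho_bzinb(params),
        trace=trace,
    )
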