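"""Synthetic data generators.

Four families of inputs are produced here:

* zero-inflated bivariate lognormal pairs (rounded to counts, zeros
  introduced per margin by a rank-based dropout rule or by exact random
  zeroing),
* BZINB pairs from preset shape/scale/masking combinations,
* a baseline count matrix emulating a species-by-sample metagenomic
  table (long right tail across features, feature-wise excess zeros
  with a decreasing mean-versus-zeros trend), and
* the crafted cluster-signal matrix: blocks of features receive a
  weighted share of a common Poisson vector so that ground-truth
  correlated modules exist.

All generators take an explicit seed (or Generator) and return
non-negative integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import rankdata

from .model import sample_bzinb, rho_bnb
from .params import BNBParams, BZINBParams

__all__ = [
    "LognormalScenario",
    "ClusterCraftConfig",
    "lognormal_scenario_names",
    "bzinb_masking_names",
    "get_lognormal_scenario",
    "get_bzinb_preset",
    "simulate_lognormal_pair",
    "apply_rank_based_zeroing",
    "apply_random_exact_zeroing",
    "simulate_bzinb_pair",
    "generate_baseline_matrix",
    "craft_cluster_signal",
    "rescale_counts",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _load_presets() -> dict:
    with resources.files(__package__).joinpath("presets.yaml").open() as fh:
        cfg = yaml.safe_load(fh)
    _validate_presets(cfg)
    return cfg


def _validate_presets(cfg: dict, n: int = 300) -> None:
    """Cross-check the stored scenarios against their implied quantities."""
    for name, sc in cfg["lognormal"].items():
        if not all(0 <= z < n for z in sc["zeros"]):
            raise ValueError(f"preset {name}: zero targets out of range")
    for name, row in cfg["bzinb"]["masking"].items():
        pi = np.asarray(row["pi"], dtype=float)
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError(f"preset {name}: pi does not sum to 1")
        expected = (n * (pi[2] + pi[3]), n * (pi[1] + pi[3]))
        stored = tuple(row["expected_zeros"])
        if not np.allclose(expected, stored, atol=1e-9):
            raise ValueError(
                f"preset {name}: stored expected zeros {stored} != analytic {expected}"
            )
    sh = cfg["bzinb"]["shapes"]
    for rho in sh["rho_targets"]:
        params = _shape_preset(sh, rho)
        if abs(rho_bnb(params) - rho) > 1e-6:
            raise ValueError(f"shape preset misses target rho={rho}")


def _shape_preset(sh: dict, rho: float) -> BNBParams:
    b = sh["beta1"]
    c = b / (b + 1.0)
    if not 0 < rho < c:
        raise ValueError(f"target rho must lie in (0, {c}), got {rho}")
    alpha0 = sh["alpha1"] * rho / (c - rho)
    return BNBParams(alpha0, sh["alpha1"], sh["alpha2"], sh["beta1"], sh["beta2"])


_PRESETS = _load_presets()


def lognormal_scenario_names() -> Tuple[str, ...]:
    return tuple(_PRESETS["lognormal"])


def bzinb_masking_names() -> Tuple[str, ...]:
    return tuple(_PRESETS["bzinb"]["masking"])


def bzinb_masking_pi(name: str) -> np.ndarray:
    return np.asarray(_PRESETS["bzinb"]["masking"][name]["pi"], dtype=float)


def bzinb_expected_zeros(name: str, n: int = 300) -> Tuple[float, float]:
    """Expected masked-zero counts (margin 1, margin 2) at sample size n."""
    pi = bzinb_masking_pi(name)
    return n * (pi[2] + pi[3]), n * (pi[1] + pi[3])


# ---------------------------------------------------------------------------
# lognormal pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LognormalScenario:
    """Bivariate lognormal pair design with per-margin zeroing."""

    mu1: float
    mu2: float
    rho: float
    nzero1: int
    nzero2: int
    mechanism1: str = "rank_based"  # or "random_exact"
    mechanism2: str = "random_exact"
    sigma: float = 1.0
    n: int = 300
    span: float = 0.3

    def __post_init__(self):
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0 <= self.nzero1 < self.n and 0 <= self.nzero2 < self.n):
            raise ValueError("zero targets must be < n")
        for m in (self.mechanism1, self.mechanism2):
            if m not in ("rank_based", "random_exact"):
                raise ValueError(f"unknown zeroing mechanism {m!r}")


def get_lognormal_scenario(name: str, rho: float, n: int = 300) -> LognormalScenario:
    sc = _PRESETS["lognormal"][name]
    (mu1, mu2), (z1, z2) = sc["means"], sc["zeros"]
    m1, m2 = sc["mechanisms"]
    scale = n / 300.0
    return LognormalScenario(
        mu1, mu2, rho, round(z1 * scale), round(z2 * scale), m1, m2, n=n
    )


def simulate_lognormal_pair(scenario: LognormalScenario, seed=None):
    """Correlated lognormal counts with per-margin excess zeros.

    Log-counts are bivariate normal with the scenario's means, common
    standard deviation and correlation; counts are the exponentials
    rounded to the nearest integer, after which each margin's zeroing
    mechanism is applied.
    """
    rng = _rng(seed)
    n, s, r = scenario.n, scenario.sigma, scenario.rho
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    z1 = scenario.mu1 + s * e1
    z2 = scenario.mu2 + s * (r * e1 + np.sqrt(1.0 - r * r) * e2)
    c1 = np.rint(np.exp(z1)).astype(np.int64)
    c2 = np.rint(np.exp(z2)).astype(np.int64)
    out = []
    for counts, nzero, mech in (
        (c1, scenario.nzero1, scenario.mechanism1),
        (c2, scenario.nzero2, scenario.mechanism2),
    ):
        if mech == "rank_based":
            counts = apply_rank_based_zeroing(
                counts, nzero / n, span=scenario.span, seed=rng
            )
        else:
            counts = apply_random_exact_zeroing(counts, nzero, seed=rng)
        out.append(counts)
    return out[0], out[1]


def apply_rank_based_zeroing(counts, pzero: float, span: float = 0.3, seed=None):
    """Dropout by abundance rank: element ``i`` is zeroed with probability
    ``(0.5 - rank_i / n) * span + pzero`` (rank 1 = smallest count, so low
    counts are likeliest to drop out, mimicking concentration-limited
    metabolite detection).  Ties receive midranks; probabilities are
    clamped to [0, 1]."""
    if not 0.0 <= pzero < 1.0:
        raise ValueError("pzero must lie in [0, 1)")
    counts = np.asarray(counts).copy()
    n = counts.size
    rng = _rng(seed)
    ranks = rankdata(counts, method="average")
    p = np.clip((0.5 - ranks / n) * span + pzero, 0.0, 1.0)
    counts[rng.random(n) < p] = 0
    return counts


def apply_random_exact_zeroing(counts, nzero: int, seed=None):
    """Set exactly ``nzero`` uniformly chosen positions to zero."""
    counts = np.asarray(counts).copy()
    if nzero > counts.size:
        raise ValueError("nzero exceeds the vector length")
    rng = _rng(seed)
    idx = rng.choice(counts.size, size=nzero, replace=False)
    counts[idx] = 0
    return counts


# ---------------------------------------------------------------------------
# BZINB pairs
# ---------------------------------------------------------------------------

def get_bzinb_preset(masking: str, rho: float) -> BZINBParams:
    """Preset BZINB parameters: a masking regime (``bzinb_a``..``bzinb_d``)
    combined with shapes/scales hitting the target latent correlation."""
    pi = bzinb_masking_pi(masking)
    bnb = _shape_preset(_PRESETS["bzinb"]["shapes"], rho)
    return BZINBParams(bnb, *pi)


def simulate_bzinb_pair(params: BZINBParams, n: int, seed=None):
    """Generative BZINB draw (thin wrapper over the model sampler)."""
    return sample_bzinb(params, n, seed)


# ---------------------------------------------------------------------------
# baseline matrix and crafted clusters
# ---------------------------------------------------------------------------

def generate_baseline_matrix(
    n_features: int = 400,
    n_samples: int = 180,
    seed=None,
    mean_count: float = 17968.0,
    nb_size: float = 0.7,
    core_sigma: float = 0.5,
    core_median: Optional[float] = None,
    dominant_fraction: float = 0.05,
    dominant_sigma: float = 0.8,
) -> pd.DataFrame:
    """Baseline species-by-sample count matrix.

    The abundance profile has the two-tier structure of shotgun species
    tables: a large core of moderate-abundance taxa (lognormal means,
    ``core_sigma`` spread) and a small dominant tier
    (``dominant_fraction``) that carries most of the reads and lifts the
    overall mean count to ``mean_count``.  Counts within a feature are
    negative binomial (``nb_size`` controls overdispersion) and every
    feature has a structural-zero probability decreasing with abundance,
    giving the characteristic decreasing mean-versus-zeros trend.

    By default the core mode is placed at ``sqrt(2 * nb_size *
    mean_count)``, so that a typical core feature's variance is about
    twice the community mean count.  That is the regime in which weighted-share
    cluster crafting (see :func:`craft_cluster_signal`) produces
    block-correlated clusters that a negative-binomial model can
    express -- a property the synthetic data is required to emulate --
    and the placement scales with ``mean_count``, so desk-scale versions
    of the matrix preserve the same mechanism.
    """
    if n_features < 1 or n_samples < 1:
        raise ValueError("dimensions must be positive")
    rng = _rng(seed)
    if core_median is None:
        core_median = float(np.sqrt(2.0 * nb_size * mean_count))
    n_dom = int(round(dominant_fraction * n_features))
    dom = np.zeros(n_features, dtype=bool)
    if n_dom:
        dom[rng.choice(n_features, n_dom, replace=False)] = True
    log_mu = rng.normal(np.log(core_median), core_sigma, n_features)
    log_mu[dom] = rng.normal(np.log(core_median) + 3.0, dominant_sigma, n_dom)
    p_zero = np.clip(
        0.75 * expit(-0.55 * (log_mu - np.log(core_median)))
        + rng.normal(0.0, 0.03, n_features),
        0.0,
        0.9,
    )
    mu = np.exp(log_mu)
    # lift the dominant tier so the expected overall mean hits the target
    core_part = np.mean(mu * (1.0 - p_zero) * ~dom)
    dom_part = np.mean(mu * (1.0 - p_zero) * dom)
    if n_dom and dom_part > 0 and mean_count > core_part:
        mu[dom] *= (mean_count - core_part) / dom_part
    else:
        mu *= mean_count / (core_part + dom_part)
    p_nb = nb_size / (nb_size + mu)
    counts = rng.negative_binomial(nb_size, p_nb[:, None], (n_features, n_samples))
    present = rng.random((n_features, n_samples)) >= p_zero[:, None]
    counts = counts * present
    return pd.DataFrame(
        counts,
        index=[f"sp{i:04d}" for i in range(n_features)],
        columns=[f"s{j:04d}" for j in range(n_samples)],
    )


@dataclass(frozen=True)
class ClusterCraftConfig:
    """Configuration of the semi-parametric cluster-signal crafting."""

    k: int = 10
    cluster_size: int = 40
    weight: float = 0.9
    lam: Optional[float] = None  # shared-vector Poisson mean; None = matrix mean
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.weight <= 1.0:
            raise ValueError("weight must lie in (0, 1]")
        if self.k < 1 or self.cluster_size < 1:
            raise ValueError("k and cluster_size must be positive")


def craft_cluster_signal(
    matrix: pd.DataFrame, config: ClusterCraftConfig = ClusterCraftConfig()
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Inject ground-truth correlated modules into a count matrix.

    Features are permuted and the first ``k * cluster_size`` split into
    ``k`` clusters.  Each cluster draws one shared Poisson vector ``R`` and
    every nonzero entry of each member feature is replaced by
    ``round(w * y + (1 - w) * R)``; zeros are left untouched, so the
    zero pattern is exactly preserved.  Returns the modified matrix and
    per-feature truth labels (1..k; 0 for unclustered features).
    """
    k, size, w = config.k, config.cluster_size, config.weight
    n_feat, n_samp = matrix.shape
    if k * size > n_feat:
        raise ValueError("matrix has too few features for the requested clusters")
    rng = _rng(config.seed)
    lam = config.lam if config.lam is not None else float(matrix.to_numpy().mean())
    perm = rng.permutation(n_feat)
    labels = np.zeros(n_feat, dtype=np.int64)
    out = matrix.to_numpy().copy()
    for c in range(k):
        members = perm[c * size : (c + 1) * size]
        labels[members] = c + 1
        shared = rng.poisson(lam, n_samp)
        for j in members:
            row = out[j]
            nz = row > 0
            row[nz] = np.rint(w * row[nz] + (1.0 - w) * shared[nz]).astype(np.int64)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns), labels


def rescale_counts(x, target_sd: float = 30.0):
    """The computational-efficiency rescaling for real count vectors:
    divide by the standard deviation, multiply by ``target_sd`` and round
    to integers (zeros map to zeros)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot rescale a constant vector")
    return np.rint(x / sd * target_sd).astype(np.int64)
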