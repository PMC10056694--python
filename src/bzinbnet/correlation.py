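"""Uniform interface over the four correlation estimators and pairwise
correlation matrices across one or two omics layers.

Spearman (midranks on ties) and Pearson are delegated to scipy; the
model-based estimators fit the BNB/BZINB model to every feature pair and
report the correlation of the latent shared-component model.  Failed
fits (constant or all-zero margins, non-convergence) yield NaN entries
with a status flag rather than aborting the matrix.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from . import model
__all__ = [
    "spearman",
    "pearson",
    "CorrMatrix",
    "PairwiseCorrelation",
    "corr_matrix",
    "benchmark_estimators",
]

METHODS = ("spearman", "pearson", "bnb", "bzinb")


def _check_pair(x, y, min_n=3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} paired observations")
    return x, y


def spearman(x, y) -> float:
    """Rank correlation with average (mid-)ranks on ties.

    Equals Pearson on midranks; with ties this is the normative form
    (the textbook 1 - 6*sum(d^2)/(n(n^2-1)) shortcut is tie-invalid).
    Constant input is undefined and raises.
    """
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def pearson(x, y) -> float:
    """Product-moment correlation; constant input raises."""
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class CorrMatrix:
    """Correlation matrix with feature identifiers and per-entry status.

    ``values`` is a rows-by-columns DataFrame (rows == columns for a
    within-layer matrix); ``status`` holds an empty string for clean
    entries and a short reason for every non-finite entry.
    """

    values: pd.DataFrame
    method: str
    status: pd.DataFrame

    @property
    def square(self) -> bool:
        return self.values.index.equals(self.values.columns)

    def to_tsv(self, path) -> None:
        """Write values as TSV plus a JSON sidecar with method/failures."""
        path = Path(path)
        self.values.to_csv(path, sep="\t")
        failures = [
            {"row": str(r), "col": str(c), "reason": self.status.at[r, c]}
            for r in self.status.index
            for c in self.status.columns
            if self.status.at[r, c]
        ]
        meta = {"method": self.method, "failures": failures}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1)
        )

    @classmethod
    def from_tsv(cls, path) -> "CorrMatrix":
        path = Path(path)
        values = pd.read_csv(path, sep="\t", index_col=0)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        method = "unknown"
        status = pd.DataFrame("", index=values.index, columns=values.columns)
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            method = meta.get("method", method)
            for f in meta.get("failures", []):
                status.at[f["row"], f["col"]] = f["reason"]
        return cls(values, method, status)


class PairwiseCorrelation(BaseEstimator):
    """All-pairs correlation estimator over the features of a count matrix.

    Parameters
    ----------
    method : {'spearman', 'pearson', 'bnb', 'bzinb'}
        Estimator applied to every feature pair.  The model-based
        choices fit the (zero-inflated) bivariate negative binomial to
        each pair and report the latent-component correlation, which is
        non-negative by construction.
    complete_pairs_only : bool
        Drop samples with a zero in either member of the pair before
        computing (the "complete data" convention).
    max_count : int or None
        Integer downscaling guard for the model-based fits: pairs whose
        counts exceed this value are scaled down (preserving zeros)
        before fitting, since the finite-sum likelihood cost grows with
        the maximum count.  ``None`` disables rescaling.
    max_iter, tol, restarts, random_state
        Passed to the per-pair fits; each pair derives its own seed so
        results are independent of evaluation order.

    Attributes
    ----------
    correlation_ : ndarray of shape (n_rows, n_cols)
    status_ : ndarray of str, '' for clean entries
    """

    def __init__(
        self,
        method: str = "bzinb",
        complete_pairs_only: bool = False,
        max_count: Optional[int] = 200,
        max_iter: int = 1000,
        tol: float = 1e-6,
        restarts: int = 1,
        random_state: int = 0,
    ):
        self.method = method
        self.complete_pairs_only = complete_pairs_only
        self.max_count = max_count
        self.max_iter = max_iter
        self.tol = tol
        self.restarts = restarts
        self.random_state = random_state

    def _pair_value(self, x, y, i, j):
        if self.complete_pairs_only:
            keep = (x > 0) & (y > 0)
            x, y = x[keep], y[keep]
        try:
            if self.method == "spearman":
                return spearman(x, y), ""
            if self.method == "pearson":
                return pearson(x, y), ""
            x = _downscale(x, self.max_count)
            y = _downscale(y, self.max_count)
            seed = np.random.default_rng([self.random_state, i, j]).integers(2**31)
            fit = (model.fit_bnb if self.method == "bnb" else model.fit_bzinb)(
                x, y, max_iter=self.max_iter, tol=self.tol,
                restarts=self.restarts, seed=int(seed),
            )
            if not fit.ok or not np.isfinite(fit.rho):
                return np.nan, fit.status or "fit failed"
            return fit.rho, "" if fit.converged else "not converged"
        except ValueError as exc:
            return np.nan, str(exc)

    def fit(self, X, Y=None):
        """Compute correlations among columns of X (or between X and Y).

        ``X`` and ``Y`` are samples-by-features count arrays sharing the
        sample ordering.
        """
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        X = np.asarray(X)
        cross = Y is not None
        Y = np.asarray(Y) if cross else X
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must share the sample axis")
        nr, nc = X.shape[1], Y.shape[1]
        vals = np.full((nr, nc), np.nan)
        status = np.full((nr, nc), "", dtype=object)
        for i in range(nr):
            j0 = 0 if cross else i
            for j in range(j0, nc):
                if not cross and i == j:
                    vals[i, i] = 1.0
                    continue
                v, s = self._pair_value(X[:, i], Y[:, j], i, j)
                vals[i, j] = v
                status[i, j] = s
                if not cross:
                    vals[j, i] = v
                    status[j, i] = s
        self.correlation_ = vals
        self.status_ = status
        return self

    def fit_transform(self, X, Y=None):
        return self.fit(X, Y).correlation_


def _downscale(x: np.ndarray, max_count: Optional[int]) -> np.ndarray:
    """Integer downscaling to keep finite-sum fits tractable; zeros and
    the zero/nonzero pattern are preserved (nonzero entries stay >= 1)."""
    x = np.asarray(x)
    if max_count is None or x.max(initial=0) <= max_count:
        return x
    scaled = np.rint(x * (max_count / x.max())).astype(np.int64)
    scaled[(x > 0) & (scaled == 0)] = 1
    return scaled


def corr_matrix(
    X: pd.DataFrame,
    Y: Optional[pd.DataFrame] = None,
    method: str = "spearman",
    complete_pairs_only: bool = False,
    **kwargs,
) -> CorrMatrix:
    """Pairwise correlations for features-by-samples count DataFrames.

    When ``Y`` is given the result is the bipartite block (features of
    ``X`` by features of ``Y``); sample columns must align.
    """
    if Y is not None and not X.columns.equals(Y.columns):
        raise ValueError("X and Y must share the same sample columns")
    est = PairwiseCorrelation(
        method=method, complete_pairs_only=complete_pairs_only, **kwargs
    )
    est.fit(X.to_numpy().T, Y.to_numpy().T if Y is not None else None)
    cols = (Y if Y is not None else X).index
    values = pd.DataFrame(est.correlation_, index=X.index, columns=cols)
    status = pd.DataFrame(est.status_, index=X.index, columns=cols)
    return CorrMatrix(values, method, status)


def benchmark_estimators(
    scenarios: Sequence[str],
    true_rhos: Sequence[float],
    n_reps: int,
    seed: int = 1,
    n: int = 300,
    methods: Sequence[str] = METHODS,
) -> pd.DataFrame:
    """Replicate study of estimator accuracy on simulated pairs.

    For every (scenario, true rho) cell, ``n_reps`` pairs are simulated
    from the named preset (a Table-style lognormal design or a BZINB
    masking regime) and all requested estimators are computed; the
    report holds the mean and median estimate plus the failure count.
    Fully deterministic for a fixed seed.
    """
    from . import simulate as sim  # local import to avoid a cycle

    rows = []
    for scenario in scenarios:
        for rho in true_rhos:
            est_values = {m: [] for m in methods}
            failures = {m: 0 for m in methods}
            for rep in range(n_reps):
                rng = np.random.default_rng(
                    [seed, zlib.crc32(scenario.encode()), int(rho * 1e6), rep]
                )
                if scenario in sim.lognormal_scenario_names():
                    sc = sim.get_lognormal_scenario(scenario, rho=rho, n=n)
                    y1, y2 = sim.simulate_lognormal_pair(sc, rng)
                    y1 = _downscale(y1, 300)
                    y2 = _downscale(y2, 300)
                else:
                    params = sim.get_bzinb_preset(scenario, rho=rho)
                    y1, y2 = sim.simulate_bzinb_pair(params, n=n, seed=rng)
                for m in methods:
                    try:
                        if m == "spearman":
                            v = spearman(y1, y2)
                        elif m == "pearson":
                            v = pearson(y1, y2)
                        else:
                            fit = (
                                model.fit_bnb if m == "bnb" else model.fit_bzinb
                            )(y1, y2, restarts=1,
                              seed=int(rng.integers(2**31)))
                            if not fit.ok or not np.isfinite(fit.rho):
                                raise ValueError(fit.status)
                            v = fit.rho
                        est_values[m].append(v)
                    except ValueError:
                        failures[m] += 1
            for m in methods:
                vals = np.asarray(est_values[m])
                rows.append(
                    {
                        "scenario": scenario,
                        "method": m,
                        "rho_true": rho,
                        "mean": vals.mean() if vals.size else np.nan,
                        "median": np.median(vals) if vals.size else np.nan,
                        "n_reps": n_reps,
                        "n_failed": failures[m],
                        "seed": seed,
                    }
                )
    return pd.DataFrame(rows)
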