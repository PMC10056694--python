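"""Parameter containers for the shared-component Poisson-Gamma count models.

The bivariate negative binomial (BNB) model couples two counts through a
common Gamma-distributed Poisson rate: with independent latent rates
``R0 ~ Gamma(alpha0, beta)``, ``R1 ~ Gamma(alpha1, beta)`` and
``R2 ~ Gamma(alpha2, beta)`` (``beta = beta1``, ``delta = beta2/beta1``),

    X1 | R ~ Poisson(R0 + R1),    X2 | R ~ Poisson(delta * (R0 + R2)),

so that marginally ``Xi ~ NB(alpha0 + alphai, 1 / (betai + 1))``.  The
zero-inflated extension (BZINB) masks the pair with zeros according to a
four-category multinomial: with probability ``pi1`` both margins are
observed, ``pi2`` only the first, ``pi3`` only the second, and ``pi4``
neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["BNBParams", "BZINBParams", "FitResult", "MomentSet"]

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class BNBParams:
    """Shape/scale parameters of the bivariate negative binomial model.

    All five parameters are strictly positive.  ``delta = beta2 / beta1``
    is the rate multiplier of the shared component in the second margin.
    """

    alpha0: float
    alpha1: float
    alpha2: float
    beta1: float
    beta2: float

    def __post_init__(self) -> None:
        for name in ("alpha0", "alpha1", "alpha2", "beta1", "beta2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")

    @property
    def delta(self) -> float:
        return self.beta2 / self.beta1

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha0, self.alpha1, self.alpha2, self.beta1, self.beta2]
        )

    def to_dict(self) -> dict:
        return {
            "alpha0": self.alpha0,
            "alpha1": self.alpha1,
            "alpha2": self.alpha2,
            "beta1": self.beta1,
            "beta2": self.beta2,
        }


@dataclass(frozen=True)
class BZINBParams:
    """BNB parameters plus the 4-category zero-inflation simplex.

    ``pi1``: both margins unmasked; ``pi2``: only the first unmasked
    (second forced to zero); ``pi3``: only the second unmasked; ``pi4``:
    both masked.  The marginal masking probability of margin 1 is
    ``pi3 + pi4`` and of margin 2 is ``pi2 + pi4``.
    """

    bnb: BNBParams
    pi1: float
    pi2: float
    pi3: float
    pi4: float

    def __post_init__(self) -> None:
        pis = self.pi
        if np.any(pis < 0) or np.any(pis > 1):
            raise ValueError(f"pi probabilities must lie in [0, 1], got {pis}")
        if abs(pis.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"pi must sum to 1 (tol {_SIMPLEX_TOL}), got {pis.sum()!r}")

    @property
    def pi(self) -> np.ndarray:
        return np.array([self.pi1, self.pi2, self.pi3, self.pi4])

    @property
    def mask_prob1(self) -> float:
        """Probability that margin 1 is masked with a structural zero."""
        return self.pi3 + self.pi4

    @property
    def mask_prob2(self) -> float:
        return self.pi2 + self.pi4

    def to_dict(self) -> dict:
        d = self.bnb.to_dict()
        d.update(pi1=self.pi1, pi2=self.pi2, pi3=self.pi3, pi4=self.pi4)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BZINBParams":
        bnb = BNBParams(d["alpha0"], d["alpha1"], d["alpha2"], d["beta1"], d["beta2"])
        return cls(bnb, d["pi1"], d["pi2"], d["pi3"], d["pi4"])


@dataclass
class FitResult:
    """Outcome of a BNB or BZINB maximum-likelihood fit.

    ``rho`` is the model-based correlation of the latent BNB component
    (NaN when the fit failed); ``trace`` is the per-iteration
    log-likelihood record of the optimizer.
    """

    params: Optional[object]  # BNBParams | BZINBParams | None on failure
    loglik: float
    n_iter: int
    converged: bool
    rho: float
    status: str = "ok"
    trace: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass(frozen=True)
class MomentSet:
    """Closed-form moments of the BNB component and of the masked pair.

    ``mean*/var*/cov`` refer to the unmasked BNB pair; the ``naive_*``
    fields are the moments of the observed (masked) pair and enter the
    naive correlation.
    """

    mean1: float
    mean2: float
    var1: float
    var2: float
    cov: float
    naive_sigma12: float
    naive_sigma1sq: float
    naive_sigma2sq: float
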