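"""Negative binomial log-likelihood, deviance and IRLS weights.

All fitting in this package uses the NB2 parameterisation
``Var(K) = mu + alpha * mu**2`` with log link; ``alpha`` is the
overdispersion (the reciprocal of the NB size ``r``).
"""

from __future__ import annotations

import numpy as np
from scipy import special

# means are clipped into this range inside IRLS to avoid overflow
MU_MIN = 1e-10
MU_MAX = 1e12


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood of counts ``y`` at means ``mu`` and dispersion ``alpha``."""
    r = 1.0 / alpha
    mu = np.clip(mu, MU_MIN, MU_MAX)
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1.0)
            + r * np.log(r / (r + mu))
            + special.xlogy(y, mu / (r + mu))
        )
    )


def nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 deviance (twice the log-likelihood gap to the saturated model)."""
    r = 1.0 / alpha
    mu = np.clip(mu, MU_MIN, MU_MAX)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = special.xlogy(y, y / mu)
    t2 = (y + r) * np.log((y + r) / (mu + r))
    return float(2.0 * np.sum(t1 - t2))


def nb_weights(mu: np.ndarray, alpha: float) -> np.ndarray:
    """Fisher-scoring working weights for the log link: mu / (1 + alpha*mu)."""
    return mu / (1.0 + alpha * mu)
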