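"""Negative binomial distribution in mean/dispersion form.

Parameterised by mean mu and dispersion theta with variance mu + mu^2/theta
(the "NB2" form; Poisson recovered as theta -> infinity). Probabilities are
evaluated through scipy's nbinom with size theta and success probability
theta / (theta + mu), which works in log space internally. Sampling uses the
gamma-Poisson mixture: lambda ~ Gamma(theta, mu/theta), X | lambda ~
Poisson(lambda).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = ["NegBinModel", "fit_theta", "nb_pmf", "nb_cdf", "nb_sample"]

LOGTHETA_LO = -5.0
LOGTHETA_HI = 10.0
LOGTHETA_TOL = 1e-8


@dataclass(frozen=True)
class NegBinModel:
    """Negative binomial with mean ``mu`` and dispersion ``theta``."""

    mu: float
    theta: float

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")

    @property
    def variance(self) -> float:
        return self.mu + self.mu**2 / self.theta

    @property
    def _p(self) -> float:
        return self.theta / (self.theta + self.mu)


def _check_k(k):
    k = np.asarray(k)
    if np.any(k < 0):
        raise ValueError("k must be non-negative")
    return k


def nb_pmf(model: NegBinModel, k):
    """P(X = k)."""
    k = _check_k(k)
    return stats.nbinom.pmf(k, model.theta, model._p)


def nb_cdf(model: NegBinModel, k):
    """P(X <= k)."""
    k = _check_k(k)
    return stats.nbinom.cdf(k, model.theta, model._p)


def nb_sf_geq(model: NegBinModel, cutoff: int) -> float:
    """Tail mass P(X >= cutoff); the per-pupil 'case' probability."""
    if cutoff <= 0:
        return 1.0
    return float(stats.nbinom.sf(cutoff - 1, model.theta, model._p))


def nb_sample(model: NegBinModel, n: int, seed=None) -> np.ndarray:
    """Draw n values via the gamma-Poisson mixture; reproducible given seed.

    ``seed`` may also be an existing numpy Generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = rng.gamma(model.theta, model.mu / model.theta, n)
    return rng.poisson(lam)


def fit_theta(scores) -> NegBinModel:
    """Estimate (mu, theta) from integer scores.

    mu is fixed at the sample mean; theta maximises the NB log-likelihood by
    bounded search over log(theta). Underdispersed samples (variance <= mean)
    are rejected with advice to use a Poisson model instead.
    """
    scores = np.asarray(scores)
    if scores.size < 10:
        raise ValueError("need at least 10 observations")
    if np.any(scores < 0):
        raise ValueError("scores must be non-negative")
    mu = float(scores.mean())
    var = float(scores.var(ddof=1))
    if var <= mu:
        raise ValueError(
            "sample variance does not exceed the mean; the data are not "
            "overdispersed - consider a Poisson model"
        )
    # compress to unique values so the likelihood is O(#unique) per evaluation
    vals, counts = np.unique(scores.astype(int), return_counts=True)

    def neg_ll(logtheta: float) -> float:
        theta = np.exp(logtheta)
        p = theta / (theta + mu)
        return -float(counts @ stats.nbinom.logpmf(vals, theta, p))

    res = minimize_scalar(
        neg_ll,
        bounds=(LOGTHETA_LO, LOGTHETA_HI),
        method="bounded",
        options={"xatol": LOGTHETA_TOL},
    )
    return NegBinModel(mu=mu, theta=float(np.exp(res.x)))
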