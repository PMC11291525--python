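"""Bootstrap confidence intervals for the school-level SD and the ICC.

Two resampling schemes are provided. The default, a parametric bootstrap,
simulates new outcome vectors from the fitted model (fresh school and pupil
draws at the estimated sigma_u, sigma_e) and refits; it matches the
model-based estimand and behaves sensibly when sigma_u is at or near the
zero boundary. The alternative resamples whole schools with replacement
(cluster nonparametric). Intervals are 2.5/97.5 percentile intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .lmm import LmmFit, ProfiledRandomInterceptLMM, fit_lmm, icc

logger = logging.getLogger(__name__)

__all__ = ["VarCompCI", "bootstrap_varcomp"]

MAX_FAILED_FRACTION = 0.10


@dataclass
class VarCompCI:
    sigma_u_ci: tuple
    icc_ci: tuple
    sigma_u_draws: np.ndarray
    icc_draws: np.ndarray
    n_boot: int
    n_failed: int
    method: str
    seed: int | None


def bootstrap_varcomp(
    fit: LmmFit,
    y,
    X,
    groups,
    n_boot: int = 2000,
    method: str = "parametric",
    seed: int | None = None,
) -> VarCompCI:
    """Percentile bootstrap CIs for sigma_u and the ICC.

    Parameters
    ----------
    fit : the point fit being bootstrapped (REML by default upstream).
    y, X, groups : the data the fit was computed from.
    method : "parametric" or "cluster_nonparametric".

    Non-converged refits are dropped with a logged count; more than 10%
    failures raises.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if method not in ("parametric", "cluster_nonparametric"):
        raise ValueError(f"unknown bootstrap method {method!r}")

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)

    sig_u = np.empty(n_boot)
    iccs = np.empty(n_boot)
    ok = np.zeros(n_boot, dtype=bool)

    if method == "parametric":
        # One precomputed fitter; only the outcome changes per replicate.
        import pandas as pd

        codes = pd.factorize(groups, sort=True)[0].astype(np.intp)
        fitter = ProfiledRandomInterceptLMM(X, codes)
        J, n = fitter.J, fitter.n
        mu = X @ fit.beta
        for b in range(n_boot):
            u = rng.normal(0.0, fit.sigma_u, J)
            e = rng.normal(0.0, fit.sigma_e, n)
            refit = fitter.fit(mu + u[codes] + e, criterion=fit.criterion)
            ok[b] = refit.converged
            sig_u[b], iccs[b] = refit.sigma_u, icc(refit)
    else:
        import pandas as pd

        codes = pd.factorize(groups, sort=True)[0].astype(np.intp)
        J = codes.max() + 1
        members = [np.flatnonzero(codes == j) for j in range(J)]
        for b in range(n_boot):
            pick = rng.integers(0, J, J)
            rows = np.concatenate([members[j] for j in pick])
            new_codes = np.repeat(np.arange(J), [len(members[j]) for j in pick])
            try:
                refit = fit_lmm(y[rows], X[rows], new_codes, criterion=fit.criterion)
            except np.linalg.LinAlgError:
                ok[b] = False
                continue
            ok[b] = refit.converged
            sig_u[b], iccs[b] = refit.sigma_u, icc(refit)

    n_failed = int((~ok).sum())
    if n_failed > MAX_FAILED_FRACTION * n_boot:
        raise RuntimeError(f"{n_failed}/{n_boot} bootstrap refits failed to converge")
    if n_failed:
        logger.warning("dropped %d non-converged bootstrap refits", n_failed)

    sig_u, iccs = sig_u[ok], iccs[ok]
    return VarCompCI(
        sigma_u_ci=(float(np.percentile(sig_u, 2.5)), float(np.percentile(sig_u, 97.5))),
        icc_ci=(float(np.percentile(iccs, 2.5)), float(np.percentile(iccs, 97.5))),
        sigma_u_draws=sig_u,
        icc_draws=iccs,
        n_boot=n_boot,
        n_failed=n_failed,
        method=method,
        seed=seed,
    )
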