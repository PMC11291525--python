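"""Multiple imputation of incomplete covariates and Rubin's-rule pooling.

The imputer is a bootstrap-EM multivariate normal: for each of the m
imputations, the rows of the cohort are resampled with replacement, a
multivariate normal is fitted to a numeric coding of the variables by EM
over the missing-data patterns, and each originally missing cell is then
drawn from its conditional normal given the row's observed cells. Ordinal
draws (IMD quintile 1-5, NS-SEC coded 1-5) are rounded and clipped to valid
categories; PHQ8 draws are rounded and clipped to [0, 24]. Observed cells
are never altered, so they are identical across the m completed datasets.

Pooling follows Rubin's rules: the pooled coefficient is the mean across
imputations; its total variance is W + (1 + 1/m) B where W is the mean
within-imputation variance and B the between-imputation variance; small-m
degrees of freedom follow (m - 1) (1 + W / ((1 + 1/m) B))^2. Variance
components have no standard Rubin variance, so sigma_u and the ICC are
pooled as plain means with the across-imputation SD reported as a spread
diagnostic. The evidence for the random intercept is summarised by the
median likelihood-ratio p-value across imputations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import NSSEC_LEVELS, ETHNICITY_LEVELS, HOUSEHOLD_LEVELS, MISSABLE
from .lmm import LmmFit, icc as _icc

__all__ = ["ImputationSet", "PooledFit", "impute", "pool_rubin"]

EM_MAX_ITER = 500
EM_TOL = 1e-6
MAX_MISSING_FRACTION = 0.95

_NSSEC_CODE = {lvl: i + 1 for i, lvl in enumerate(NSSEC_LEVELS)}
_HOUSEHOLD_CODE = {lvl: i + 1 for i, lvl in enumerate(HOUSEHOLD_LEVELS)}


@dataclass
class ImputationSet:
    m: int
    completed: list  # list of DataFrames with no missing cells in MISSABLE
    imputer_params: list  # per imputation: {"mean": ..., "cov": ..., "columns": ...}
    seed: int | None
    sub_seeds: list = field(default_factory=list)
    # per imputation: the numeric matrix with conditional-normal draws in the
    # missing cells *before* rounding/clipping (diagnostic: under MCAR these
    # latent draws are mean-unbiased for the observed-data distribution)
    latent: list = field(default_factory=list)
    columns: list = field(default_factory=list)


def _numeric_coding(cohort: pd.DataFrame, outcome: str) -> tuple[np.ndarray, list]:
    """Numeric matrix for the EM model: outcome, age, sex, ethnicity dummies,
    household ordinal (complete predictors) plus the three incomplete
    columns coded imd 1-5, nssec 1-5, phq8 count."""
    cols: dict[str, np.ndarray] = {}
    cols[outcome] = cohort[outcome].to_numpy(dtype=float)
    cols["age"] = cohort["age"].to_numpy(dtype=float)
    cols["sex_male"] = (cohort["sex"] == "male").to_numpy(dtype=float)
    for lvl in ETHNICITY_LEVELS[1:]:
        cols[f"eth_{lvl.split()[0].lower()}"] = (cohort["ethnicity"] == lvl).to_numpy(dtype=float)
    cols["household_ord"] = cohort["household_size"].map(_HOUSEHOLD_CODE).to_numpy(dtype=float)
    cols["imd_quintile"] = cohort["imd_quintile"].to_numpy(dtype=float)
    cols["nssec_ord"] = cohort["nssec"].map(_NSSEC_CODE).to_numpy(dtype=float)
    cols["phq8"] = cohort["phq8"].to_numpy(dtype=float)
    names = list(cols)
    return np.column_stack([cols[c] for c in names]), names


def _em_mvnormal(Z: np.ndarray, max_iter: int = EM_MAX_ITER, tol: float = EM_TOL):
    """EM estimate of (mu, Sigma) of a multivariate normal with missing data.

    Iterates over distinct missingness patterns; accumulates expected
    sufficient statistics including the conditional covariance of the
    missing block. Raises on non-convergence.
    """
    n, p = Z.shape
    miss = np.isnan(Z)
    mu = np.nanmean(Z, axis=0)
    filled = np.where(miss, mu, Z)
    sigma = np.cov(filled, rowvar=False, bias=True) + 1e-6 * np.eye(p)

    pattern_ids = (miss @ (1 << np.arange(p))).astype(np.int64)
    patterns = {}
    for pid in np.unique(pattern_ids):
        rows = np.flatnonzero(pattern_ids == pid)
        patterns[pid] = (rows, miss[rows[0]])

    for _ in range(max_iter):
        Ez = Z.copy()
        cc = np.zeros((p, p))  # summed conditional covariance contributions
        for rows, pat in patterns.values():
            if not pat.any():
                continue
            o = ~pat
            Soo = sigma[np.ix_(o, o)]
            Smo = sigma[np.ix_(pat, o)]
            solve = np.linalg.solve(Soo, np.eye(o.sum()))
            B = Smo @ solve
            cond_mean = mu[pat] + (Z[np.ix_(rows, o)] - mu[o]) @ B.T
            Ez[np.ix_(rows, pat)] = cond_mean
            cond_cov = sigma[np.ix_(pat, pat)] - B @ Smo.T
            idx = np.flatnonzero(pat)
            cc[np.ix_(idx, idx)] += len(rows) * cond_cov
        mu_new = Ez.mean(axis=0)
        centred = Ez - mu_new
        sigma_new = (centred.T @ centred + cc) / n
        sigma_new += 1e-10 * np.eye(p)
        delta = max(np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max())
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            return mu, sigma
    raise RuntimeError(f"EM did not converge within {max_iter} iterations")


def _conditional_draw(z_row, pat, mu, sigma, rng) -> np.ndarray:
    """Draw the missing block of one row from N(cond mean, cond cov)."""
    o = ~pat
    Soo = sigma[np.ix_(o, o)]
    Smo = sigma[np.ix_(pat, o)]
    B = Smo @ np.linalg.solve(Soo, np.eye(int(o.sum())))
    cond_mean = mu[pat] + B @ (z_row[o] - mu[o])
    cond_cov = sigma[np.ix_(pat, pat)] - B @ Smo.T
    # symmetrise + jitter before factorising
    cond_cov = (cond_cov + cond_cov.T) / 2 + 1e-10 * np.eye(pat.sum())
    L = np.linalg.cholesky(cond_cov)
    return cond_mean + L @ rng.standard_normal(int(pat.sum()))


def impute(cohort: pd.DataFrame, m: int = 20, seed: int | None = None, outcome: str = "sdq_total") -> ImputationSet:
    """Generate m completed cohorts by bootstrap-EM multivariate-normal
    imputation of imd_quintile, nssec and phq8."""
    if m < 1:
        raise ValueError("m must be >= 1")
    needed = ["school_id", outcome, "age", "sex", "ethnicity", "household_size"]
    if cohort[needed].isna().any().any():
        bad = [c for c in needed if cohort[c].isna().any()]
        raise ValueError(f"missingness must be confined to {MISSABLE}; also missing: {bad}")
    for col in MISSABLE:
        frac = cohort[col].isna().mean()
        if frac > MAX_MISSING_FRACTION:
            raise ValueError(f"column {col!r} is {frac:.0%} missing")

    Z, names = _numeric_coding(cohort, outcome)
    miss = np.isnan(Z)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(m)
    sub_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    if not miss.any():
        return ImputationSet(
            m=m,
            completed=[cohort.copy() for _ in range(m)],
            imputer_params=[],
            seed=seed,
            sub_seeds=sub_seeds,
        )

    nssec_back = {i + 1: lvl for i, lvl in enumerate(NSSEC_LEVELS)}
    completed, params, latents = [], [], []
    row_has_miss = np.flatnonzero(miss.any(axis=1))
    for child in children:
        rng = np.random.default_rng(child)
        boot = rng.integers(0, len(Z), len(Z))
        mu, sigma = _em_mvnormal(Z[boot])
        params.append({"mean": mu, "cov": sigma, "columns": names})

        Zimp = Z.copy()
        for i in row_has_miss:
            Zimp[i, miss[i]] = _conditional_draw(Z[i], miss[i], mu, sigma, rng)
        latents.append(Zimp.copy())

        out = cohort.copy()
        j_imd, j_nssec, j_phq = names.index("imd_quintile"), names.index("nssec_ord"), names.index("phq8")
        imd = np.clip(np.rint(Zimp[:, j_imd]), 1, 5)
        nss = np.clip(np.rint(Zimp[:, j_nssec]), 1, 5).astype(int)
        phq = np.clip(np.rint(Zimp[:, j_phq]), 0, 24)
        out["imd_quintile"] = np.where(miss[:, j_imd], imd, cohort["imd_quintile"].to_numpy(dtype=float))
        nssec_col = cohort["nssec"].astype(object).copy()
        nssec_col[miss[:, j_nssec]] = [nssec_back[v] for v in nss[miss[:, j_nssec]]]
        out["nssec"] = nssec_col
        out["phq8"] = np.where(miss[:, j_phq], phq, cohort["phq8"].to_numpy(dtype=float))
        completed.append(out)

    return ImputationSet(
        m=m, completed=completed, imputer_params=params, seed=seed,
        sub_seeds=sub_seeds, latent=latents, columns=names,
    )


@dataclass
class PooledFit:
    labels: list
    beta_pooled: np.ndarray
    within_var: np.ndarray
    between_var: np.ndarray
    total_var: np.ndarray
    df: np.ndarray
    m: int
    sigma_u_pooled: float
    sigma_u_spread: float
    icc_pooled: float
    icc_spread: float
    lrt_p_median: float | None = None

    @property
    def beta_se(self) -> np.ndarray:
        return np.sqrt(self.total_var)


def pool_rubin(fits: list, lrt_p_values=None) -> PooledFit:
    """Combine per-imputation model fits by Rubin's rules."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to pool")
    labels = list(fits[0].labels)
    for f in fits[1:]:
        if list(f.labels) != labels:
            raise ValueError("coefficient labels differ across fits")
    m = len(fits)
    betas = np.array([f.beta for f in fits])
    W = np.array([np.diag(f.beta_cov) for f in fits]).mean(axis=0)
    beta_pooled = betas.mean(axis=0)
    B = betas.var(axis=0, ddof=1)
    total = W + (1.0 + 1.0 / m) * B
    with np.errstate(divide="ignore"):
        df = np.where(B > 0, (m - 1) * (1.0 + W / ((1.0 + 1.0 / m) * B)) ** 2, np.inf)
    sig_u = np.array([f.sigma_u for f in fits])
    iccs = np.array([_icc(f) for f in fits])
    return PooledFit(
        labels=labels,
        beta_pooled=beta_pooled,
        within_var=W,
        between_var=B,
        total_var=total,
        df=df,
        m=m,
        sigma_u_pooled=float(sig_u.mean()),
        sigma_u_spread=float(sig_u.std(ddof=1)),
        icc_pooled=float(iccs.mean()),
        icc_spread=float(iccs.std(ddof=1)),
        lrt_p_median=(float(np.median(lrt_p_values)) if lrt_p_values is not None else None),
    )
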