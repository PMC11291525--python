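"""Random-intercept linear mixed model fitted by profiled REML/ML.

The model is

    y_ij = x_ij' beta + u_j + e_ij,   u_j ~ N(0, sigma_u^2),  e_ij ~ N(0, sigma_e^2)

for pupil i in school j. With lambda = sigma_u^2 / sigma_e^2 the marginal
covariance is sigma_e^2 * V0(lambda) where V0 is block diagonal with blocks
I + lambda * J per school. Both beta and sigma_e^2 have closed forms given
lambda, so estimation reduces to a bounded one-dimensional search over
log(lambda); each criterion evaluation costs O(J p^2) using per-school
sufficient statistics, which makes bootstrap refits cheap.

The restricted log-likelihood follows the Harville form (without the
constant |X'X| term):

    L_R = -1/2 [ (n-p) (log 2*pi*s2 + 1) + log|V0| + log|X' V0^-1 X| ]

with s2 = r' V0^-1 r / (n - p) profiled out. The ML log-likelihood replaces
(n-p) with n and drops the |X' V0^-1 X| term.

BLUPs of the school intercepts have the closed shrinkage form
u_j = lambda n_j / (1 + lambda n_j) * (mean within-school residual), with
conditional SD sigma_e * sqrt(lambda / (1 + lambda n_j)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "ModelSpec",
    "LmmFit",
    "LrtResult",
    "build_design",
    "fit_lmm",
    "icc",
    "lrt_random_intercept",
    "school_quantile_mean",
    "quantile_mean",
    "school_means",
    "fit_to_json",
    "fit_from_json",
]

LOGLAM_LO = -20.0
LOGLAM_HI = 10.0
LOGLAM_TOL = 1e-10
# The profiled criterion can be multimodal for very small/degenerate designs,
# so the 1-D search first scans a coarse grid to bracket the global optimum.
N_SCAN = 41

# Covariate terms in the order the adjusted model reports them.
DEFAULT_FIXED_TERMS = (
    "age",
    "sex",
    "season",
    "imd_quintile",
    "ethnicity",
    "phq8",
    "nssec",
    "household_size",
)

_CATEGORY_LEVELS = {
    # reference level first
    "sex": ["female", "male"],
    "season": ["winter", "spring", "summer", "autumn"],
    "imd_quintile": [1, 2, 3, 4, 5],
    "ethnicity": [
        "Pakistani",
        "White British and White Other",
        "Asian (other than Pakistani)",
        "Mixed",
        "Other",
        "Black African and Black Caribbean",
    ],
    "nssec": [
        "Managerial, administrative and professional",
        "Intermediate",
        "Small employers and own account workers",
        "Lower supervisory and technical",
        "Semi-routine and routine",
    ],
    "household_size": ["1-3", "4-5", "6-7", "8+"],
    "weekday": ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"],
}

_MISSABLE = ("imd_quintile", "nssec", "phq8")


@dataclass(frozen=True)
class ModelSpec:
    """Which outcome and fixed effects to fit.

    An empty ``fixed_terms`` tuple gives the crude (intercept + random
    intercept only) model. Age enters as centred linear and quadratic terms;
    PHQ8 as a linear term; all other terms as one-hot indicators against
    fixed reference categories (female, winter, most-deprived IMD quintile,
    Pakistani, managerial NS-SEC, household 1-3). When missing values remain
    in imd_quintile / nssec / phq8 a "Missing" indicator column is added per
    affected term (for PHQ8 the linear term is mean-filled alongside it).
    """

    outcome: str = "sdq_total"
    fixed_terms: tuple = DEFAULT_FIXED_TERMS
    missing_indicators: bool = True

    @classmethod
    def crude(cls, outcome: str = "sdq_total") -> "ModelSpec":
        return cls(outcome=outcome, fixed_terms=())


def build_design(cohort: pd.DataFrame, spec: ModelSpec):
    """Build (y, X, labels, group codes, group labels) for :func:`fit_lmm`.

    Raises on empty cohorts, unseen category levels (named in the error),
    and all-missing columns.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    for col in ("school_id", spec.outcome):
        if col not in cohort.columns:
            raise ValueError(f"cohort lacks column {col!r}")

    y = cohort[spec.outcome].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"outcome column {spec.outcome!r} contains missing values")

    cols = [np.ones(len(cohort))]
    labels = ["(Intercept)"]

    for term in spec.fixed_terms:
        if term not in cohort.columns and term != "age":
            raise ValueError(f"cohort lacks column {term!r}")
        if term == "age":
            age = cohort["age"].to_numpy(dtype=float)
            age_c = age - age.mean()
            cols += [age_c, age_c**2]
            labels += ["age", "age^2"]
        elif term == "phq8":
            v = cohort["phq8"].to_numpy(dtype=float)
            miss = np.isnan(v)
            if miss.all():
                raise ValueError("column 'phq8' is entirely missing")
            if miss.any():
                if not spec.missing_indicators:
                    raise ValueError("phq8 has missing values and missing_indicators=False")
                v = np.where(miss, v[~miss].mean(), v)
                cols += [v, miss.astype(float)]
                labels += ["phq8", "phq8[Missing]"]
            else:
                cols.append(v)
                labels.append("phq8")
        else:
            levels = _CATEGORY_LEVELS[term]
            vals = cohort[term]
            if term == "imd_quintile":
                vals = vals.astype(float)
                miss = vals.isna().to_numpy()
                seen = set(vals.dropna().astype(int).tolist())
            else:
                miss = vals.isna().to_numpy()
                seen = set(vals.dropna().tolist())
            if miss.all():
                raise ValueError(f"column {term!r} is entirely missing")
            unseen = seen - set(levels)
            if unseen:
                raise ValueError(f"unseen level(s) in {term!r}: {sorted(map(str, unseen))}")
            arr = vals.to_numpy()
            for level in levels[1:]:
                if term == "imd_quintile":
                    ind = (vals == level).to_numpy().astype(float)
                    lab = f"imd_quintile[{level}]"
                else:
                    ind = (arr == level).astype(float)
                    lab = f"{term}[{level}]"
                cols.append(ind)
                labels.append(lab)
            if miss.any():
                if not spec.missing_indicators:
                    raise ValueError(f"{term} has missing values and missing_indicators=False")
                cols.append(miss.astype(float))
                labels.append(f"{term}[Missing]")

    X = np.column_stack(cols)
    codes, group_labels = pd.factorize(cohort["school_id"], sort=True)
    return y, X, labels, codes.astype(np.intp), list(group_labels)


@dataclass
class LmmFit:
    """A fitted random-intercept model."""

    beta: np.ndarray
    labels: list
    beta_cov: np.ndarray
    sigma_u: float
    sigma_e: float
    loglik: float
    criterion: str
    n_schools: int
    n_pupils: int
    blups: pd.DataFrame  # columns: school_id, blup, cond_se
    converged: bool
    lam: float = field(default=0.0)

    @property
    def icc(self) -> float:
        return icc(self)

    @property
    def beta_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.beta_cov))


class ProfiledRandomInterceptLMM:
    """Reusable profiled fitter: precomputes X-side sufficient statistics so
    repeated fits with new outcome vectors (bootstrap replicates) are cheap."""

    def __init__(self, X: np.ndarray, codes: np.ndarray, group_labels=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, p = X.shape
        if len(codes) != n:
            raise ValueError("groups length does not match X")
        self.J = int(codes.max()) + 1 if n else 0
        if self.J < 2:
            raise ValueError("need at least 2 groups")
        self._check_rank(X)
        self.X, self.codes, self.n, self.p = X, codes, n, p
        self.group_labels = list(group_labels) if group_labels is not None else list(range(self.J))
        self.n_j = np.bincount(codes, minlength=self.J).astype(float)
        if (self.n_j == 0).any():
            raise ValueError("every group must receive at least one observation")
        self.XtX = X.T @ X
        self.S = np.empty((self.J, p))  # per-group column sums of X
        for k in range(p):
            self.S[:, k] = np.bincount(codes, weights=X[:, k], minlength=self.J)

    @staticmethod
    def _check_rank(X: np.ndarray) -> None:
        r = np.linalg.qr(X, mode="r")
        diag = np.abs(np.diag(r))
        tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
        bad = np.flatnonzero(diag <= tol)
        if bad.size:
            raise ValueError(f"design matrix is rank deficient; collinear column indices: {bad.tolist()}")

    # -- y-side statistics -------------------------------------------------
    def _ystats(self, y: np.ndarray):
        Xty = self.X.T @ y
        yty = float(y @ y)
        s_y = np.bincount(self.codes, weights=y, minlength=self.J)
        return Xty, yty, s_y

    def _criterion_parts(self, lam: float, Xty, yty, s_y):
        """GLS pieces at a given lambda (unit-variance V0)."""
        c = lam / (1.0 + lam * self.n_j)  # per-group weight
        A = self.XtX - (self.S * c[:, None]).T @ self.S  # X' V0^-1 X
        b = Xty - self.S.T @ (c * s_y)  # X' V0^-1 y
        beta = np.linalg.solve(A, b)
        quad = yty - float(c @ s_y**2) - float(b @ beta)  # r' V0^-1 r
        quad = max(quad, 1e-300)
        ldV0 = float(np.log1p(lam * self.n_j).sum())
        return A, beta, quad, ldV0

    def _neg_profiled(self, loglam: float, Xty, yty, s_y, reml: bool) -> float:
        lam = np.exp(loglam)
        A, _, quad, ldV0 = self._criterion_parts(lam, Xty, yty, s_y)
        n, p = self.n, self.p
        if reml:
            dof = n - p
            s2 = quad / dof
            _, ldA = np.linalg.slogdet(A)
            ll = -0.5 * (dof * (np.log(2 * np.pi * s2) + 1.0) + ldV0 + ldA)
        else:
            s2 = quad / n
            ll = -0.5 * (n * (np.log(2 * np.pi * s2) + 1.0) + ldV0)
        return -ll

    def fit(self, y: np.ndarray, criterion: str = "reml") -> LmmFit:
        criterion = criterion.lower()
        if criterion not in ("reml", "ml"):
            raise ValueError("criterion must be 'reml' or 'ml'")
        reml = criterion == "reml"
        y = np.asarray(y, dtype=float)
        if len(y) != self.n:
            raise ValueError("y length does not match design")
        Xty, yty, s_y = self._ystats(y)

        scan = np.linspace(LOGLAM_LO, LOGLAM_HI, N_SCAN)
        scan_vals = np.array([self._neg_profiled(g, Xty, yty, s_y, reml) for g in scan])
        k = int(np.argmin(scan_vals))
        res = minimize_scalar(
            self._neg_profiled,
            bounds=(scan[max(k - 1, 0)], scan[min(k + 1, N_SCAN - 1)]),
            args=(Xty, yty, s_y, reml),
            method="bounded",
            options={"xatol": LOGLAM_TOL},
        )
        loglam, fun = float(res.x), float(res.fun)
        # The bounded search cannot touch the interval endpoints; take the
        # upper endpoint when the criterion keeps improving towards it
        # (degenerate designs), and treat an optimum at (or tied with) the
        # lower bound as the boundary sigma_u = 0.
        if scan_vals[-1] < fun:
            loglam, fun = LOGLAM_HI, float(scan_vals[-1])
        if scan_vals[0] <= fun + 1e-10:
            loglam, boundary = -np.inf, True
        else:
            boundary = False
        converged = bool(res.success) and loglam < LOGLAM_HI - 1e-6

        lam = 0.0 if boundary else float(np.exp(loglam))
        A, beta, quad, ldV0 = self._criterion_parts(lam, Xty, yty, s_y)
        dof = self.n - self.p if reml else self.n
        s2 = quad / dof
        if reml:
            _, ldA = np.linalg.slogdet(A)
            ll = -0.5 * (dof * (np.log(2 * np.pi * s2) + 1.0) + ldV0 + ldA)
        else:
            ll = -0.5 * (dof * (np.log(2 * np.pi * s2) + 1.0) + ldV0)

        sigma_e = float(np.sqrt(s2))
        sigma_u = float(np.sqrt(lam * s2))
        beta_cov = s2 * np.linalg.inv(A)

        c = lam / (1.0 + lam * self.n_j)
        resid_sums = s_y - self.S @ beta
        blup = c * resid_sums
        cond_se = sigma_e * np.sqrt(lam / (1.0 + lam * self.n_j))
        blups = pd.DataFrame(
            {"school_id": self.group_labels, "blup": blup, "cond_se": cond_se}
        )
        return LmmFit(
            beta=beta,
            labels=getattr(self, "labels", [f"x{k}" for k in range(self.p)]),
            beta_cov=beta_cov,
            sigma_u=sigma_u,
            sigma_e=sigma_e,
            loglik=float(ll),
            criterion=criterion,
            n_schools=self.J,
            n_pupils=self.n,
            blups=blups,
            converged=converged,
            lam=lam,
        )


def fit_lmm(y, X, groups, criterion: str = "reml", labels=None, group_labels=None) -> LmmFit:
    """Fit the random-intercept model y = X beta + Z u + e.

    ``groups`` may be integer codes or arbitrary hashable labels.
    """
    groups = np.asarray(groups)
    if groups.dtype.kind in "iu" and groups.min() >= 0:
        codes = groups.astype(np.intp)
        glabels = group_labels if group_labels is not None else np.arange(codes.max() + 1)
        # compress unused codes
        uniq = np.unique(codes)
        if len(uniq) != codes.max() + 1:
            remap = {g: i for i, g in enumerate(uniq)}
            codes = np.array([remap[g] for g in codes], dtype=np.intp)
            glabels = [glabels[g] for g in uniq]
    else:
        codes, uniq = pd.factorize(groups, sort=True)
        codes = codes.astype(np.intp)
        glabels = list(uniq)
    fitter = ProfiledRandomInterceptLMM(np.asarray(X, dtype=float), codes, glabels)
    if labels is not None:
        fitter.labels = list(labels)
    return fitter.fit(np.asarray(y, dtype=float), criterion=criterion)


def icc(fit: LmmFit) -> float:
    """Intraclass correlation sigma_u^2 / (sigma_u^2 + sigma_e^2)."""
    vu, ve = fit.sigma_u**2, fit.sigma_e**2
    return vu / (vu + ve)


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    p_value: float  # boundary-corrected 0.5 chi2_0 + 0.5 chi2_1 mixture
    p_chi2_1: float  # conservative plain chi2_1 alternative
    loglik_mixed: float
    loglik_ols: float


def _ols_loglik(y: np.ndarray, X: np.ndarray) -> float:
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    s2 = rss / n
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)


def lrt_random_intercept(y, X, groups) -> LrtResult:
    """Likelihood-ratio test for the school random intercept.

    Compares the ML-fitted mixed model with the fixed-effects-only linear
    model. Because sigma_u^2 = 0 sits on the boundary of the parameter
    space, the reference distribution is the 50:50 mixture of a point mass
    at zero and chi-square with 1 df, so p = 0.5 * P(chi2_1 >= statistic).
    The plain chi2_1 p-value is also reported as a conservative alternative.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    mixed = fit_lmm(y, X, groups, criterion="ml")
    ll0 = _ols_loglik(y, X)
    stat = max(0.0, 2.0 * (mixed.loglik - ll0))
    return LrtResult(
        statistic=stat,
        p_value=0.5 * float(stats.chi2.sf(stat, 1)),
        p_chi2_1=float(stats.chi2.sf(stat, 1)),
        loglik_mixed=mixed.loglik,
        loglik_ols=ll0,
    )


def quantile_mean(center: float, sigma_u: float, q: float) -> float:
    """Mean score of a school at quantile q of the school-level distribution:
    center + Phi^-1(q) * sigma_u."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    return float(center + stats.norm.ppf(q) * sigma_u)


def school_quantile_mean(fit: LmmFit, q: float, center: float) -> float:
    """Mean score of a school at quantile q of the fitted N(center, sigma_u^2)
    school-level distribution."""
    return quantile_mean(center, fit.sigma_u, q)


def school_means(fit: LmmFit, center: float) -> pd.DataFrame:
    """Per-school shrunken means center + BLUP_j with 95% conditional
    intervals (+- 1.96 conditional SE)."""
    out = fit.blups.copy()
    out["mean"] = center + out["blup"]
    out["lo"] = out["mean"] - 1.96 * out["cond_se"]
    out["hi"] = out["mean"] + 1.96 * out["cond_se"]
    return out[["school_id", "mean", "lo", "hi", "blup", "cond_se"]]


def fit_to_json(fit: LmmFit, path=None) -> dict:
    """Serialise a fit; writes JSON when ``path`` is given."""
    payload = {
        "labels": list(fit.labels),
        "beta": fit.beta.tolist(),
        "beta_se": fit.beta_se.tolist(),
        "beta_cov": fit.beta_cov.tolist(),
        "sigma_u": fit.sigma_u,
        "sigma_e": fit.sigma_e,
        "icc": icc(fit),
        "loglik": fit.loglik,
        "criterion": fit.criterion,
        "n_schools": fit.n_schools,
        "n_pupils": fit.n_pupils,
        "converged": fit.converged,
        "lambda": fit.lam,
        "blups": fit.blups.to_dict(orient="list"),
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=2))
    return payload


def fit_from_json(source) -> LmmFit:
    payload = json.loads(Path(source).read_text()) if not isinstance(source, dict) else source
    return LmmFit(
        beta=np.asarray(payload["beta"], dtype=float),
        labels=list(payload["labels"]),
        beta_cov=np.asarray(payload["beta_cov"], dtype=float),
        sigma_u=float(payload["sigma_u"]),
        sigma_e=float(payload["sigma_e"]),
        loglik=float(payload["loglik"]),
        criterion=payload["criterion"],
        n_schools=int(payload["n_schools"]),
        n_pupils=int(payload["n_pupils"]),
        blups=pd.DataFrame(payload["blups"]),
        converged=bool(payload["converged"]),
        lam=float(payload.get("lambda", 0.0)),
    )
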