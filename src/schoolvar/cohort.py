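"""Synthetic multilevel pupil cohorts.

Generates pupil-level datasets with the clustered structure of a city-wide
primary-school survey: pupils nested in schools, a school-level random
intercept on the outcome, realistic covariate marginals, and controlled
missing-completely-at-random (MCAR) gaps in a subset of covariates.

The outcome is an SDQ-style total difficulties score (0-40). Two outcome
mechanisms are supported:

``gaussian``
    y_ij = intercept + x_ij' beta + u_j + e_ij with u_j ~ N(0, sigma_u^2)
    per school and e_ij ~ N(0, sigma_e^2) per pupil. Both the unrounded
    value (``sdq_total_raw``) and the value rounded and clipped to [0, 40]
    (``sdq_total``) are recorded.

``negbin_identity``
    y_ij ~ NegBin(mean = max(0.1, intercept [+ x_ij' beta] + u_j),
    dispersion theta) on an identity scale, matching the overdispersed
    integer scores seen in real SDQ data.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MEAN_CLIP_FLOOR = 0.1  # lowest admissible negative-binomial mean

SEX_LEVELS = ("female", "male")
ETHNICITY_LEVELS = (
    "Pakistani",
    "White British and White Other",
    "Asian (other than Pakistani)",
    "Mixed",
    "Other",
    "Black African and Black Caribbean",
)
IMD_LEVELS = (1, 2, 3, 4, 5)  # 1 = most deprived quintile
HOUSEHOLD_LEVELS = ("1-3", "4-5", "6-7", "8+")
NSSEC_LEVELS = (
    "Managerial, administrative and professional",
    "Intermediate",
    "Small employers and own account workers",
    "Lower supervisory and technical",
    "Semi-routine and routine",
)
SEASON_LEVELS = ("winter", "spring", "summer", "autumn")
WEEKDAY_LEVELS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")

#: Stable column order used for CSV round-trips.
COLUMNS = [
    "school_id",
    "sdq_total",
    "sdq_total_raw",
    "emotional",
    "conduct",
    "hyperactivity",
    "peer",
    "age",
    "sex",
    "ethnicity",
    "imd_quintile",
    "household_size",
    "nssec",
    "phq8",
    "season",
    "weekday",
]

#: Columns eligible for injected missingness (the outcome and school id never
#: go missing).
MISSABLE = ("imd_quintile", "nssec", "phq8")


def _default_marginals() -> dict:
    """Category frequencies of the survey population (observed cells only)."""
    return {
        "sex": {"female": 2461, "male": 2602},
        "ethnicity": {
            "Pakistani": 2828,
            "White British and White Other": 1393,
            "Asian (other than Pakistani)": 500,
            "Mixed": 210,
            "Other": 68,
            "Black African and Black Caribbean": 61,
        },
        "imd_quintile": {1: 3442, 2: 1068, 3: 283, 4: 155, 5: 55},
        "household_size": {"1-3": 577, "4-5": 2477, "6-7": 1474, "8+": 522},
        "nssec": {
            "Managerial, administrative and professional": 1723,
            "Intermediate": 795,
            "Small employers and own account workers": 836,
            "Lower supervisory and technical": 481,
            "Semi-routine and routine": 842,
        },
    }


def _default_beta() -> dict:
    """Fixed-effect coefficients (score units) used by the generator.

    Categorical effects follow the adjusted regression estimates observed in
    the survey. Age enters on a centred basis (years from the sample mean)
    with mild curvature.
    """
    return {
        "age": -0.2,
        "age^2": -0.02,
        "sex": {"male": 1.22},
        "season": {"spring": 0.04, "summer": 0.28, "autumn": 0.24},
        "imd_quintile": {2: -0.46, 3: -1.00, 4: -1.60, 5: -2.33},
        "ethnicity": {
            "White British and White Other": 1.69,
            "Asian (other than Pakistani)": -0.19,
            "Mixed": 1.53,
            "Other": -0.61,
            "Black African and Black Caribbean": -0.43,
        },
        "phq8": 0.38,
        "nssec": {
            "Intermediate": 0.58,
            "Small employers and own account workers": 0.24,
            "Lower supervisory and technical": 0.53,
            "Semi-routine and routine": 0.66,
        },
        "household_size": {"4-5": -0.69, "6-7": -0.76, "8+": -0.81},
    }


# Subscale generator settings: (baseline mean, school-level SD). Baselines are
# the observed school-level medians; SDs the observed crude school-level SDs.
SUBSCALE_PARAMS = {
    "conduct": (1.58, 0.35),
    "emotional": (2.18, 0.13),
    "hyperactivity": (3.46, 0.57),
    "peer": (1.58, 0.38),
}
SUBSCALE_THETA = 2.0  # shared overdispersion for subscale counts


@dataclass
class ClusterSizeDist:
    """Discretised lognormal school-size distribution.

    Defaults target a median of 29 pupils per school with IQR 16-51
    (log-median log 29; log-SD chosen so the quartile ratio matches),
    truncated to [5, 200] by resampling.
    """

    log_median: float = float(np.log(29.0))
    log_sd: float = 0.860
    lower: int = 5
    upper: int = 200

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        sizes = np.empty(n, dtype=int)
        need = np.ones(n, dtype=bool)
        while need.any():
            draw = rng.lognormal(self.log_median, self.log_sd, int(need.sum()))
            draw = np.rint(draw).astype(int)
            ok = (draw >= self.lower) & (draw <= self.upper)
            idx = np.flatnonzero(need)
            sizes[idx[ok]] = draw[ok]
            need[idx[ok]] = False
        return sizes


@dataclass
class CohortGenParams:
    """Parameters of the synthetic cohort generator.

    sigma_u and sigma_e are on the score scale; theta is the
    negative-binomial dispersion (variance mu + mu^2/theta) used in
    ``negbin_identity`` mode.
    """

    n_schools: int = 135
    cluster_size_dist: ClusterSizeDist = field(default_factory=ClusterSizeDist)
    # With the default coefficients and covariate marginals the expected
    # covariate contribution is ~+2.19 score points, so an intercept of 6.65
    # puts the marginal outcome mean at ~8.84 (the observed survey mean).
    intercept: float = 6.65
    beta: dict | None = field(default_factory=_default_beta)
    sigma_u: float = 1.41
    sigma_e: float = 5.85
    theta: float = 2.81
    outcome_mode: str = "gaussian"
    missing_rates: dict = field(
        default_factory=lambda: {"imd_quintile": 0.01, "nssec": 0.05, "phq8": 0.03}
    )
    covariate_marginals: dict = field(default_factory=_default_marginals)
    phq8_mean: float = 3.9
    phq8_theta: float = 0.85
    age_mean: float = 9.7
    age_sd: float = 0.9
    make_subscales: bool = True
    seed: int | None = None

    def validate(self) -> None:
        if self.n_schools < 2:
            raise ValueError("n_schools must be >= 2")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")
        if self.sigma_e <= 0:
            raise ValueError("sigma_e must be > 0")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.outcome_mode not in ("gaussian", "negbin_identity"):
            raise ValueError(f"unknown outcome_mode {self.outcome_mode!r}")
        for col, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for {col} outside [0, 1]: {rate}")


def _sample_categorical(levels, weights: Mapping, n: int, rng) -> np.ndarray:
    keys = list(levels)
    w = np.array([float(weights[k]) for k in keys], dtype=float)
    w = w / w.sum()
    idx = rng.choice(len(keys), size=n, p=w)
    return np.asarray(keys, dtype=object)[idx]


def _sample_truncated_normal(mean, sd, lo, hi, n, rng) -> np.ndarray:
    out = np.empty(n)
    need = np.ones(n, dtype=bool)
    while need.any():
        draw = rng.normal(mean, sd, int(need.sum()))
        ok = (draw >= lo) & (draw <= hi)
        idx = np.flatnonzero(need)
        out[idx[ok]] = draw[ok]
        need[idx[ok]] = False
    return out


def _sample_negbin(mean, theta, n, rng) -> np.ndarray:
    """Gamma-Poisson mixture draw; `mean` may be scalar or per-draw array."""
    lam = rng.gamma(theta, np.broadcast_to(np.asarray(mean) / theta, (n,)))
    return rng.poisson(lam)


def _linear_predictor(df: pd.DataFrame, beta: Mapping, intercept: float) -> np.ndarray:
    lp = np.full(len(df), float(intercept))
    if not beta:
        return lp
    age_c = df["age"].to_numpy() - df["age"].to_numpy().mean()
    lp += beta.get("age", 0.0) * age_c
    lp += beta.get("age^2", 0.0) * age_c**2
    lp += beta.get("phq8", 0.0) * df["phq8"].to_numpy(dtype=float)
    for col in ("sex", "season", "imd_quintile", "ethnicity", "nssec", "household_size"):
        effects = beta.get(col)
        if not effects:
            continue
        vals = df[col].to_numpy()
        for level, coef in effects.items():
            lp += np.where(vals == level, float(coef), 0.0)
    return lp


def generate_cohort(params: CohortGenParams) -> pd.DataFrame:
    """Generate one synthetic cohort as a tidy pupil-level DataFrame.

    Deterministic given ``params.seed``. Column order follows ``COLUMNS``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    dist = params.cluster_size_dist
    if isinstance(dist, (int, np.integer)):  # every school the same size
        sizes = np.full(params.n_schools, int(dist))
    else:
        sizes = dist.sample(params.n_schools, rng)
    if (sizes < 1).any():
        raise ValueError("every school must receive at least one pupil")
    school_ids = np.repeat([f"S{j:03d}" for j in range(params.n_schools)], sizes)
    codes = np.repeat(np.arange(params.n_schools), sizes)
    n = int(sizes.sum())

    marg = params.covariate_marginals
    df = pd.DataFrame(
        {
            "school_id": school_ids,
            "age": _sample_truncated_normal(params.age_mean, params.age_sd, 6.0, 12.0, n, rng),
            "sex": _sample_categorical(SEX_LEVELS, marg["sex"], n, rng),
            "ethnicity": _sample_categorical(ETHNICITY_LEVELS, marg["ethnicity"], n, rng),
            "imd_quintile": _sample_categorical(IMD_LEVELS, marg["imd_quintile"], n, rng).astype(float),
            "household_size": _sample_categorical(HOUSEHOLD_LEVELS, marg["household_size"], n, rng),
            "nssec": _sample_categorical(NSSEC_LEVELS, marg["nssec"], n, rng),
            "phq8": np.minimum(_sample_negbin(params.phq8_mean, params.phq8_theta, n, rng), 24).astype(float),
            "season": _sample_categorical(SEASON_LEVELS, {s: 1 for s in SEASON_LEVELS}, n, rng),
            "weekday": _sample_categorical(WEEKDAY_LEVELS, {d: 1 for d in WEEKDAY_LEVELS}, n, rng),
        }
    )

    u = rng.normal(0.0, params.sigma_u, params.n_schools)
    lp = _linear_predictor(df, params.beta or {}, params.intercept) + u[codes]

    if params.outcome_mode == "gaussian":
        raw = lp + rng.normal(0.0, params.sigma_e, n)
        df["sdq_total_raw"] = raw
        df["sdq_total"] = np.clip(np.rint(raw), 0, 40).astype(int)
    else:
        n_clipped = int((lp < MEAN_CLIP_FLOOR).sum())
        if n_clipped:
            logger.warning(
                "negbin_identity: %d pupil means below %.1f clipped", n_clipped, MEAN_CLIP_FLOOR
            )
        mean = np.maximum(lp, MEAN_CLIP_FLOOR)
        df["sdq_total"] = _sample_negbin(mean, params.theta, n, rng).astype(int)
        df["sdq_total_raw"] = df["sdq_total"].astype(float)

    if params.make_subscales:
        for name, (base, s_u) in SUBSCALE_PARAMS.items():
            u_s = rng.normal(0.0, s_u, params.n_schools)
            mean_s = np.maximum(base + u_s[codes], MEAN_CLIP_FLOOR)
            df[name] = np.minimum(_sample_negbin(mean_s, SUBSCALE_THETA, n, rng), 10).astype(int)
    else:
        for name in SUBSCALE_PARAMS:
            df[name] = np.nan

    return df[COLUMNS]


def inject_missingness(
    cohort: pd.DataFrame, rates: Mapping[str, float], seed: int | None = None
) -> pd.DataFrame:
    """Set covariate cells missing completely at random.

    Each eligible cell (columns in ``MISSABLE``) is independently blanked
    with its column rate. Returns a copy; the input is untouched.
    """
    for col, rate in rates.items():
        if col not in MISSABLE:
            raise ValueError(f"column {col!r} is not eligible for missingness")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {col} outside [0, 1]: {rate}")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    for col in MISSABLE:  # fixed order keeps the draw sequence stable
        rate = float(rates.get(col, 0.0))
        if rate == 0.0:
            continue
        mask = rng.random(len(out)) < rate
        if col == "nssec":
            out[col] = out[col].astype(object)
            out.loc[mask, col] = None
        else:
            out.loc[mask, col] = np.nan
    return out


def write_cohort(cohort: pd.DataFrame, path, params: CohortGenParams | None = None) -> None:
    """Write a cohort CSV (missing cells as empty fields) plus a JSON sidecar
    recording the generator parameters and seed."""
    path = Path(path)
    cohort.to_csv(path, index=False, na_rep="")
    if params is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        payload = asdict(params)
        payload["covariate_marginals"] = {
            k: {str(kk): vv for kk, vv in v.items()} for k, v in payload["covariate_marginals"].items()
        }
        if payload.get("beta"):
            payload["beta"] = {
                k: ({str(kk): vv for kk, vv in v.items()} if isinstance(v, dict) else v)
                for k, v in payload["beta"].items()
            }
        sidecar.write_text(json.dumps(payload, indent=2))


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks columns: {missing}")
    return df[COLUMNS]
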