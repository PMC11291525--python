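"""Descriptive summaries and the end-to-end analysis pipeline.

``run_pipeline`` sequences the whole analysis: simulate or load a cohort,
summarise it, fit the crude and adjusted random-intercept models (pooling
over multiple imputations when covariates are missing), test the random
intercept, bootstrap the variance-component intervals, estimate the
negative-binomial dispersion, and run the caseload simulation. Every output
carries the package version, a hash of the configuration, and the seeds
used, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortGenParams,
    MISSABLE,
    generate_cohort,
    inject_missingness,
    read_cohort,
    write_cohort,
)
from .bootstrap import bootstrap_varcomp
from .caseload import SchoolSimConfig, table3
from .impute import impute, pool_rubin
from .lmm import ModelSpec, build_design, fit_lmm, fit_to_json, icc, lrt_random_intercept
from .negbin import fit_theta

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "summarize_cohort", "run_pipeline", "format_p"]

SDQ_BANDS = [
    (0, 14, "0-14 (Close to average or normal)"),
    (15, 17, "15-17 (Slightly raised)"),
    (18, 19, "18-19 (High)"),
    (20, 40, "20-40 (Very high)"),
]


def sdq_band(score: int) -> str:
    """Categorise an SDQ total score into its reporting band."""
    for lo, hi, label in SDQ_BANDS:
        if lo <= score <= hi:
            return label
    raise ValueError(f"score outside 0-40: {score}")


def format_p(p: float) -> str:
    """p to 3 significant figures with a '<0.001' floor."""
    return "<0.001" if p < 0.001 else f"{p:.3g}"


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table: counts and percentages per categorical level,
    median [IQR] for age / PHQ8 / SDQ, SDQ bands, and missing counts."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    n = len(cohort)
    rows = [("Total", "", n, 100.0)]

    def cat(var, series):
        vc = series.value_counts(dropna=False)
        for level, count in vc.items():
            label = "Missing" if pd.isna(level) else str(level)
            rows.append((var, label, int(count), 100.0 * count / n))

    def med_iqr(var, series):
        s = series.dropna()
        rows.append(
            (var, f"Median [IQR] {s.median():.2f} [{s.quantile(0.25):.2f}-{s.quantile(0.75):.2f}]", int(s.size), 100.0 * s.size / n)
        )

    cat("Sex", cohort["sex"])
    cat("Ethnicity", cohort["ethnicity"])
    cat("IMD quintile", cohort["imd_quintile"])
    cat("Household size", cohort["household_size"])
    cat("NS-SEC", cohort["nssec"])
    med_iqr("Age", cohort["age"])
    med_iqr("PHQ8", cohort["phq8"])
    med_iqr("SDQ total", cohort["sdq_total"])
    cat("SDQ band", cohort["sdq_total"].map(sdq_band))
    for col in MISSABLE:
        rows.append(("Missing cells", col, int(cohort[col].isna().sum()), 100.0 * cohort[col].isna().mean()))

    return pd.DataFrame(rows, columns=["variable", "level", "n", "percent"])


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "schoolvar_run"
    cohort_path: str | None = None  # load this CSV instead of simulating
    cohort_params: CohortGenParams = field(default_factory=CohortGenParams)
    outcome: str = "sdq_total"
    seed: int = 0
    m_imputations: int = 20
    n_boot: int = 2000
    bootstrap_method: str = "parametric"
    sim: SchoolSimConfig = field(default_factory=SchoolSimConfig)
    max_age: float | None = None  # exclusion filter, e.g. pupils past primary age

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cp = raw.pop("cohort_params", None)
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if cp:
            cfg.cohort_params = CohortGenParams(**cp)
        if sim:
            cfg.sim = SchoolSimConfig(**sim)
        return cfg

    def hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # where outputs land does not define the analysis
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(config: RunConfig, seeds: dict) -> dict:
    return {"package": f"schoolvar {__version__}", "config_hash": config.hash(), "seeds": seeds}


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; writes all artifacts under ``config.outdir``
    and returns them in memory as a dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ["cohort", "missing", "impute", "bootstrap", "simulation"], ss.spawn(5)
        )
    }
    prov = _provenance(config, stage_seeds)
    header = f"{prov['package']} config={prov['config_hash']} seeds={stage_seeds}"

    # 1. cohort ------------------------------------------------------------
    if config.cohort_path:
        cohort = read_cohort(config.cohort_path)
    else:
        params = config.cohort_params
        params.seed = stage_seeds["cohort"]
        cohort = generate_cohort(params)
        if any(r > 0 for r in params.missing_rates.values()):
            cohort = inject_missingness(cohort, params.missing_rates, stage_seeds["missing"])
        write_cohort(cohort, out / "cohort.csv", params)
    if config.max_age is not None:
        n_before = len(cohort)
        cohort = cohort[cohort["age"] <= config.max_age].reset_index(drop=True)
        logger.info("excluded %d pupils above age %.1f", n_before - len(cohort), config.max_age)

    # 2. descriptives ------------------------------------------------------
    summary = summarize_cohort(cohort)
    with open(out / "summary.csv", "w") as fh:
        fh.write(f"# {header}\n")
        summary.to_csv(fh, index=False)

    # 3. crude fit + LRT ---------------------------------------------------
    crude_spec = ModelSpec.crude(config.outcome)
    y, X, labels, codes, glabels = build_design(cohort, crude_spec)
    crude = fit_lmm(y, X, codes, criterion="reml", labels=labels, group_labels=glabels)
    lrt = lrt_random_intercept(y, X, codes)
    payload = fit_to_json(crude)
    payload["provenance"] = prov
    (out / "crude_fit.json").write_text(json.dumps(payload, indent=2))
    (out / "lrt.json").write_text(
        json.dumps(
            {
                "statistic": lrt.statistic,
                "p_value": lrt.p_value,
                "p_value_formatted": format_p(lrt.p_value),
                "p_chi2_1": lrt.p_chi2_1,
                "provenance": prov,
            },
            indent=2,
        )
    )

    # 4. adjusted fit (MI pooling when covariates are missing) -------------
    adj_spec = ModelSpec(outcome=config.outcome)
    has_missing = cohort[list(MISSABLE)].isna().any().any()
    if has_missing:
        imp = impute(cohort, m=config.m_imputations, seed=stage_seeds["impute"], outcome=config.outcome)
        fits, ps = [], []
        for completed in imp.completed:
            ya, Xa, la, ca, ga = build_design(completed, adj_spec)
            fits.append(fit_lmm(ya, Xa, ca, criterion="reml", labels=la, group_labels=ga))
            ps.append(lrt_random_intercept(ya, Xa, ca).p_value)
        pooled = pool_rubin(fits, ps)
        sigma_u_adj = pooled.sigma_u_pooled
        adj_payload = {
            "labels": pooled.labels,
            "beta_pooled": pooled.beta_pooled.tolist(),
            "beta_se": pooled.beta_se.tolist(),
            "df": pooled.df.tolist(),
            "m": pooled.m,
            "sigma_u_pooled": pooled.sigma_u_pooled,
            "sigma_u_spread": pooled.sigma_u_spread,
            "icc_pooled": pooled.icc_pooled,
            "icc_spread": pooled.icc_spread,
            "lrt_p_median": pooled.lrt_p_median,
            "lrt_p_median_formatted": format_p(pooled.lrt_p_median),
            "imputer": "bootstrap-EM multivariate normal",
            "sub_seeds": imp.sub_seeds,
            "provenance": prov,
        }
        (out / "adjusted_fit.json").write_text(json.dumps(adj_payload, indent=2))
        adj_cohort_for_boot = imp.completed[0]
        adjusted = fits[0]
    else:
        ya, Xa, la, ca, ga = build_design(cohort, adj_spec)
        adjusted = fit_lmm(ya, Xa, ca, criterion="reml", labels=la, group_labels=ga)
        sigma_u_adj = adjusted.sigma_u
        adj_payload = fit_to_json(adjusted)
        adj_payload["provenance"] = prov
        (out / "adjusted_fit.json").write_text(json.dumps(adj_payload, indent=2))
        adj_cohort_for_boot = cohort

    # 5. bootstrap CIs (crude model) ---------------------------------------
    ci = bootstrap_varcomp(
        crude, y, X, codes, n_boot=config.n_boot, method=config.bootstrap_method, seed=stage_seeds["bootstrap"]
    )
    (out / "ci.json").write_text(
        json.dumps(
            {
                "model": "crude",
                "sigma_u": crude.sigma_u,
                "sigma_u_ci": ci.sigma_u_ci,
                "icc": icc(crude),
                "icc_ci": ci.icc_ci,
                "n_boot": ci.n_boot,
                "n_failed": ci.n_failed,
                "method": ci.method,
                "provenance": prov,
            },
            indent=2,
        )
    )

    # 6. dispersion --------------------------------------------------------
    nb = fit_theta(cohort[config.outcome].to_numpy(dtype=int))
    (out / "theta.json").write_text(
        json.dumps({"mu": nb.mu, "theta": nb.theta, "provenance": prov}, indent=2)
    )

    # 7. caseload table ----------------------------------------------------
    sim = config.sim
    sim.center = float(cohort[config.outcome].mean())
    sim.theta = nb.theta
    sim.seed = stage_seeds["simulation"]
    result = table3(crude.sigma_u, sigma_u_adj, config=sim)
    result.to_csv(out / "table3.csv", provenance=header)

    return {
        "cohort": cohort,
        "summary": summary,
        "crude": crude,
        "adjusted": adjusted,
        "sigma_u_adjusted": sigma_u_adj,
        "lrt": lrt,
        "ci": ci,
        "negbin": nb,
        "table3": result,
        "provenance": prov,
    }
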