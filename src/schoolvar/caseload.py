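"""Per-school caseload simulation.

Translates the fitted school-level distribution of mean SDQ scores into the
number of pupils expected to score at or above clinical cutoffs (15
"slightly raised", 20 "very high") in a school of typical size. For a school
whose mean sits at a chosen quantile of the N(center, sigma_u^2)
school-level distribution, each of ``n_pupils`` pupil scores is drawn from a
negative binomial with that mean and shared dispersion theta; the caseload
is the count of scores >= cutoff (a score exactly at the cutoff is a case).
Repeating over many simulated schools gives the 2.5/50/97.5% quantiles of
the caseload, and independent lower/upper-quartile pairs give the
distribution of the between-quartile difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .negbin import NegBinModel

__all__ = [
    "SchoolSimConfig",
    "CaseloadSample",
    "SchoolSimResult",
    "simulate_school_cases",
    "simulate_quartile_difference",
    "table3",
]


@dataclass
class SchoolSimConfig:
    """Settings of the caseload simulation."""

    n_pupils: int = 396
    n_sims: int = 10_000
    cutoffs: tuple = (15, 20)
    quantiles_of_schools: tuple = (0.25, 0.5, 0.75)
    report_quantiles: tuple = (0.025, 0.5, 0.975)
    theta: float = 2.81
    center: float = 8.84
    sigma_u: float = 1.41
    seed: int | None = None

    def validate(self) -> None:
        if self.n_pupils < 1 or self.n_sims < 1:
            raise ValueError("counts must be positive")
        for q in tuple(self.quantiles_of_schools) + tuple(self.report_quantiles):
            if not 0.0 < q < 1.0:
                raise ValueError(f"probability outside (0,1): {q}")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")


@dataclass
class CaseloadSample:
    counts: np.ndarray
    quantiles: dict  # report quantile -> count

    @property
    def median(self) -> float:
        return self.quantiles[0.5]


def _draw_counts(mean, theta, n_pupils, cutoff, n_sims, rng) -> np.ndarray:
    """Case counts for n_sims schools; vectorised gamma-Poisson draws."""
    lam = rng.gamma(theta, mean / theta, size=(n_sims, n_pupils))
    scores = rng.poisson(lam)
    return (scores >= cutoff).sum(axis=1)


def _quantiles(counts, probs) -> dict:
    return {float(p): float(np.quantile(counts, p)) for p in probs}


def simulate_school_cases(
    mean: float,
    theta: float,
    n_pupils: int = 396,
    cutoff: int = 15,
    n_sims: int = 10_000,
    seed=None,
    report_quantiles=(0.025, 0.5, 0.975),
) -> CaseloadSample:
    """Simulate caseloads for schools whose mean score is ``mean``.

    ``seed`` may be an int or an existing numpy Generator.
    """
    if mean <= 0:
        raise ValueError("mean must be > 0")
    NegBinModel(mean, theta)  # parameter validation
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = _draw_counts(mean, theta, n_pupils, cutoff, n_sims, rng)
    return CaseloadSample(counts=counts, quantiles=_quantiles(counts, report_quantiles))


def simulate_quartile_difference(
    mean_low: float,
    mean_high: float,
    theta: float,
    n_pupils: int = 396,
    cutoff: int = 15,
    n_sims: int = 10_000,
    seed=None,
    report_quantiles=(0.025, 0.5, 0.975),
) -> CaseloadSample:
    """Distribution of (upper-quartile minus lower-quartile school) caseload.

    Each replicate pairs one independently simulated school at each mean;
    independent pairing makes the difference variance the sum of the two
    marginal variances.
    """
    if mean_low > mean_high:
        raise ValueError("mean_low must not exceed mean_high")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo = _draw_counts(mean_low, theta, n_pupils, cutoff, n_sims, rng)
    hi = _draw_counts(mean_high, theta, n_pupils, cutoff, n_sims, rng)
    diff = hi - lo
    return CaseloadSample(counts=diff, quantiles=_quantiles(diff, report_quantiles))


@dataclass
class SchoolSimResult:
    """Caseload quantile table plus the configuration that produced it."""

    table: pd.DataFrame  # rows: (block, position); columns per cutoff
    config: dict = field(default_factory=dict)

    def formatted(self) -> pd.DataFrame:
        """Rows as 'median (q2.5, q97.5)' strings, one column per cutoff."""
        out = {}
        for cutoff in sorted({c for c, _ in self.table.columns}):
            sub = self.table[cutoff]
            out[f"cutoff={cutoff}"] = [
                f"{row['median']:.0f} ({row['q2.5']:.0f}, {row['q97.5']:.0f})"
                for _, row in sub.iterrows()
            ]
        return pd.DataFrame(out, index=self.table.index)

    def to_csv(self, path, provenance: str | None = None) -> None:
        with open(path, "w") as fh:
            if provenance:
                fh.write(f"# {provenance}\n")
            self.formatted().to_csv(fh)


def _sigma_of(fit_or_sigma) -> float:
    return float(getattr(fit_or_sigma, "sigma_u", fit_or_sigma))


def table3(
    crude_fit,
    adjusted_fit,
    theta: float | None = None,
    config: SchoolSimConfig | None = None,
) -> SchoolSimResult:
    """Full caseload table: middle / lower- / upper-quartile schools and the
    quartile difference, for the crude and adjusted school-level SDs and
    every cutoff.

    ``crude_fit`` / ``adjusted_fit`` may be LmmFit objects or plain sigma_u
    values. The "middle" school mean is the distribution center for both the
    crude and adjusted blocks. The quartile-difference rows re-simulate
    independent lower/upper pairs rather than differencing the marginal rows.
    """
    config = config or SchoolSimConfig()
    if theta is not None:
        config.theta = float(theta)
    config.validate()
    from .lmm import quantile_mean

    rng = np.random.default_rng(config.seed)
    rq = config.report_quantiles
    q_lo, q_mid, q_hi = sorted(config.quantiles_of_schools)

    rows = {}
    for cutoff in config.cutoffs:
        mid = simulate_school_cases(
            config.center, config.theta, config.n_pupils, cutoff, config.n_sims, rng, rq
        )
        rows[("middle", "middle", cutoff)] = mid.quantiles
        for block, sigma in (("crude", _sigma_of(crude_fit)), ("adjusted", _sigma_of(adjusted_fit))):
            m_lo = quantile_mean(config.center, sigma, q_lo)
            m_hi = quantile_mean(config.center, sigma, q_hi)
            for pos, m in (("lower quartile", m_lo), ("upper quartile", m_hi)):
                s = simulate_school_cases(
                    m, config.theta, config.n_pupils, cutoff, config.n_sims, rng, rq
                )
                rows[(block, pos, cutoff)] = s.quantiles
            d = simulate_quartile_difference(
                m_lo, m_hi, config.theta, config.n_pupils, cutoff, config.n_sims, rng, rq
            )
            rows[(block, "difference", cutoff)] = d.quantiles

    index = pd.MultiIndex.from_tuples(
        [
            ("middle", "middle"),
            ("crude", "lower quartile"),
            ("crude", "upper quartile"),
            ("crude", "difference"),
            ("adjusted", "lower quartile"),
            ("adjusted", "upper quartile"),
            ("adjusted", "difference"),
        ],
        names=["block", "position"],
    )
    columns = pd.MultiIndex.from_product(
        [list(config.cutoffs), ["q2.5", "median", "q97.5"]], names=["cutoff", "quantile"]
    )
    table = pd.DataFrame(index=index, columns=columns, dtype=float)
    qmap = {"q2.5": 0.025, "median": 0.5, "q97.5": 0.975}
    for (block, pos, cutoff), quants in rows.items():
        for qname, qp in qmap.items():
            table.loc[(block, pos), (cutoff, qname)] = quants[qp]
    cfg = asdict(config)
    cfg["sigma_u_crude"] = _sigma_of(crude_fit)
    cfg["sigma_u_adjusted"] = _sigma_of(adjusted_fit)
    return SchoolSimResult(table=table, config=cfg)
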