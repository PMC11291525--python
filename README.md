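# schoolvar

Estimating how much of the variation in children's emotional and
behavioural problems sits *between schools* — and what that variation means
in practical terms — from clustered survey data.

The package is built for epidemiologists and biostatisticians analysing
pupil-level mental-health scores (the Strengths and Difficulties
Questionnaire, SDQ: total difficulties 0–40, four subscales 0–10) collected
across many schools, as in a city-wide birth-cohort follow-up. Because such
data are typically access-controlled, the package ships a synthetic-cohort
generator with the same multilevel structure, so the full pipeline is
testable and demonstrable end to end.

## The model

Pupil *i* in school *j* is modelled with a random-intercept linear mixed
model

> y<sub>ij</sub> = x<sub>ij</sub>′β + u<sub>j</sub> + e<sub>ij</sub>,  u<sub>j</sub> ~ N(0, σ<sub>u</sub>²),  e<sub>ij</sub> ~ N(0, σ<sub>e</sub>²)

fitted by profiled REML (or ML), where x<sub>ij</sub> holds pupil-level
covariates: age (centred linear + quadratic), sex, ethnicity, neighbourhood
deprivation (IMD quintile), parental occupation (NS-SEC), mother's PHQ8
depression score, household size, and survey season. The quantities of
interest are:

- **σ<sub>u</sub>** — the SD of school-level mean scores (crude: no
  covariates; adjusted: with covariates);
- **ICC** = σ<sub>u</sub>²/(σ<sub>u</sub>² + σ<sub>e</sub>²) — the share of
  variance at school level, with parametric (or cluster) bootstrap CIs;
- a likelihood-ratio test of σ<sub>u</sub>² = 0 against the
  boundary-corrected ½χ²₀ + ½χ²₁ reference;
- per-school BLUPs (shrunken school means) with conditional intervals;
- a **caseload simulation**: pupil scores in a school of *n* = 396 follow a
  negative binomial with mean drawn from N(center, σ<sub>u</sub>²) at a
  chosen quantile and dispersion θ estimated from the data; the number of
  pupils scoring ≥ 15 ("slightly raised") or ≥ 20 ("very high") per school
  is summarised over 10,000 simulated schools.

Incomplete covariates (IMD, NS-SEC, PHQ8) are handled by bootstrap-EM
multivariate-normal multiple imputation (m = 20 by default) with
Rubin's-rule pooling; the random-intercept test uses the median p-value
across imputations.

## Worked example

```python
import numpy as np, pandas as pd
from schoolvar import (CohortGenParams, generate_cohort, fit_lmm, icc,
                       quantile_mean, fit_theta, table3, SchoolSimConfig)

# a synthetic cohort with school-level SD 1.41 and pupil-level SD 5.85
params = CohortGenParams(sigma_u=1.41, sigma_e=5.85, beta=None,
                         intercept=8.84, missing_rates={}, seed=20260924)
cohort = generate_cohort(params)

codes = pd.factorize(cohort["school_id"])[0]
y = cohort["sdq_total_raw"].to_numpy()
fit = fit_lmm(y, np.ones((len(y), 1)), codes)
print(f"sigma_u = {fit.sigma_u:.2f}, ICC = {100 * icc(fit):.2f}%")
print(f"upper-quartile school mean = {quantile_mean(8.84, fit.sigma_u, 0.75):.2f}")

res = table3(fit.sigma_u, 1.04, theta=2.81,
             config=SchoolSimConfig(n_sims=10_000, seed=1))
print(res.formatted())
```

Output:

```
sigma_u = 1.52, ICC = 6.28%
upper-quartile school mean = 9.87
                           cutoff=15    cutoff=20
block    position
middle   middle          63 (50, 78)  24 (15, 34)
crude    lower quartile  45 (33, 58)   15 (8, 22)
         upper quartile  82 (67, 98)  35 (24, 47)
         difference      37 (18, 57)   20 (7, 34)
adjusted lower quartile  50 (38, 64)  17 (10, 26)
         upper quartile  76 (61, 92)  31 (21, 42)
         difference       25 (5, 46)   14 (1, 27)
```

The fitted school-level SD (1.52) recovers the generator truth (1.41)
within sampling error, and the caseload table reads: a 396-pupil school in
the middle of the distribution has a median of 63 pupils with a raised
score (95% simulation interval 50–78); moving a school from the lower to
the upper quartile of the *adjusted* distribution changes the caseload by a
median of 25 pupils.

The same pipeline runs from the shell:

```bash
schoolvar run-all --seed 1 --outdir run1
schoolvar simulate-cohort --seed 4 --out cohort.csv
schoolvar fit --cohort cohort.csv --no-adjust --out fit.json
schoolvar school-sim --crude-fit fit.json --seed 2 --out table3.csv
```

## Layout

| module | contents |
| --- | --- |
| `schoolvar.cohort` | synthetic multilevel cohort generator, MCAR missingness, CSV I/O |
| `schoolvar.lmm` | design builder, profiled REML/ML fitter, ICC, BLUPs, LRT, quantile means |
| `schoolvar.bootstrap` | parametric / cluster bootstrap CIs for σ_u and ICC |
| `schoolvar.impute` | bootstrap-EM multivariate-normal imputation, Rubin's-rule pooling |
| `schoolvar.negbin` | mean/dispersion negative binomial: θ estimation, pmf/cdf, sampler |
| `schoolvar.caseload` | per-school caseload simulation and the quartile table |
| `schoolvar.report` | descriptive tables, end-to-end pipeline with provenance |
| `schoolvar.cli` | `schoolvar` command-line interface |

See `docs/methods.md` for the statistical details and design choices.
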