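# Methods

This note documents the statistical model behind `schoolvar`, the
assumptions it makes, the numerical choices in the implementation, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## The random-intercept model and its estimation

The outcome y_ij of pupil i in school j follows

    y_ij = x_ij' beta + u_j + e_ij,    u_j ~ N(0, sigma_u^2),  e_ij ~ N(0, sigma_e^2),

with independent school effects u_j and pupil residuals e_ij. The marginal
covariance is sigma_e^2 * V0(lambda), lambda = sigma_u^2 / sigma_e^2, with
V0 block diagonal (blocks I + lambda J per school). Three facts make the
fit a one-dimensional problem:

1. given lambda, the GLS coefficients beta(lambda) are closed-form;
2. given lambda and beta, sigma_e^2 profiles out as r'V0^-1 r / (n - p)
   (REML) or / n (ML);
3. V0^-1 has the closed per-school form I - (lambda / (1 + lambda n_j)) J,
   so every criterion evaluation needs only per-school sums of X and y —
   O(J p^2) work after a single O(n p^2) precomputation.

The profiled criterion is the Harville restricted log-likelihood (without
the additive |X'X| constant):

    L_R(lambda) = -1/2 [ (n-p)(log 2 pi s2 + 1) + log|V0| + log|X'V0^-1 X| ],

ML replaces (n-p) with n and drops the last determinant. This convention
matches lme4 and statsmodels MixedLM; the test suite confirms agreement
with MixedLM to ~1e-5 in the estimates and ~1e-7 in the log-likelihood.

**Optimisation.** The criterion is minimised over log(lambda) in
[-20, 10]. For very small or degenerate designs (few schools, nearly
saturated fixed effects) the profile can be multimodal, so the search first
scans 41 equally spaced points to bracket the global optimum and then runs
bounded Brent refinement in the bracketing interval (xatol 1e-10). The
interval endpoints are evaluated explicitly: an optimum at (or tied with)
the lower bound is reported as exactly sigma_u = 0 (the boundary case), and
an optimum pinned at the upper bound is flagged `converged = False` rather
than silently returned. Rank-deficient design matrices are rejected up
front with the offending column indices (QR diagnostic).

**BLUPs.** The conditional mean of u_j is the shrunken within-school mean
residual, u_j = (lambda n_j / (1 + lambda n_j)) * mean residual, with
conditional SD sigma_e * sqrt(lambda / (1 + lambda n_j)); per-school 95%
intervals are +-1.96 conditional SDs. These are conditional (given the
variance estimates) intervals, not profile intervals. Singleton schools are
allowed and contribute normally.

**Quantile means.** A school at quantile q of the fitted school-level
distribution has mean center + qnorm(q) * sigma_u. The "adjusted"
distribution is centred at the same overall mean as the crude one (the
covariate adjustment moves variance, not the centre): with center 8.84 this
gives 7.88/9.79 at sigma_u = 1.41 and 8.13/9.54 at sigma_u = 1.04.

**Likelihood-ratio test.** sigma_u^2 = 0 lies on the parameter boundary,
so twice the ML log-likelihood gap against the fixed-effects-only model is
referred to the 50:50 mixture of a point mass at zero and chi-square(1):
p = 0.5 * P(chi2_1 >= T). The plain chi2_1 p-value is also reported as a
conservative alternative. Simulation at 30 schools x 20 pupils puts the
type-I error at ~2% for nominal 5% — the mixture is itself slightly
conservative in finite samples, which we accept rather than calibrate away.

## Design matrix conventions

Reference categories: female; winter; most-deprived IMD quintile;
Pakistani; managerial/administrative/professional NS-SEC; household 1–3.
Age enters centred at the sample mean, as linear and squared-centred terms;
PHQ8 enters linearly. With complete data the adjusted model has 23
non-intercept terms. When missing values remain (analyses run without
imputation), IMD and NS-SEC gain a "Missing" indicator level and PHQ8 is
mean-filled alongside a missing indicator. Weekday of survey completion is
supported as an optional term but excluded from the default adjustment set,
which follows the reporting layout of the adjusted model. The quadratic-age
basis is our own (centre-then-square) convention; age coefficients are
therefore comparable only within this package.

## Bootstrap intervals for sigma_u and the ICC

Default: parametric bootstrap, n_boot = 2000, percentile 2.5/97.5
endpoints. Each replicate simulates y* = X beta_hat + Z u* + e* from the
fitted variances and refits; this matches the model-based estimand and is
well behaved at the sigma_u = 0 boundary (the interval's lower end collapses
to 0 there, as it should). A cluster nonparametric alternative (resampling
whole schools with replacement) is provided and labelled in the output.
Non-converged refits are dropped with a logged count; more than 10%
failures is an error. Percentile rather than BCa endpoints: the simplest
defensible interval, and the one whose coverage we verify by simulation
(96.5% observed for a nominal 95% interval at the survey-scale design,
200 outer replicates x 500 bootstrap draws — the reduced draw count per
replicate keeps the coverage study tractable; endpoint noise at 500 draws
is ~0.3 percentage points of ICC).

## Multiple imputation

The imputer is a bootstrap-EM multivariate normal, the same family as
EM-with-bootstrap imputation engines used for cross-sectional survey data:
per imputation, (1) resample rows with replacement, (2) fit (mu, Sigma) of
a joint normal over a numeric coding of the variables by EM across
missingness patterns (max 500 iterations, tolerance 1e-6, tiny ridge for
factorisation stability), (3) draw each missing cell of the *original*
data from its conditional normal given the row's observed cells. Numeric
coding: outcome, age, sex indicator, five ethnicity indicators, household
band ordinal (complete columns), plus IMD 1–5, NS-SEC 1–5 ordinals and the
PHQ8 count (incomplete columns). Ordinal draws are rounded and clipped to
their ranges; PHQ8 to [0, 24]. Observed cells are never modified, so they
are bit-identical across the m = 20 completed datasets.

Round-and-clip at a floor biases imputed means of skewed counts slightly
upward (for PHQ8, about +0.5 points at survey-like skewness — the latent
conditional-normal draws are the mean-unbiased quantity, and both are
exposed for diagnostics). This is an accepted property of normal-model
imputation of skewed ordinals, shared by the engines this scheme mirrors.

Pooling follows Rubin's rules: pooled beta = mean; total variance
W + (1 + 1/m) B; df = (m-1)(1 + W/((1+1/m)B))^2. Variance components have
no standard Rubin variance, so sigma_u and ICC are pooled as plain means
with the across-imputation SD reported as a spread diagnostic; evidence for
the random intercept is the median LRT p-value across imputations. In the
pipeline, bootstrap CIs accompany the crude model always; for the adjusted
model with missing data they are computed on the first completed dataset
(labelled as such), since imputation spread is reported separately.

## Negative binomial and the caseload simulation

The pupil-level score distribution is negative binomial in mean/dispersion
(NB2) form: mean mu, dispersion theta, variance mu + mu^2/theta.
Probabilities go through scipy's nbinom (log-space gamma functions);
sampling is the gamma–Poisson mixture. theta is estimated with mu fixed at
the sample mean and a bounded search over log(theta) in [-5, 10] (xatol
1e-8); estimating theta jointly with mu moves the estimate negligibly, and
fixing mu at the mean keeps the fitted mean exact. Underdispersed samples
are rejected with advice to use a Poisson model.

The caseload simulation draws, for each of 10,000 simulated schools, 396
pupil scores from NB(mean, theta) with the school mean set at a chosen
quantile of N(center, sigma_u^2), and counts scores at or above the cutoff
(15 "slightly raised", 20 "very high"; a score equal to the cutoff is a
case, consistent with the band labels starting at 15). Reported are the
2.5/50/97.5% quantiles of the counts. Quartile differences pair one
independently simulated lower-quartile and one upper-quartile school per
replicate; independent pairing makes the difference variance the sum of the
marginal variances, which matches the width of the published difference
intervals (a common-shock pairing would be markedly narrower). The
intervals are simulation quantiles — they describe between-school-and-
sampling variability at fixed parameter values, not inferential uncertainty
in sigma_u or theta. Draws are not truncated at the SDQ maximum of 40: at
mu <= 10 and theta ~ 2.8 the tail mass beyond 40 is ~2e-4 and the effect on
case counts at cutoffs 15/20 is nil.

## The synthetic cohort generator

The generator emulates a city-wide primary-school survey: 135 schools by
default, cluster sizes from a discretised lognormal with median 29 and IQR
16–51 (log-SD 0.860), truncated to [5, 200] by resampling — a lognormal
with that quartile spread has a heavier right tail than the real size
distribution, so the default total lands around 5,300–5,700 pupils rather
than ~5,000; the median and IQR are the calibrated quantities. Covariate
marginals follow the survey's published distribution (56% Pakistani
heritage, 68% most-deprived IMD quintile, etc.); PHQ8 is drawn from
NB(3.9, 0.85), matched to the published band frequencies and median/IQR;
age is truncated normal (9.7, 0.9) on [6, 12]; season and weekday are
uniform. Default fixed effects use the published adjusted coefficients for
the categorical terms and PHQ8, mild centred-age effects (-0.2/yr,
-0.02/yr^2) on our own basis, and an intercept of 6.65 chosen so the
marginal outcome mean sits at the observed 8.84.

Outcomes come in two modes. Gaussian mode records both the exact value and
the value rounded/clipped to [0, 40]; parameter-recovery tests use the
exact values so rounding bias cannot contaminate oracle comparisons.
Identity-link negative-binomial mode draws NB(max(0.1, intercept + x'beta
+ u_j), theta) — the 0.1 floor keeps the distribution defined, with a
logged warning when it binds. Missingness is MCAR at per-column rates
(defaults 1% IMD, 5% NS-SEC, 3% PHQ8).

What the generator does *not* emulate: covariate–covariate and
covariate–school dependence (covariates are drawn independently of each
other and of the school, so the crude and adjusted school-level SDs
coincide in truth — real data show the adjustment shrinking sigma_u);
MAR/MNAR missingness; survey non-response; measurement properties of the
SDQ across ethnic/language groups. Passing tests therefore demonstrate
correctness of the estimators under the stated model, not robustness to
those real-data features.

## Problem sizes in the test suite

Simulation-based checks use sizes chosen to make Monte-Carlo error small
relative to their tolerances: the caseload table at the full 10,000
simulated schools; parameter recovery and bootstrap coverage at 200
replicate cohorts (full survey scale) with 500 bootstrap draws each; LRT
calibration at 1,000 null simulations of 30 schools x 20 pupils;
negative-binomial self-consistency at 1e6 draws; dense-oracle equivalence
on random instances up to 50 observations (grid of 3,000–10,000 lambda
points). The MI pipeline recovery check runs 3 replicate cohorts of 80
schools with m = 5 imputations; its tolerance (+-0.2 on sigma_u) reflects
that reduced averaging.

## Known limitations

- One grouping level only: no crossed or nested random effects, no random
  slopes, no non-Gaussian mixed models.
- The linear mixed model is applied to bounded integer scores, as is
  standard for SDQ analyses; the Gaussian residual is an approximation to a
  right-skewed count.
- BLUP intervals are conditional on the estimated variances and do not
  propagate uncertainty in sigma_u, sigma_e.
- Caseload-table intervals are simulation quantiles at point estimates of
  (sigma_u, theta), not confidence intervals for the caseload.
- The normal imputation model treats ordinals as continuous; with the low
  missingness rates here (1–5%) the induced bias is negligible for the
  variance components, which are the targets of the analysis.
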