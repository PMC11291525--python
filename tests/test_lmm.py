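"""Random-intercept model: design matrix, profiled REML/ML vs dense oracle,
BLUP shrinkage, ICC, quantile means, and the boundary LRT."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from schoolvar import (
    CohortGenParams,
    ModelSpec,
    build_design,
    fit_lmm,
    generate_cohort,
    icc,
    inject_missingness,
    lrt_random_intercept,
    quantile_mean,
    school_means,
    school_quantile_mean,
)
from conftest import dense_blups, dense_grid_fit, dense_restricted_loglik

# The 23 fixed-effect labels of the adjusted model (complete data), in
# reporting order.
ADJUSTED_LABELS = (
    ["age", "age^2", "sex[male]"]
    + [f"season[{s}]" for s in ("spring", "summer", "autumn")]
    + [f"imd_quintile[{q}]" for q in (2, 3, 4, 5)]
    + [
        "ethnicity[White British and White Other]",
        "ethnicity[Asian (other than Pakistani)]",
        "ethnicity[Mixed]",
        "ethnicity[Other]",
        "ethnicity[Black African and Black Caribbean]",
    ]
    + ["phq8"]
    + [
        "nssec[Intermediate]",
        "nssec[Small employers and own account workers]",
        "nssec[Lower supervisory and technical]",
        "nssec[Semi-routine and routine]",
    ]
    + [f"household_size[{h}]" for h in ("4-5", "6-7", "8+")]
)


class TestBuildDesign:
    def test_adjusted_design_has_23_labels_in_order(self, crude_cohort):
        params = CohortGenParams(n_schools=25, seed=31)
        cohort = generate_cohort(params)
        y, X, labels, codes, glabels = build_design(cohort, ModelSpec())
        assert labels[0] == "(Intercept)"
        assert labels[1:] == ADJUSTED_LABELS
        assert X.shape == (len(cohort), 24)
        assert len(glabels) == 25

    def test_reference_level_row_is_intercept_only(self):
        row = pd.DataFrame(
            {
                "school_id": ["S1", "S1", "S2"],
                "sdq_total": [8, 9, 10],
                "age": [9.0, 10.0, 11.0],
                "sex": ["female"] * 3,
                "season": ["winter"] * 3,
                "imd_quintile": [1.0] * 3,
                "ethnicity": ["Pakistani"] * 3,
                "phq8": [0.0] * 3,
                "nssec": ["Managerial, administrative and professional"] * 3,
                "household_size": ["1-3"] * 3,
            }
        )
        y, X, labels, *_ = build_design(row, ModelSpec())
        # pupil at the sample-mean age, all reference categories, phq8=0:
        # both centred-age terms vanish, leaving only the intercept
        k = labels.index("age")
        assert X[1, k] == pytest.approx(0.0)
        nonzero = np.flatnonzero(np.abs(X[1]) > 1e-12)
        assert nonzero.tolist() == [0]

    def test_missing_indicator_columns_only_when_missing(self):
        cohort = generate_cohort(CohortGenParams(n_schools=15, seed=33))
        y, X, labels, *_ = build_design(cohort, ModelSpec())
        assert not any("Missing" in lab for lab in labels)
        withmiss = inject_missingness(
            cohort, {"imd_quintile": 0.05, "nssec": 0.05, "phq8": 0.05}, seed=1
        )
        y2, X2, labels2, *_ = build_design(withmiss, ModelSpec())
        assert "imd_quintile[Missing]" in labels2
        assert "nssec[Missing]" in labels2
        assert "phq8[Missing]" in labels2
        assert X2.shape[1] == X.shape[1] + 3

    def test_unseen_level_named_in_error(self):
        cohort = generate_cohort(CohortGenParams(n_schools=10, seed=34))
        cohort.loc[cohort.index[0], "ethnicity"] = "Martian"
        with pytest.raises(ValueError, match="Martian"):
            build_design(cohort, ModelSpec())

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            build_design(pd.DataFrame(), ModelSpec())


class TestProfiledFit:
    def test_sigma_u_zero_boundary_equals_ols(self):
        # groups with identical means and almost-zero noise: no school effect
        codes = np.repeat(np.arange(3), 2)
        y = np.array([5.0, 5.0, 5.0, 5.0, 5.0, 5.5])
        X = np.ones((6, 1))
        fit = fit_lmm(y, X, codes)
        assert fit.sigma_u == 0.0
        beta_ols = y.mean()
        assert fit.beta[0] == pytest.approx(beta_ols, abs=1e-10)

    def test_toy_fit_matches_dense_grid_oracle(self, toy_lmm_data):
        y, X, codes = toy_lmm_data
        for criterion in ("reml", "ml"):
            fit = fit_lmm(y, X, codes, criterion=criterion)
            _, ll_grid = dense_grid_fit(y, X, codes, reml=criterion == "reml")
            assert fit.loglik >= ll_grid - 1e-9
            assert abs(fit.loglik - ll_grid) < 1e-4

    def test_matches_statsmodels_mixedlm(self):
        from statsmodels.regression.mixed_linear_model import MixedLM

        rng = np.random.default_rng(21)
        codes = np.repeat(np.arange(25), 12)
        X = np.column_stack([np.ones(300), rng.normal(size=300), rng.normal(size=300)])
        y = X @ [8.0, 1.0, -0.5] + rng.normal(0, 1.3, 25)[codes] + rng.normal(0, 2.4, 300)
        ours = fit_lmm(y, X, codes)
        sm = MixedLM(y, X, groups=codes).fit(reml=True)
        assert ours.sigma_u == pytest.approx(float(np.sqrt(np.asarray(sm.cov_re)[0, 0])), abs=1e-3)
        assert ours.sigma_e == pytest.approx(float(np.sqrt(sm.scale)), abs=1e-3)
        assert np.allclose(ours.beta, np.asarray(sm.fe_params), atol=1e-4)
        assert ours.loglik == pytest.approx(float(sm.llf), abs=1e-5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n_groups=st.integers(2, 5),
        per_group=st.integers(2, 10),
        p_extra=st.integers(0, 2),
        reml=st.booleans(),
    )
    def test_profiled_equals_dense_oracle_on_random_instances(
        self, seed, n_groups, per_group, p_extra, reml
    ):
        """On every random instance of <= 50 observations the profiled fit
        attains the dense grid-search optimum (loglik gap < 1e-4)."""
        rng = np.random.default_rng(seed)
        codes = np.repeat(np.arange(n_groups), per_group)
        n = len(codes)
        X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(p_extra)])
        sigma_u = rng.uniform(0.0, 2.0)
        y = rng.normal(0, sigma_u, n_groups)[codes] + rng.normal(0, 1.0, n)
        crit = "reml" if reml else "ml"
        fit = fit_lmm(y, X, codes, criterion=crit)
        _, ll_grid = dense_grid_fit(y, X, codes, reml=reml, n_grid=3000)
        assert fit.loglik >= ll_grid - 1e-9
        assert abs(fit.loglik - ll_grid) < 1e-4
        # fit's own loglik agrees with the dense evaluation at its lambda
        ll_dense = dense_restricted_loglik(y, X, codes, fit.lam, reml)
        assert fit.loglik == pytest.approx(ll_dense, abs=1e-8)

    def test_rank_deficient_design_rejected(self, toy_lmm_data):
        y, X, codes = toy_lmm_data
        X2 = np.column_stack([X, X[:, 0]])  # duplicated constant column
        with pytest.raises(ValueError, match="rank deficient"):
            fit_lmm(y, X2, codes)

    def test_reml_and_ml_sigma_e_agree_at_large_n(self):
        rng = np.random.default_rng(3)
        codes = np.repeat(np.arange(200), 50)
        n = len(codes)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [5.0, 1.0] + rng.normal(0, 1.0, 200)[codes] + rng.normal(0, 2.0, n)
        reml = fit_lmm(y, X, codes, criterion="reml")
        ml = fit_lmm(y, X, codes, criterion="ml")
        assert abs(reml.sigma_e - ml.sigma_e) / reml.sigma_e < 0.01

    def test_icc_invariant_to_affine_rescaling(self, toy_lmm_data):
        y, X, codes = toy_lmm_data
        base = icc(fit_lmm(y, X, codes))
        scaled = icc(fit_lmm(3.7 * y + 11.0, X, codes))
        assert abs(base - scaled) < 1e-8

    def test_singleton_groups_permitted(self):
        codes = np.array([0, 0, 0, 1, 2, 2])
        y = np.array([4.0, 5.0, 6.0, 9.0, 2.0, 3.0])
        fit = fit_lmm(y, np.ones((6, 1)), codes)
        assert fit.n_schools == 3
        assert len(fit.blups) == 3


class TestBlups:
    def test_blups_match_dense_conditional_means(self, toy_lmm_data):
        y, X, codes = toy_lmm_data
        fit = fit_lmm(y, X, codes)
        expected = dense_blups(y, X, codes, fit.lam, fit.sigma_e**2)
        assert np.allclose(fit.blups["blup"].to_numpy(), expected, atol=1e-8)

    def test_blup_mean_near_zero(self, crude_cohort):
        codes = pd.factorize(crude_cohort["school_id"])[0]
        y = crude_cohort["sdq_total_raw"].to_numpy()
        fit = fit_lmm(y, np.ones((len(y), 1)), codes)
        b = fit.blups["blup"].to_numpy()
        assert abs(b.mean()) < 1e-2 * fit.sigma_u  # shrinkage keeps them centred
        assert len(b) == fit.n_schools

    def test_shrinkage_monotone_in_group_size(self):
        # two schools with the same raw mean residual, different sizes
        codes = np.array([0] * 2 + [1] * 60 + [2] * 60)
        rng = np.random.default_rng(5)
        filler = rng.normal(8.0, 1.0, 60)
        y = np.concatenate([[10.0, 10.0], filler + 2.0, filler - 2.0])
        fit = fit_lmm(y, np.ones((122, 1)), codes)
        small = fit.blups.loc[fit.blups.school_id == 0, "blup"].iloc[0]
        grand_resid_small = y[:2].mean() - fit.beta[0]
        # shrinkage factor lambda n / (1 + lambda n) < 1 and increasing in n
        lam = fit.lam
        assert small == pytest.approx(lam * 2 / (1 + lam * 2) * grand_resid_small, rel=1e-8)

    def test_large_group_blup_approaches_raw_residual(self):
        rng = np.random.default_rng(6)
        codes = np.repeat(np.arange(40), 200)
        u = rng.normal(0, 2.0, 40)
        y = 5.0 + u[codes] + rng.normal(0, 1.0, len(codes))
        fit = fit_lmm(y, np.ones((len(y), 1)), codes)
        raw = pd.Series(y).groupby(codes).mean() - fit.beta[0]
        shrink = fit.lam * 200 / (1 + fit.lam * 200)
        assert shrink > 0.99
        assert np.allclose(fit.blups["blup"], raw * shrink, atol=1e-8)

    def test_school_means_intervals(self, toy_lmm_data):
        y, X, codes = toy_lmm_data
        fit = fit_lmm(y, X, codes)
        sm = school_means(fit, center=9.0)
        assert np.allclose(sm["mean"], 9.0 + fit.blups["blup"])
        assert np.allclose(sm["hi"] - sm["mean"], 1.96 * fit.blups["cond_se"])


class TestQuantileMeans:
    def test_median_quantile_returns_center(self):
        assert quantile_mean(8.84, 1.41, 0.5) == pytest.approx(8.84)

    @pytest.mark.parametrize(
        "sigma_u,q,expected,tol",
        [
            # upper quartiles printed to 2 dp; lower quartiles rounded from
            # an unprinted exact value, so checked to +-0.01
            (1.41, 0.75, 9.79, 0.005),  # crude upper quartile
            (1.41, 0.25, 7.88, 0.01),  # crude lower quartile
            (1.04, 0.75, 9.54, 0.005),  # adjusted upper quartile
            (1.04, 0.25, 8.13, 0.01),  # adjusted lower quartile
        ],
    )
    def test_published_quartile_means(self, sigma_u, q, expected, tol):
        assert quantile_mean(8.84, sigma_u, q) == pytest.approx(expected, abs=tol)

    def test_invalid_quantile_rejected(self, toy_lmm_data):
        y, X, codes = toy_lmm_data
        fit = fit_lmm(y, X, codes)
        with pytest.raises(ValueError):
            school_quantile_mean(fit, 1.2, 8.84)


class TestLrt:
    def test_statistic_nonnegative_and_null_p_moderate(self):
        rng = np.random.default_rng(8)
        codes = np.repeat(np.arange(20), 10)
        y = rng.normal(0, 1, 200)  # no school effect
        res = lrt_random_intercept(y, np.ones((200, 1)), codes)
        assert res.statistic >= 0.0
        assert res.p_value > 0.05  # near its null median of ~0.5

    def test_strong_school_effect_detected(self):
        """At survey scale with sigma_u around 1, the random-intercept test is
        decisively significant in nearly all replicates."""
        detected = 0
        for rep in range(20):
            params = CohortGenParams(
                sigma_u=1.04, sigma_e=5.85, beta=None, intercept=8.84,
                missing_rates={}, make_subscales=False, seed=600 + rep,
            )
            c = generate_cohort(params)
            codes = pd.factorize(c["school_id"])[0]
            res = lrt_random_intercept(
                c["sdq_total_raw"].to_numpy(), np.ones((len(c), 1)), codes
            )
            detected += res.p_value < 0.001
        assert detected >= 19

    def test_mixture_p_half_of_chi2(self):
        rng = np.random.default_rng(9)
        codes = np.repeat(np.arange(10), 8)
        y = rng.normal(0, 1, 80) + rng.normal(0, 0.8, 10)[codes]
        res = lrt_random_intercept(y, np.ones((80, 1)), codes)
        assert res.p_value == pytest.approx(0.5 * res.p_chi2_1)
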