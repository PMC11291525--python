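import numpy as np
import pandas as pd
import pytest

from schoolvar import CohortGenParams, generate_cohort


@pytest.fixture(scope="session")
def toy_lmm_data():
    """3 schools x 4 pupils with printed-in-test outcomes."""
    codes = np.repeat(np.arange(3), 4)
    y = np.array([8.0, 10.0, 7.0, 9.0, 12.0, 11.0, 13.0, 10.0, 6.0, 5.0, 7.0, 8.0])
    X = np.ones((12, 1))
    return y, X, codes


@pytest.fixture(scope="session")
def crude_cohort():
    """Paper-scale cohort with no covariate effects: the crude-model truth
    sigma_u=1.41, sigma_e=5.85 (ICC 5.49%)."""
    params = CohortGenParams(
        sigma_u=1.41,
        sigma_e=5.85,
        beta=None,
        intercept=8.84,
        missing_rates={},
        make_subscales=False,
        seed=20260924,
    )
    return generate_cohort(params)


@pytest.fixture(scope="session")
def small_cohort():
    """20 schools of ~25 pupils with full covariate structure and missingness."""
    from schoolvar import inject_missingness

    params = CohortGenParams(n_schools=20, seed=7)
    cohort = generate_cohort(params)
    return inject_missingness(cohort, params.missing_rates, seed=8)


def dense_restricted_loglik(y, X, codes, lam, reml=True):
    """Independent dense-matrix oracle for the profiled criterion: builds
    V0 = I + lam * Z Z^T explicitly and evaluates the (restricted)
    log-likelihood with sigma_e^2 profiled out."""
    n, p = X.shape
    Z = np.zeros((n, codes.max() + 1))
    Z[np.arange(n), codes] = 1.0
    V0 = np.eye(n) + lam * (Z @ Z.T)
    Vinv = np.linalg.inv(V0)
    A = X.T @ Vinv @ X
    beta = np.linalg.solve(A, X.T @ Vinv @ y)
    r = y - X @ beta
    quad = float(r @ Vinv @ r)
    _, ldV0 = np.linalg.slogdet(V0)
    if reml:
        dof = n - p
        s2 = quad / dof
        _, ldA = np.linalg.slogdet(A)
        return -0.5 * (dof * (np.log(2 * np.pi * s2) + 1.0) + ldV0 + ldA)
    s2 = quad / n
    return -0.5 * (n * (np.log(2 * np.pi * s2) + 1.0) + ldV0)


def dense_grid_fit(y, X, codes, reml=True, n_grid=10_000):
    """Grid-search oracle over log(lambda) in [-20, 10]."""
    grid = np.linspace(-20.0, 10.0, n_grid)
    lls = np.array([dense_restricted_loglik(y, X, codes, np.exp(g), reml) for g in grid])
    k = int(np.argmax(lls))
    return float(np.exp(grid[k])), float(lls[k])


def dense_blups(y, X, codes, lam, sigma_e2):
    """Conditional means of the random intercepts from the dense model:
    E[u | y] = sigma_u^2 Z^T V^{-1} (y - X beta)."""
    n, p = X.shape
    Z = np.zeros((n, codes.max() + 1))
    Z[np.arange(n), codes] = 1.0
    sigma_u2 = lam * sigma_e2
    V = sigma_u2 * (Z @ Z.T) + sigma_e2 * np.eye(n)
    Vinv = np.linalg.inv(V)
    A = X.T @ Vinv @ X
    beta = np.linalg.solve(A, X.T @ Vinv @ y)
    return sigma_u2 * (Z.T @ (Vinv @ (y - X @ beta)))
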