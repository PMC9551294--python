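import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import timecoda as tc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def brute_force_nonwear(met, run_minutes=60, strict=True):
    """Independent oracle: scan every maximal zero-run with a plain loop."""
    met = np.asarray(met, dtype=float)
    mask = np.zeros(met.size, dtype=bool)
    i = 0
    while i < met.size:
        if met[i] == 0.0:
            j = i
            while j < met.size and met[j] == 0.0:
                j += 1
            length = j - i
            if (length > run_minutes) if strict else (length >= run_minutes):
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask


def ols_normal_equations(X, y):
    """Independent OLS oracle: solve the normal equations directly and build
    classical t-based inference from first principles."""
    from scipy import stats

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - p)
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    tval = beta / se
    pvals = 2 * stats.t.sf(np.abs(tval), n - p)
    tcrit = stats.t.ppf(0.975, n - p)
    return beta, se, pvals, (beta - tcrit * se, beta + tcrit * se), sigma2


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 40-participant study with epochs (shared, read-only)."""
    cfg = tc.CohortConfig(n_participants=40, seed=424242, days_per_participant=7)
    covariates, outcomes, epochs, truth = tc.generate_study(cfg)
    return cfg, covariates, outcomes, epochs, truth


@pytest.fixture(scope="session")
def default_cohort():
    """Calibrated full-size cohort (no epoch streams) for statistical checks."""
    cfg = tc.CohortConfig(seed=2017)
    covariates, truth = tc.generate_cohort(cfg)
    outcomes = tc.generate_outcomes(covariates, truth, cfg)
    table = covariates.merge(outcomes, on="participant_id")
    return cfg, table, truth
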