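import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from cogfoot import (
    HorseshoeConfig,
    default_scenario,
    fit_linear_horseshoe,
    fit_logistic_horseshoe,
    generate_cohort,
)
from cogfoot.preprocess import ColumnMeta, DesignMatrix, OutcomeVector


def make_design(
    n: int,
    n_meds: int,
    seed: int,
    beta: np.ndarray | None = None,
    binary_outcome: bool = False,
    exposure_prevalence: float = 0.3,
    n_covariates: int = 0,
) -> tuple[DesignMatrix, OutcomeVector]:
    """A standardized design with medication and covariate columns.

    Medications are Bernoulli exposures (standardized), covariates standard
    normal; the outcome is linear (or logistic) in the standardized columns
    with unit noise, so ``beta`` is on the standardized scale directly.
    """
    rng = np.random.default_rng(seed)
    p = 1 + n_meds + n_covariates
    cols = [ColumnMeta("intercept", "intercept")]
    X = [np.ones(n)]
    for i in range(n_meds):
        raw = (rng.random(n) < exposure_prevalence).astype(float)
        meta = ColumnMeta(f"A{i:02d}AA{i:02d}", "medication", 5)
        meta.mean, meta.sd = float(raw.mean()), float(raw.std())
        X.append((raw - meta.mean) / meta.sd)
        cols.append(meta)
    for i in range(n_covariates):
        raw = rng.standard_normal(n)
        meta = ColumnMeta(f"cov{i}", "covariate")
        meta.mean, meta.sd = float(raw.mean()), float(raw.std())
        X.append((raw - meta.mean) / meta.sd)
        cols.append(meta)
    X = np.column_stack(X)
    if beta is None:
        beta = np.zeros(p)
    eta = X @ beta
    if binary_outcome:
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
        out = OutcomeVector(y, "binary", False, "y")
    else:
        y = eta + rng.standard_normal(n)
        out = OutcomeVector(y, "continuous", False, "y")
    return DesignMatrix(X=X, columns=cols, row_index=np.arange(n)), out


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(default_scenario(n_participants=6000, seed=3))


@pytest.fixture(scope="session")
def stored_linear_fit():
    """A linear horseshoe fit with a few real effects, reused across tests."""
    beta = np.zeros(13)
    beta[1], beta[2], beta[3] = 0.4, -0.3, 0.1
    design, y = make_design(n=1500, n_meds=10, seed=42, beta=beta, n_covariates=2)
    cfg = HorseshoeConfig(n_iter=1300, burn_in=300, seed=7, unpenalized=("intercept",))
    return fit_linear_horseshoe(design, y, cfg), design, y


@pytest.fixture(scope="session")
def stored_logistic_fit():
    beta = np.zeros(7)
    beta[0], beta[1] = 1.0, -0.5
    design, y = make_design(
        n=1500, n_meds=6, seed=11, beta=beta, binary_outcome=True
    )
    cfg = HorseshoeConfig(n_iter=1100, burn_in=300, seed=9, unpenalized=("intercept",))
    return fit_logistic_horseshoe(design, y, cfg), design, y
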