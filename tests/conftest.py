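"""Shared fixtures: small GLMM instances and simulated populations."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from reproage.simulate import SimulationConfig, simulate_population


def make_glmm_instance(n_ind, n_yr, per, s2i, s2y, seed, beta=(0.3, 0.4)):
    """A small crossed-design Bernoulli dataset with known parameters."""
    rng = np.random.default_rng(seed)
    nobs = n_ind * per
    ind = np.repeat(np.arange(n_ind), per)
    yr = rng.integers(0, n_yr, nobs)
    X = np.column_stack([np.ones(nobs), rng.normal(size=nobs)])
    beta = np.asarray(beta, float)
    u = rng.normal(0, np.sqrt(s2i), n_ind)
    v = rng.normal(0, np.sqrt(s2y), n_yr)
    y = rng.binomial(1, expit(X @ beta + u[ind] + v[yr])).astype(float)
    return y, X, beta, s2i, s2y, ind, yr


#: Small instances with modest variance components, where the Laplace
#: approximation is expected to track the exact likelihood closely.
ORACLE_FIXTURES = [
    (8, 2, 5, 0.09, 0.04, 101),
    (12, 3, 5, 0.09, 0.04, 102),
    (15, 3, 3, 0.0625, 0.0225, 103),
    (20, 3, 4, 0.04, 0.04, 104),
    (10, 4, 4, 0.0625, 0.04, 105),
]


@pytest.fixture(scope="session")
def wa_population():
    """Default (wandering-albatross-like) simulated population with truth."""
    cfg = SimulationConfig(seed=2024)
    records, truth = simulate_population(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def wa_annotated(wa_population):
    from reproage import records as rec

    _, df, _ = wa_population
    hist = rec.build_histories(df, int(df["season"].max()))
    return rec.derive_covariates(df, hist), hist


@pytest.fixture()
def tiny_csv(tmp_path):
    path = tmp_path / "records.csv"
    pd.DataFrame(
        {
            "individual_id": ["b1", "b1", "b1", "b2"],
            "species": ["WA"] * 4,
            "sex": ["F"] * 4,
            "season": [2000, 2001, 2003, 2001],
            "age": [10, 11, 13, 8],
            "outcome": [0, 1, 1, 0],
            "partner_id": ["A", "A", "B", "C"],
        }
    ).to_csv(path, index=False)
    return path
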