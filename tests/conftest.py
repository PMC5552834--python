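import numpy as np
import pandas as pd
import pytest

from metarisk import CohortTable, SyntheticConfig, generate_cohort
from metarisk.synthetic import ContinuousCovariate, CategoricalCovariate


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_samples=160, n_progressors=40, n_targeted=4, n_untargeted=16,
        planted_effects=(("alpha", np.log(2.2)), ("beta", np.log(0.55))),
        marker_correlations=(("alpha", "beta", -0.3),),
        covariate_model={
            "age": ContinuousCovariate(mean=(48.0, 53.0), sd=(10.0, 10.0)),
            "sex": CategoricalCovariate(levels=(0.0, 1.0),
                                        probs=((0.5, 0.5), (0.5, 0.5))),
        },
        missing_rate=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture
def tiny_table():
    """Hand-built 6-sample cohort with known values."""
    ids = pd.Index([f"s{i}" for i in range(6)], name="sample_id")
    features = pd.DataFrame(
        {"f1": [2.0, np.nan, 5.0, 3.0, 4.0, 1.0],
         "f2": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]},
        index=ids)
    covariates = pd.DataFrame(
        {"age": [40.0, 50.0, np.nan, 55.0, 60.0, 45.0],
         "sex": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0]},
        index=ids)
    outcome = pd.Series([0, 0, 1, 0, 1, 1], index=ids, name="progressor")
    return CohortTable(features=features, covariates=covariates,
                       outcome=outcome)
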