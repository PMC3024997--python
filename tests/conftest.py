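import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from emexposure import CohortSchema, CohortTable, MissingnessSpec, compact_config

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def toy_schema():
    return CohortSchema(
        covariates={
            "maternal_age": ["<=25", "25-30", "30-35", ">35"],
            "parity": ["0", "1", "2", "3", "4+"],
            "smoking": ["no", "yes"],
        }
    )


@pytest.fixture
def toy_table(toy_schema):
    """Six hand-tallied records covering all exposure states and genders."""
    df = pd.DataFrame(
        {
            "id": [f"c{i}" for i in range(6)],
            "gender": ["male", "male", "female", "female", "male", "female"],
            "asd": [1, 0, 0, 1, 1, 0],
            "hypoxia": ["positive", "negative", "positive", None, None, "negative"],
            "fullterm": [1, 1, 0, 1, None, 1],
            "maternal_age": ["<=25", "25-30", "25-30", ">35", "30-35", "<=25"],
            "parity": ["0", "1", "0", "2", "4+", "3"],
            "smoking": ["no", "yes", "no", "no", "yes", "no"],
        }
    )
    return CohortTable(df=df, schema=toy_schema)


def dense_config(n=400, outcome_rate=0.25, missing_rate=0.4, seed=0, true_or=2.0):
    """A small, information-dense cohort for exercising the EM machinery.

    The common outcome and MCAR missingness keep tiny cohorts identifiable,
    which unit tests of the numerics need; scientific recovery experiments
    use the package defaults instead.
    """
    return compact_config(
        n=n,
        outcome_rate=outcome_rate,
        true_or=true_or,
        missingness=MissingnessSpec("mcar", missing_rate),
        seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
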