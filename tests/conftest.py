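import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kdscreen import CohortTable, FeatureSchema, make_fixture_suite
from kdscreen.cohort import Feature

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# lightgbm/sklearn emit a harmless feature-name warning on ndarray input
warnings.filterwarnings("ignore", message=".*does not have valid feature names.*")


@pytest.fixture(scope="session")
def small_suite():
    """Desk-scale train/test/external triple shared by read-only tests."""
    return make_fixture_suite(7, n_train=2500, n_test=1500, n_external=600)


@pytest.fixture(scope="session")
def tiny_schema() -> FeatureSchema:
    return FeatureSchema(
        features=(
            Feature("marker", "blood", "continuous"),
            Feature("cells", "urine", "count"),
            Feature("flag", "demographic", "categorical"),
        ),
        label_name="y",
    )


def make_table(schema: FeatureSchema, n: int, pos_rate: float, seed: int) -> CohortTable:
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < pos_rate).astype(int)
    values = np.column_stack(
        [
            rng.normal(0, 1, n) + labels,
            rng.poisson(4, n),
            rng.integers(0, 3, n).astype(float),
        ]
    )
    return CohortTable(schema=schema, values=values, labels=labels)


@pytest.fixture(scope="session")
def tiny_table(tiny_schema) -> CohortTable:
    return make_table(tiny_schema, 200, 0.3, seed=11)
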