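import numpy as np
import pandas as pd
import pytest

from mealnet.core_data import FoodGroupTaxonomy, MealMatrix, example_hei_standards
from mealnet.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort shared by integration-style tests."""
    return generate_cohort(GeneratorConfig(n_participants=25, seed=11))


@pytest.fixture(scope="session")
def standards():
    return example_hei_standards()


@pytest.fixture
def toy_taxonomy():
    groups = ("milk", "cereal", "fruit", "bread")
    mapping = {"M1": "milk", "M2": "milk", "C1": "cereal", "F1": "fruit", "B1": "bread"}
    return FoodGroupTaxonomy(mapping=mapping, groups=groups)


def make_meal_matrix(values: np.ndarray, groups=None) -> MealMatrix:
    """Wrap a raw array in a MealMatrix with synthetic meal keys."""
    n = len(values)
    groups = groups or [f"g{j}" for j in range(values.shape[1])]
    keys = pd.DataFrame({
        "participant_id": [f"p{i % 7}" for i in range(n)],
        "recall_id": [f"r{i}" for i in range(n)],
        "trimester": [1 + (i % 3) for i in range(n)],
        "meal_type": ["breakfast"] * n,
        "occasion_index": [1] * n,
    })
    return MealMatrix(keys=keys, values=pd.DataFrame(values, columns=groups, dtype=float))
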