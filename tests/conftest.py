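import numpy as np
import pandas as pd
import pytest

from scaleimpute import (
    AmputedDataset,
    CovariateSpec,
    MissingnessPlan,
    ScaleSpec,
    SurveyDataset,
    get_preset,
)


@pytest.fixture(scope="session")
def tiny_scale() -> ScaleSpec:
    return ScaleSpec(name="tiny", n_items=3, response_min=1, response_max=4)


@pytest.fixture(scope="session")
def tiny_covariate_specs() -> tuple[CovariateSpec, ...]:
    return (
        CovariateSpec(
            name="gender", kind="categorical",
            levels=("female", "male"), probabilities=(0.5, 0.5),
            effect_on_trait=0.3,
        ),
        CovariateSpec(name="age", kind="continuous", mean=16.0, sd=2.0),
    )


@pytest.fixture
def tiny_dataset(tiny_scale, tiny_covariate_specs) -> SurveyDataset:
    """Ten respondents, three 1-4 items, hand-set values."""
    items = pd.DataFrame(
        {
            "item_01": [1, 2, 3, 4, 1, 2, 3, 4, 1, 2],
            "item_02": [2, 2, 3, 3, 4, 4, 1, 1, 2, 3],
            "item_03": [3, 1, 4, 2, 3, 1, 4, 2, 3, 1],
        }
    )
    covariates = pd.DataFrame(
        {
            "gender": pd.Categorical(
                ["male", "male", "male", "male", "male",
                 "female", "female", "female", "female", "female"],
                categories=["female", "male"],
            ),
            "age": np.linspace(12.0, 21.0, 10),
        }
    )
    return SurveyDataset(
        ids=np.arange(1, 11), items=items, covariates=covariates, scale=tiny_scale
    )


@pytest.fixture
def tiny_amputed(tiny_dataset) -> AmputedDataset:
    """Hand-set mask: 3 of 30 cells missing, spread over rows 0, 3, 7."""
    mask = np.zeros((10, 3), dtype=bool)
    mask[0, 1] = True
    mask[3, 0] = True
    mask[7, 2] = True
    plan = MissingnessPlan(mechanism="MCAR", target_rate=0.1, seed=1)
    return AmputedDataset(base=tiny_dataset, mask=mask, plan=plan)


@pytest.fixture(scope="session")
def rses_small() -> SurveyDataset:
    """A small RSES-like population shared across tests."""
    return get_preset("rses").generate(n=400, seed=5)


@pytest.fixture(scope="session")
def rses_preset():
    return get_preset("rses")
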