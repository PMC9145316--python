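import numpy as np
import pandas as pd
import pytest

from mixtox.exposure import ConsumptionSurvey, ExposureDistribution, FoodConversionTable


@pytest.fixture
def toy_survey() -> ConsumptionSurvey:
    """One 10-kg individual surveyed two days, eating 100 g of bread on day 1."""
    individuals = pd.DataFrame({
        "individual_id": ["i1"],
        "body_weight_kg": [10.0],
        "age_group": ["1-2"],
    })
    records = pd.DataFrame({
        "individual_id": ["i1"],
        "day": [1],
        "food_code": ["bread"],
        "amount_g": [100.0],
    })
    return ConsumptionSurvey(individuals=individuals, records=records, n_survey_days=2)


@pytest.fixture
def identity_conversion() -> FoodConversionTable:
    return FoodConversionTable(rows=pd.DataFrame({
        "food_code": ["bread"],
        "sample_code": ["wheat_composite"],
        "proportion": [1.0],
    }))


@pytest.fixture
def single_concentration() -> pd.DataFrame:
    return pd.DataFrame({
        "sample_code": ["wheat_composite"],
        "compound": ["CIT"],
        "value_ug_per_kg": [50.0],
        "censored": [False],
        "lod_ug_per_kg": [1.0],
        "loq_ug_per_kg": [2.0],
    })


def make_exposure(values, compound="X", scenario="UB", ids=None) -> ExposureDistribution:
    values = np.asarray(values, dtype=float)
    ids = ids if ids is not None else [f"i{k}" for k in range(len(values))]
    return ExposureDistribution(compound=compound, scenario=scenario,
                                individual_ids=list(ids), values=values)
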