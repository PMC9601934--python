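import numpy as np
import pandas as pd
import pytest

from dynagower import (
    MixedPanel,
    VariableSpec,
    covid_like_spec,
    distance_series,
    generate_panel,
    mixed_type_spec,
)


@pytest.fixture(scope="session")
def toy_panel() -> MixedPanel:
    """4 entities, 2 times, fixed values: 2 quantitative + 2 binary + 1 categorical."""
    variables = [
        VariableSpec("temp", "quantitative", "clinical"),
        VariableSpec("crp", "quantitative", "clinical"),
        VariableSpec("cough", "binary", "symptoms"),
        VariableSpec("fever", "binary", "symptoms"),
        VariableSpec("strain", "categorical", "virology"),
    ]
    entities = ["A", "B", "C", "D"]
    frames = {
        "t1": pd.DataFrame(
            {
                "temp": [36.5, 37.2, 38.9, 36.8],
                "crp": [1.0, 5.5, 12.0, 2.2],
                "cough": [0, 1, 1, 0],
                "fever": [0, 0, 1, 1],
                "strain": ["alpha", "alpha", "delta", "beta"],
            },
            index=entities,
        ),
        "t2": pd.DataFrame(
            {
                "temp": [36.6, 37.9, 39.4, 36.7],
                "crp": [1.4, 7.0, 15.5, 2.0],
                "cough": [0, 1, 1, 1],
                "fever": [0, 1, 1, 0],
                "strain": ["alpha", "delta", "delta", "beta"],
            },
            index=entities,
        ),
    }
    return MixedPanel(entities, ["t1", "t2"], variables, frames)


@pytest.fixture(scope="session")
def mixed_panel() -> MixedPanel:
    return generate_panel(mixed_type_spec(0))


@pytest.fixture(scope="session")
def mixed_series(mixed_panel):
    return distance_series(mixed_panel, seed=0)


@pytest.fixture(scope="session")
def covid_panel() -> MixedPanel:
    return generate_panel(covid_like_spec(0))


@pytest.fixture(scope="session")
def covid_series(covid_panel):
    return distance_series(covid_panel, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
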