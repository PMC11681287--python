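import numpy as np
import pandas as pd
import pytest

from emsdemand import (
    CityTemplate,
    GeneratorConfig,
    generate_registry,
    generate_survey,
)


@pytest.fixture(scope="session")
def default_registry():
    """The full 261-neighborhood default city, seed 11."""
    return generate_registry(CityTemplate(), seed=11)


@pytest.fixture(scope="session")
def default_survey(default_registry):
    """A 1,964-patient survey at the default 9.3% ambulance-use rate."""
    return generate_survey(default_registry, GeneratorConfig(seed=11))


@pytest.fixture
def small_template():
    """A two-municipality toy city with one net outflow municipality."""
    return CityTemplate(
        municipalities=("A", "B"),
        districts_per_municipality=(1, 1),
        neighborhoods_per_district=(3, 2),
        base_population=100_000,
        commuter_net_inflow_by_municipality={"A": 5_000, "B": -2_000},
        municipality_population_weights=(1.0, 1.0),
    )


@pytest.fixture
def small_registry(small_template):
    return generate_registry(small_template, seed=7)


def make_counts(rows):
    """Build a per-neighborhood counts frame from (id, n_total, n_ambulance) tuples."""
    return pd.DataFrame(rows, columns=["neighborhood_id", "n_total", "n_ambulance"])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
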