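import numpy as np
import pandas as pd
import pytest

from flightline.synth import EffortModel, OutlierModel, SimulationConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


def small_config(**overrides) -> SimulationConfig:
    """A fast, reduced-size simulation for structural tests."""
    base = dict(
        seed=7,
        n_species=8,
        years=(2000, 2014),
        records_per_year_range=(18.0, 35.0),
        n_families=3,
        n_subfamilies=4,
        n_genera=8,
        effort=EffortModel(n_observers=40),
        outliers=OutlierModel(p_event=0.05),
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate(small_config())


def toy_records(rows) -> pd.DataFrame:
    """Build a raw records table from (observer, date, county, species, count)."""
    return pd.DataFrame(
        rows, columns=["observer_id", "date", "county", "species", "count"]
    )
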