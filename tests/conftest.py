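import numpy as np
import pytest

from soil2leaf.core import MeasurementTable
from soil2leaf.synthetic import OrchardSimConfig, generate_orchard_dataset


@pytest.fixture
def tiny_table() -> MeasurementTable:
    """2 sites x 2 trees, one element in both compartments."""
    rows = [
        ("S1", "T1", "leaf", "Cd", 0.2, "mg/kg"),
        ("S1", "T2", "leaf", "Cd", 0.4, "mg/kg"),
        ("S2", "T1", "leaf", "Cd", 0.1, "mg/kg"),
        ("S2", "T2", "leaf", "Cd", 0.3, "mg/kg"),
        ("S1", "T0", "soil", "Cd", 0.2, "mg/kg"),
        ("S2", "T0", "soil", "Cd", 0.1, "mg/kg"),
    ]
    return MeasurementTable.from_records(rows)


@pytest.fixture
def small_sim_config() -> OrchardSimConfig:
    return OrchardSimConfig(n_sites=8, trees_per_site=3, seed=11)


@pytest.fixture
def small_orchard(small_sim_config):
    return generate_orchard_dataset(small_sim_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
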