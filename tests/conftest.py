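import numpy as np
import pandas as pd
import pytest

from rxadherence.simulate import SimulationConfig, simulate_population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_population():
    """One mixed-archetype population shared across read-only tests."""
    cfg = SimulationConfig(n_patients=300, seed=42)
    return simulate_population(cfg)


def make_dispensings(rows):
    """rows: (patient_id, iso_date, atc, supply) tuples."""
    return pd.DataFrame(
        rows, columns=["patient_id", "dispense_date", "atc_code", "days_supply"]
    )


def make_patients(rows):
    """rows: (patient_id, birth_iso_date, sex) tuples."""
    return pd.DataFrame(rows, columns=["patient_id", "birth_date", "sex"])
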