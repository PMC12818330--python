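import pandas as pd
import pytest

from rtiepi import PeriodDefinition, ScenarioConfig, default_codelist
from rtiepi.simulate import simulate_registry


@pytest.fixture(scope="session")
def codelist():
    return default_codelist()


@pytest.fixture(scope="session")
def perioddef():
    return PeriodDefinition()


@pytest.fixture(scope="session")
def small_scenario():
    return ScenarioConfig(n_persons=3000, seed=11)


@pytest.fixture(scope="session")
def small_registry(small_scenario):
    """One small simulated registry shared across tests."""
    return simulate_registry(small_scenario)


def make_consultations(rows):
    """Build a consultation frame from (patient_id, date, service, modes, diags)."""
    df = pd.DataFrame(rows, columns=["patient_id", "date", "service_type",
                                     "mode_codes", "diagnosis_codes"])
    df["date"] = pd.to_datetime(df["date"])
    return df


def make_dispensings(rows):
    df = pd.DataFrame(rows, columns=["patient_id", "date", "atc_code"])
    df["date"] = pd.to_datetime(df["date"])
    return df


def make_persons(ids, birth="1980-06-15", sex="female"):
    n = len(ids)
    return pd.DataFrame({
        "patient_id": list(ids),
        "birth_date": pd.to_datetime([birth] * n),
        "sex": [sex] * n,
        "death_date": pd.NaT,
        "residency_start": pd.Timestamp("2018-01-01"),
        "residency_end": pd.NaT,
    })
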