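import numpy as np
import pandas as pd
import pytest

from missig.schema import default_lab_schema
from missig.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def schema():
    return default_lab_schema()


@pytest.fixture(scope="session")
def small_cohort(schema):
    """A 300-patient default-mechanism cohort shared across tests."""
    return generate_cohort(schema, SimulationConfig(n_patients=300), seed=7)


@pytest.fixture(scope="session")
def mnar_day1(small_cohort):
    return small_cohort.day(1)


def make_values(rows, columns=None, ids=None):
    """Small value matrix with None marking absent cells."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in rows]
    )
    columns = columns or [f"T{j}" for j in range(arr.shape[1])]
    ids = ids if ids is not None else list(range(1, arr.shape[0] + 1))
    return pd.DataFrame(arr, index=pd.Index(ids, name="patient_id"), columns=columns)


@pytest.fixture
def toy_values():
    return make_values
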