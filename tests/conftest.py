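import numpy as np
import pandas as pd
import pytest

from cagmicro import AbundanceTable, SimulationConfig, simulate


@pytest.fixture
def tiny_counts() -> AbundanceTable:
    """3 taxa x 4 samples, two paired patients."""
    df = pd.DataFrame(
        [[2, 8, 5, 1], [3, 1, 4, 7], [5, 1, 1, 2]],
        index=["gA", "gB", "gC"],
        columns=["P1_TT", "P1_NT", "P2_TT", "P2_NT"],
    )
    return AbundanceTable(df, kind="counts")


@pytest.fixture
def tiny_meta(tiny_counts) -> pd.DataFrame:
    rows = []
    for s in tiny_counts.samples:
        pid, tis = s.split("_")
        rows.append({"sample_id": s, "patient_id": pid, "tissue": tis})
    return pd.DataFrame(rows).set_index("sample_id")


@pytest.fixture(scope="session")
def default_dataset():
    """One reference-condition synthetic dataset shared across tests."""
    return simulate(SimulationConfig(seed=11))


def make_meta(sample_ids, tissues, patients=None, **clinical) -> pd.DataFrame:
    patients = patients or [s.split("_")[0] for s in sample_ids]
    df = pd.DataFrame({"patient_id": patients, "tissue": tissues},
                      index=pd.Index(sample_ids, name="sample_id"))
    for k, v in clinical.items():
        df[k] = v
    return df
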