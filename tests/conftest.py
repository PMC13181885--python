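import numpy as np
import pandas as pd
import pytest

from milletsoil import table1
from milletsoil.io import SoilSampleTable


@pytest.fixture(scope="session")
def mean_pool_table() -> SoilSampleTable:
    """One row per (treatment, year) at the published group mean."""
    return SoilSampleTable(table1.treatment_mean_table())


@pytest.fixture(scope="session")
def replicate_mean_table() -> SoilSampleTable:
    """24 pseudo-replicates at the group means (3 per treatment-year)."""
    return SoilSampleTable(table1.mean_sample_table())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture()
def toy_soil() -> SoilSampleTable:
    """Small hand-built soil table: 2 treatments x 1 year x 3 reps."""
    rows = []
    vals = {"A": {"pH": [7.0, 7.1, 7.2], "TC": [10.0, 11.0, 12.0],
                  "TN": [1.0, 1.1, 1.2]},
            "B": {"pH": [6.0, 6.1, 6.2], "TC": [20.0, 21.0, 22.0],
                  "TN": [2.0, 2.1, 2.2]}}
    for trt, d in vals.items():
        for rep in range(3):
            rows.append({"treatment": trt, "year": 2022,
                         "replicate": rep + 1,
                         "pH": d["pH"][rep], "TC": d["TC"][rep],
                         "TN": d["TN"][rep]})
    return SoilSampleTable(pd.DataFrame(rows))
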