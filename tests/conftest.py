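import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import msmark as mk

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """Scaled-down study for fast unit tests."""
    return mk.SimConfig(
        cohort1={"control": 10, "RR": 8, "SP": 8, "PP": 6},
        cohort2={"control": 0, "RR": 10, "SP": 10, "PP": 6},
        n_converters=6,
        n_proteins=20,
        n_mirnas=120,
        n_diff_proteins=4,
        n_diff_mirnas=10,
        seed=7,
    )


@pytest.fixture
def toy_npx():
    """Tiny hand-checkable NPX matrix: 4 samples x 3 proteins."""
    values = pd.DataFrame(
        {
            "CD27": [5.0, 6.0, np.nan, 4.5],
            "IL7": [2.0, np.nan, 3.0, 2.5],
            "CXCL13": [7.0, 7.5, 8.0, 6.5],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    below = pd.DataFrame(False, index=values.index, columns=values.columns)
    below.loc["s3", "CD27"] = True
    below.loc["s2", "IL7"] = True
    lod = pd.Series({"CD27": 3.0, "IL7": 1.5, "CXCL13": 4.0})
    run = pd.Series("run1", index=values.index)
    return mk.NpxMatrix(values, lod, run, below)


def make_meta(n, subtypes=("control", "RR"), seed=0, compartment="serum", cohort="I"):
    """Cross-sectional metadata with n samples cycled over the subtypes."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        rows.append({
            "sample_id": f"s{i + 1}",
            "individual_id": f"i{i + 1}",
            "cohort": cohort,
            "compartment": compartment,
            "subtype": subtypes[i % len(subtypes)],
            "age": float(rng.uniform(30, 65)),
            "sex": "M" if rng.random() < 0.5 else "F",
            "sample_date": (pd.Timestamp("2015-01-01") + pd.Timedelta(days=i)).strftime("%Y-%m-%d"),
            "converter": False,
            "conversion_date": None,
            "batch": f"b{1 + int(rng.random() < 0.5)}",
        })
    return mk.validate_meta(pd.DataFrame(rows))
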