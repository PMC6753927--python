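import numpy as np
import pandas as pd
import pytest

from biofilmnet.io import EnvTable, OtuTable


@pytest.fixture
def toy_otu():
    """3 OTUs x 4 samples with simple hand-checkable values."""
    df = pd.DataFrame(
        [[1.0, 0.0, 5.0, 2.0],
         [4.0, 7.0, 5.0, 1.0],
         [4.0, 0.0, 5.0, 3.0]],
        index=["otu1", "otu2", "otu3"],
        columns=["s1", "s2", "s3", "s4"])
    return OtuTable(df, taxonomy={"otu1": "Bacteria;Proteobacteria;g1",
                                  "otu2": "Bacteria;Bacteroidetes;g2",
                                  "otu3": "Bacteria;Proteobacteria;g3"},
                    kind_label="bacteria")


def make_env_frame(n=11, seed=0):
    rng = np.random.default_rng(seed)
    g = np.linspace(0, 1, n)
    df = pd.DataFrame({
        "GD": 2 + 28 * g,
        "GA": 0.7 - 0.6 * g,
        "GS": 0.8 - 0.7 * g,
        "NDVI": -0.05 + 0.5 * g,
        "elevation": 3800 - 1100 * g,
        "pH": 7.6 + 0.8 * g,
        "Cond": 130 + 150 * g,
        "TN": 0.5 + rng.normal(0, 0.1, n),
        "NO3": 0.3 + rng.normal(0, 0.05, n),
        "NH4": 0.08 + rng.normal(0, 0.01, n),
        "TP": 0.05 + rng.normal(0, 0.01, n),
        "SRP": 0.02 + rng.normal(0, 0.004, n),
        "DOC": 1.0 + 2.0 * g,
        "lat": np.full(n, 43.05),
        "lon": 86.75 + 0.01 * np.arange(n),
    }, index=pd.Index([f"S{i+1:02d}" for i in range(n)], name="sample_id"))
    return df


@pytest.fixture
def env11():
    return EnvTable(make_env_frame())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
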