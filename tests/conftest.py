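import numpy as np
import pandas as pd
import pytest

from mbratools import synthetic_data as sd
from mbratools.otu_io import OtuTable, attach_metadata


@pytest.fixture(scope="session")
def small_study():
    """Reduced synthetic study (2 donors x 2 + pool x 2, 100 OTUs)."""
    sim = sd.SimConfig(
        n_donors=2, replicates_per_donor=2, pool_replicates=2,
        n_otus=100, seed=7,
    )
    reactor = sd.ReactorConfig(days=21, depth=2_000)
    return sd.simulate_study(sim, reactor)


@pytest.fixture(scope="session")
def default_study():
    """Full-size default synthetic study (3 donors x 3 + pool x 6)."""
    return sd.simulate_study(sd.SimConfig(seed=11))


@pytest.fixture
def toy_table():
    """Hand-built 4-sample, 3-OTU table with metadata (2 fecal, 2 reactor)."""
    counts = pd.DataFrame(
        [[5, 0, 2], [1, 1, 1], [10, 0, 5], [0, 10, 5]],
        index=pd.Index(["AF", "BF", "A1_d01", "A1_d02"], name="sample"),
        columns=["Otu01", "Otu02", "Otu03"],
    )
    meta = pd.DataFrame(
        {
            "sample": ["AF", "BF", "A1_d01", "A1_d02"],
            "donor": ["A", "B", "A", "A"],
            "vessel": ["AF", "BF", "A1", "A1"],
            "day": [0, 0, 1, 2],
            "sample_class": ["fecal", "fecal", "reactor", "reactor"],
        }
    ).set_index("sample")
    return attach_metadata(OtuTable(counts), meta)


def make_table(rows, otus=None, sample_ids=None):
    rows = np.asarray(rows)
    otus = otus or [f"Otu{i:02d}" for i in range(rows.shape[1])]
    sample_ids = sample_ids or [f"s{i}" for i in range(rows.shape[0])]
    counts = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample"),
                          columns=otus)
    return OtuTable(counts)
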