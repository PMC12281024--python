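import numpy as np
import pandas as pd
import pytest

from dietlink import curation, simulate


@pytest.fixture
def tiny_replicates() -> curation.ReplicateCountTable:
    """Two samples x two replicates over three MOTUs, hand-sized."""
    counts = pd.DataFrame(
        {
            "A_r1": [30, 70, 0],
            "A_r2": [50, 50, 0],
            "B_r1": [10, 10, 80],
            "B_r2": [12, 8, 80],
        },
        index=pd.Index(["m1", "m2", "m3"], name="motu_id"),
    )
    mapping = {"A_r1": "A", "A_r2": "A", "B_r1": "B", "B_r2": "B"}
    return curation.ReplicateCountTable(counts=counts,
                                        replicate_to_sample=mapping)


@pytest.fixture
def tiny_meta() -> curation.MotuMeta:
    return curation.MotuMeta(pd.DataFrame(
        {
            "seq_length": [40, 55, 23],
            "total_reads": [102, 138, 160],
            "best_identity": [1.0, 0.97, 0.95],
            "family": ["Salicaceae", "Salicaceae", "Poaceae"],
            "functional_group": ["deciduous_shrub", "deciduous_shrub",
                                 "grass"],
        },
        index=pd.Index(["m1", "m2", "m3"], name="motu_id"),
    ))


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study, shared across tests (seed 1)."""
    return simulate.generate_study(simulate.default_config(seed=1))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
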