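import numpy as np
import pandas as pd
import pytest

from rercall.counts import CountTable, SampleMeta
from rercall.simulate import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def default_sim():
    """One default-config simulated experiment shared across tests."""
    return simulate_counts(SimConfig(seed=11))


@pytest.fixture(scope="session")
def null_sim():
    """All-biparental (dosage-proportional) experiment: no true imprinting."""
    return simulate_counts(
        SimConfig(
            n_biparental=2000,
            n_meg_like=0,
            n_peg_like=0,
            n_genotype_biased=0,
            n_pav_maternal_te=0,
            n_pav_silent=0,
            seed=13,
        )
    )


@pytest.fixture
def tiny_table():
    """Hand-built 3-feature, 2x2-library contrast with unit library sizes."""
    samples = [
        SampleMeta("AxB_r1", "A", "B", 1, library_size=1_000_000),
        SampleMeta("AxB_r2", "A", "B", 2, library_size=1_000_000),
        SampleMeta("BxA_r1", "B", "A", 1, library_size=1_000_000),
        SampleMeta("BxA_r2", "B", "A", 2, library_size=1_000_000),
    ]
    counts = pd.DataFrame(
        {
            "AxB_r1": [20, 0, 5],
            "AxB_r2": [20, 0, 5],
            "BxA_r1": [10, 12, 5],
            "BxA_r2": [10, 8, 5],
        },
        index=["geneA1", "geneA2", "teB1"],
    )
    features = pd.DataFrame(
        {"genome": ["A", "A", "B"], "kind": ["gene", "gene", "TE"]},
        index=counts.index,
    )
    return CountTable(counts, samples, features)
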