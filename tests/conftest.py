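import numpy as np
import pandas as pd
import pytest

from xdosage import (
    CountMatrix,
    SimulationConfig,
    TissuePlan,
    simulate_expression,
    simulate_genome,
)


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Small, fast configuration: 3 chromosomes, 60 genes."""
    return SimulationConfig(
        n_autosomes=2, n_genes_per_chrom=20, n_windows_per_chrom=12, seed=11
    )


@pytest.fixture(scope="session")
def tiny_genome(tiny_config):
    return simulate_genome(tiny_config)


@pytest.fixture(scope="session")
def tiny_counts(tiny_genome, tiny_config):
    cm, truth = simulate_expression(
        tiny_genome, tiny_config, [TissuePlan("gut", n_replicates=2)]
    )
    return cm, truth


def make_count_matrix(counts: dict, lengths=None, tissue="t") -> CountMatrix:
    """Hand-build a CountMatrix from {sample_id: [counts...]} columns.

    Sample sex is inferred from an 'F' or 'M' in the sample id.
    """
    df = pd.DataFrame(counts)
    df.index = [f"g{i+1}" for i in range(len(df))]
    if lengths is None:
        lengths = [1000] * len(df)
    meta = pd.DataFrame(
        {
            "sample_id": df.columns,
            "tissue": tissue,
            "sex": ["F" if "F" in c else "M" for c in df.columns],
            "replicate": [i + 1 for i in range(len(df.columns))],
        }
    )
    return CountMatrix(
        counts=df.astype(np.int64),
        samples=meta,
        gene_lengths=pd.Series(lengths, index=df.index, dtype=float),
    ).validate()
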