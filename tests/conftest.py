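import numpy as np
import pandas as pd
import pytest

from lymphomap.simulate import SimulationConfig, simulate_experiment
from lymphomap.types import CountMatrix, GroupDesign


@pytest.fixture(scope="session")
def default_experiment():
    """One full synthetic experiment at the default (study-shaped) settings."""
    return simulate_experiment(SimulationConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_count_matrix(values, gene_ids=None, sample_ids=None, biotype="protein_coding"):
    """Small helper: build a CountMatrix from a nested list."""
    arr = np.asarray(values, dtype=np.int64)
    genes = gene_ids or [f"g{i}" for i in range(arr.shape[0])]
    samples = sample_ids or [f"s{j}" for j in range(arr.shape[1])]
    counts = pd.DataFrame(arr, index=pd.Index(genes, name="gene_id"), columns=samples)
    if isinstance(biotype, str):
        bt = pd.Series(biotype, index=counts.index)
    else:
        bt = pd.Series(list(biotype), index=counts.index)
    return CountMatrix(counts, bt)


def make_design(groups_by_sample, control="control", validate=True):
    return GroupDesign(pd.Series(groups_by_sample), control_group=control, validate=validate)
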