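import numpy as np
import pandas as pd
import pytest

from methsplice import stepminer
from methsplice.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact 2-cancer dataset with planted effects, shared across tests."""
    cfg = SimConfig(
        n_cancers=2,
        samples_per_cancer=40,
        n_genes=12,
        cpgs_per_gene=8,
        exons_per_gene=6,
        isoforms_per_gene=2,
        frac_expressed=0.8,
        frac_planted=0.1,
        effect_r=0.8,
        seed=17,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_cohorts(small_dataset):
    labels, _ = stepminer.stratify_matrix(small_dataset.gene_expr)
    return stepminer.cohorts_from_labels(labels)
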