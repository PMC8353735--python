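import numpy as np
import pytest

from scltmg import synthetic as syn
from scltmg.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete synthetic configuration."""
    return syn.SyntheticConfig(
        n_genes=120,
        n_cells_per_group=25,
        frac_deg=0.1,
        effect_size=2.0,
        dropout_alpha=0.3,
        n_modules=2,
        module_size_genes=12,
        module_size_cells=10,
        noise_flip_rate=0.05,
        frac_mito=0.05,
        graph_spec=syn.GraphSpec(n_metabolites=5, n_modules=4, genes_per_module=3),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return syn.generate_counts(small_config)


def make_matrix(counts, conditions=None, mito=None, gene_ids=None):
    counts = np.asarray(counts)
    g, c = counts.shape
    return ExpressionMatrix(
        counts=counts,
        gene_ids=np.array(gene_ids if gene_ids is not None else [f"g{i}" for i in range(g)], dtype=object),
        cell_ids=np.array([f"c{j}" for j in range(c)], dtype=object),
        cell_condition=np.array(conditions if conditions is not None else ["A"] * c, dtype=object),
        is_mito=np.array(mito if mito is not None else [False] * g, dtype=bool),
    )
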