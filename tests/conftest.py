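import numpy as np
import pandas as pd
import pytest

from dyngrn.datatypes import ExpressionMatrix, Interaction, InteractionCatalog
from dyngrn.synth import generate_ground_truth_network, simulate_dataset


def make_expression(values: np.ndarray, timepoints, replicates, gene_ids=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from an array laid out time-major."""
    n_genes = values.shape[0]
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    names, rows = [], []
    for t in timepoints:
        for r in range(1, replicates + 1):
            names.append(f"t{t:g}_r{r}")
            rows.append((f"t{t:g}_r{r}", float(t), r))
    frame = pd.DataFrame(values, index=gene_ids, columns=names)
    design = pd.DataFrame(rows, columns=["sample", "time_hours", "replicate"]).set_index("sample")
    return ExpressionMatrix(frame, design)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x (3 time points x 2 replicates) with simple patterns."""
    rng = np.random.default_rng(7)
    base = np.array(
        [
            [0.0, 0.0, 1.0, 1.0, 2.0, 2.0],  # rising
            [2.0, 2.0, 1.0, 1.0, 0.0, 0.0],  # falling
            [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],  # flat
        ]
    )
    return make_expression(base + 0.01 * rng.standard_normal(base.shape), [0, 1, 3], 2)


@pytest.fixture
def tiny_catalog() -> InteractionCatalog:
    return InteractionCatalog(
        [
            Interaction("Birc2", "Casp6", "inhibition"),
            Interaction("Cldn14", "Cldn5", "binding/association"),
            Interaction("Tnfrsf1a", "Daxx", "activation"),
        ]
    )


@pytest.fixture(scope="session")
def default_truth():
    return generate_ground_truth_network(50, 0.04, 2, seed=7)


@pytest.fixture(scope="session")
def default_dataset(default_truth):
    return simulate_dataset(default_truth, noise_sd=0.1, n_null_genes=150, seed=7)
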