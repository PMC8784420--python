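import numpy as np
import pandas as pd
import pytest

from irlnc.core_io import ExpressionMatrix


def make_matrix(values, gene_ids=None, sample_ids=None, cancer_label="") -> ExpressionMatrix:
    """Build a validated ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"G{i}" for i in range(1, n_genes + 1)]
    sample_ids = sample_ids or [f"S{i}" for i in range(1, n_samples + 1)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), cancer_label
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_bundle():
    """One simulated cancer with the default planting, fixed seed."""
    from irlnc.synthetic import simulate_cancer

    return simulate_cancer(seed=42, cancer_label="TEST")
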