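import numpy as np
import pandas as pd
import pytest

from chromkit import IntensityMatrix, SampleDesign


def make_two_group_design(n_a=3, n_b=3, fraction="proteome"):
    cols = [f"A_{i}" for i in range(1, n_a + 1)] + [f"B_{i}" for i in range(1, n_b + 1)]
    table = pd.DataFrame(
        {
            "fraction": [fraction] * (n_a + n_b),
            "condition": ["A"] * n_a + ["B"] * n_b,
            "replicate": list(range(1, n_a + 1)) + list(range(1, n_b + 1)),
        },
        index=pd.Index(cols, name="sample_id"),
    )
    return SampleDesign(table), cols


def make_matrix(values, columns, protein_ids=None, gene_names=None):
    values = np.asarray(values, dtype=float)
    if protein_ids is None:
        protein_ids = [f"P{i:04d}" for i in range(1, values.shape[0] + 1)]
    frame = pd.DataFrame(values, index=protein_ids, columns=columns)
    genes = None
    if gene_names is not None:
        genes = pd.Series(gene_names, index=protein_ids)
    return IntensityMatrix(frame, scale_tag="log2", gene_names=genes)


@pytest.fixture
def two_group():
    """3-vs-3 design plus a small deterministic matrix."""
    design, cols = make_two_group_design()
    rng = np.random.default_rng(0)
    matrix = make_matrix(rng.normal(20, 1, (10, 6)), cols)
    return matrix, design, cols
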