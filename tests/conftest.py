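"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from spatype import ExpressionDataset, generate_synthetic_pair, normalize_cells


@pytest.fixture
def tiny_dataset():
    """3 cells x 4 genes with coordinates and labels."""
    return ExpressionDataset(
        cells=["c1", "c2", "c3"],
        genes=["ga", "gb", "gc", "gd"],
        counts=np.array([[1.0, 0, 2, 3], [0, 4, 0, 1], [5, 0, 0, 0]]),
        coords=np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]]),
        labels=["A", "B", "A"],
    )


@pytest.fixture(scope="session")
def separable_pair():
    """Highly separable 3-type pair: stage-1 training sanity fixture."""
    return generate_synthetic_pair(
        n_types=3, n_genes=50, n_ref_cells=500, n_srt_cells=400,
        separation=3.0, dropout_rate=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def separable_pair_normalized(separable_pair):
    ref, srt = separable_pair
    return normalize_cells(ref, use_log1p=True), normalize_cells(srt, use_log1p=True)
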