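import numpy as np
import pandas as pd
import pytest

from dcap import (
    OutlierConfig,
    SingleCellDataset,
    SynthConfig,
    build_reference,
    generate_synthetic_sc,
)


def make_sc(counts, subjects, types, gene_ids=None):
    """Hand-build a SingleCellDataset from a counts array and label lists."""
    counts = np.asarray(counts, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(counts.shape[0])]
    meta = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(counts.shape[1])],
            "subject_id": subjects,
            "cell_type": types,
        }
    )
    return SingleCellDataset(counts=counts, gene_ids=gene_ids, cell_meta=meta)


@pytest.fixture
def tiny_sc():
    """3 genes x 4 cells, two subjects, two cell types."""
    counts = np.array(
        [
            [2.0, 1.0, 5.0, 0.0],
            [2.0, 5.0, 3.0, 4.0],
            [0.0, 0.0, 2.0, 6.0],
        ]
    )
    return make_sc(
        counts,
        subjects=["s1", "s1", "s2", "s2"],
        types=["A", "B", "A", "B"],
    )


@pytest.fixture(scope="session")
def synth_sc():
    """A moderate synthetic dataset shared by read-only tests."""
    return generate_synthetic_sc(
        SynthConfig(n_genes=120, n_cell_types=4, n_subjects=3, random_seed=11)
    )


@pytest.fixture(scope="session")
def synth_ref(synth_sc):
    return build_reference(
        synth_sc,
        theta_config=OutlierConfig(rho=1.0),
        size_config=OutlierConfig(rho=1e9),
    )
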