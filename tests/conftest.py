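import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ovimmune.io import CountMatrix, NormalizedMatrix
from ovimmune.simulate import SimConfig, default_config, simulate_counts


def make_counts(dense, genes=None, barcodes=None, **kw) -> CountMatrix:
    """Build a CountMatrix from a dense genes x cells array."""
    dense = np.asarray(dense)
    n_g, n_c = dense.shape
    genes = genes if genes is not None else [f"g{i}" for i in range(n_g)]
    barcodes = barcodes if barcodes is not None else [f"c{i}" for i in range(n_c)]
    return CountMatrix(
        genes=np.asarray(genes, dtype=object),
        barcodes=np.asarray(barcodes, dtype=object),
        counts=sp.csr_matrix(dense),
        **kw,
    )


def make_norm(dense, genes=None, barcodes=None) -> NormalizedMatrix:
    dense = np.asarray(dense, dtype=float)
    n_g, n_c = dense.shape
    genes = genes if genes is not None else [f"g{i}" for i in range(n_g)]
    barcodes = barcodes if barcodes is not None else [f"c{i}" for i in range(n_c)]
    return NormalizedMatrix(
        genes=np.asarray(genes, dtype=object),
        barcodes=np.asarray(barcodes, dtype=object),
        values=sp.csr_matrix(dense),
    )


def two_group_cells(barcodes, n_young, cell_type="T") -> pd.DataFrame:
    """Cell table assigning the first n_young barcodes to the young group."""
    return pd.DataFrame(
        {
            "barcode": list(barcodes),
            "age_group": ["young"] * n_young + ["old"] * (len(barcodes) - n_young),
            "cluster_id": 0,
            "cell_type": cell_type,
        }
    )


def small_pipeline_config(seed: int = 0) -> SimConfig:
    """Scaled-down version of the default study conditions.

    baseline_mean 0.5 on 800 genes keeps detected features per cell
    (~290) inside the default QC window.
    """
    cfg = default_config(seed=seed, n_genes=800)
    return dataclasses.replace(
        cfg,
        cells_per_type_young=(60, 50, 40, 30, 30, 20),
        cells_per_type_old=(50, 45, 40, 30, 30, 80),
        baseline_mean=0.5,
    )


@pytest.fixture(scope="session")
def small_null_sim():
    """One cell type, no plantings: 80 cells per age group, 600 genes."""
    cfg = SimConfig(
        n_cell_types=1,
        cells_per_type_young=(80,),
        cells_per_type_old=(80,),
        n_genes=600,
        baseline_mean=0.5,
        seed=11,
    )
    return (cfg, *simulate_counts(cfg))
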