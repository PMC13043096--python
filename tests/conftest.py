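import anndata as ad
import numpy as np
import pandas as pd
import pytest

import thregulon as tg


def make_adata(X, genes=None, cells=None, counts=None):
    """Dense AnnData helper: X is cells x genes normalized values."""
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    genes = list(genes) if genes is not None else [f"g{i:03d}" for i in range(g)]
    cells = list(cells) if cells is not None else [f"c{i:03d}" for i in range(n)]
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    if counts is not None:
        adata.layers["counts"] = np.asarray(counts)
    return adata


@pytest.fixture(scope="session")
def small_study():
    """A small but complete simulated study with planted signals."""
    cfg = tg.SimConfig(cells_per_stratum=60, n_genes=800, seed=1)
    return tg.generate_study(cfg)


@pytest.fixture(scope="session")
def small_scored(small_study):
    """QC'd + normalized matrix and its NES frame for the small study."""
    adata, report = tg.apply_qc(small_study.adata)
    adata = tg.normalize_log2cpm(adata)
    nes = tg.score_regulons(adata, small_study.regulons)
    return adata, nes, report
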