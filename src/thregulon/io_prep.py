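"""Expression matrix I/O, quality control, and log2-CPM normalization.

The in-memory container is an :class:`anndata.AnnData` with cells as
observations and genes as variables; raw counts live in ``layers["counts"]``
and the normalized matrix in ``X``.  On disk the interchange format is the
10x-style gene x cell Matrix Market triplet (matrix.mtx + genes.tsv +
barcodes.tsv), or a dense gene x cell TSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import io as sio

from .regulons import RegulonSet, DEFAULT_MIN_SIZE

logger = logging.getLogger(__name__)

LR_FAMILIES = ("ECM/integrin", "IL-6", "IGF-1", "Notch/Jagged", "other")


class SchemaError(ValueError):
    """A required file, column or dimension contract is violated."""


@dataclass
class QCThresholds:
    """Inclusive per-cell retention bounds.

    A cell is kept iff umi_min <= total UMI <= umi_max, gene_min <= detected
    genes <= gene_max, and mito_min <= mitochondrial UMI proportion <=
    mito_max.  Mitochondrial genes are identified by name prefix.
    """

    umi_min: int = 100
    umi_max: int = 8000
    gene_min: int = 500
    gene_max: int = 50000
    mito_min: float = 0.01
    mito_max: float = 0.15
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if not (self.umi_min < self.umi_max and self.gene_min < self.gene_max
                and self.mito_min < self.mito_max):
            raise ValueError("QC thresholds require min < max for each pair")
        if not (0 <= self.mito_min <= 1 and 0 <= self.mito_max <= 1):
            raise ValueError("mito bounds must lie in [0, 1]")


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    removed_umi_low: int
    removed_umi_high: int
    removed_genes_low: int
    removed_genes_high: int
    removed_mito_low: int
    removed_mito_high: int
    thresholds: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self) | {"n_removed": self.n_removed}, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _check_unique(labels: pd.Index, what: str) -> None:
    if labels.has_duplicates:
        dups = labels[labels.duplicated()].unique().tolist()[:5]
        raise SchemaError(f"duplicate {what} ids, e.g. {dups}")


def read_expression(path: str | Path, format: str = "mtx_dir") -> ad.AnnData:
    """Read a gene x cell matrix into an AnnData (cells x genes).

    ``mtx_dir`` expects matrix.mtx + genes.tsv + barcodes.tsv in a directory;
    ``dense_tsv`` expects a TSV with gene ids in the first column and cell ids
    as header.  Dimension mismatches between the matrix and its sidecar lists
    raise a :class:`SchemaError` rather than silently truncating.
    """
    path = Path(path)
    if format == "mtx_dir":
        mtx = path / "matrix.mtx"
        genes_f = path / "genes.tsv"
        barcodes_f = path / "barcodes.tsv"
        for f in (mtx, genes_f, barcodes_f):
            if not f.exists():
                raise SchemaError(f"missing file: {f}")
        M = sio.mmread(str(mtx)).tocsr()  # genes x cells
        genes = pd.read_csv(genes_f, sep="\t", header=None)[0].astype(str)
        barcodes = pd.read_csv(barcodes_f, sep="\t", header=None)[0].astype(str)
        if M.shape[0] != len(genes):
            raise SchemaError(f"matrix declares {M.shape[0]} genes but genes.tsv has {len(genes)}")
        if M.shape[1] != len(barcodes):
            raise SchemaError(f"matrix declares {M.shape[1]} cells but barcodes.tsv has {len(barcodes)}")
        counts = M.T.tocsr()
        obs_names, var_names = pd.Index(barcodes), pd.Index(genes)
    elif format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        counts = sp.csr_matrix(df.to_numpy().T)
        obs_names, var_names = pd.Index(df.columns.astype(str)), pd.Index(df.index.astype(str))
    else:
        raise ValueError(f"unknown format {format!r}")
    _check_unique(obs_names, "cell")
    _check_unique(var_names, "gene")
    if counts.nnz and counts.data.min() < 0:
        raise SchemaError("negative counts in matrix")
    adata = ad.AnnData(
        X=None,
        layers={"counts": counts},
        obs=pd.DataFrame(index=obs_names),
        var=pd.DataFrame(index=var_names),
    )
    return adata


def write_expression(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write counts as gene x cell Matrix Market with gene/barcode sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = adata.layers["counts"]
    counts = sp.csr_matrix(counts) if not sp.issparse(counts) else counts
    sio.mmwrite(str(outdir / "matrix.mtx"), counts.T.tocoo())
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    required = {"cell_id", "condition", "timepoint_dpi", "population"}
    missing = required - set(meta.columns)
    if missing:
        raise SchemaError(f"metadata missing columns: {sorted(missing)}")
    if meta["cell_id"].duplicated().any():
        raise SchemaError("metadata has duplicate cell_id rows")
    return meta.set_index("cell_id")


def attach_metadata(adata: ad.AnnData, meta: pd.DataFrame) -> ad.AnnData:
    """Join per-cell metadata into .obs; metadata must cover every cell."""
    missing = adata.obs_names.difference(meta.index)
    if len(missing):
        raise SchemaError(f"{len(missing)} cells missing from metadata, e.g. {list(missing[:3])}")
    for col in meta.columns:
        adata.obs[col] = meta.loc[adata.obs_names, col].to_numpy()
    return adata


def qc_metrics(adata: ad.AnnData, mito_prefix: str = "mt-") -> pd.DataFrame:
    """Per-cell total UMI, detected gene count and mito UMI proportion."""
    counts = adata.layers["counts"]
    counts = sp.csr_matrix(counts) if not sp.issparse(counts) else counts
    total = np.asarray(counts.sum(axis=1)).ravel()
    detected = np.asarray((counts > 0).sum(axis=1)).ravel()
    mito_mask = adata.var_names.str.startswith(mito_prefix)
    mito = np.asarray(counts[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {"total_umi": total, "n_genes": detected, "mito_frac": mito_frac},
        index=adata.obs_names,
    )


def apply_qc(adata: ad.AnnData, thresholds: QCThresholds | None = None) -> tuple[ad.AnnData, QCReport]:
    """Filter low-quality cells by UMI count, gene count and mito proportion.

    Bounds are inclusive.  Cell order is preserved.  Removing every cell is an
    error.  The report counts, per rule, the cells violating that rule (a cell
    may violate several).
    """
    t = thresholds or QCThresholds()
    m = qc_metrics(adata, t.mito_prefix)
    umi_low = m["total_umi"] < t.umi_min
    umi_high = m["total_umi"] > t.umi_max
    genes_low = m["n_genes"] < t.gene_min
    genes_high = m["n_genes"] > t.gene_max
    mito_low = m["mito_frac"] < t.mito_min
    mito_high = m["mito_frac"] > t.mito_max
    keep = ~(umi_low | umi_high | genes_low | genes_high | mito_low | mito_high)
    if not keep.any():
        raise ValueError("empty after QC: every cell violates at least one threshold")
    report = QCReport(
        n_input=adata.n_obs,
        n_retained=int(keep.sum()),
        removed_umi_low=int(umi_low.sum()),
        removed_umi_high=int(umi_high.sum()),
        removed_genes_low=int(genes_low.sum()),
        removed_genes_high=int(genes_high.sum()),
        removed_mito_low=int(mito_low.sum()),
        removed_mito_high=int(mito_high.sum()),
        thresholds=asdict(t),
    )
    logger.info("QC: retained %d / %d cells", report.n_retained, report.n_input)
    return adata[keep.to_numpy()].copy(), report


def normalize_log2cpm(adata: ad.AnnData) -> ad.AnnData:
    """Set X to log2(counts-per-million + 1); zero counts map to zero.

    normalized[c, g] = log2(counts[c, g] / total[c] * 1e6 + 1).  A zero-total
    cell is an error (it should have been removed by QC).
    """
    counts = adata.layers["counts"]
    dense = counts.toarray() if sp.issparse(counts) else np.asarray(counts, dtype=float)
    total = dense.sum(axis=1)
    if np.any(total == 0):
        raise ValueError("cell with zero total UMI: apply QC before normalization")
    cpm = dense / total[:, None] * 1e6
    adata.X = np.log2(cpm + 1.0)
    return adata


def read_regulon_table(path: str | Path, min_size: int = DEFAULT_MIN_SIZE) -> RegulonSet:
    """Read a (tf, target, mode, likelihood) TSV into a RegulonSet."""
    df = pd.read_csv(path, sep="\t")
    return RegulonSet.from_frame(df, min_size=min_size)


def read_lr_table(path: str | Path) -> pd.DataFrame:
    """Read a (ligand, receptor, family) TSV; validates the schema.

    Duplicate (ligand, receptor) rows are an error; unknown extra columns are
    tolerated.  Family labels outside the configured vocabulary are coerced to
    "other" with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"ligand", "receptor"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"LR table missing columns: {sorted(missing)}")
    if "family" not in df.columns:
        df["family"] = "other"
    if df.duplicated(["ligand", "receptor"]).any():
        raise SchemaError("duplicate (ligand, receptor) rows in LR table")
    unknown = ~df["family"].isin(LR_FAMILIES)
    if unknown.any():
        logger.warning("%d LR rows with unknown family coerced to 'other'", int(unknown.sum()))
        df.loc[unknown, "family"] = "other"
    return df[["ligand", "receptor", "family"] + [c for c in df.columns if c not in ("ligand", "receptor", "family")]]
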