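"""Ligand-receptor communication scoring between cell populations.

An edge is a directed (sender population, receiver population, ligand,
receptor) quadruple at one (condition, timepoint).  Its interaction score is
the arithmetic mean of the sender-population mean normalized ligand
expression and the receiver-population mean normalized receptor expression
(a multiplicative variant is available).  Differential communication is the
per-edge delta = perturbed - reference score; deltas are aggregated into
pathway families (ECM/integrin, IL-6, IGF-1, Notch/Jagged, ...) with a
Wilcoxon rank-sum test of member-edge scores between conditions and BH
adjustment across family keys.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .regulons import bh_adjust, wilcoxon_rank_sum

logger = logging.getLogger(__name__)


def _counts_detection(adata, genes: pd.Index) -> pd.DataFrame:
    """Fraction of cells with count > 0 per gene per population."""
    counts = adata.layers["counts"]
    counts = sp.csr_matrix(counts) if not sp.issparse(counts) else counts
    loc = adata.var_names.get_indexer(genes)
    out = {}
    pops = pd.unique(adata.obs["population"])
    for pop in pops:
        mask = (adata.obs["population"] == pop).to_numpy()
        det = np.zeros(len(genes))
        present = loc >= 0
        sub = counts[mask][:, loc[present]]
        det[present] = np.asarray((sub > 0).mean(axis=0)).ravel()
        out[pop] = det
    return pd.DataFrame(out, index=genes)


def filter_expressed(net: pd.DataFrame, adata, min_frac: float = 0.05) -> pd.DataFrame:
    """Keep LR pairs whose ligand and receptor are each detected (count > 0)
    in at least ``min_frac`` of the cells of at least one population."""
    genes = pd.Index(pd.unique(pd.concat([net["ligand"], net["receptor"]])))
    det = _counts_detection(adata, genes)
    max_det = det.max(axis=1)
    ok_gene = max_det >= min_frac if min_frac > 0 else pd.Series(True, index=genes)
    keep = net["ligand"].map(ok_gene).fillna(False) & net["receptor"].map(ok_gene).fillna(False)
    removed = net[~keep]
    if len(removed):
        logger.info("filter_expressed removed %d / %d pairs", len(removed), len(net))
    out = net[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError("LR network empty after expressed-gene filtering")
    return out


def _group_means(adata, genes: pd.Index) -> pd.DataFrame:
    """Mean normalized expression per (population, condition, timepoint) for
    the requested genes; rows are group keys, columns genes."""
    if adata.X is None:
        raise ValueError("normalized layer missing: run normalize_log2cpm first")
    X = adata.X
    X = X.toarray() if hasattr(X, "toarray") else np.asarray(X)
    loc = adata.var_names.get_indexer(genes)
    if (loc < 0).any():
        missing = genes[loc < 0].tolist()[:5]
        logger.warning("%d LR genes absent from matrix (treated as 0), e.g. %s",
                       int((loc < 0).sum()), missing)
    sub = np.zeros((adata.n_obs, len(genes)))
    present = loc >= 0
    sub[:, present] = X[:, loc[present]]
    df = pd.DataFrame(sub, columns=genes, index=adata.obs_names)
    keys = adata.obs[["population", "condition", "timepoint_dpi"]]
    return df.groupby([keys["population"], keys["condition"], keys["timepoint_dpi"]], observed=True).mean()


def score_edges(adata, net: pd.DataFrame, variant: str = "mean") -> pd.DataFrame:
    """Score every directed edge at every (condition, timepoint).

    score = 1/2 (sender-mean ligand + receiver-mean receptor) for the "mean"
    variant, or the product of the two means for "product".  All ordered
    (sender, receiver) population pairs are scored, including sender ==
    receiver.  Strata with zero cells are skipped with a note in the log.
    """
    if variant not in ("mean", "product"):
        raise ValueError(f"unknown edge-score variant {variant!r}")
    genes = pd.Index(pd.unique(pd.concat([net["ligand"], net["receptor"]])))
    gm = _group_means(adata, genes)
    pops = list(pd.unique(adata.obs["population"]))
    groups = adata.obs.groupby(["condition", "timepoint_dpi"], observed=True).size()
    rows = []
    for (cond, tp), _ in groups.items():
        avail = {p for p in pops if (p, cond, tp) in gm.index}
        skipped = set(pops) - avail
        if skipped:
            logger.info("skipping empty strata %s at (%s, %s)", sorted(skipped), cond, tp)
        for sender in pops:
            if sender not in avail:
                continue
            for receiver in pops:
                if receiver not in avail:
                    continue
                lig_means = gm.loc[(sender, cond, tp)]
                rec_means = gm.loc[(receiver, cond, tp)]
                for _, pair in net.iterrows():
                    lm = float(lig_means[pair["ligand"]])
                    rm = float(rec_means[pair["receptor"]])
                    score = 0.5 * (lm + rm) if variant == "mean" else lm * rm
                    rows.append(
                        {"sender": sender, "receiver": receiver,
                         "ligand": pair["ligand"], "receptor": pair["receptor"],
                         "family": pair.get("family", "other"),
                         "condition": cond, "timepoint_dpi": tp, "score": score}
                    )
    return pd.DataFrame(rows)


EDGE_KEYS = ["sender", "receiver", "ligand", "receptor", "family", "timepoint_dpi"]


def differential_edges(
    table: pd.DataFrame,
    contrast_levels: tuple[str, str] = ("CTRL", "HYPO"),
) -> pd.DataFrame:
    """Per-edge condition differential delta = score(alt) - score(ref).

    Returns one row per matched (sender, receiver, pair, timepoint) with both
    condition scores and the delta; unmatched keys are dropped with a note.
    """
    ref, alt = contrast_levels
    wide = table.pivot_table(index=EDGE_KEYS, columns="condition", values="score", observed=True)
    n_unmatched = int(wide[[ref, alt]].isna().any(axis=1).sum()) if {ref, alt} <= set(wide.columns) else len(wide)
    if not {ref, alt} <= set(wide.columns):
        raise ValueError(f"conditions {contrast_levels} not both present in edge table")
    if n_unmatched:
        logger.info("dropping %d edges scored in only one condition", n_unmatched)
    wide = wide.dropna(subset=[ref, alt]).reset_index()
    wide = wide.rename(columns={ref: "score_ref", alt: "score_alt"})
    wide["delta"] = wide["score_alt"] - wide["score_ref"]
    return wide[EDGE_KEYS + ["score_ref", "score_alt", "delta"]]


def aggregate_pathways(
    diff: pd.DataFrame,
    by: tuple[str, ...] = ("sender", "receiver", "family", "timepoint_dpi"),
    min_edges: int = 3,
) -> pd.DataFrame:
    """Aggregate edge differentials into pathway families.

    mean_delta averages member-edge deltas; p is a two-sided Wilcoxon
    rank-sum of member-edge scores between conditions; BH adjustment is
    applied across all keys.  Keys with fewer than ``min_edges`` member edges
    are reported without a p value.
    """
    rows = []
    for key, sub in diff.groupby(list(by), sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(by, key))
        row["n_edges"] = len(sub)
        row["mean_delta"] = float(sub["delta"].mean())
        if len(sub) >= min_edges:
            _, p = wilcoxon_rank_sum(sub["score_ref"].to_numpy(), sub["score_alt"].to_numpy())
            row["p"] = p
        else:
            row["p"] = np.nan
        rows.append(row)
    out = pd.DataFrame.from_records(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def per_cell_pathway_score(
    adata,
    net: pd.DataFrame,
    family: str,
    standardize_by: pd.Series | None = None,
) -> pd.Series:
    """Per-cell pathway module score: mean normalized expression over the
    union of the family's ligand and receptor genes present in the matrix.

    If ``standardize_by`` (a per-cell grouping, e.g. population) is given the
    score is z-scored within each group for downstream modeling.
    """
    sub = net[net["family"] == family]
    if sub.empty:
        raise KeyError(f"family {family!r} not in LR network")
    genes = pd.Index(pd.unique(pd.concat([sub["ligand"], sub["receptor"]])))
    loc = adata.var_names.get_indexer(genes)
    loc = loc[loc >= 0]
    if loc.size == 0:
        raise ValueError(f"family {family!r}: none of its genes are in the matrix")
    if adata.X is None:
        raise ValueError("normalized layer missing: run normalize_log2cpm first")
    X = adata.X
    X = X.toarray() if hasattr(X, "toarray") else np.asarray(X)
    score = pd.Series(X[:, loc].mean(axis=1), index=adata.obs_names, name=family)
    if standardize_by is not None:
        grp = standardize_by.loc[score.index]
        mu = score.groupby(grp, observed=True).transform("mean")
        sd = score.groupby(grp, observed=True).transform("std").replace(0.0, np.nan)
        score = ((score - mu) / sd).fillna(0.0)
        score.name = family
    return score
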