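"""Regulon containers and per-cell activity inference.

A regulon is a transcription factor (TF) together with its target genes, each
annotated with a mode of regulation ``s`` (sign, in [-1, 1]) and a likelihood
weight ``w`` (confidence, in (0, 1]).  Per-cell activity is scored with a
signed, two-tail analytic rank-based enrichment statistic: within each cell,
genes are rank-transformed to standard-normal quantiles and a regulon's
enrichment score is the weighted signed sum of its targets' quantiles,
normalised so that under target exchangeability the score is ~N(0, 1).  This
is the normalized enrichment score (NES) consumed by every downstream stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 5


@dataclass
class Regulon:
    """A TF with signed, weighted targets.

    ``targets`` maps gene -> (mode, likelihood) with mode in [-1, 1] and
    likelihood in (0, 1].
    """

    tf: str
    genes: list[str] = field(default_factory=list)
    modes: np.ndarray = field(default_factory=lambda: np.empty(0))
    likelihoods: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, dtype=float)
        self.likelihoods = np.asarray(self.likelihoods, dtype=float)
        if len(self.genes) != len(set(self.genes)):
            raise ValueError(f"regulon {self.tf!r} has duplicate targets")
        if not (len(self.genes) == self.modes.size == self.likelihoods.size):
            raise ValueError(f"regulon {self.tf!r}: ragged target annotation")
        if np.any(np.abs(self.modes) > 1):
            raise ValueError(f"regulon {self.tf!r}: modes outside [-1, 1]")
        if np.any((self.likelihoods <= 0) | (self.likelihoods > 1)):
            raise ValueError(f"regulon {self.tf!r}: likelihoods outside (0, 1]")

    @property
    def size(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tf": self.tf,
                "target": self.genes,
                "mode": self.modes,
                "likelihood": self.likelihoods,
            }
        )


class RegulonSet:
    """An ordered collection of regulons, keyed by TF name."""

    def __init__(self, regulons: list[Regulon] | None = None):
        self._regulons: dict[str, Regulon] = {}
        for r in regulons or []:
            self.add(r)

    def add(self, regulon: Regulon) -> None:
        if regulon.tf in self._regulons:
            raise ValueError(f"duplicate regulon {regulon.tf!r}")
        self._regulons[regulon.tf] = regulon

    def __len__(self) -> int:
        return len(self._regulons)

    def __contains__(self, tf: str) -> bool:
        return tf in self._regulons

    def __getitem__(self, tf: str) -> Regulon:
        return self._regulons[tf]

    def __iter__(self):
        return iter(self._regulons.values())

    @property
    def tfs(self) -> list[str]:
        return list(self._regulons)

    def to_frame(self) -> pd.DataFrame:
        if not self._regulons:
            return pd.DataFrame(columns=["tf", "target", "mode", "likelihood"])
        return pd.concat([r.to_frame() for r in self], ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, min_size: int = DEFAULT_MIN_SIZE) -> "RegulonSet":
        """Build a RegulonSet from a (tf, target, mode, likelihood) table.

        Modes are clipped to [-1, 1]; missing likelihoods default to 1 and are
        clipped to (0, 1].  Duplicate (tf, target) rows are collapsed keeping
        the max-|likelihood| row.  Regulons smaller than ``min_size`` are
        dropped with a warning.
        """
        required = {"tf", "target", "mode"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"regulon table missing required columns: {sorted(missing)}")
        df = df.copy()
        if "likelihood" not in df.columns:
            df["likelihood"] = 1.0
        df["likelihood"] = df["likelihood"].fillna(1.0).clip(1e-12, 1.0)
        df["mode"] = df["mode"].astype(float).clip(-1.0, 1.0)
        # keep max-|likelihood| row per (tf, target)
        df = (
            df.assign(_absw=df["likelihood"].abs())
            .sort_values("_absw", kind="stable")
            .drop_duplicates(["tf", "target"], keep="last")
            .drop(columns="_absw")
        )
        out = cls()
        for tf, sub in df.groupby("tf", sort=False):
            if len(sub) < min_size:
                logger.warning("dropping regulon %s: %d targets < min_size %d", tf, len(sub), min_size)
                continue
            out.add(
                Regulon(
                    tf=str(tf),
                    genes=sub["target"].astype(str).tolist(),
                    modes=sub["mode"].to_numpy(),
                    likelihoods=sub["likelihood"].to_numpy(),
                )
            )
        return out


def rank_quantiles(X: np.ndarray) -> np.ndarray:
    """Per-cell standard-normal quantiles of expression ranks.

    ``X`` is cells x genes.  Genes are ranked ascending within each cell with
    average ranks for ties; fractional ranks r = rank / (G + 1) are mapped
    through the standard normal inverse CDF.  A cell whose expression is
    constant maps every gene to quantile 0.
    """
    X = np.asarray(X)
    G = X.shape[1]
    ranks = stats.rankdata(X, axis=1, method="average")
    return stats.norm.ppf(ranks / (G + 1.0))


def score_regulons(
    adata,
    regulons: RegulonSet,
    min_size: int = DEFAULT_MIN_SIZE,
) -> pd.DataFrame:
    """Score each regulon in each cell; returns a regulon x cell NES frame.

    For a regulon with targets t (mode s_t, likelihood w_t) and per-cell
    quantiles q_t:

        ES  = sum_t  w_t * s_t * q_t
        NES = (ES - q.mean * sum_t w_t s_t) / sqrt(sum_t w_t^2 * var(q)/v0)

    where var(q) is the variance of the cell's full quantile vector and v0
    the variance of the tie-free quantile grid Phi^-1(i/(G+1)).  For a cell
    without ties the centering term is zero and var(q) = v0, so NES reduces
    to ES / sqrt(sum w^2), which is ~N(0, 1) when the target quantiles are
    exchangeable with the gene background.  Sparse single-cell profiles put a
    large tie block at zero, which would otherwise deflate the null variance;
    the per-cell correction keeps the analytic null calibrated under that
    sparsity.  Regulons retaining fewer than ``min_size`` targets after
    intersecting the matrix's gene universe are excluded with a warning.
    """
    if adata.X is None:
        raise ValueError("normalized layer missing: run normalize_log2cpm first")
    X = adata.X
    X = X.toarray() if hasattr(X, "toarray") else np.asarray(X)
    gene_index = pd.Index(adata.var_names)
    Q = rank_quantiles(X)  # cells x genes
    G = Q.shape[1]
    grid = stats.norm.ppf(np.arange(1, G + 1) / (G + 1.0))
    v0 = float(np.mean(grid**2))
    q_mean = Q.mean(axis=1)
    q_var = Q.var(axis=1)
    tie_scale = np.sqrt(np.where(q_var > 0, q_var / v0, 1.0))

    rows = {}
    for reg in regulons:
        loc = gene_index.get_indexer(reg.genes)
        keep = loc >= 0
        if keep.sum() < min_size:
            logger.warning(
                "regulon %s excluded: %d of %d targets in gene universe (< %d)",
                reg.tf, int(keep.sum()), reg.size, min_size,
            )
            continue
        idx = loc[keep]
        w = reg.likelihoods[keep]
        s = reg.modes[keep]
        es = Q[:, idx] @ (w * s) - q_mean * np.sum(w * s)
        nes = es / (np.sqrt(np.sum(w**2)) * tie_scale)
        rows[reg.tf] = np.where(q_var > 0, nes, 0.0)
    if not rows:
        raise ValueError("no regulon retained enough targets to score")
    nes = pd.DataFrame(rows, index=adata.obs_names).T
    nes.index.name = "regulon"
    return nes


def build_program(regulons: RegulonSet, tf_list: list[str], name: str) -> Regulon:
    """Merge several TF regulons into one program-level meta-regulon.

    The target set is the union; a gene targeted by multiple TFs gets
    mode = sign(sum w*s) and likelihood = mean(w).  Exact cancellation
    (sum w*s == 0) drops the gene.
    """
    missing = [tf for tf in tf_list if tf not in regulons]
    if missing:
        raise KeyError(f"TFs not in regulon set: {missing}")
    ws: dict[str, list[float]] = {}
    wsum: dict[str, float] = {}
    for tf in tf_list:
        reg = regulons[tf]
        for g, s, w in zip(reg.genes, reg.modes, reg.likelihoods):
            ws.setdefault(g, []).append(w)
            wsum[g] = wsum.get(g, 0.0) + w * s
    genes, modes, liks = [], [], []
    for g, wlist in ws.items():
        if wsum[g] == 0.0:
            continue
        genes.append(g)
        modes.append(np.sign(wsum[g]))
        liks.append(float(np.mean(wlist)))
    if not genes:
        raise ValueError(f"program {name!r}: empty target union after cancellation")
    return Regulon(tf=name, genes=genes, modes=np.array(modes), likelihoods=np.array(liks))


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon (Mann-Whitney) rank-sum test.

    Exact for small tie-free samples, tie-corrected normal approximation
    otherwise; two identical samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", use_continuity=False, method="auto")
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (NaNs pass through)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def compare_groups(
    nes: pd.DataFrame,
    meta: pd.DataFrame,
    stratify_by: tuple[str, ...] = ("population", "timepoint_dpi"),
    contrast: str = "condition",
    contrast_levels: tuple[str, str] = ("CTRL", "HYPO"),
    min_cells: int = 3,
) -> pd.DataFrame:
    """Wilcoxon rank-sum contrast of per-cell NES within each stratum.

    Returns one row per (regulon, stratum) with W, p, BH-adjusted fdr (across
    all reported tests) and delta_median = median(alt) - median(ref).  Strata
    with fewer than ``min_cells`` cells on either side are skipped and
    recorded with a note.
    """
    ref, alt = contrast_levels
    meta = meta.loc[nes.columns]
    records = []
    strat_cols = list(stratify_by)
    for key, sub in meta.groupby(strat_cols, sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        mask_ref = sub[contrast] == ref
        mask_alt = sub[contrast] == alt
        note = ""
        if mask_ref.sum() < min_cells or mask_alt.sum() < min_cells:
            note = f"skipped: <{min_cells} cells per side"
        for regulon in nes.index:
            row = dict(zip(strat_cols, key))
            row["regulon"] = regulon
            if note:
                row.update(W=np.nan, p=np.nan, delta_median=np.nan, note=note)
            else:
                a = nes.loc[regulon, sub.index[mask_ref]].to_numpy(dtype=float)
                b = nes.loc[regulon, sub.index[mask_alt]].to_numpy(dtype=float)
                W, p = wilcoxon_rank_sum(a, b)
                row.update(
                    W=W, p=p,
                    delta_median=float(np.median(b) - np.median(a)),
                    note="",
                )
            row["n_ref"] = int(mask_ref.sum())
            row["n_alt"] = int(mask_alt.sum())
            records.append(row)
    out = pd.DataFrame.from_records(records)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    cols = ["regulon", *strat_cols, "n_ref", "n_alt", "W", "p", "fdr", "delta_median", "note"]
    return out[cols]


def regulon_concordance(
    nes_a: pd.DataFrame,
    nes_b: pd.DataFrame,
    meta: pd.DataFrame,
    stratify_by: tuple[str, ...] = ("population", "timepoint_dpi"),
    contrast: str = "condition",
    contrast_levels: tuple[str, str] = ("CTRL", "HYPO"),
    fdr_gate: float | None = 0.05,
) -> tuple[float, pd.DataFrame]:
    """Cross-resource concordance of condition contrasts.

    Both NES matrices are contrasted with :func:`compare_groups`; concordance
    is the fraction of (regulon, stratum) contrasts whose delta_median signs
    agree, among contrasts passing ``fdr_gate`` in at least one resource.  If
    no contrast passes the gate (or the gate is None) all testable contrasts
    are used.  Returns (proportion, merged contingency table).
    """
    shared = nes_a.index.intersection(nes_b.index)
    if shared.empty:
        raise ValueError("no shared regulon labels between resources")
    if not nes_a.columns.equals(nes_b.columns):
        raise ValueError("cell sets differ between resources")
    keys = ["regulon", *stratify_by]
    ca = compare_groups(nes_a.loc[shared], meta, stratify_by, contrast, contrast_levels)
    cb = compare_groups(nes_b.loc[shared], meta, stratify_by, contrast, contrast_levels)
    merged = ca.merge(cb, on=keys, suffixes=("_a", "_b"))
    merged = merged.dropna(subset=["delta_median_a", "delta_median_b"])
    if merged.empty:
        raise ValueError("no testable contrasts shared between resources")
    gated = merged
    if fdr_gate is not None:
        sel = (merged["fdr_a"] < fdr_gate) | (merged["fdr_b"] < fdr_gate)
        if sel.any():
            gated = merged[sel]
    agree = np.sign(gated["delta_median_a"]) == np.sign(gated["delta_median_b"])
    gated = gated.assign(agree=agree.to_numpy())
    return float(agree.mean()), gated


def correlate_programs(
    nes: pd.DataFrame,
    x: str,
    y: str,
    meta: pd.DataFrame,
    stratify_by: tuple[str, ...] = ("population",),
) -> pd.DataFrame:
    """Cell-wise Spearman correlation between two NES rows within strata.

    A stratum where either row is constant has undefined rho and is reported
    as missing with a note.
    """
    for label in (x, y):
        if label not in nes.index:
            raise KeyError(f"row {label!r} not in NES matrix")
    meta = meta.loc[nes.columns]
    strat_cols = list(stratify_by)
    records = []
    for key, sub in meta.groupby(strat_cols, sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        a = nes.loc[x, sub.index].to_numpy(dtype=float)
        b = nes.loc[y, sub.index].to_numpy(dtype=float)
        row = dict(zip(strat_cols, key))
        row["n"] = len(sub)
        if np.all(a == a[0]) or np.all(b == b[0]):
            row.update(spearman_rho=np.nan, p=np.nan, note="constant row in stratum")
        else:
            rho, p = stats.spearmanr(a, b)
            row.update(spearman_rho=float(rho), p=float(p), note="")
        records.append(row)
    return pd.DataFrame.from_records(records)
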