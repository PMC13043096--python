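"""Direct (regulon-driven) versus indirect (paracrine) decomposition.

Per (population, phase) stratum, a program's per-cell NES is regressed on
the thyroid-receptor regulon NES (the direct, nuclear predictor) and the
ligand-receptor pathway module scores (the indirect, paracrine predictors),
all z-scored within the stratum so the coefficients are standardized betas.
Phases pool the regeneration timepoints: early = 0-5 dpi, late = 14 dpi.
Each beta is then summarized qualitatively (activation / repression / weak /
none) from its magnitude and BH-adjusted significance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .regulons import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_PHASES: dict[str, tuple[float, ...]] = {"early": (0.0, 5.0), "late": (14.0,)}


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def fit_decomposition(
    nes: pd.DataFrame,
    pathway_scores: pd.DataFrame,
    meta: pd.DataFrame,
    program: str,
    thr: str = "Thra",
    phases: dict[str, tuple[float, ...]] | None = None,
    min_cells: int = 30,
) -> pd.DataFrame:
    """Standardized OLS of program NES on THR NES and pathway scores.

    Returns one row per (population, program, phase, predictor) with the
    standardized beta, its standard error and two-sided p value; ``fdr`` is
    BH-adjusted across all emitted coefficients.  Strata with fewer than
    ``min_cells`` cells are skipped; a rank-deficient design is fitted with
    the pseudo-inverse and flagged.
    """
    phases = phases or DEFAULT_PHASES
    for label in (program, thr):
        if label not in nes.index:
            raise KeyError(f"row {label!r} not in NES matrix")
    meta = meta.loc[nes.columns]
    pathway_scores = pathway_scores.loc[nes.columns]
    predictors = [thr, *pathway_scores.columns]
    rows = []
    for pop in pd.unique(meta["population"]):
        for phase, tps in phases.items():
            sel = (meta["population"] == pop) & meta["timepoint_dpi"].isin(tps)
            n = int(sel.sum())
            if n < min_cells:
                logger.warning("skipping %s/%s: %d cells < %d", pop, phase, n, min_cells)
                continue
            cells = meta.index[sel]
            y = _zscore(nes.loc[program, cells].to_numpy(dtype=float))
            Xcols = [_zscore(nes.loc[thr, cells].to_numpy(dtype=float))]
            Xcols += [_zscore(pathway_scores.loc[cells, c].to_numpy(dtype=float))
                      for c in pathway_scores.columns]
            X = np.column_stack([np.ones(n), *Xcols])
            rank = np.linalg.matrix_rank(X)
            flagged = rank < X.shape[1]
            if flagged:
                logger.warning("rank-deficient design in %s/%s (rank %d < %d): pseudo-inverse fit",
                               pop, phase, rank, X.shape[1])
            XtX_pinv = np.linalg.pinv(X.T @ X)
            beta = XtX_pinv @ X.T @ y
            resid = y - X @ beta
            df = n - rank
            sigma2 = float(resid @ resid) / df if df > 0 else np.nan
            se = np.sqrt(np.maximum(np.diag(XtX_pinv), 0) * sigma2)
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = beta / se
            pvals = 2 * stats.t.sf(np.abs(tstat), df) if df > 0 else np.full_like(beta, np.nan)
            for j, pred in enumerate(predictors, start=1):
                rows.append(
                    {"population": pop, "program": program, "phase": phase,
                     "predictor": pred, "beta": float(beta[j]), "se": float(se[j]),
                     "p": float(pvals[j]), "n": n, "rank_deficient": flagged}
                )
    out = pd.DataFrame.from_records(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def categorize_betas(rows: pd.DataFrame, tau_strong: float = 0.1, alpha: float = 0.05) -> pd.DataFrame:
    """Qualitative category per coefficient.

    activation: beta >= tau_strong and fdr < alpha; repression: beta <=
    -tau_strong and fdr < alpha; weak: fdr < alpha but |beta| < tau_strong;
    none otherwise.
    """
    if "fdr" not in rows.columns:
        raise ValueError("fdr column required: run fit_decomposition first")
    out = rows.copy()

    def cat(r):
        if not np.isfinite(r["fdr"]) or r["fdr"] >= alpha:
            return "none"
        if r["beta"] >= tau_strong:
            return "activation"
        if r["beta"] <= -tau_strong:
            return "repression"
        return "weak"

    out["category"] = out.apply(cat, axis=1)
    return out


def decomposition_heatmap(rows: pd.DataFrame) -> pd.DataFrame:
    """Categorical matrix (population x predictor) per (program, phase),
    suitable for a tile heatmap."""
    if "category" not in rows.columns:
        raise ValueError("run categorize_betas first")
    return rows.pivot_table(
        index=["program", "phase", "population"], columns="predictor",
        values="category", aggfunc="first", observed=True,
    )
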