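"""Temporal trajectory modeling of per-cell regulon activity.

For each (regulon, population) stratum, per-cell NES values are regressed on
time with a natural cubic regression spline basis (k basis functions, knots
at quantiles of the observed timepoints — the "cr" construction).  A shared
model (one smooth plus a condition offset) is compared to a full model (one
smooth per condition) by a nested ANOVA F test.  With three sampled
timepoints and k=3 the smooth is saturated — the full model interpolates the
(condition, timepoint) stratum means — and the rank-deficient designs that
result are handled by rank-revealing least squares.  Stability of stratum
means is quantified by a within-stratum bootstrap of cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from .regulons import bh_adjust

logger = logging.getLogger(__name__)


def cr_basis(t: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Cardinal natural-cubic-spline basis: column j is the natural cubic
    spline interpolating the j-th indicator over the knots."""
    t = np.asarray(t, dtype=float)
    knots = np.asarray(knots, dtype=float)
    B = np.empty((t.size, knots.size))
    for j in range(knots.size):
        e = np.zeros(knots.size)
        e[j] = 1.0
        B[:, j] = CubicSpline(knots, e, bc_type="natural")(t)
    return B


def _spline_knots(times: np.ndarray, k: int) -> np.ndarray:
    uniq = np.unique(times)
    if uniq.size < 2:
        raise ValueError("need >= 2 distinct timepoints for a smooth")
    k_eff = min(k, uniq.size)
    return np.unique(np.quantile(uniq, np.linspace(0, 1, k_eff)))


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least squares via pinv; returns (beta, RSS, rank)."""
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return beta, rss, int(rank)


@dataclass
class SmoothFitPair:
    """A shared-vs-condition-specific smooth comparison for one stratum."""

    regulon: str
    population: str
    k: int
    knots: np.ndarray
    contrast_levels: tuple[str, str]
    fitted: pd.DataFrame            # condition, timepoint_dpi, fit, ci_lo, ci_hi, n
    rss_shared: float
    rss_full: float
    df_resid_shared: int
    df_resid_full: int
    rank_shared: int
    rank_full: int
    F: float = np.nan
    p: float = np.nan
    fdr: float = np.nan
    note: str = ""
    coef_shared: np.ndarray = field(default_factory=lambda: np.empty(0))
    coef_full: np.ndarray = field(default_factory=lambda: np.empty(0))


def _design(B: np.ndarray, cond_ind: np.ndarray, full: bool) -> np.ndarray:
    n = B.shape[0]
    cols = [np.ones(n), cond_ind.astype(float)]
    cols.extend(B.T)
    if full:
        cols.extend((B * cond_ind[:, None]).T)
    return np.column_stack(cols)


def fit_trajectory(
    nes: pd.DataFrame,
    meta: pd.DataFrame,
    regulon: str,
    population: str,
    k: int = 3,
    contrast: str = "condition",
    contrast_levels: tuple[str, str] = ("CTRL", "HYPO"),
) -> SmoothFitPair:
    """Fit the shared and condition-specific smooths for one stratum.

    Shared model: NES ~ condition + s(time; k).  Full model adds a separate
    smooth per condition.  Fitted means and 95% CIs at each observed
    (condition, timepoint) come from the coefficient covariance under
    homoskedastic normal errors.  A condition observed at a single timepoint
    forces a fallback to the shared fit (noted).
    """
    if regulon not in nes.index:
        raise KeyError(f"regulon {regulon!r} not in NES matrix")
    meta = meta.loc[nes.columns]
    sel = meta["population"] == population
    if not sel.any():
        raise ValueError(f"no cells in population {population!r}")
    sub = meta[sel]
    y = nes.loc[regulon, sub.index].to_numpy(dtype=float)
    t = sub["timepoint_dpi"].to_numpy(dtype=float)
    cond = sub[contrast].to_numpy()
    ref, alt = contrast_levels
    cond_ind = (cond == alt).astype(float)

    for level in contrast_levels:
        if np.unique(t[cond == level]).size < 2:
            note = f"condition {level} observed at <2 timepoints: full model falls back to shared"
            break
    else:
        note = ""

    knots = _spline_knots(t, k)
    B = cr_basis(t, knots)
    Xs = _design(B, cond_ind, full=False)
    Xf = Xs if note else _design(B, cond_ind, full=True)

    beta_s, rss_s, rank_s = _ols(Xs, y)
    beta_f, rss_f, rank_f = _ols(Xf, y)
    rss_f = min(rss_f, rss_s)  # numerical guard: full nests shared
    n = y.size
    df_s, df_f = n - rank_s, n - rank_f

    # fitted means + CI at each observed (condition, timepoint)
    sigma2 = rss_f / df_f if df_f > 0 else np.nan
    XtX_pinv = np.linalg.pinv(Xf.T @ Xf)
    rows = []
    for level, ind in zip(contrast_levels, (0.0, 1.0)):
        tps = np.unique(t[cond == (level)])
        if tps.size == 0:
            continue
        B0 = cr_basis(tps, knots)
        X0 = _design(B0, np.full(tps.size, ind), full=not note)
        fit = X0 @ beta_f
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X0, XtX_pinv, X0), 0) * sigma2)
        tcrit = stats.t.ppf(0.975, df_f) if df_f > 0 else np.nan
        for tp, f, s_ in zip(tps, fit, se):
            rows.append(
                {"condition": level, "timepoint_dpi": float(tp), "fit": float(f),
                 "ci_lo": float(f - tcrit * s_), "ci_hi": float(f + tcrit * s_),
                 "n": int(np.sum((cond == level) & (t == tp)))}
            )
    fit_pair = SmoothFitPair(
        regulon=regulon, population=population, k=k, knots=knots,
        contrast_levels=contrast_levels, fitted=pd.DataFrame(rows),
        rss_shared=rss_s, rss_full=rss_f,
        df_resid_shared=df_s, df_resid_full=df_f,
        rank_shared=rank_s, rank_full=rank_f,
        note=note, coef_shared=beta_s, coef_full=beta_f,
    )
    F, p = compare_smooths_anova(fit_pair)
    fit_pair.F, fit_pair.p = F, p
    return fit_pair


def compare_smooths_anova(fit: SmoothFitPair) -> tuple[float, float]:
    """Nested-model F test of condition-specific versus shared smooths.

    F = [(RSS_shared - RSS_full)/ddf] / [RSS_full/df_resid_full]; p from the
    F distribution.  ddf = 0 (fallback fits) gives (nan, nan).
    """
    ddf = fit.rank_full - fit.rank_shared
    if ddf <= 0 or fit.df_resid_full <= 0:
        return np.nan, np.nan
    num = (fit.rss_shared - fit.rss_full) / ddf
    den = fit.rss_full / fit.df_resid_full
    if den == 0:
        return np.nan, np.nan
    F = max(num / den, 0.0)
    p = float(stats.f.sf(F, ddf, fit.df_resid_full))
    return float(F), p


def fit_all_trajectories(
    nes: pd.DataFrame,
    meta: pd.DataFrame,
    k: int = 3,
    contrast: str = "condition",
    contrast_levels: tuple[str, str] = ("CTRL", "HYPO"),
) -> tuple[pd.DataFrame, list[SmoothFitPair]]:
    """Fit every (regulon, population) stratum; BH-adjust the ANOVA p values
    across strata.  Returns a summary table and the fit objects."""
    meta = meta.loc[nes.columns]
    fits, rows = [], []
    for regulon in nes.index:
        for population in pd.unique(meta["population"]):
            try:
                fp = fit_trajectory(nes, meta, regulon, population, k, contrast, contrast_levels)
            except ValueError as exc:
                logger.warning("skipping %s/%s: %s", regulon, population, exc)
                continue
            fits.append(fp)
            rows.append(
                {"regulon": regulon, "population": population, "F": fp.F, "p": fp.p,
                 "rss_shared": fp.rss_shared, "rss_full": fp.rss_full, "note": fp.note}
            )
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = bh_adjust(table["p"].to_numpy())
        for fp, fdr in zip(fits, table["fdr"]):
            fp.fdr = float(fdr) if np.isfinite(fdr) else np.nan
    return table, fits


def bootstrap_nes(
    nes: pd.DataFrame,
    meta: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    stratify_by: tuple[str, ...] = ("population", "condition", "timepoint_dpi"),
) -> pd.DataFrame:
    """Percentile bootstrap of the stratum mean NES.

    Cells are resampled with replacement within each stratum; the 2.5%/97.5%
    percentiles of the resampled means give the CI.  A single-cell stratum
    yields a degenerate CI equal to the observed value and is flagged.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    meta = meta.loc[nes.columns]
    strat_cols = list(stratify_by)
    records = []
    for key, sub in meta.groupby(strat_cols, sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        vals = nes.loc[:, sub.index].to_numpy(dtype=float)  # regulons x n
        n = vals.shape[1]
        idx = rng.integers(0, n, size=(B, n))
        for r, regulon in enumerate(nes.index):
            v = vals[r]
            boot_means = v[idx].mean(axis=1)
            lo, hi = np.percentile(boot_means, [2.5, 97.5])
            records.append(
                dict(zip(strat_cols, key))
                | {"regulon": regulon, "n": n, "mean": float(v.mean()),
                   "ci_lo": float(lo), "ci_hi": float(hi),
                   "degenerate": bool(n == 1)}
            )
    return pd.DataFrame.from_records(records)
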