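"""End-to-end pipeline orchestration from a single plain-text config.

Stages run in order qc -> normalize -> score -> trajectory -> lr ->
decompose; each stage writes its outputs under a stage-named subdirectory of
the output directory and the run ends with a machine-readable
run_summary.json recording versions, the config hash, the seed and per-stage
row counts.  Stages communicate only through their written interface files'
in-memory equivalents.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io_prep, regulons as reg, trajectory as traj, communication as comm, decomposition as dec

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


DEFAULT_PROGRAMS = {"Myc_E2f": ["Myc", "E2f1"], "Foxo_Ppargc1a": ["Foxo1", "Ppargc1a"]}


@dataclass
class PipelineConfig:
    matrix: str
    metadata: str
    regulons: str
    lr_pairs: str
    out: str
    qc: dict = field(default_factory=dict)
    regulon_min_size: int = 5
    k: int = 3
    bootstrap_B: int = 1000
    seed: int | None = None
    min_frac: float = 0.05
    edge_score_variant: str = "mean"
    tau_strong: float = 0.1
    alpha: float = 0.05
    thr: str = "Thra"
    programs: dict = field(default_factory=lambda: dict(DEFAULT_PROGRAMS))
    phases: dict = field(default_factory=lambda: {"early": [0.0, 5.0], "late": [14.0]})
    contrast_levels: tuple[str, str] = ("CTRL", "HYPO")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        paths = raw.pop("paths", {})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            cfg = cls(**paths, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        if isinstance(cfg.contrast_levels, list):
            cfg.contrast_levels = tuple(cfg.contrast_levels)
        return cfg

    def validate(self) -> None:
        for name in ("matrix", "metadata", "regulons", "lr_pairs"):
            p = getattr(self, name, None)
            if not p:
                raise ConfigError(f"missing required path: {name}")
            if not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        if self.seed is None and self.bootstrap_B > 0:
            raise ConfigError("seed is mandatory when bootstrapping is enabled")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run summary."""
    cfg.validate()
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__, "config_hash": cfg.digest(), "seed": cfg.seed,
        "config": asdict(cfg), "stages": {},
    }

    def stage_dir(name: str) -> Path:
        d = out / name
        d.mkdir(exist_ok=True)
        return d

    # qc
    adata = io_prep.read_expression(cfg.matrix, format="mtx_dir")
    meta = io_prep.read_metadata(cfg.metadata)
    io_prep.attach_metadata(adata, meta)
    thresholds = io_prep.QCThresholds(**cfg.qc) if cfg.qc else io_prep.QCThresholds()
    adata, report = io_prep.apply_qc(adata, thresholds)
    report.to_json(stage_dir("qc") / "qc_report.json")
    logger.info("[qc] cells in=%d out=%d", report.n_input, report.n_retained)
    summary["stages"]["qc"] = {"cells_in": report.n_input, "cells_out": report.n_retained}

    # normalize
    adata = io_prep.normalize_log2cpm(adata)
    summary["stages"]["normalize"] = {"cells": adata.n_obs, "genes": adata.n_vars}

    # score
    regset = io_prep.read_regulon_table(cfg.regulons, min_size=cfg.regulon_min_size)
    for name, tfs in cfg.programs.items():
        regset.add(reg.build_program(regset, list(tfs), name))
    nes = reg.score_regulons(adata, regset, min_size=cfg.regulon_min_size)
    sdir = stage_dir("score")
    nes.to_csv(sdir / "nes.tsv", sep="\t")
    meta_qc = adata.obs[["sample_id", "condition", "timepoint_dpi", "population"]] \
        if "sample_id" in adata.obs else adata.obs[["condition", "timepoint_dpi", "population"]]
    groups = reg.compare_groups(nes, meta_qc, contrast_levels=cfg.contrast_levels)
    groups.to_csv(sdir / "group_contrasts.tsv", sep="\t", index=False)
    logger.info("[score] regulons scored=%d tests=%d", nes.shape[0], len(groups))
    summary["stages"]["score"] = {"regulons": int(nes.shape[0]), "contrasts": int(len(groups))}

    # trajectory
    tdir = stage_dir("trajectory")
    ttab, fits = traj.fit_all_trajectories(nes, meta_qc, k=cfg.k, contrast_levels=cfg.contrast_levels)
    ttab.to_csv(tdir / "anova.tsv", sep="\t", index=False)
    fitted = pd.concat(
        [fp.fitted.assign(regulon=fp.regulon, population=fp.population) for fp in fits],
        ignore_index=True,
    ) if fits else pd.DataFrame()
    fitted.to_csv(tdir / "fitted_curves.tsv", sep="\t", index=False)
    boot = traj.bootstrap_nes(nes, meta_qc, B=cfg.bootstrap_B, seed=int(cfg.seed or 0))
    boot.to_csv(tdir / "bootstrap_ci.tsv", sep="\t", index=False)
    logger.info("[trajectory] strata fitted=%d bootstrap rows=%d", len(ttab), len(boot))
    summary["stages"]["trajectory"] = {"strata": int(len(ttab)), "bootstrap_rows": int(len(boot))}

    # lr
    ldir = stage_dir("lr")
    net = io_prep.read_lr_table(cfg.lr_pairs)
    net = comm.filter_expressed(net, adata, min_frac=cfg.min_frac)
    edges = comm.score_edges(adata, net, variant=cfg.edge_score_variant)
    diff = comm.differential_edges(edges, contrast_levels=cfg.contrast_levels)
    fams = comm.aggregate_pathways(diff)
    edges.to_csv(ldir / "edge_scores.tsv", sep="\t", index=False)
    diff.to_csv(ldir / "edge_deltas.tsv", sep="\t", index=False)
    fams.to_csv(ldir / "pathway_aggregates.tsv", sep="\t", index=False)
    logger.info("[lr] pairs=%d edges=%d family keys=%d", len(net), len(edges), len(fams))
    summary["stages"]["lr"] = {"pairs": int(len(net)), "edges": int(len(edges)), "family_keys": int(len(fams))}

    # decompose
    ddir = stage_dir("decompose")
    families = [f for f in pd.unique(net["family"]) if f != "other"]
    pathway_scores = pd.DataFrame(
        {f: comm.per_cell_pathway_score(adata, net, f, standardize_by=adata.obs["population"])
         for f in families}
    )
    phases = {k: tuple(float(t) for t in v) for k, v in cfg.phases.items()}
    parts = []
    for prog in cfg.programs:
        parts.append(dec.fit_decomposition(
            nes, pathway_scores, meta_qc, program=prog, thr=cfg.thr, phases=phases))
    rows = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    if len(rows):
        rows["fdr"] = reg.bh_adjust(rows["p"].to_numpy())
        rows = dec.categorize_betas(rows, tau_strong=cfg.tau_strong, alpha=cfg.alpha)
        dec.decomposition_heatmap(rows).to_csv(ddir / "category_heatmap.tsv", sep="\t")
    rows.to_csv(ddir / "decomposition.tsv", sep="\t", index=False)
    logger.info("[decompose] coefficients=%d", len(rows))
    summary["stages"]["decompose"] = {"coefficients": int(len(rows))}

    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    return summary
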