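"""Synthetic single-cell study generator with planted ground truth.

Emulates the design of the muscle-regeneration study the analysis stack is
built for: two thyroid conditions (euthyroid CTRL, hypothyroid HYPO) sampled
at 0, 5 and 14 days post-injury (dpi) across four cell populations
(myogenic, FAP, myeloid, lymphoid).  Counts are negative binomial with a
per-cell lognormal library-size factor; planted transcription-factor
activity shifts the log-mean of a TF's targets by ``a * s * w *
effect_size`` (activity x mode x likelihood x global effect size), and
planted ligand-receptor signals shift ligand genes in the sender population
and receptor genes in the receiver.  A configurable fraction of cells is
forced to violate a quality-control rule by explicit overrides so expected
filter counts are exact.  Everything planted is emitted as a GroundTruth
object for use as a test oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_prep import write_expression
from .regulons import Regulon, RegulonSet

Stratum = tuple[str, str, float]  # (population, condition, timepoint)


@dataclass
class TFSpec:
    """A planted transcription factor: target count, repression fraction and
    an activity value per (population, condition, timepoint) stratum
    (missing strata default to ``default_activity``)."""

    name: str
    n_targets: int = 25
    repressed_fraction: float = 0.3
    activity: dict[Stratum, float] = field(default_factory=dict)
    default_activity: float = 0.0

    def a(self, pop: str, cond: str, tp: float) -> float:
        return self.activity.get((pop, cond, tp), self.default_activity)


@dataclass
class LRSpec:
    """A planted ligand-receptor signal: the named ligand gene is shifted in
    the sender population and the receptor gene in the receiver, by
    ``strength`` (natural-log units of gene mean) per (condition, timepoint)."""

    ligand: str
    receptor: str
    sender: str
    receiver: str
    family: str = "other"
    strength: dict[tuple[str, float], float] = field(default_factory=dict)
    default_strength: float = 0.0

    def s(self, cond: str, tp: float) -> float:
        return self.strength.get((cond, tp), self.default_strength)


def default_tf_specs() -> list[TFSpec]:
    """Receptor and program regulons with trajectories shaped like the study:
    CTRL thyroid-receptor activity rises at 5 dpi and renormalizes by 14 dpi
    in myogenic cells and FAPs while HYPO is blunted; the proliferative
    program peaks early under CTRL and is inverted (late surge) under HYPO;
    the oxidative program does the opposite."""
    responsive = ("myogenic", "FAP")

    def traj(pops, ctrl, hypo):
        act = {}
        for p in pops:
            for tp, v in ctrl.items():
                act[(p, "CTRL", tp)] = v
            for tp, v in hypo.items():
                act[(p, "HYPO", tp)] = v
        return act

    return [
        TFSpec("Thra", activity=traj(responsive, {0: 0.0, 5: 1.5, 14: 0.3}, {0: 0.0, 5: 0.3, 14: 0.1})),
        TFSpec("Thrb", activity=traj(responsive, {0: 0.0, 5: 1.0, 14: 0.2}, {0: 0.0, 5: 0.8, 14: -0.3})),
        TFSpec("Myc", activity=traj(responsive, {0: 0.2, 5: 1.5, 14: 0.4}, {0: -0.3, 5: 0.2, 14: 1.2})),
        TFSpec("E2f1", activity=traj(responsive, {0: 0.1, 5: 1.3, 14: 0.3}, {0: -0.2, 5: 0.1, 14: 1.0})),
        TFSpec("Foxo1", activity=traj(responsive, {0: 0.2, 5: 0.3, 14: 1.2}, {0: 0.3, 5: 1.2, 14: 0.1})),
        TFSpec("Ppargc1a", activity=traj(responsive, {0: 0.1, 5: 0.2, 14: 1.0}, {0: 0.2, 5: 1.0, 14: 0.0})),
    ]


def default_lr_specs() -> list[LRSpec]:
    """Planted communication in the four pathway families: matrix-integrin
    signaling reduced at baseline but FAP-driven late under HYPO, transient
    IGF-1/IL-6 amplification, and global late Notch/Jagged activation."""
    return [
        LRSpec("Col1a1", "Itgb1", "FAP", "myogenic", "ECM/integrin",
               strength={("CTRL", 0): 0.8, ("HYPO", 0): 0.2, ("HYPO", 14): 1.0}),
        LRSpec("Fn1", "Itgav", "myogenic", "myeloid", "ECM/integrin",
               strength={("HYPO", 5): 0.8}),
        LRSpec("Igf1", "Igf1r", "FAP", "myogenic", "IGF-1",
               strength={("HYPO", 5): 0.8}),
        LRSpec("Il6", "Il6ra", "myeloid", "FAP", "IL-6",
               strength={("HYPO", 5): 0.6, ("HYPO", 14): 0.6}),
        LRSpec("Jag1", "Notch1", "FAP", "myogenic", "Notch/Jagged",
               strength={("HYPO", 14): 0.8}),
        LRSpec("Dll1", "Notch2", "myogenic", "FAP", "Notch/Jagged",
               strength={("HYPO", 14): 0.6}),
    ]


@dataclass
class SimConfig:
    """Study-design and noise parameters of the generator.

    Defaults encode the emulated design: 2 conditions x 3 timepoints x 4
    populations at 600 cells per stratum (2,400 cells per condition-timepoint
    sample).  ``effect_size`` converts one unit of planted TF activity into a
    natural-log shift of a unit-likelihood target's mean; ``dispersion`` is
    the NB shape (inverse overdispersion).  Mitochondrial genes are a
    dedicated low-noise block carrying ``mito_frac`` of each cell's mass so
    the QC proportion is well controlled.
    """

    n_genes: int = 2000
    populations: tuple[str, ...] = ("myogenic", "FAP", "myeloid", "lymphoid")
    conditions: tuple[str, str] = ("CTRL", "HYPO")
    timepoints: tuple[float, ...] = (0, 5, 14)
    cells_per_stratum: int | dict[Stratum, int] = 600
    tf_specs: list[TFSpec] = field(default_factory=default_tf_specs)
    lr_specs: list[LRSpec] = field(default_factory=default_lr_specs)
    n_background_lr_pairs: int = 40
    effect_size: float = 0.35
    dispersion: float = 2.0
    mito_dispersion: float = 10.0
    libsize_lognorm: tuple[float, float] = (math.log(3000.0), 0.15)
    gene_logmean_sd: float = 0.4
    pop_logmean_sd: float = 0.1
    mito_gene_count: int = 20
    mito_prefix: str = "mt-"
    mito_frac: float = 0.06
    qc_fail_fraction: float = 0.05
    planted_beta: pd.DataFrame | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions required (reference, perturbed)")
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise ValueError("timepoints must be strictly increasing")
        if self.n_genes <= 0 or self.mito_gene_count < 0:
            raise ValueError("gene counts must be nonnegative")
        if not (0 <= self.qc_fail_fraction <= 1):
            raise ValueError("qc_fail_fraction must be in [0, 1]")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def n_cells(self, stratum: Stratum) -> int:
        if isinstance(self.cells_per_stratum, dict):
            n = self.cells_per_stratum.get(stratum, 0)
        else:
            n = self.cells_per_stratum
        if n <= 0:
            raise ValueError(f"empty stratum {stratum}: no cells configured")
        return int(n)


@dataclass
class GroundTruth:
    """Everything the generator planted, as oracle tables."""

    tf_activity: pd.DataFrame      # tf, population, condition, timepoint_dpi, a
    edge_strength: pd.DataFrame    # ligand, receptor, sender, receiver, family, condition, timepoint_dpi, strength
    qc_fail_cells: list[str]
    planted_beta: pd.DataFrame     # population, program, phase, predictor, coefficient

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.tf_activity.to_csv(outdir / "tf_activity.tsv", sep="\t", index=False)
        self.edge_strength.to_csv(outdir / "edge_strength.tsv", sep="\t", index=False)
        pd.Series(self.qc_fail_cells, name="cell_id").to_csv(outdir / "qc_fail_cells.tsv", sep="\t", index=False)
        self.planted_beta.to_csv(outdir / "planted_beta.tsv", sep="\t", index=False)


class StudyData(NamedTuple):
    adata: ad.AnnData
    meta: pd.DataFrame
    regulons: RegulonSet
    lr_network: pd.DataFrame
    truth: GroundTruth


def generate_regulon_prior(
    n_tfs: int,
    targets_per_tf: int,
    repressed_fraction: float,
    seed: int,
    gene_universe: list[str] | None = None,
    n_genes: int = 2000,
    tf_names: list[str] | None = None,
    allow_overlap: bool = True,
) -> RegulonSet:
    """Draw a synthetic regulon prior table.

    Each regulon gets ``targets_per_tf`` targets sampled from the gene
    universe; ``floor(repressed_fraction * targets_per_tf)`` of them get mode
    -1 and the rest +1; likelihood weights are uniform on (0, 1].  With
    ``allow_overlap=False`` the target sets are disjoint, which requires a
    large enough universe.
    """
    if targets_per_tf < 1:
        raise ValueError("targets_per_tf must be >= 1")
    if not (0 <= repressed_fraction <= 1):
        raise ValueError("repressed_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    universe = list(gene_universe) if gene_universe is not None else [f"g{i:04d}" for i in range(n_genes)]
    if not allow_overlap and n_tfs * targets_per_tf > len(universe):
        raise ValueError(
            f"cannot draw {n_tfs} disjoint regulons of {targets_per_tf} targets "
            f"from a universe of {len(universe)} genes"
        )
    names = tf_names if tf_names is not None else [f"TF{i + 1}" for i in range(n_tfs)]
    if len(names) != n_tfs:
        raise ValueError("tf_names length must equal n_tfs")
    n_rep = int(math.floor(repressed_fraction * targets_per_tf))
    pool = np.array(universe)
    out = RegulonSet()
    for name in names:
        targets = rng.choice(pool, size=targets_per_tf, replace=False)
        if not allow_overlap:
            pool = np.setdiff1d(pool, targets, assume_unique=False)
        modes = np.ones(targets_per_tf)
        modes[:n_rep] = -1.0
        rng.shuffle(modes)
        likelihoods = 1.0 - rng.random(targets_per_tf)  # uniform on (0, 1]
        out.add(Regulon(tf=name, genes=list(targets), modes=modes, likelihoods=likelihoods))
    return out


def pure_noise_config(
    cells_per_stratum: int = 500,
    n_genes: int = 1000,
    n_tfs: int = 10,
    regulon_size: int = 25,
    seed: int = 0,
    **overrides,
) -> SimConfig:
    """A gene-exchangeable null study: flat baselines, no planted activity.

    Every gene (including the mito block, whose mass fraction is pinned to
    its share of the universe) has the same expected expression, so regulon
    targets are exchangeable with the background and the analytic NES null
    is exact.  This is the configuration under which null calibration of the
    scorer is assessed; with heterogeneous baselines a fixed regulon picks up
    a stable rank-tendency offset that only condition contrasts remove.
    """
    mito_n = overrides.pop("mito_gene_count", 20)
    defaults = dict(
        n_genes=n_genes,
        cells_per_stratum=cells_per_stratum,
        timepoints=(0,),
        gene_logmean_sd=0.0,
        pop_logmean_sd=0.0,
        mito_gene_count=mito_n,
        mito_frac=mito_n / (n_genes + mito_n),
        tf_specs=[TFSpec(f"TF{i + 1}", n_targets=regulon_size) for i in range(n_tfs)],
        lr_specs=[],
        qc_fail_fraction=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def _build_gene_universe(config: SimConfig) -> tuple[list[str], np.ndarray]:
    """Generic genes + mito block + any named LR genes; returns names and a
    boolean mito mask."""
    generic = [f"g{i:04d}" for i in range(config.n_genes)]
    mito = [f"{config.mito_prefix}{i + 1}" for i in range(config.mito_gene_count)]
    named = []
    for lr in config.lr_specs:
        for g in (lr.ligand, lr.receptor):
            if g not in named and g not in generic and g not in mito:
                named.append(g)
    genes = generic + named + mito
    mask = np.zeros(len(genes), dtype=bool)
    mask[len(generic) + len(named):] = True
    return genes, mask


def generate_study(config: SimConfig) -> StudyData:
    """Generate the full synthetic study.

    Returns the counts AnnData (cells x genes, ``layers["counts"]``), the
    per-cell metadata, the regulon prior (covering every planted TF), the
    ligand-receptor network table and the GroundTruth oracle.  The same
    config (including seed) always yields byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    genes, mito_mask = _build_gene_universe(config)
    gene_index = pd.Index(genes)
    n_genes = len(genes)

    # Baseline log-mean per gene, with small population-specific deviations.
    # Named LR genes get a common baseline (the population mean level) so a
    # planted communication shift, not baseline heterogeneity, dominates the
    # between-condition and between-edge differences of their edge scores.
    base_logmean = rng.normal(0.0, config.gene_logmean_sd, size=n_genes)
    named_lr = gene_index.get_indexer(
        [g for lr in config.lr_specs for g in (lr.ligand, lr.receptor)])
    base_logmean[named_lr[named_lr >= 0]] = 0.0
    pop_dev = {
        pop: rng.normal(0.0, config.pop_logmean_sd, size=n_genes)
        for pop in config.populations
    }

    # Regulon prior covering the planted TFs.  Targets are drawn from the
    # full universe (mito block included, so targets stay exchangeable with
    # the ranked background and the analytic null is unbiased); only the
    # named LR genes are excluded so planted signals do not interact.
    lr_genes = {g for lr in config.lr_specs for g in (lr.ligand, lr.receptor)}
    target_pool = [g for g in genes if g not in lr_genes]
    regulons = RegulonSet()
    for spec in config.tf_specs:
        prior = generate_regulon_prior(
            1, spec.n_targets, spec.repressed_fraction,
            seed=int(rng.integers(2**31)), gene_universe=target_pool, tf_names=[spec.name],
        )
        regulons.add(prior[spec.name])

    # LR network: planted pairs plus unplanted background pairs.
    lr_rows = [
        {"ligand": lr.ligand, "receptor": lr.receptor, "family": lr.family}
        for lr in config.lr_specs
    ]
    bg_pool = [g for g, m in zip(genes, mito_mask) if not m and g not in lr_genes]
    for _ in range(config.n_background_lr_pairs):
        lig, rec = rng.choice(bg_pool, size=2, replace=False)
        lr_rows.append({"ligand": str(lig), "receptor": str(rec), "family": "other"})
    lr_network = pd.DataFrame(lr_rows).drop_duplicates(["ligand", "receptor"]).reset_index(drop=True)

    # Per-gene NB shape: mito block is low-noise so the QC proportion stays
    # inside its band for non-overridden cells.
    shape = np.full(n_genes, config.dispersion)
    shape[mito_mask] = config.mito_dispersion

    mu_log, sigma_log = config.libsize_lognorm
    counts_blocks, obs_rows, stratum_probs = [], [], []
    tf_rows, edge_rows = [], []

    for cond in config.conditions:
        for tp in config.timepoints:
            for pop in config.populations:
                stratum = (pop, cond, float(tp))
                n_cells = config.n_cells(stratum)
                logmu = base_logmean + pop_dev[pop]
                logmu = logmu.copy()
                for spec in config.tf_specs:
                    a = spec.a(pop, cond, tp)
                    if a != 0.0:
                        reg = regulons[spec.name]
                        idx = gene_index.get_indexer(reg.genes)
                        logmu[idx] += a * reg.modes * reg.likelihoods * config.effect_size
                for lr in config.lr_specs:
                    s = lr.s(cond, tp)
                    if s != 0.0:
                        if pop == lr.sender:
                            logmu[gene_index.get_loc(lr.ligand)] += s
                        if pop == lr.receiver:
                            logmu[gene_index.get_loc(lr.receptor)] += s
                w = np.exp(logmu)
                # pin the mito block to its configured mass fraction
                w_m = w[mito_mask].sum()
                w_o = w[~mito_mask].sum()
                if w_m > 0:
                    w[mito_mask] *= (config.mito_frac / (1 - config.mito_frac)) * w_o / w_m
                p = w / w.sum()
                lib = rng.lognormal(mu_log, sigma_log, size=n_cells)
                mu = lib[:, None] * p[None, :]
                lam = rng.gamma(shape[None, :], mu / shape[None, :])
                block = rng.poisson(lam).astype(np.int32)
                counts_blocks.append(block)
                sample_id = f"{cond}_d{int(tp)}"
                for i in range(n_cells):
                    obs_rows.append(
                        {
                            "cell_id": f"{cond}_d{int(tp)}_{pop}_{i:04d}",
                            "sample_id": sample_id,
                            "condition": cond,
                            "timepoint_dpi": float(tp),
                            "population": pop,
                        }
                    )
                stratum_probs.extend([p] * n_cells)
                for spec in config.tf_specs:
                    tf_rows.append(
                        {"tf": spec.name, "population": pop, "condition": cond,
                         "timepoint_dpi": float(tp), "a": spec.a(pop, cond, tp)}
                    )
                for lr in config.lr_specs:
                    if pop == lr.sender:
                        edge_rows.append(
                            {"ligand": lr.ligand, "receptor": lr.receptor,
                             "sender": lr.sender, "receiver": lr.receiver,
                             "family": lr.family, "condition": cond,
                             "timepoint_dpi": float(tp), "strength": lr.s(cond, tp)}
                        )

    counts = np.vstack(counts_blocks)
    meta = pd.DataFrame(obs_rows).set_index("cell_id")
    n_total = counts.shape[0]

    # QC-failing cells by explicit override, cycling four failure modes.
    n_fail = int(round(config.qc_fail_fraction * n_total))
    fail_idx = np.sort(rng.choice(n_total, size=n_fail, replace=False)) if n_fail else np.array([], dtype=int)
    modes = ["umi_low", "umi_high", "mito_high", "mito_low"]
    for j, ci in enumerate(fail_idx):
        mode = modes[j % 4]
        p = stratum_probs[ci]
        if mode == "umi_low":
            counts[ci] = rng.multinomial(50, p)
        elif mode == "umi_high":
            counts[ci] = rng.multinomial(9000, p)
        elif mode == "mito_high":
            non_mito_total = int(counts[ci, ~mito_mask].sum())
            pm = p[mito_mask] / p[mito_mask].sum()
            counts[ci, mito_mask] = rng.multinomial(int(round(non_mito_total * 0.5)), pm)
        else:  # mito_low
            counts[ci, mito_mask] = 0

    adata = ad.AnnData(
        X=None,
        layers={"counts": sp.csr_matrix(counts)},
        obs=meta.copy(),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )

    truth = GroundTruth(
        tf_activity=pd.DataFrame(tf_rows).drop_duplicates(
            ["tf", "population", "condition", "timepoint_dpi"]).reset_index(drop=True),
        edge_strength=pd.DataFrame(
            edge_rows, columns=["ligand", "receptor", "sender", "receiver",
                                "family", "condition", "timepoint_dpi", "strength"]
        ).drop_duplicates().reset_index(drop=True),
        qc_fail_cells=[meta.index[i] for i in fail_idx],
        planted_beta=(
            config.planted_beta.copy() if config.planted_beta is not None
            else pd.DataFrame(columns=["population", "program", "phase", "predictor", "coefficient"])
        ),
    )
    return StudyData(adata, meta, regulons, lr_network, truth)


def simulate_decomposition_dataset(
    planted_beta: pd.DataFrame,
    n_per_stratum: int = 400,
    noise_sd: float = 1.0,
    seed: int = 0,
    populations: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw per-cell predictors and program responses from a planted linear
    model, as an exact oracle for the direct-vs-paracrine decomposition.

    ``planted_beta`` has columns (population, program, phase, predictor,
    coefficient); phases are "early" (cells at 0 and 5 dpi) and "late"
    (14 dpi).  Predictors (the receptor-regulon NES and the pathway module
    scores) are iid standard normal; each program response is the planted
    linear combination plus N(0, noise_sd) noise.  Returns (nes, pathway
    scores, metadata): nes rows are the programs plus any regulon-type
    predictors; pathway scores are cells x pathway columns.
    """
    req = {"population", "program", "phase", "predictor", "coefficient"}
    if not req <= set(planted_beta.columns):
        raise ValueError(f"planted_beta missing columns: {sorted(req - set(planted_beta.columns))}")
    rng = np.random.default_rng(seed)
    pops = tuple(populations) if populations is not None else tuple(
        pd.unique(planted_beta["population"]))
    programs = list(pd.unique(planted_beta["program"]))
    predictors = list(pd.unique(planted_beta["predictor"]))
    phase_tps = {"early": (0.0, 5.0), "late": (14.0,)}

    cells, pop_col, tp_col = [], [], []
    X_blocks, Y_blocks = [], []
    for pop in pops:
        for phase, tps in phase_tps.items():
            n = n_per_stratum
            X = rng.normal(size=(n, len(predictors)))
            Y = rng.normal(0.0, noise_sd, size=(n, len(programs)))
            sub = planted_beta[(planted_beta["population"] == pop) & (planted_beta["phase"] == phase)]
            for _, row in sub.iterrows():
                j = predictors.index(row["predictor"])
                k = programs.index(row["program"])
                Y[:, k] += float(row["coefficient"]) * X[:, j]
            X_blocks.append(X)
            Y_blocks.append(Y)
            for i in range(n):
                cells.append(f"{pop}_{phase}_{i:04d}")
                pop_col.append(pop)
                tp_col.append(tps[i % len(tps)])
    X = np.vstack(X_blocks)
    Y = np.vstack(Y_blocks)
    idx = pd.Index(cells, name="cell_id")
    meta = pd.DataFrame(
        {"condition": "CTRL", "timepoint_dpi": tp_col, "population": pop_col}, index=idx)
    # regulon-type predictors (by convention those not containing '/', e.g.
    # Thra) ride in the NES matrix; the rest are pathway module scores
    reg_predictors = [p for p in predictors if "/" not in p and "-" not in p]
    path_predictors = [p for p in predictors if p not in reg_predictors]
    nes = pd.DataFrame(Y.T, index=pd.Index(programs, name="regulon"), columns=idx)
    for p in reg_predictors:
        nes.loc[p] = X[:, predictors.index(p)]
    pathway_scores = pd.DataFrame(
        {p: X[:, predictors.index(p)] for p in path_predictors}, index=idx)
    return nes, pathway_scores, meta


def write_study(study: StudyData, outdir: str | Path) -> None:
    """Write the study in the package's on-disk interchange layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(study.adata, outdir)
    study.meta.reset_index().to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    study.regulons.to_frame().to_csv(outdir / "regulons.tsv", sep="\t", index=False)
    study.lr_network.to_csv(outdir / "lr_pairs.tsv", sep="\t", index=False)
    study.truth.write(outdir / "truth")
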