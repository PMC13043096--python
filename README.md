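# thregulon

Integrative single-cell analysis of thyroid-hormone signaling during
skeletal-muscle regeneration — as a tested, reusable pipeline.

Hypothyroidism impairs muscle repair after injury. Single-cell RNA-seq of
regenerating muscle (euthyroid CTRL vs hypothyroid HYPO, sampled at 0, 5 and
14 days post-injury across myogenic, fibro-adipogenic progenitor (FAP),
myeloid and lymphoid populations) lets one ask *how*: does triiodothyronine
act directly, through thyroid-hormone-receptor (THR) transcriptional
programs inside each cell, or indirectly, through paracrine ligand-receptor
signaling between populations? `thregulon` implements the four analysis
stages needed to answer that, plus a synthetic-data generator with planted
ground truth so every stage is testable without any download.

## What it computes

**1. Regulon activity (NES).** A regulon is a transcription factor with
target genes, each carrying a regulation mode *s* ∈ [−1, 1] and a likelihood
weight *w* ∈ (0, 1] (the CollecTRI/DoRothEA tabular shape). Within each cell,
genes are ranked by normalized expression and mapped to standard-normal
quantiles *q*; a regulon's enrichment is the signed, weighted sum

    ES = Σ_t  w_t · s_t · q_t ,     NES = (ES − q̄ Σ w_t s_t) / √(Σ w_t² · var(q)/v₀)

standardized so NES ~ N(0, 1) when targets are exchangeable with the
background (the `var(q)/v₀` term keeps the null calibrated under the zero-count
tie block of sparse data; it is the identity for tie-free profiles).
Program-level activity (proliferative *Myc*/*E2f*, oxidative
*Foxo*/*Ppargc1a*) comes from merged meta-regulons. Conditions are contrasted
per (population × timepoint) stratum with Wilcoxon rank-sum tests and
Benjamini-Hochberg correction, cross-resource concordance and program
covariation (Spearman) included.

**2. Temporal trajectories.** Per (regulon × population), per-cell NES is
regressed on time with a cubic regression spline basis (k = 3); a shared
smooth (plus condition offset) is compared with condition-specific smooths by
a nested ANOVA F test, and stratum means get percentile bootstrap CIs
(1,000 resamples).

**3. Ligand-receptor communication.** Edge score for (sender S, receiver R,
ligand, receptor) = ½·(mean ligand expression in S + mean receptor
expression in R), per condition × timepoint, after an expressed-gene filter.
Differential activity Δ = HYPO − CTRL is aggregated into pathway families
(ECM/integrin, IL-6, IGF-1, Notch/Jagged) with rank-sum tests and FDR.

**4. Direct vs paracrine decomposition.** Per population and phase
(early = 0–5 dpi, late = 14 dpi), program NES is regressed on THR-regulon NES
(direct) and per-cell pathway module scores (indirect), all z-scored within
stratum; standardized β's are summarized as activation / repression / weak /
none.

## Worked example

```python
import thregulon as tg

cfg = tg.SimConfig(cells_per_stratum=200, seed=1)   # 2 cond x 3 dpi x 4 populations
study = tg.generate_study(cfg)

adata, report = tg.apply_qc(study.adata)
print(f"QC: retained {report.n_retained}/{report.n_input} cells")
adata = tg.normalize_log2cpm(adata)

nes = tg.score_regulons(adata, study.regulons)
table, fits = tg.fit_all_trajectories(nes, adata.obs)
row = table.query("regulon=='Thra' and population=='myogenic'").iloc[0]
print(f"Thra x myogenic: F = {row.F:.1f}, FDR = {row.fdr:.2e}")

net = tg.filter_expressed(study.lr_network, adata)
diff = tg.differential_edges(tg.score_edges(adata, net))
jag = diff.query("ligand=='Jag1' and sender=='FAP' and receiver=='myogenic'")
print({int(t): round(d, 2) for t, d in zip(jag.timepoint_dpi, jag.delta)})
```

prints

```
QC: retained 4560/4800 cells
Thra x myogenic: F = 44.0, FDR = 1.14e-18
{0: 0.02, 5: -0.41, 14: 2.54}
```

The generator plants a blunted HYPO *Thra* induction in myogenic cells and
FAPs (the trajectory ANOVA detects it, F = 44; the unplanted myeloid stratum
gives F = 0.4, FDR = 0.72) and a late Notch/Jagged signal from FAPs to
myogenic cells (Δ = +2.5 at 14 dpi, near zero before). QC removes exactly the
240 cells planted to violate a filter rule.

The same pipeline runs from the shell:

```bash
thregulon simulate --out study/ --seed 1
thregulon run-all --config pipeline.yaml     # qc -> score -> trajectory -> lr -> decompose
```

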