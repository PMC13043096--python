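# Methods

This note documents the statistical machinery in `thregulon`: the models and
their assumptions, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical edge cases.

## Quality control and normalization

Cells are retained iff (inclusive bounds on every rule):

| metric | min | max |
| --- | --- | --- |
| total UMI | 100 | 8,000 |
| detected genes | 500 | 50,000 |
| mitochondrial UMI proportion | 1% | 15% |

Mitochondrial genes are identified by a configurable name prefix (default
`mt-`). Bound strictness is not canonical; inclusive was chosen so a cell at
exactly 15% mito is kept, and both bounds and prefix are configurable.
Normalization is the uniform `log2(CPM + 1)` transform. The alternative
reading "add 1 only to zero values" is equivalent at zero but discontinuous
elsewhere and was rejected; a zero count always maps to exactly 0 and a
cell's normalized column depends only on its own counts.

## Regulon activity (NES)

Within each cell, genes are ranked ascending by normalized expression with
average ranks for ties (average ties keep the null symmetric), mapped to
fractional ranks r = rank/(G+1) and to normal quantiles q = Φ⁻¹(r). For a
regulon with targets t (mode s_t, likelihood w_t):

    ES  = Σ_t w_t s_t q_t
    NES = (ES − q̄ Σ_t w_t s_t) / sqrt(Σ_t w_t² · var(q)/v₀)

where q̄ and var(q) are the mean and variance of the cell's full quantile
vector and v₀ is the variance of the tie-free grid Φ⁻¹(i/(G+1)). This is the
signed two-tail analytic rank-based enrichment score with an analytic
N(0, 1) null; the one-tail magnitude term and the pleiotropy/shadow
correction of the full VIPER machinery are deliberately omitted — the NES
contract consumed downstream (one ~N(0,1) activity per regulon per cell) is
preserved by the simpler estimator, which is also exactly checkable against
a permutation oracle.

Two properties of the standardization deserve note:

* **Tie correction.** Sparse profiles put a large tie block at zero
  (typically 30–50% of genes), which deflates the variance of q and would
  deflate the null NES sd to ~0.85–0.9. The `var(q)/v₀` factor restores the
  analytic null under sparsity and is exactly 1 for tie-free cells, so
  closed-form examples (a single target ranked 3rd of 3 genes scores
  Φ⁻¹(0.75) ≈ 0.6745) are unaffected. A fully constant cell has var(q) = 0
  and scores 0 for every regulon.
* **Exchangeability caveat.** The null assumes targets exchangeable with the
  ranked background. With heterogeneous baseline expression a *fixed*
  regulon acquires a stable offset (its targets have persistent rank
  tendencies); this is inherent to rank scoring with fixed priors, affects
  every resource equally, and cancels in condition contrasts, which is why
  group comparisons — not raw NES levels — carry the inference. Null
  calibration is therefore assessed under the generator's gene-exchangeable
  configuration (`pure_noise_config`: flat baselines, zero planted
  activity), where stratum means are within ±0.05 and sds within
  [0.9, 1.1].

Regulons need ≥ 5 targets after intersection with the matrix (default
`min_size`); duplicate prior edges keep the max-|likelihood| row. Programs
(e.g. *Myc*/*E2f*) merge the target sets of several TFs: a gene claimed by
multiple TFs gets mode sign(Σ w·s) and likelihood mean(w), and is dropped on
exact cancellation. Merging (rather than averaging per-TF NES) keeps the
one-NES-per-cell contract used by the temporal and decomposition stages.

Group contrasts use the two-sided Wilcoxon rank-sum test (exact for small
tie-free samples, tie-corrected asymptotic otherwise) with BH adjustment
across all reported (regulon × stratum) tests and delta_median =
median(HYPO) − median(CTRL). Cross-resource concordance is the fraction of
contrasts whose delta_median signs agree, gated to contrasts reaching
FDR < 0.05 in at least one resource (gate configurable; if nothing passes,
all testable contrasts are used). No attempt is made to reproduce any
particular published concordance percentage — the metric behind such numbers
is not identifiable, so the definition here is explicit and configurable.

## Temporal smooths

Per (regulon × population), per-cell NES is modeled with a natural
cubic-regression-spline basis in time ("cr" construction: cardinal natural
splines interpolating indicators at k knots placed at quantiles of the
observed timepoints; default k = 3):

* shared model: NES ~ condition + s(time)
* full model: NES ~ condition + s(time) + condition:s(time)

With three sampled timepoints and k = 3 the smooth is saturated — the full
model interpolates the six (condition × timepoint) stratum means — and both
designs are rank-deficient by construction. Fits use rank-revealing least
squares (`lstsq`/pinv); degrees of freedom come from the design rank, so the
nested ANOVA

    F = [(RSS_shared − RSS_full)/Δdf] / [RSS_full/df_resid_full]

is exact despite the redundancy. No smoothing penalty is estimated: with
k = 3 on three timepoints there is nothing to penalize. Errors are treated
as homoskedastic within stratum for the 95% CIs (t-quantile × prediction
SE from the pseudo-inverse covariance). A condition observed at fewer than
two timepoints forces a fallback to the shared fit, reported with a note
and a missing F. Both raw and BH-adjusted ANOVA p values are reported.
Under the null the rejection rate at α = 0.05 is calibrated (measured
0.046–0.054 over 500-rep batches) and a 0.5-NES divergence at 5 dpi with 300
cells/stratum is detected with power ≥ 0.99.

Bootstrap stability: cells are resampled with replacement within each
(population × condition × timepoint) stratum, B = 1000 by default, seeded;
the 2.5/97.5 percentiles of the resampled stratum means give the CI
(measured coverage 0.94–0.96 for a N(0,1) stratum of 200 cells). A
single-cell stratum yields a degenerate, flagged CI.

## Ligand-receptor communication

Pairs are gene-to-gene (no multi-subunit complexes), with a closed family
vocabulary {ECM/integrin, IL-6, IGF-1, Notch/Jagged, other}. A pair survives
the expressed-gene filter if both genes are detected (count > 0) in ≥ 5% of
the cells of at least one population (threshold configurable). The edge
score is the arithmetic mean of sender-population mean ligand expression and
receiver-population mean receptor expression on the normalized matrix; the
phrase "mean ligand/receptor expression" is ambiguous between a mean and a
product, so a product variant is available behind `variant="product"`. All
ordered population pairs are scored, including self-edges. Δ = HYPO − CTRL
per matched edge; family aggregation reports the mean member-edge Δ and a
two-sided rank-sum p comparing member-edge scores between conditions
(families with < 3 member edges are reported without p), BH-adjusted across
keys. Per-cell pathway module scores average the normalized expression of
the family's gene union and are z-scored within population for downstream
modeling.

## Direct vs paracrine decomposition

Per population and phase (early pools 0 and 5 dpi; late is 14 dpi — separate
per-phase fits, no interaction terms), the program NES is regressed jointly
(one multiple regression, not marginal fits) on the THR-regulon NES (default
*Thra*; *Thrb* selectable) and the pathway module scores, every variable
z-scored within the stratum so coefficients are standardized β's.
Collinear designs are fitted with the pseudo-inverse and flagged; strata
under 30 cells are skipped. β's are BH-adjusted jointly and categorized:
activation (β ≥ 0.1, FDR < 0.05), repression (β ≤ −0.1, FDR < 0.05), weak
(FDR < 0.05, |β| < 0.1), none otherwise. The 0.1 threshold is a reporting
convention, exposed on the CLI, not an inferential claim.

## Synthetic data generator

The generator emulates the study design: two conditions (CTRL, HYPO), three
timepoints (0, 5, 14 dpi), four populations (myogenic, FAP, myeloid,
lymphoid), 600 cells per stratum by default (2,400 cells per
condition × timepoint sample, within the realistic 2,000–7,000 range for a
pooled library). Counts are negative binomial (gamma-Poisson, shape 2.0)
around gene relative abundances times a lognormal per-cell library factor
(median 3,000 UMI, σ = 0.15) — the standard noise family for scRNA-seq
counts. Gene baselines are lognormal (σ = 0.4 natural-log units) with small
population-specific deviations (σ = 0.1); a dedicated low-noise
mitochondrial block (20 genes, shape 10) is pinned to 6% of each cell's
mass so the QC proportion is tightly controlled.

Planted structure:

* **TF activity** a(population, condition, timepoint) shifts each target's
  log-mean by a·s·w·effect_size — the simplest mechanism consistent with
  signed, weighted regulons. Default TF specs (Thra, Thrb, Myc, E2f1, Foxo1,
  Ppargc1a) encode trajectories shaped like the biology: CTRL receptor
  activity peaks at 5 dpi and renormalizes, HYPO is blunted; the
  proliferative program peaks early under CTRL and late under HYPO, the
  oxidative program the opposite. Regulon targets are drawn from the full
  gene universe so they remain exchangeable with the ranked background.
* **LR signals** shift the ligand gene in the sender and the receptor gene
  in the receiver by `strength` natural-log units. Named LR genes start from
  a common baseline so the planted shift, not baseline heterogeneity,
  dominates the between-edge and between-condition differences of the edge
  scores — without this the unpaired family rank-sum has no usable power at
  realistic effect sizes.
* **QC failures** are explicit overrides (library downsampled to 50,
  upsampled to 9,000, mito forced to ~33% or to 0), cycling the four modes
  over a seeded random `qc_fail_fraction` of cells, so expected filter
  counts are exact rather than distributional. The non-overridden cells pass
  all QC rules with wide margins at the default depth; very small gene
  universes (< ~600 genes) would push detected-gene counts under the
  500-gene floor, so test configurations stay above 800 genes.
* **Decomposition truth** is generated by `simulate_decomposition_dataset`,
  which draws predictors iid N(0, 1) and builds program responses from a
  planted coefficient table; planting exact OLS coefficients through the
  count-level simulator is not possible, so the count simulator carries the
  planted table through as metadata while the direct construction serves as
  the decomposition oracle.

Identical configs (including seed) produce byte-identical outputs; all
randomness flows from one `numpy` Generator.

What the generator does **not** emulate: doublets, ambient RNA, batch
effects, UMI collision, mouse-level replicate variance (the study pools
three mice per library, so strata are single pooled samples), dropout beyond
NB sampling, and any real gene-gene covariance structure. Passing tests
therefore demonstrate correctness of the estimators under the stated
generative assumptions, not robustness to every artifact of real data.

## Problem sizes and numerical choices

Calibration and recovery checks run at desk scale: 2,000 cells for null NES
calibration; 50 cells × 10 regulons × 10,000 permutations for the oracle
comparison; 300 cells/stratum for activity recovery; 500/200 replicates for
ANOVA type-I/power; 500 outer replicates (B = 1000, n = 200) for bootstrap
coverage; 100 replicates each for LR family power, null family rate, and
decomposition recovery. Spline designs are solved by `lstsq` with pinv-based
covariance (rank-deficiency is expected, see above); z-scoring uses
population variance (ddof 0); a zero-variance predictor z-scores to zeros; BH
adjustment passes NaN p-values through untouched. Seeds are mandatory for
every stochastic stage and are threaded through run configs.

## Known limitations

* NES levels (as opposed to contrasts) are only interpretable under target
  exchangeability; fixed regulons on real data carry stable offsets.
* The edge score uses population-mean expression, so it cannot resolve
  within-population heterogeneity of senders or receivers, and no
  permutation-based specificity test (CellPhoneDB-style) is performed.
* The decomposition is a standardized multiple regression — an association
  decomposition, not formal causal mediation.
* With three timepoints the "smooth" is a saturated fit; k > 3 only has
  meaning with denser time sampling.
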