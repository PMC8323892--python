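# Methods

## The problem this package models

Field-collected insects from many localities rarely yield true
biological replicates per condition: RNA is pooled per locality ×
tissue × host plant and sequenced once.  Replication is then obtained
*across* comparisons (different localities sharing a condition), not
within them, and differential expression must be decided per pairwise
contrast by thresholds rather than by a dispersion-based test.  Every
downstream statistic in this package operates on those per-contrast
threshold calls.

## Quality control

Three gene filters run in a fixed order; the report records each rule's
before/removed/after counts and the library sizes in force.

- **R1, low count**: a gene is dropped when its maximum count across
  samples is below 2.  The alternative reading — dropping a gene when
  *any single* sample is below 2 — would discard nearly the whole
  matrix at realistic sparsity and is inconsistent with retention rates
  of 50–70 %; it remains selectable (`low_count_mode="any-sample"`).
- **R2, coverage**: keep genes with ≥ 10 counts in at least one sample.
- **R3, expression**: keep genes with CPM ≥ 1 in at least two samples.
  CPM here uses **raw** library sizes because the filter precedes
  normalization in the workflow.

Sample flags never remove data: a sample is flagged when its 100
largest counts exceed 35 % of its library (amplification/bottleneck
signature; the rule is skipped with a warning under 100 genes) or when
fewer than `min_high_count_genes` genes (default 1000 — "very few" is
not quantified anywhere, so it is an explicit parameter) reach 10
counts.  Flagged samples are excluded from contrasts by default but
kept in the matrix and in normalization; both choices are flags in the
pipeline config.  Note the top-100 rule is calibrated for full
transcriptomes (where 100 genes are ~0.1 % of the assembly); on
desk-scale simulations where 100 genes are several percent of the
matrix, the share threshold must be raised accordingly (the test
configurations do this explicitly).

## Normalization

TMM follows the standard recipe: reference = the sample whose
upper-quartile of depth-scaled counts is closest to the mean
upper-quartile; per sample, M = log₂((x/N)/(x_r/N_r)) and
A = ½log₂ of the product over genes positive in both; double trim (30 %
of M, 5 % of A, rank-based with the `floor(n·t)+1 … n−floor(n·t)`
bounds); factor = 2^(weighted mean of surviving M) with weights equal
to the inverse delta-method binomial variance of M; finally all factors
are rescaled to geometric mean 1.  A sample with no positive overlap
with the reference gets factor 1 with a warning.

FPKM_gi = counts_gi · 10⁹ / (length_g · effective library size_i), with
effective size = raw size × TMM factor by default (raw sizes via a
flag, since either convention is defensible when the upstream
quantifier is unknown).  CPM is defined analogously with 10⁶ and no
length term.

## DEG calling

The "adjusted" fold change is an interpretation made explicit here:
within a contrast, each sample's FPKM column is multiplied by
(grand median of the contrast samples' per-gene medians)/(its own
median), computed over QC-retained genes; a zero median leaves the
sample unscaled with a warning.  Group summaries are arithmetic means
of the scaled columns (median by config; groups have 1–5 samples).
Calls: `up_in_g1` when ΔFPKM > 1 (strict) and log₂FC ≥ 1; `up_in_g2`
symmetrically at ≤ −1 (the threshold pair "≥ 1 up, ≤ 1 down" in the
original description must mean ≤ −1, since ≤ 1 would label every
non-upregulated gene down-regulated); `not_evaluable` when either group
mean is zero — no pseudocount is added, because a gene absent from one
side has no defined fold change.  There is deliberately **no**
multiple-testing correction: the rule is a threshold, not a test.
Antisymmetry under group swap and the invariance of calls to scaling
any single sample's column are exact and tested.

## Category statistics

Counting unit: one cell per contrast × side × functional gene group;
a group contributes cells to a contrast only when at least one of its
genes is evaluable there.  The detoxification category is additionally
aggregated by summation.  The Wilcoxon signed-rank test pairs the two
sides of the same comparison cell (this pairing is the natural reading
of per-comparison points, made explicit here); zeros are dropped
(Pratt's treatment by config), ties get midranks, and the exact null
distribution — computed by subset-sum convolution over the doubled
midranks, equivalent to enumerating all 2ⁿ sign vectors — is used up to
n = 25, beyond which the normal approximation with tie and continuity
corrections applies.  Kruskal–Wallis (tie-corrected, χ² reference)
delegates to scipy.  Significance level is 0.05 throughout.  Host
tests pool tissues by default; a per-tissue mode exists.

## Rank-based ANOVA

Rank fits minimize Jaeckel's dispersion D(β) = Σ a(R(eᵢ))eᵢ with
Wilcoxon scores a(i) = √12(i/(n+1) − ½).  For these scores
D(β) = √12/(2(n+1)) Σ_{i<j}|eᵢ−eⱼ|, so the minimization is solved
*exactly* as median (LAD) regression on the pairwise-differenced data
(statsmodels QuantReg), refined by a Nelder–Mead polish on D and exact
coordinate-wise line searches whose weighted-median midpoint rule
centers flat optima — making the binary-covariate slope precisely the
Hodges–Lehmann estimator.  The scale parameter τ =
(√12∫f²)⁻¹ is estimated by the Koul–Sievers–McKean window estimator
(δ-quantile bandwidth of the trimmed pairwise absolute residual
differences over √n, δ = 0.8 when n/p > 5 else 0.95, √(n/(n−p−1))
degrees-of-freedom correction).  Nested models are compared by
F = (RD/q)/(τ̂/2) against F(q, n − p_full − 1); its type-I error at
α = 0.05 is verified by simulation to lie in [0.03, 0.07] (2 × 3
factorial, n = 60, 2000 replicates), and on a single binary predictor
its p-value tracks the Wilcoxon rank-sum p (mean |Δp| ≈ 0.01 at
n = 100).  The interaction battery fits, per category, main effects of
host side, tissue and functional group plus one pairwise interaction at
a time (treatment coding, first level reference; the test is
coding-invariant); the DEG count per cell is treated as a continuous
response for ranking, with midranks at ties.

## Intensity statistic

Per comparison (or group) × tissue × category × direction, the |log₂FC|
values of that direction's DEGs span [min, max], split into five
equal-width bins (right-open, last closed; bins are per cell, not
global).  The cell value is the weighted median of the bin midpoints
with bin counts as weights, lower midpoint on an exact half-weight tie.
Cells with n ≤ 1 are excluded — one transcript gives no distribution —
and a zero range degenerates to the common value.  Weighted medians of
bin indices or of within-bin raw medians are available by config; bin
midpoints are the default because they keep the statistic on the log₂FC
scale that heatmap color bars display.

## Venn partitions

DEG identities are pooled per comparison group over both directions
*before* partitioning, so direction never splits a region.  3–4 labelled
sets are partitioned by exact membership pattern; disjointness and
union coverage are asserted on every call.  For groups spanning two
species with independent assemblies, identity matching can use the
protein-annotation string instead of transcript ids, since
assembly-specific ids cannot coincide across species.

## Enrichment

Preranked mode with a gene-label permutation null is the only mode
implemented: most contrasts have one pooled sample per side, so
phenotype permutation is impossible.  Genes are ranked by adjusted
log₂FC (descending, lexicographic tie-break).  The running sum adds
|r|^p/Σ_hits|r|^p at hits (p = 1) and subtracts 1/(N−N_h) at misses; ES
is the signed extremum, computed in O(k) from the hit positions; at
p = 0 it reduces to the classical KS statistic (tested).  NES divides
ES by the mean same-sign |null ES| of the matching set size; nominal p
is the same-sign null tail fraction.  FDR q pools normalized null and
observed scores per sign class, q = (null tail fraction)/(observed tail
fraction) clipped to [0, 1] and made monotone in |NES| within the sign
class.  Significant sets require q < 0.05 strictly and at least one
leading-edge gene with |log₂FC| > 1 (a set-mean alternative exists by
config).  The overlap graph connects significant sets whose combined
coefficient ½·Jaccard + ½·overlap reaches 0.375 (the conventional
enrichment-map default); hierarchical grouping of terms is represented
by the graph's connected components rather than a dendrogram.

## Synthetic data

The generator's defaults define the demo study: 20 pooled samples —
head and abdomen pools for three host plants (legume/Fabaceae,
citrus/Rutaceae, aster/Asteraceae) maintained on the natal host, plus
host-switched pools for the two crop hosts — yielding 12 pairwise
contrasts in 4 contrast groups (host comparisons within tissue,
within-"other" comparisons, switch-vs-maintain, and switched-host
comparisons), inside the 1–5-samples-per-group and 2–15-contrasts-per-
group envelope of the emulated design.  Counts are gamma-Poisson
(negative binomial, var = μ + φμ², φ = 0.1 by default) around
library-size-scaled relative abundances.  Baseline abundance is a
two-component log-normal: an expressed component (log-mean 3, log-sd 1)
and, for 40 % of unannotated genes, a background component shifted down
by 6 natural-log units — mimicking the low-abundance fragment cloud of
a de novo assembly.  With these defaults ~63 % of genes survive QC and
healthy samples keep their top-100 read share under 35 %, reproducing
the *structure* (not the numbers) of real retention statistics.  Gene
lengths are uniform on 200–5000 bp.  Planted effects multiply expected
counts by 2^effect for a gene subset in all samples matching a
metadata condition; planted subsets are drawn from expressed genes
(a regulated gene is by definition an expressed one), and every planted
(gene, condition) pair is recorded in the truth table.  The demo plants
+3 log₂ host-detection in legume feeders, +3 log₂ detoxification in
citrus feeders, +2 log₂ immune in aster feeders and +1.5 log₂ immune
under host switch.

What the generator does **not** emulate: read-level error, positional /
GC bias, correlated gene modules beyond the planted categories,
between-locality biological variance beyond NB noise, and cross-species
orthology complications.  Passing recovery tests therefore demonstrate
correctness of the pipeline's arithmetic and decision rules under the
assumed noise model, not field performance.

## Numerical choices and problem sizes

- Exact signed-rank distribution up to n = 25 (subset-sum DP over
  doubled midranks; O(n · Σrank)).
- Rank-fit tolerances: QuantReg defaults, Nelder–Mead xatol 1e-6 /
  fatol 1e-8, coordinate-descent convergence 1e-12, max 20 sweeps.
- TMM, FPKM and the intensity statistic are deterministic closed forms;
  oracle tests pin them to 1e-9/1e-12.
- Simulation-based checks use problem sizes chosen for fast, stable
  estimates: 2000-gene recovery fixtures over 10 seeds, 2000-replicate
  null calibration of the interaction test, 1000-permutation GSEA
  nulls, and the 5000-gene demo pipeline (seconds per run).
- All stochastic stages consume seeds derived from a single
  configuration seed; reruns are byte-identical.

## Known limitations

- The median-scaling construction of the "adjusted" fold change is a
  declared interpretation of an unpublished in-house adjustment; it is
  configurable (summary statistic, raw-vs-TMM FPKM) precisely because
  the original arithmetic is unknown.
- The threshold DEG rule has no error-rate control; its false-positive
  behaviour is characterized empirically (≤ 2 % on null genes at the
  demo's noise level), not guaranteed.
- The exact Wilcoxon p is conservative at tiny n, as all exact rank
  tests are.
- Gene sets are flat; no GO-graph ancestry or propagation.
- 3- and 4-way Venns only; the schematic figures are not
  area-proportional.
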