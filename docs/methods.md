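# Methods

`clonepulse` implements, as a tested pipeline over synthetic data with
known ground truth, a single-cell multi-omics analysis of myelodysplastic
syndromes (MDS) under hypomethylating-agent (HMA) therapy: paired bone-marrow
samples at diagnosis and after treatment, profiled for targeted DNA variants,
amplicon read depth, and surface proteins (ADT) on each cell. This note
records the models, the defaults and why, and what the synthetic experiments
do and do not demonstrate.

## Data model

Each sample is a triple of matrices over one barcode set:

* **Genotypes** — cells x variants categorical calls (WT / HET / HOM /
  MISSING) with per-call read depth, Phred-like genotype quality (GQ) and
  alternate-allele fraction (AF). Variant records carry gene, consequence
  class, population minor-allele frequency (MAF) and a bulk-NGS whitelist
  flag.
* **Amplicon counts** — cells x panel amplicons (BED-convention 0-based
  half-open coordinates; variant positions are 1-based, VCF convention).
* **ADT counts** — cells x antibodies, with isotype controls flagged.

Containers are one HDF5 file per sample with named layers; CSV and
MatrixMarket fallbacks cover the tabular pieces. When modalities retain
different cell sets, the cohort assembler intersects barcodes per sample —
DNA and protein QC legitimately keep different cells, and the intersection is
what the joint genotype x phenotype analyses can use.

## Quality control and allele dropout

Filters run in a fixed order with strict comparators: per-call (GQ > 30,
depth > 10, AF > 20% for non-WT calls; failures become MISSING), then
per-variant (genotyped in > 50% of cells; mutated in >= 1% of cells;
nonsynonymous-exonic or splicing consequence; MAF <= 0.01 unless
whitelisted), then per-cell (>= 50% of genotypes present). Variants failing
only the genotyped-fraction rule but showing good support (median GQ and AF
above the call thresholds among mutated cells) are *reported* without
seeding clones. "Mutated" means HET or HOM throughout, and fraction
denominators use genotyped cells where the choice is ambiguous.

Allele dropout (ADO) — the loss of one allele during single-cell
amplification — is estimated from germline heterozygous variants: mutated in
>= 92% of genotyped cells at both timepoints with a VAF-by-cell-count
(`100·(n_HET + 2·n_HOM) / (2·n_genotyped)`) inside [49.2, 52.7] at both.
Per variant, `ADO% = 100·(n_WT + n_HOM)/n_genotyped`; the sample value
averages the five selected variants nearest VAF 50 (all of them, with a
warning, when fewer qualify — at a few thousand cells the sampling noise of
VAF regularly pushes one of five variants just outside the window).

## Clones, phylogeny, dynamics

A clone is a maximal set of cells with an identical variant→zygosity
signature over retained variants. Cells with any MISSING retained call are
*unassigned*, not imputed: clone identity requires a complete signature.
Clones under 1% of assigned cells are pooled into a `minor` bucket unless
they carry a whitelisted variant that no major clone carries — the whitelist
guarantees a bulk-confirmed variant is never silently pooled away, but does
not promote every dropout/error combination of already-represented variants
to clone status.

Dropout-artifact clones — one HET→WT or HET→HOM substitution away from a
larger clone — are merged into that clone when their size is at most
`parent_cells × ADO/100 × 1.5`; the 1.5 safety factor (config-exposed)
automates what is otherwise a manual inspection, and simulations confirm it
never absorbs clones 3x above the dropout expectation.

The phylogeny orders clones by mutation-set inclusion with zygosity
progression (HET may deepen to HOM, never the reverse), roots at the WT
clone, and attaches each clone to its largest proper ancestor (deepest
signature; cell count breaks ties). Incomparable clone pairs sharing
mutations their lowest common ancestor lacks are recorded as conflicts
rather than raised. Topology is `linear` iff no node has two children.
Shannon diversity (natural log) and the predominant-clone fraction are
computed over mutant-clone fractions renormalized to mutant cells.

Paired-timepoint dynamics are classified with two config-exposed thresholds
(`shrink_factor = 0.5`, `new_clone_min = 0.02`): **shrinkage** when every
diagnosis mutant clone falls below `shrink_factor` times its diagnosis
fraction of all cells and no new clone at or above `new_clone_min` appears;
**expansion** when a new clone that large appears or a minority clone more
than doubles *and* reaches `new_clone_min` (the size floor keeps a handful
of noise cells from flipping the call); otherwise **stable**.

CHIP (clonal hematopoiesis) flags use three definitions: the TET2 / DNMT3A /
ASXL1 core, that core plus SF3B1 and TP53, or any supplied driver gene at a
VAF-by-cell-count above 2%.

## Copy number

Amplicons detected (>= 1 read) in fewer than half the cells are dropped;
counts are normalized per cell total, then per amplicon mean. Clone-level
ploidy is `2 × median(clone) / median(baseline)` per amplicon against a
diploid baseline clone (the WT clone, >= 50 cells). The baseline median in
the denominator makes the baseline exactly diploid on itself — a mean
denominator under skewed negative-binomial depths would not. Region calls
use midpoints between integer copy states: loss < 1.5, gain > 2.5 (both
config-exposed). Independently, CNV-defined clones are detected from
genotype data: a deletion pushes a germline het variant's per-cell AF toward
0 or 1, a gain toward 1/3 or 2/3; a clone is flagged when its mean deviation
|AF − 0.5| at in-region het variants exceeds the baseline's by more than
0.15 with rank-sum confirmation at α = 0.01. Regions without a het variant
yield *not evaluable*, which is distinct from negative.

## Surface protein

Cells with total ADT counts below 200 or above 100,000 are dropped
(boundaries kept). Counts are scaled to counts-per-million with a +1
pseudocount and centered-log-ratio (CLR) transformed over all antibody
columns including isotypes, so CLR values sum to zero per cell; denoising
then subtracts each cell's mean isotype CLR from every target CLR, floored
at 0, and drops the isotype columns. This per-cell background subtraction is
a simple, fully specified stand-in for published isotype-based denoising
methods; it removes flat cell-to-cell background shifts exactly
(simulations with doubled background in half the cells leave null-antibody
group means within 0.05) but cannot model antibody-specific background.

Clustering: PCA to 15 components, k = 20 nearest neighbors,
shared-neighbor (Jaccard) edge weights with Seurat-style pruning, and
seeded modularity-based community detection (Leiden with a configurable
resolution; chosen over plain Louvain because it admits a seed and makes
the determinism contract testable). These parameter values are package
choices — published workflows of this kind typically name the algorithm but
not its parameters — and all are config-exposed. Clusters whose
across-antibody variance of mean CLR falls below 0.05 are discarded as
technical artifacts. Annotation applies
first-match marker rules on cluster-mean denoised CLR (per-rule high/low
cutoffs, defaults 2.0/1.3 on the synthetic CLR scale); a required-high
marker absent from the panel fails the rule, a required-low one is vacuous.
Populations drawing > 90% of their cells from one sample are flagged
rare-single-sample and excluded from the six-compartment rollup
(progenitors, immature erythroid, myeloid, T, NK, B).

LISI (local inverse Simpson index) measures per-cell label mixing with a
Gaussian kernel calibrated to a target perplexity (default 30): the index is
the inverse Simpson concentration of the kernel-weighted label distribution,
1 for an isolated label up to the label count for perfect mixing. The
plug-in estimator is biased low when the effective neighborhood is not much
larger than the label count, so mixing diagnostics over many samples need a
proportionally large perplexity: the 28-sample mixing experiment uses
perplexity 500 (~18 per label) on 2,800 cells, where an identically
distributed simulation reads >= 0.9 x 28.

## Compositional testing

Cell-type abundance between two conditions is tested with a
Dirichlet-multinomial log-linear model: `alpha_{s,k} = exp(b0_k + c_s b1_k)`
with the reference population's `b1` fixed at 0. The reference is
auto-selected as the population with the smallest coefficient of variation
of its proportion across samples. Effects are maximum-likelihood estimates
(L-BFGS with analytic gradients). Inclusion probabilities come from a
within-condition bootstrap: the probability that a replicate's effect keeps
the point estimate's sign *and* exceeds the cohort's median absolute effect.
The magnitude gate encodes the sparsity assumption of spike-and-slab
compositional models — most populations are unaffected, so the median
|effect| estimates the null background — and is what keeps a global null
from producing stably-signed small effects. Populations are declared
credible by expected-false-discovery thresholding: the largest
inclusion-ranked set whose mean (1 − inclusion) stays at or below the FDR
(default 0.1). At 6 vs 6 samples of 3,000 cells (concentration 50), 20-seed
experiments measure a null flagged fraction of ~0.09 and detection of a
3-fold depletion in 19–20/20 seeds. This is a compatible reimplementation
of the published Bayesian model's contract (reference category, automatic
reference, FDR-thresholded credibility), not a clone of its MCMC.

The exact small-sample tests are: two-sided Fisher (probability-mass-
at-most-observed convention), Wilcoxon signed-rank with full sign-assignment
enumeration for n <= 25 (tie-tolerant via midranks; the convolution over
doubled ranks is exact), rank-sum with assignment enumeration for combined
n <= 20, Spearman with exact permutation p for n <= 9, and Bonferroni
`min(1, m·p)`. The hand-written exact paths exist because library exact
modes refuse ties; each is verified against an independent brute-force
enumeration oracle in the tests.

## Synthetic cohorts

The default cohort mimics a realistic paired MDS study design: 14
patients, paired samples, ~4,000 cells/sample by default; a 519-amplicon /
53-gene panel and a 42-target + 3-isotype antibody panel (synthetic
stand-ins at the scale of commercial MDS panels, whose real design tables
are proprietary); clone hierarchies of 3–5 mutant clones over recurrent
myeloid genes; symmetric ADO (HET→WT or HET→HOM with probability ½ each,
default rate 10% — typical for targeted single-cell amplicon genotyping);
independent per-call noise (GQ pass rate 0.98, 2% missingness, 0.3% call
errors, negative-binomial depth with mean 40 and dispersion 3 — no
quantitative noise model is published for this platform, so these are
package choices, all config-exposed);
NB amplicon depths with planted copy-number events that also shift germline
het AFs; cell-type-specific ADT means over a shared isotype background; and
three dynamics patterns — shrinkage (mutant clones multiplied by 0.2, WT
absorbing), stable, expansion (a new superset-signature clone at 10%).
The default cohort assigns shrinkage to seven responders, one responder
without callable mutant clones, stable to five nonresponders and expansion
to one — a response structure characteristic of HMA-treated MDS cohorts,
where clonal shrinkage tracks clinical response. Mutant clones are
skewed toward progenitor/erythroid/myeloid compartments, WT cells toward
lymphoid, which drives the genotype x phenotype contrasts.

What the generator does **not** model: doublets, ambient/antibody-specific
ADT background beyond the flat isotype term, read-level errors,
between-patient variability in cell-type composition (each sample draws
cell types i.i.d. from its clone mixes — so cohort-level compositional
contrasts on the default cohort see only multinomial noise plus planted
clone dynamics), segmental CNV boundaries inside a chromosome, or
subclonal CNV fractions. Passing tests therefore demonstrate correct
recovery of the modeled structure, not robustness to every artifact of real
Tapestri data.

## Problem sizes and numerical choices

The verification experiments use: ADO recovery at 2,000 cells × 50 seeds;
clone/phylogeny recovery on noiseless 6-clone hierarchies at 1,500 cells;
dynamics classification at 3,000 cells × 100 seeds per pattern (5% ADO);
ploidy at 3,000 cells × 50 monosomy + 10 trisomy seeds with a 120-amplicon
panel; compositional calibration at 6 vs 6 samples × 20 seeds with 500
bootstraps; and the end-to-end run at 1,500 cells/sample with a 60-amplicon
panel and 100 bootstraps. These sizes keep each experiment's Monte-Carlo
error well inside the asserted tolerances while the full suite stays
desk-scale. Determinism is end-to-end: one seeded generator per cohort, a
seeded PCA/Leiden/bootstrap chain, and byte-identical CSV output across
reruns at a fixed seed.

Degenerate inputs are defined errors, not silent results: zero genotyped
cells for a VAF, no germline variants for ADO, an all-removed cell/amplicon
filter, a too-small diploid baseline, fewer than three samples per condition
level, constant vectors for rank correlation, all-zero paired differences.
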