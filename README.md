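# clonepulse

Clonal architecture and immunophenotype analysis of paired single-cell
DNA + surface-protein bone-marrow samples.

In myelodysplastic syndromes (MDS) treated with a hypomethylating agent
(HMA), the questions that matter are cellular: which mutant clones exist at
diagnosis, how they relate (linear vs branched phylogeny), what happens to
each clone under therapy, and which immunophenotypic populations carry the
mutations. Tapestri-style platforms answer these with three matrices per
sample — cell x variant genotype calls, cell x amplicon read counts, and
cell x antibody (ADT) counts. `clonepulse` is the analysis layer over those
matrices, aimed at analysts working with paired diagnosis / post-treatment
targeted single-cell data, and it ships a ground-truth-generating simulator
so every stage is testable without access to patient data.

The pipeline:

* **Genotype QC and allele dropout (ADO).** Strict per-call (GQ > 30,
  DP > 10, AF > 20%), per-variant (genotyped > 50%, mutated >= 1%,
  nonsynonymous/splicing, MAF <= 0.01 unless bulk-whitelisted) and per-cell
  (>= 50% genotyped) filters. ADO is estimated from germline heterozygous
  variants (mutated in >= 92% of cells at both timepoints, VAF-by-cell-count
  in [49.2, 52.7]) as `100·(n_WT + n_HOM)/n_genotyped`, averaged over the
  five variants nearest VAF 50.
* **Clones and phylogeny.** Clones are cells with identical
  variant→zygosity signatures; dropout-artifact clones (one HET→WT/HET→HOM
  step from a larger clone, within `parent × ADO × 1.5`) are merged back. The
  phylogeny is the mutation-set-inclusion order with zygosity progression,
  rooted at WT. Clone statistics: Shannon diversity `H = −Σ pᵢ ln pᵢ` over
  mutant-clone fractions, predominant-clone fraction, CHIP flags
  (TET2/DNMT3A/ASXL1 core, +SF3B1/TP53, or driver VAF > 2%).
* **Clonal dynamics.** Paired timepoints are classified as shrinkage
  (every mutant clone below 0.5x its diagnosis fraction, no new clones),
  expansion (a new clone >= 2% or a doubling minority clone), or stable.
* **Copy number.** Amplicon counts are normalized per cell total and per
  amplicon mean; clone ploidy is `2·median(clone)/median(WT)` per amplicon
  with loss/gain calls at 1.5/2.5, plus CNV-clone detection from
  heterozygous-VAF shifts (deletion → AF toward 0/1, gain → 1/3 or 2/3).
* **Immunophenotype.** ADT QC (totals in [200, 100000]), CPM+1 + CLR
  normalization, isotype-background subtraction, PCA → SNN graph → seeded
  modularity clustering, marker-rule annotation into populations and six
  compartments, and LISI sample-mixing diagnostics.
* **Statistics.** A Dirichlet-multinomial compositional test with automatic
  reference selection and FDR-thresholded credibility (default 0.1), plus
  exact two-sided Fisher, exact (tie-tolerant) Wilcoxon signed-rank and
  rank-sum, Spearman, and Bonferroni correction.
* **Integration.** Clone x annotation joins, mutant fractions by compartment
  (pooled progenitor/erythroid/myeloid vs lymphoid), per-gene lineage
  enrichment, and compositional dynamics of mutant vs WT partitions.

See `docs/methods.md` for model details, defaults, and limitations.

## Worked example

One simulated patient (2,000 cells/sample, 10% allele dropout, a
three-clone hierarchy that shrinks under therapy):

```python
from clonepulse import (single_patient_config, simulate_cohort,
                        filter_genotype_calls, select_germline_het, ado_rate,
                        filter_variants, filter_cells, call_clones,
                        flag_ado_clones, classify_dynamics, clone_stats)

cfg = single_patient_config("shrinkage", n_cells=2000, ado_rate=0.10, seed=7)
cohort, truth = simulate_cohort(cfg)

dx = filter_genotype_calls(cohort.get("P01", "diagnosis").genotype)
post = filter_genotype_calls(cohort.get("P01", "post_treatment").genotype)
ado = ado_rate(dx, post, select_germline_het(dx, post))
print(f"sample ADO: {ado.sample_ado:.1f}% from {len(ado.variants_used)} germline variants")

clone_sets = {}
for tp, gm in (("diagnosis", dx), ("post_treatment", post)):
    kept, _, _ = filter_variants(gm)
    gm = filter_cells(kept)
    wl = {r.name for r in gm.variants if r.whitelisted}
    clone_sets[tp] = flag_ado_clones(call_clones(gm, whitelist=wl), ado)

stats = clone_stats(clone_sets["diagnosis"])
print(f"diagnosis: {stats['n_mutant_clones']} mutant clones, "
      f"Shannon H = {stats['shannon']:.3f}, "
      f"predominant fraction = {stats['predominant_fraction']:.2f}")
call = classify_dynamics(clone_sets["diagnosis"], clone_sets["post_treatment"])
print(f"dynamics: {call.pattern} "
      f"(mutant fraction {call.mutant_fraction['diagnosis']:.2f} -> "
      f"{call.mutant_fraction['post_treatment']:.2f})")
```

Output:

```
sample ADO: 10.0% from 5 germline variants
diagnosis: 3 mutant clones, Shannon H = 1.006, predominant fraction = 0.48
dynamics: shrinkage (mutant fraction 0.50 -> 0.09)
```

The estimator reads back the planted 10% dropout; the three-clone hierarchy
and its near-even diversity (H close to ln 3 ≈ 1.10) are recovered; and the
therapy response registers as shrinkage, with the mutant cell fraction
collapsing from 50% to 9%.

For a whole cohort there is a one-shot driver (`run_pipeline`, or
`clonepulse run` from the shell) that writes per-stage CSV tables — patient
summaries with clone counts, diversity, dynamics pattern and CHIP flags, a
fishplot-layout clone-fraction table, ploidy calls, annotations, and
compositional results — plus a JSON run log.

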