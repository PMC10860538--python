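"""Genotype x immunophenotype integration and the end-to-end pipeline.

Joins clone assignments with cell annotations on barcodes, computes
mutant-cell distribution across immune compartments (pooled
progenitor/erythroid/myeloid versus lymphoid), per-gene lineage enrichment,
mutant-partition compositional dynamics, and drives the full analysis:
QC -> ADO -> clones -> dynamics -> ploidy -> protein -> composition ->
integration, writing tidy CSV tables and a machine-readable run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clonal_architecture import (
    Clone, CloneSet, build_phylogeny, call_clones, chip_flags,
    classify_dynamics, clone_gene_attribution, clone_stats, flag_ado_clones,
)
from .cnv_ploidy import PloidyError, compute_ploidy, filter_amplicons, normalize_reads
from .core_io import CohortTable, Sample
from .protein_phenotype import (
    MarkerRule, annotate, cluster_cells, default_marker_rules,
    denoise_isotypes, drop_artifact_clusters, lisi, normalize_clr,
    qc_adt_cells,
)
from .stats_composition import (
    CompositionInput, CompositionResult, StatsError, bonferroni,
    composition_test, fisher_exact, wilcoxon_signed_rank,
)
from .variant_qc import (
    QCThresholds, ado_rate, filter_cells, filter_genotype_calls,
    filter_variants, select_germline_het,
)

logger = logging.getLogger("clonepulse")

MYELOID_POOL = ("progenitors", "immature_erythroid", "myeloid")
LYMPHOID_POOL = ("T", "NK", "B")


# ---------------------------------------------------------------------------
# joining modalities
# ---------------------------------------------------------------------------


def join_modalities(clone_set: CloneSet, annotation: pd.DataFrame
                    ) -> pd.DataFrame:
    """Inner-join clone assignments with cell annotations on barcode.

    ``annotation`` needs columns barcode, population, compartment. Output
    rows carry clone_id, n_mutations (distinct mutated variants in the
    clone's signature), mutant_flag, population and compartment; cells
    assigned only in one modality are dropped and counted.
    """
    rows = []
    for clone in clone_set.clones:
        if clone.clone_id == "minor":
            continue  # heterogeneous pool: no single signature
        n_mut = len(clone.signature)
        for b in clone.barcodes:
            rows.append((b, clone.clone_id, n_mut))
    dna = pd.DataFrame(rows, columns=["barcode", "clone_id", "n_mutations"])
    merged = dna.merge(annotation[["barcode", "population", "compartment"]],
                       on="barcode", how="inner")
    if merged.empty:
        raise ValueError("no shared barcodes between clones and annotations")
    n_dna_only = len(dna) - len(merged)
    n_prot_only = len(annotation) - len(merged)
    logger.info("join: %d cells kept, %d DNA-only, %d protein-only dropped",
                len(merged), n_dna_only, n_prot_only)
    merged["mutant_flag"] = merged["n_mutations"] > 0
    return merged


# ---------------------------------------------------------------------------
# compartment analyses
# ---------------------------------------------------------------------------


def mutant_fraction_by_compartment(integrated: pd.DataFrame
                                   ) -> tuple[pd.DataFrame, float | None]:
    """Mutant fraction in pooled Pro/Ery/Mye vs lymphoid per patient.

    ``integrated`` needs a patient column. Returns the per-patient fraction
    table and the paired signed-rank p across patients (None when fewer than
    two patients contribute both compartments).
    """
    if "patient" not in integrated.columns:
        raise ValueError("integrated table needs a 'patient' column")
    rows = []
    for patient, grp in integrated.groupby("patient"):
        mye = grp[grp["compartment"].isin(MYELOID_POOL)]
        lym = grp[grp["compartment"].isin(LYMPHOID_POOL)]
        if len(mye) == 0 or len(lym) == 0:
            logger.info("patient %s: empty compartment, excluded from test",
                        patient)
            continue
        rows.append({
            "patient": patient,
            "mutant_fraction_pro_ery_mye": mye["mutant_flag"].mean(),
            "mutant_fraction_lymphoid": lym["mutant_flag"].mean(),
        })
    table = pd.DataFrame(rows)
    p = None
    if len(table) >= 2:
        diff = (table["mutant_fraction_pro_ery_mye"]
                - table["mutant_fraction_lymphoid"])
        if (diff != 0).any():
            p = wilcoxon_signed_rank(diff.to_numpy())
    return table, p


def gene_lineage_enrichment(integrated: pd.DataFrame,
                            clone_genes: dict[tuple[str, str], set[str]],
                            ) -> pd.DataFrame:
    """Per-gene Fisher test of mutant/WT x Pro_Ery_Mye/lymphoid cells.

    ``clone_genes`` maps (patient, clone_id) to the clone's mutated genes.
    For each gene, cells from patients carrying it are cross-tabulated as
    mutant-for-the-gene vs WT against pooled myeloid-lineage vs lymphoid
    compartments; p values are Bonferroni-adjusted over genes tested.
    """
    genes = sorted({g for gs in clone_genes.values() for g in gs})
    rows = []
    for gene in genes:
        carriers = {pat for (pat, _cid), gs in clone_genes.items()
                    if gene in gs}
        sub = integrated[integrated["patient"].isin(carriers)
                         & integrated["compartment"].isin(
                             MYELOID_POOL + LYMPHOID_POOL)].copy()
        if sub.empty:
            continue
        sub["gene_mut"] = [
            gene in clone_genes.get((pat, cid), set())
            for pat, cid in zip(sub["patient"], sub["clone_id"])]
        sub["pool"] = np.where(sub["compartment"].isin(MYELOID_POOL),
                               "pro_ery_mye", "lymphoid")
        a = int((sub["gene_mut"] & (sub["pool"] == "pro_ery_mye")).sum())
        b = int((sub["gene_mut"] & (sub["pool"] == "lymphoid")).sum())
        c = int((~sub["gene_mut"] & (sub["pool"] == "pro_ery_mye")).sum())
        d = int((~sub["gene_mut"] & (sub["pool"] == "lymphoid")).sum())
        if a + b == 0:
            continue
        p = fisher_exact([[a, b], [c, d]])
        mut_rate_mye = a / (a + c) if a + c else 0.0
        mut_rate_lym = b / (b + d) if b + d else 0.0
        rows.append({"gene": gene, "mut_pro_ery_mye": a, "mut_lymphoid": b,
                     "wt_pro_ery_mye": c, "wt_lymphoid": d, "p": p,
                     "enriched_in": ("pro_ery_mye"
                                     if mut_rate_mye >= mut_rate_lym
                                     else "lymphoid")})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adjusted"] = bonferroni(out["p"].to_numpy())
    return out


def mutant_population_dynamics(per_sample: pd.DataFrame, *, fdr: float = 0.1,
                               n_boot: int = 500, seed: int = 0,
                               min_samples: int = 3
                               ) -> dict[str, CompositionResult]:
    """Compositional tests on mutant and WT cell partitions.

    ``per_sample`` holds one row per cell with columns patient, timepoint,
    response, population, mutant_flag. Runs the compositional test on the
    mutant and WT partitions comparing timepoints within responders (and
    nonresponders) and comparing response groups at each timepoint; contrasts
    lacking enough samples are skipped with a log line.
    """
    results: dict[str, CompositionResult] = {}

    def run(name: str, sub: pd.DataFrame, by: str) -> None:
        counts = (sub.groupby(["patient", "timepoint", "response",
                               "population"])
                  .size().unstack(fill_value=0))
        meta = counts.index.to_frame(index=False)
        counts.index = range(len(counts))
        cond = meta[by]
        keep = counts.sum(axis=1) > 0
        counts, cond = counts[keep], cond[keep]
        try:
            data = CompositionInput(counts=counts, condition=cond)
            results[name] = composition_test(data, fdr=fdr, n_boot=n_boot,
                                             seed=seed)
        except StatsError as exc:
            logger.info("composition contrast %s skipped: %s", name, exc)

    for partition, flag in (("mutant", True), ("wt", False)):
        part = per_sample[per_sample["mutant_flag"] == flag]
        if part.empty:
            continue
        for resp in ("responder", "nonresponder"):
            sub = part[part["response"] == resp]
            if not sub.empty:
                run(f"{partition}_{resp}_timepoint", sub, "timepoint")
        for tp in ("diagnosis", "post_treatment"):
            sub = part[part["timepoint"] == tp]
            if not sub.empty:
                run(f"{partition}_{tp}_response", sub, "response")
    return results


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    marker_rules: list[MarkerRule] = field(default_factory=default_marker_rules)
    shrink_factor: float = 0.5
    new_clone_min: float = 0.02
    ado_safety_factor: float = 1.5
    fdr: float = 0.1
    n_boot: int = 200
    cluster_resolution: float = 1.0
    n_components: int = 15
    knn: int = 20
    lisi_perplexity: float = 30.0
    min_baseline_cells: int = 50
    seed: int = 0


def _qc_patient_pair(dx: Sample, post: Sample, cfg: PipelineConfig):
    """Call-filter both timepoints, estimate ADO, variant+cell filter on the
    union of kept variants (the paired samples are analyzed jointly)."""
    dx_calls = filter_genotype_calls(dx.genotype, cfg.thresholds)
    post_calls = filter_genotype_calls(post.genotype, cfg.thresholds)
    germline = select_germline_het(dx_calls, post_calls)
    ado = ado_rate(dx_calls, post_calls, germline) if germline else None

    kept_names: set[str] = set()
    filtered = {}
    for tp, gm in (("diagnosis", dx_calls), ("post_treatment", post_calls)):
        kept, _reported, _dropped = filter_variants(gm, cfg.thresholds)
        filtered[tp] = gm
        kept_names |= {rec.name for rec in kept.variants}
    out = {}
    for tp, gm in filtered.items():
        idx = [j for j, rec in enumerate(gm.variants)
               if rec.name in kept_names]
        sub = gm.subset(variants=np.array(idx, dtype=int))
        out[tp] = filter_cells(sub, cfg.thresholds) if idx else sub
    return out["diagnosis"], out["post_treatment"], ado, germline


def _merge_clone_sets(dx: CloneSet, post: CloneSet) -> CloneSet:
    """Union of both timepoints' clones, matched by signature."""
    merged: dict = {}
    for cs in (dx, post):
        for clone in cs.clones:
            if clone.clone_id == "minor":
                continue
            if clone.key in merged:
                merged[clone.key].barcodes.extend(clone.barcodes)
            else:
                merged[clone.key] = Clone(clone.clone_id,
                                          dict(clone.signature),
                                          list(clone.barcodes))
    gene_map = {**dx.gene_map, **post.gene_map}
    return CloneSet(list(merged.values()),
                    unassigned=dx.unassigned + post.unassigned,
                    gene_map=gene_map)


def run_pipeline(cohort: CohortTable, outdir: str | Path,
                 cfg: PipelineConfig | None = None) -> dict[str, pd.DataFrame]:
    """Execute the full analysis and write per-stage CSV tables.

    Returns the report tables; every artifact is also written under
    ``outdir``. Deterministic given ``cfg.seed``.
    """
    cfg = cfg or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    paired = cohort.paired_patients
    if not paired:
        raise ValueError("pipeline requires at least one paired patient")

    clone_rows, ado_rows, summary_rows, ploidy_rows = [], [], [], []
    dna_cells = []  # per-cell clone assignment with sample keys
    clone_genes: dict[tuple[str, str], set[str]] = {}

    for patient in paired:
        dx_s = cohort.get(patient, "diagnosis")
        post_s = cohort.get(patient, "post_treatment")
        dx_gm, post_gm, ado, _germ = _qc_patient_pair(dx_s, post_s, cfg)

        wl_names = {rec.name for rec in dx_gm.variants if rec.whitelisted}
        sets = {}
        for tp, gm in (("diagnosis", dx_gm), ("post_treatment", post_gm)):
            cs = call_clones(gm, whitelist=wl_names)
            if ado is not None:
                cs = flag_ado_clones(cs, ado,
                                     safety_factor=cfg.ado_safety_factor)
            sets[tp] = cs
        dyn = classify_dynamics(sets["diagnosis"], sets["post_treatment"],
                                shrink_factor=cfg.shrink_factor,
                                new_clone_min=cfg.new_clone_min)

        merged = _merge_clone_sets(sets["diagnosis"], sets["post_treatment"])
        phylo = build_phylogeny(merged)
        attribution = clone_gene_attribution(phylo)
        stats_dx = clone_stats(sets["diagnosis"])

        for clone in merged.clones:
            clone_genes[(patient, clone.clone_id)] = clone.genes(
                merged.gene_map)

        for tp, cs in sets.items():
            fr = cs.fractions_of_all()
            id_by_key = {c.key: c.clone_id for c in merged.clones}
            for clone in cs.clones:
                if clone.clone_id == "minor":
                    continue
                cid = id_by_key.get(clone.key, clone.clone_id)
                clone_rows.append({
                    "patient": patient, "clone_id": cid, "timepoint": tp,
                    "fraction": fr[clone.clone_id],
                    "n_cells": clone.n_cells,
                    "signature": ";".join(
                        f"{k}:{v}" for k, v in sorted(clone.signature.items())),
                })
                for b in clone.barcodes:
                    dna_cells.append((patient, tp, b, cid,
                                      len(clone.signature)))

        if ado is not None:
            ado_rows.append({"patient": patient,
                             "sample_ado_percent": ado.sample_ado,
                             "n_variants_used": len(ado.variants_used)})

        # ploidy vs the WT diploid baseline, diagnosis sample
        wt = sets["diagnosis"].wt_clone
        try:
            filtered_amp = filter_amplicons(dx_s.amplicon)
            normalized, filtered_amp = normalize_reads(filtered_amp)
            memberships = {c.clone_id: c.barcodes
                           for c in sets["diagnosis"].clones
                           if c.clone_id != "minor"}
            ptab = compute_ploidy(normalized, filtered_amp, memberships,
                                  baseline=wt.clone_id if wt else "WT",
                                  min_baseline_cells=cfg.min_baseline_cells)
            calls = ptab.region_calls
            calls.insert(0, "patient", patient)
            ploidy_rows.append(calls)
        except PloidyError as exc:
            logger.warning("patient %s: ploidy skipped (%s)", patient, exc)

        chip = {}
        pred_id = attribution["predominant_clone"]
        if pred_id is not None:
            pred = phylo.clones[pred_id]
            chip = {f"chip_{d}_predominant":
                    chip_flags(pred, d, merged.gene_map)
                    for d in ("core3", "core5")}
        summary_rows.append({
            "patient": patient,
            "response": dx_s.meta.response,
            "n_mutant_clones_dx": stats_dx["n_mutant_clones"],
            "shannon_dx": stats_dx["shannon"],
            "predominant_fraction_dx": stats_dx["predominant_fraction"],
            "topology": phylo.topology,
            "n_conflicts": len(phylo.conflicts),
            "dynamics_pattern": dyn.pattern,
            "mutant_fraction_dx": dyn.mutant_fraction["diagnosis"],
            "mutant_fraction_post": dyn.mutant_fraction["post_treatment"],
            "predominant_fraction_post":
                dyn.predominant_fraction["post_treatment"],
            "sample_ado_percent": ado.sample_ado if ado else None,
            "first_clone_genes": ";".join(sorted(attribution["first_clone_genes"])),
            "predominant_clone_genes":
                ";".join(sorted(attribution["predominant_clone_genes"])),
            **chip,
        })

    summary = pd.DataFrame(summary_rows)

    # dynamics x response association (patients without mutant clones excluded)
    callable_ = summary[summary["n_mutant_clones_dx"] > 0]
    shrink = callable_["dynamics_pattern"] == "shrinkage"
    resp = callable_["response"] == "responder"
    dyn_table = [[int((shrink & resp).sum()), int((shrink & ~resp).sum())],
                 [int((~shrink & resp).sum()), int((~shrink & ~resp).sum())]]
    dynamics_fisher_p = fisher_exact(dyn_table) if callable_.shape[0] else None

    # --- protein stage on the pooled cohort -------------------------------
    adt_parts, sample_labels, meta_rows = [], [], {}
    for s in cohort.samples:
        adt = qc_adt_cells(s.adt)
        adt_parts.append(adt)
        sample_labels.extend([f"{s.meta.patient_id}_{s.meta.timepoint}"]
                             * adt.n_cells)
        meta_rows[f"{s.meta.patient_id}_{s.meta.timepoint}"] = s.meta
    from .core_io import ADTMatrix
    pooled = ADTMatrix(
        np.concatenate([a.barcodes for a in adt_parts]),
        adt_parts[0].antibodies,
        np.vstack([a.counts for a in adt_parts]),
    )
    norm = denoise_isotypes(normalize_clr(pooled))
    labels = cluster_cells(norm, n_components=cfg.n_components, k=cfg.knn,
                           resolution=cfg.cluster_resolution, seed=cfg.seed)
    labels = drop_artifact_clusters(norm, labels)
    annotation = annotate(norm, labels, cfg.marker_rules,
                          sample_of_cell=np.asarray(sample_labels))
    ann = annotation.table.copy()
    ann["sample"] = sample_labels

    from sklearn.decomposition import PCA
    emb = PCA(n_components=min(cfg.n_components, norm.values.shape[1]),
              random_state=cfg.seed).fit_transform(norm.values)
    try:
        lisi_res = lisi(emb, np.asarray(sample_labels),
                        perplexity=cfg.lisi_perplexity)
        lisi_df = pd.DataFrame({
            "metric": ["mean_lisi", "median_lisi", "n_samples"],
            "value": [lisi_res.mean, lisi_res.median,
                      len(set(sample_labels))]})
    except Exception as exc:  # tiny cohorts cannot support the perplexity
        logger.warning("LISI skipped: %s", exc)
        lisi_df = pd.DataFrame({"metric": [], "value": []})

    # --- integration ------------------------------------------------------
    dna_df = pd.DataFrame(dna_cells, columns=["patient", "timepoint",
                                              "barcode", "clone_id",
                                              "n_mutations"])
    integrated = dna_df.merge(
        ann[["barcode", "population", "compartment", "sample"]],
        on="barcode", how="inner")
    integrated["mutant_flag"] = integrated["n_mutations"] > 0
    integrated["response"] = [meta_rows[s].response
                              for s in integrated["sample"]]

    dx_int = integrated[integrated["timepoint"] == "diagnosis"]
    compartment_table, compartment_p = mutant_fraction_by_compartment(dx_int)
    enrichment = gene_lineage_enrichment(dx_int, clone_genes)
    comp_results = mutant_population_dynamics(
        integrated, fdr=cfg.fdr, n_boot=cfg.n_boot, seed=cfg.seed)

    comp_rows = []
    for contrast, res in comp_results.items():
        t = res.table.copy()
        t.insert(0, "contrast", contrast)
        t["reference"] = res.reference
        comp_rows.append(t)
    composition = (pd.concat(comp_rows, ignore_index=True)
                   if comp_rows else pd.DataFrame())

    report = {
        "patient_summary": summary,
        "fishplot": pd.DataFrame(clone_rows),
        "ado": pd.DataFrame(ado_rows),
        "ploidy_calls": (pd.concat(ploidy_rows, ignore_index=True)
                         if ploidy_rows else pd.DataFrame()),
        "annotation": ann,
        "lisi": lisi_df,
        "compartment_fractions": compartment_table,
        "gene_lineage_enrichment": enrichment,
        "composition": composition,
    }
    for name, df in report.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    run_log = {
        "version": __version__,
        "seed": cfg.seed,
        "n_samples": len(cohort.samples),
        "n_paired_patients": len(paired),
        "dynamics_fisher_p": dynamics_fisher_p,
        "compartment_wilcoxon_p": compartment_p,
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2,
                                                    sort_keys=True))
    report["run_log"] = pd.DataFrame([run_log])
    return report
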