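"""Synthetic Tapestri-style cohorts with known ground truth.

Generates paired (diagnosis / post-treatment) bone-marrow samples that mimic
the statistical structure of targeted single-cell DNA + ADT sequencing in
myelodysplastic syndromes treated with a hypomethylating agent:

* clonal genotype signatures with zygosity and a known phylogeny,
* symmetric allele dropout (HET -> WT or HOM with equal probability),
* per-call depth / genotype-quality / alt-fraction noise,
* negative-binomial amplicon depths with planted copy-number events,
* cell-type-specific ADT means over a shared isotype background,
* two-timepoint clone-proportion dynamics (shrinkage / stable / expansion).

Every generated quantity is recorded in a :class:`TruthBundle` so downstream
estimators can be scored against ground truth without any external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    GT_HET, GT_HOM, GT_MISSING, GT_WT,
    ADTMatrix, Amplicon, AmpliconCountMatrix, Antibody, CohortTable,
    GenotypeMatrix, Sample, SampleMeta, VariantRecord,
)

logger = logging.getLogger("clonepulse")

DYNAMICS_PATTERNS = ("shrinkage", "stable", "expansion")

# ---------------------------------------------------------------------------
# study-scale panel and antibody definitions
# ---------------------------------------------------------------------------

# 53 genes recurrently mutated in myeloid malignancies, with (GRCh37-style)
# chromosome assignments used to lay out synthetic amplicons.
PANEL_GENES: dict[str, str] = {
    "TET2": "chr4", "DNMT3A": "chr2", "ASXL1": "chr20", "SF3B1": "chr2",
    "TP53": "chr17", "RUNX1": "chr21", "U2AF1": "chr21", "BCOR": "chrX",
    "EZH2": "chr7", "ZRSR2": "chrX", "STAG2": "chrX", "NRAS": "chr1",
    "IDH1": "chr2", "IDH2": "chr15", "PHF6": "chrX", "PTEN": "chr10",
    "NF1": "chr17", "CUX1": "chr7", "SRSF2": "chr17", "JAK2": "chr9",
    "CBL": "chr11", "KRAS": "chr12", "SETBP1": "chr18", "ETV6": "chr12",
    "GATA2": "chr3", "CEBPA": "chr19", "FLT3": "chr13", "KIT": "chr4",
    "NPM1": "chr5", "WT1": "chr11", "CALR": "chr19", "MPL": "chr1",
    "CSF3R": "chr1", "PPM1D": "chr17", "RAD21": "chr8", "SMC1A": "chrX",
    "SMC3": "chr10", "BRAF": "chr7", "PTPN11": "chr12", "GNAS": "chr20",
    "GNB1": "chr1", "KDM6A": "chrX", "BCORL1": "chrX", "LUC7L2": "chr7",
    "DDX41": "chr5", "ETNK1": "chr12", "SH2B3": "chr12", "CTCF": "chr16",
    "RIT1": "chr1", "MYD88": "chr3", "PIGA": "chrX", "STAT3": "chr17",
    "ATRX": "chrX",
}

N_STUDY_AMPLICONS = 519

# 42 surface targets + 3 isotype controls, TotalSeq-style heme panel.
ADT_TARGETS = [
    "CD3", "CD4", "CD8", "CD19", "CD20", "CD22", "CD34", "CD38", "CD45",
    "CD45RA", "CD45RO", "CD56", "CD71", "CD117", "CD123", "CD11b", "CD11c",
    "CD13", "CD14", "CD15", "CD16", "CD33", "CD64", "CD68", "CD2", "CD5",
    "CD7", "CD10", "CD25", "CD30", "CD49d", "CD62P", "CD69", "CD83", "CD90",
    "CD138", "CD163", "CD1c", "CD303", "HLA-DR", "CD235a", "CD44",
]
ADT_ISOTYPES = ["IgG1-iso", "IgG2a-iso", "IgG2b-iso"]


def study_panel() -> list[Amplicon]:
    """A synthetic 519-amplicon panel over the 53 myeloid genes.

    Synthetic stand-in for a commercial MDS targeted-DNA panel design
    (real design tables are vendor-proprietary); the gene count, amplicon
    count and BED-style layout match the scale of published panels.
    """
    genes = list(PANEL_GENES)
    per_gene = [10] * 42 + [9] * 11  # 42*10 + 11*9 = 519
    assert sum(per_gene) == N_STUDY_AMPLICONS and len(per_gene) == len(genes)
    amplicons = []
    for g_idx, (gene, n_amp) in enumerate(zip(genes, per_gene)):
        base = 1_000_000 * (g_idx + 1)
        for k in range(n_amp):
            start = base + 300 * k
            amplicons.append(Amplicon(
                amplicon_id=f"AMPL_{gene}_{k + 1:02d}",
                chrom=PANEL_GENES[gene], start=start, end=start + 250,
                gene=gene,
            ))
    return amplicons


def study_antibodies() -> list[Antibody]:
    """The 42-target + 3-isotype synthetic ADT panel."""
    return ([Antibody(n, False) for n in ADT_TARGETS]
            + [Antibody(n, True) for n in ADT_ISOTYPES])


# ---------------------------------------------------------------------------
# cell types and ADT means
# ---------------------------------------------------------------------------

#: population -> major compartment rollup
CELLTYPE_COMPARTMENT = {
    "HSPC": "progenitors",
    "CMP": "progenitors",
    "erythroid_immature": "immature_erythroid",
    "monocyte": "myeloid",
    "nc_monocyte": "myeloid",
    "granulocyte": "myeloid",
    "T": "T",
    "NK": "NK",
    "B": "B",
    "rare_cd11c": "rare",
}

_BASELINE_ADT_MEAN = 5.0

# marker means per population; antibodies not listed sit at baseline
ADT_PROFILES: dict[str, dict[str, float]] = {
    "HSPC": {"CD34": 600, "CD90": 300, "CD117": 200, "CD45": 150,
             "HLA-DR": 200, "CD13": 100, "CD33": 80, "CD38": 30},
    "CMP": {"CD34": 500, "CD38": 300, "CD123": 150, "CD117": 250,
            "CD45": 150, "HLA-DR": 250, "CD33": 150, "CD13": 150},
    "erythroid_immature": {"CD71": 700, "CD235a": 400, "CD117": 80,
                           "CD45": 30},
    "monocyte": {"CD14": 600, "CD11b": 500, "CD33": 400, "CD64": 300,
                 "CD4": 80, "CD45": 400, "HLA-DR": 300, "CD13": 200,
                 "CD68": 150, "CD163": 120},
    "nc_monocyte": {"CD16": 500, "CD14": 60, "CD11b": 400, "CD33": 250,
                    "HLA-DR": 350, "CD45": 400},
    "granulocyte": {"CD15": 500, "CD11b": 450, "CD16": 300, "CD13": 250,
                    "CD33": 200, "CD45": 250},
    "T": {"CD3": 700, "CD2": 300, "CD5": 300, "CD7": 350, "CD45": 500,
          "CD4": 200, "CD8": 200, "CD45RO": 150},
    "NK": {"CD56": 600, "CD16": 350, "CD7": 300, "CD2": 200, "CD45": 450},
    "B": {"CD19": 600, "CD20": 500, "CD22": 300, "CD45": 450,
          "HLA-DR": 300, "CD10": 50},
    "rare_cd11c": {"CD11c": 500, "CD45": 400, "CD49d": 400, "CD62P": 400},
}

#: cell-type mix of the wild-type (unmutated) clone
WT_CELLTYPE_MIX = {
    "HSPC": 0.04, "CMP": 0.05, "erythroid_immature": 0.12, "monocyte": 0.14,
    "nc_monocyte": 0.04, "granulocyte": 0.16, "T": 0.25, "NK": 0.08,
    "B": 0.12,
}
#: mutant clones are skewed toward progenitor/erythroid/myeloid compartments
MUTANT_CELLTYPE_MIX = {
    "HSPC": 0.14, "CMP": 0.14, "erythroid_immature": 0.18, "monocyte": 0.18,
    "nc_monocyte": 0.05, "granulocyte": 0.21, "T": 0.06, "NK": 0.02,
    "B": 0.02,
}


def adt_mean_table(antibodies: list[Antibody] | None = None,
                   isotype_background: float = 20.0) -> pd.DataFrame:
    """Cell-type x antibody expected-count table (background excluded)."""
    antibodies = antibodies or study_antibodies()
    rows = {}
    for ct, profile in ADT_PROFILES.items():
        rows[ct] = [0.0 if ab.is_isotype
                    else profile.get(ab.name, _BASELINE_ADT_MEAN)
                    for ab in antibodies]
    return pd.DataFrame(rows, index=[ab.name for ab in antibodies]).T


# ---------------------------------------------------------------------------
# simulation specs
# ---------------------------------------------------------------------------


@dataclass
class CloneSpec:
    """Ground-truth clone: signature, ancestry, CNVs, proportions, mix."""

    clone_id: str
    signature: dict[str, int] = field(default_factory=dict)  # variant name -> GT_HET/GT_HOM
    parent_id: str | None = None
    cnv_events: list[tuple[str, int, int, int]] = field(default_factory=list)
    # (chrom, start, end, copies in {1,2,3})
    proportions: dict[str, float] = field(default_factory=dict)  # timepoint -> frac
    celltype_mix: dict[str, float] = field(default_factory=dict)

    @property
    def is_wt(self) -> bool:
        return not self.signature


@dataclass
class PatientSim:
    patient_id: str
    response: str  # responder | nonresponder
    clones: list[CloneSpec]  # diagnosis proportions live in CloneSpec.proportions
    dynamics_pattern: str = "stable"
    expansion_variant: str | None = None  # somatic variant acquired post-treatment


@dataclass
class SimConfig:
    """All noise-model and scale parameters of the generator.

    Defaults reflect a realistic paired MDS cohort: ~4,000 QC-scale cells
    per sample,
    a 10% symmetric allele-dropout rate typical for targeted single-cell
    amplicon genotyping, negative-binomial amplicon depths, and a flat
    shared isotype ADT background.
    """

    patients: list[PatientSim] = field(default_factory=list)
    variants: list[VariantRecord] = field(default_factory=list)
    germline_het: list[str] = field(default_factory=list)  # variant names
    n_cells: int = 4000
    ado_rate: float = 0.10
    genotype_error_rate: float = 0.003
    missing_rate: float = 0.02
    depth_mean: float = 40.0
    depth_dispersion: float = 3.0
    gq_pass_rate: float = 0.98
    amplicons: list[Amplicon] | None = None  # None -> study_panel()
    antibodies: list[Antibody] | None = None  # None -> study_antibodies()
    isotype_background: float = 20.0
    adt_dispersion: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in (("ado_rate", self.ado_rate),
                           ("genotype_error_rate", self.genotype_error_rate),
                           ("missing_rate", self.missing_rate),
                           ("gq_pass_rate", self.gq_pass_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name}={rate} outside [0, 1]")
        if self.depth_mean <= 0 or self.isotype_background < 0:
            raise ValueError("depth/background means must be positive")


@dataclass
class TruthBundle:
    """Everything the generator decided, for scoring estimators against."""

    cells: pd.DataFrame  # patient, timepoint, barcode, clone_id, cell_type
    clone_signatures: dict[tuple[str, str], dict[str, int]]
    proportions: pd.DataFrame  # patient, timepoint, clone_id, fraction
    ado_rate: float
    cnv_events: pd.DataFrame  # patient, clone_id, chrom, start, end, copies
    dynamics: dict[str, str]  # patient -> pattern


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def simulate_dynamics(pattern: str, base: dict[str, float], *,
                      shrink_factor: float = 0.2,
                      new_clone_fraction: float = 0.10,
                      wt_clone_id: str = "WT",
                      new_clone_id: str = "NEW",
                      ) -> tuple[dict[str, float], dict[str, float]]:
    """Derive post-treatment clone proportions from diagnosis proportions.

    ``shrinkage`` multiplies every mutant clone by ``shrink_factor`` (< 0.5)
    and lets the WT clone absorb the difference; ``stable`` copies the input;
    ``expansion`` introduces a new clone (key ``new_clone_id``) at
    ``new_clone_fraction`` taken from the WT clone.
    """
    if pattern not in DYNAMICS_PATTERNS:
        raise ValueError(f"unknown dynamics pattern {pattern!r}")
    total = sum(base.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"diagnosis proportions sum to {total}, not 1")
    dx = dict(base)
    if pattern == "stable":
        return dx, dict(base)
    if pattern == "shrinkage":
        if not 0.0 < shrink_factor < 0.5:
            raise ValueError("shrink_factor must lie in (0, 0.5)")
        post = {}
        for cid, frac in base.items():
            post[cid] = frac if cid == wt_clone_id else frac * shrink_factor
        post[wt_clone_id] = 1.0 - sum(v for k, v in post.items()
                                      if k != wt_clone_id)
        return dx, post
    # expansion
    if base.get(wt_clone_id, 0.0) <= new_clone_fraction:
        raise ValueError("WT clone too small to source the new clone")
    post = dict(base)
    post[wt_clone_id] -= new_clone_fraction
    post[new_clone_id] = new_clone_fraction
    return dx, post


# ---------------------------------------------------------------------------
# default cohort builders
# ---------------------------------------------------------------------------


def _somatic_variant(gene: str, idx: int, consequence: str = "missense",
                     whitelisted: bool = False) -> VariantRecord:
    chrom = PANEL_GENES.get(gene, "chr1")
    return VariantRecord(chrom=chrom, pos=1_000_000 + 1000 * idx, ref="C",
                         alt="T", gene=gene, consequence=consequence,
                         population_maf=None, whitelisted=whitelisted)


def default_germline_variants() -> list[VariantRecord]:
    """Five germline heterozygous SNPs spread over the panel chromosomes."""
    spots = [("chr2", "DNMT3A"), ("chr4", "TET2"), ("chr7", "EZH2"),
             ("chr17", "TP53"), ("chr20", "ASXL1")]
    return [VariantRecord(chrom=c, pos=5_000_000 + 777 * i, ref="A", alt="G",
                          gene=g, consequence="synonymous",
                          population_maf=0.30)
            for i, (c, g) in enumerate(spots)]


def default_patient(patient_id: str, response: str, pattern: str, *,
                    topology: str = "linear",
                    genes: tuple[str, ...] = ("TET2", "ASXL1", "RUNX1"),
                    cnv: tuple[str, int, int, int] | None = None,
                    variant_offset: int = 0) -> PatientSim:
    """One patient's clone hierarchy with study-like gene usage.

    ``topology`` is ``linear`` (consecutive acquisition) or ``branched``
    (two children of the first clone). A ``cnv`` event, if given, is attached
    to the terminal clone.
    """
    v = [f"{g}_m{variant_offset + i}" for i, g in enumerate(genes)]
    if topology == "linear":
        clones = [
            CloneSpec("WT", {}, None, [], {"diagnosis": 0.45}, dict(WT_CELLTYPE_MIX)),
            CloneSpec("C1", {v[0]: GT_HET}, "WT", [], {"diagnosis": 0.25},
                      dict(MUTANT_CELLTYPE_MIX)),
            CloneSpec("C2", {v[0]: GT_HET, v[1]: GT_HET}, "C1", [],
                      {"diagnosis": 0.20}, dict(MUTANT_CELLTYPE_MIX)),
            CloneSpec("C3", {v[0]: GT_HET, v[1]: GT_HET, v[2]: GT_HET}, "C2",
                      [], {"diagnosis": 0.10}, dict(MUTANT_CELLTYPE_MIX)),
        ]
    elif topology == "branched":
        clones = [
            CloneSpec("WT", {}, None, [], {"diagnosis": 0.45}, dict(WT_CELLTYPE_MIX)),
            CloneSpec("C1", {v[0]: GT_HET}, "WT", [], {"diagnosis": 0.20},
                      dict(MUTANT_CELLTYPE_MIX)),
            CloneSpec("C2", {v[0]: GT_HET, v[1]: GT_HET}, "C1", [],
                      {"diagnosis": 0.22}, dict(MUTANT_CELLTYPE_MIX)),
            CloneSpec("C3", {v[0]: GT_HET, v[2]: GT_HET}, "C1", [],
                      {"diagnosis": 0.13}, dict(MUTANT_CELLTYPE_MIX)),
        ]
    else:
        raise ValueError(f"unknown topology {topology!r}")
    if cnv is not None:
        clones[-1].cnv_events.append(cnv)
    return PatientSim(patient_id, response, clones, pattern,
                      expansion_variant=f"{genes[-1]}_new{variant_offset}")


def default_cohort_config(n_cells: int = 4000, seed: int = 0, *,
                          n_amplicons: int | None = None) -> SimConfig:
    """The 14-patient, 28-sample study-shaped cohort.

    Eight responders (seven with shrinking mutant clones plus one patient
    without callable mutant clones) and six nonresponders (five stable, one
    expanding) — a response structure characteristic of HMA-treated MDS
    cohorts.
    ``n_amplicons`` trims the amplicon panel for faster runs (None = full
    519-amplicon panel).
    """
    gene_sets = [
        ("TET2", "ASXL1", "RUNX1"), ("TET2", "DNMT3A", "NRAS"),
        ("TET2", "U2AF1", "STAG2"), ("ASXL1", "EZH2", "CUX1"),
        ("TP53", "RUNX1", "PHF6"), ("SF3B1", "BCOR", "IDH1"),
        ("TET2", "ZRSR2", "NF1"),  # responders 1-7
        ("DNMT3A", "U2AF1", "PTEN"), ("TET2", "TP53", "KRAS"),
        ("ASXL1", "RUNX1", "JAK2"), ("TET2", "EZH2", "CBL"),
        ("DNMT3A", "SRSF2", "GATA2"), ("U2AF1", "SETBP1", "ETV6"),
    ]
    patients: list[PatientSim] = []
    variants: dict[str, VariantRecord] = {}
    idx = 0
    for i in range(7):  # responders with mutant clones: shrinkage
        topo = "branched" if i % 2 else "linear"
        cnv = ("chr7", 0, 10_000_000_000, 1) if i == 2 else None
        p = default_patient(f"P{i + 1:02d}", "responder", "shrinkage",
                            topology=topo, genes=gene_sets[i],
                            cnv=cnv, variant_offset=idx)
        patients.append(p)
        idx += 4
    # responder without callable mutant clones (panel-negative patient)
    patients.append(PatientSim(
        "P08", "responder",
        [CloneSpec("WT", {}, None, [], {"diagnosis": 1.0}, dict(WT_CELLTYPE_MIX))],
        "stable"))
    for j in range(5):  # nonresponders: stable
        p = default_patient(f"P{j + 9:02d}", "nonresponder", "stable",
                            topology="branched" if j % 2 else "linear",
                            genes=gene_sets[7 + j], variant_offset=idx)
        patients.append(p)
        idx += 4
    # nonresponder with expansion
    p = default_patient("P14", "nonresponder", "expansion",
                        genes=gene_sets[12], variant_offset=idx)
    patients.append(p)

    for pat in patients:
        for clone in pat.clones:
            for vname in clone.signature:
                if vname not in variants:
                    gene = vname.split("_")[0]
                    variants[vname] = _somatic_variant(gene, len(variants),
                                                       whitelisted=True)
        if pat.expansion_variant and pat.expansion_variant not in variants:
            gene = pat.expansion_variant.split("_")[0]
            variants[pat.expansion_variant] = _somatic_variant(
                gene, len(variants), whitelisted=True)

    germline = default_germline_variants()
    amplicons = study_panel()
    if n_amplicons is not None:
        amplicons = amplicons[:n_amplicons]
    cfg = SimConfig(
        patients=patients,
        variants=list(variants.values()) + germline,
        germline_het=[g.name for g in germline],
        n_cells=n_cells, amplicons=amplicons, seed=seed,
    )
    # name lookup: somatic variants are addressed by their synthetic names
    cfg._name_map = {}  # type: ignore[attr-defined]
    for vname, rec in variants.items():
        cfg._name_map[vname] = rec
    return cfg


def single_patient_config(pattern: str = "stable", *, n_cells: int = 4000,
                          ado_rate: float = 0.10, seed: int = 0,
                          topology: str = "linear",
                          cnv: tuple[str, int, int, int] | None = None,
                          n_amplicons: int | None = 60,
                          **kwargs) -> SimConfig:
    """Convenience config: one paired patient with the default hierarchy."""
    pat = default_patient("P01",
                          "responder" if pattern == "shrinkage" else "nonresponder",
                          pattern, topology=topology, cnv=cnv)
    variants = {}
    for clone in pat.clones:
        for vname in clone.signature:
            if vname not in variants:
                variants[vname] = _somatic_variant(vname.split("_")[0],
                                                   len(variants), whitelisted=True)
    if pat.expansion_variant:
        variants[pat.expansion_variant] = _somatic_variant(
            pat.expansion_variant.split("_")[0], len(variants), whitelisted=True)
    germline = default_germline_variants()
    amplicons = study_panel()
    if n_amplicons is not None:
        amplicons = amplicons[:n_amplicons]
    cfg = SimConfig(patients=[pat],
                    variants=list(variants.values()) + germline,
                    germline_het=[g.name for g in germline],
                    n_cells=n_cells, ado_rate=ado_rate, seed=seed,
                    amplicons=amplicons, **kwargs)
    cfg._name_map = dict(variants)  # type: ignore[attr-defined]
    return cfg


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _variant_name_map(config: SimConfig) -> dict[str, VariantRecord]:
    """Map synthetic clone-signature names and record names to records."""
    mapping = dict(getattr(config, "_name_map", {}))
    for rec in config.variants:
        mapping.setdefault(rec.name, rec)
    return mapping


def _clone_proportions(pat: PatientSim, config: SimConfig
                       ) -> tuple[list[CloneSpec], dict[str, dict[str, float]]]:
    """Resolve both-timepoint proportions, materializing expansion clones."""
    base = {c.clone_id: c.proportions["diagnosis"] for c in pat.clones}
    clones = list(pat.clones)
    dx, post = simulate_dynamics(pat.dynamics_pattern, base)
    if "NEW" in post:
        if pat.expansion_variant is None:
            raise ValueError(f"{pat.patient_id}: expansion needs a variant")
        mutants = [c for c in clones if not c.is_wt]
        parent = max(mutants, key=lambda c: base[c.clone_id])
        sig = dict(parent.signature)
        sig[pat.expansion_variant] = GT_HET
        clones.append(CloneSpec("NEW", sig, parent.clone_id, [],
                                {}, dict(MUTANT_CELLTYPE_MIX)))
    return clones, {"diagnosis": dx, "post_treatment": post}


def _draw_genotypes(rng: np.random.Generator, true_gt: np.ndarray,
                    config: SimConfig) -> tuple[np.ndarray, ...]:
    """Apply ADO + call errors + missingness; emit aligned QC layers."""
    n, v = true_gt.shape
    gt = true_gt.copy()

    # symmetric allele dropout at heterozygous sites
    het = gt == GT_HET
    drop = het & (rng.random((n, v)) < config.ado_rate)
    to_hom = rng.random((n, v)) < 0.5
    gt[drop & to_hom] = GT_HOM
    gt[drop & ~to_hom] = GT_WT

    # sporadic genotype call errors: jump to one of the other two codes
    err = rng.random((n, v)) < config.genotype_error_rate
    if err.any():
        shift = rng.integers(1, 3, size=(n, v))
        gt[err] = (gt[err] + shift[err]) % 3

    # missing calls
    gt[rng.random((n, v)) < config.missing_rate] = GT_MISSING

    # depth: negative binomial (mean, dispersion r)
    r = config.depth_dispersion
    p = r / (r + config.depth_mean)
    depth = rng.negative_binomial(r, p, size=(n, v)).astype(np.int32)

    # genotype quality: pass_rate of calls get GQ in (31, 99), rest (0, 30)
    passing = rng.random((n, v)) < config.gq_pass_rate
    quality = np.where(passing, rng.uniform(31.0, 99.0, (n, v)),
                       rng.uniform(0.0, 30.0, (n, v)))

    # alt fraction consistent with the *observed* call
    af = np.empty((n, v))
    af[gt == GT_WT] = rng.beta(1.0, 40.0, int((gt == GT_WT).sum()))
    af[gt == GT_HET] = np.clip(
        rng.normal(0.5, 0.07, int((gt == GT_HET).sum())), 0.25, 0.75)
    af[gt == GT_HOM] = 1.0 - rng.beta(1.0, 40.0, int((gt == GT_HOM).sum()))
    af[gt == GT_MISSING] = np.nan
    depth[gt == GT_MISSING] = 0
    quality[gt == GT_MISSING] = 0.0
    return gt, depth, quality, af


def _cnv_allele_shift(rng: np.random.Generator, gt: np.ndarray,
                      af: np.ndarray, cells: np.ndarray, copies: int,
                      keep_alt: bool) -> None:
    """Rewrite genotype/alt-fraction at a germline-het site inside a CNV."""
    if copies == 1:  # one allele physically lost in every clone cell
        if keep_alt:
            gt[cells] = GT_HOM
            af[cells] = 1.0 - rng.beta(1.0, 40.0, cells.size)
        else:
            gt[cells] = GT_WT
            af[cells] = rng.beta(1.0, 40.0, cells.size)
    elif copies == 3:  # duplicated allele shifts the het fraction
        centre = 2.0 / 3.0 if keep_alt else 1.0 / 3.0
        af[cells] = np.clip(rng.normal(centre, 0.05, cells.size), 0.05, 0.95)


def simulate_cohort(config: SimConfig) -> tuple[CohortTable, TruthBundle]:
    """Generate a full cohort plus its ground truth, deterministically.

    One seeded generator drives the whole cohort; identical configs produce
    bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    name_map = _variant_name_map(config)
    amplicons = config.amplicons if config.amplicons is not None else study_panel()
    antibodies = (config.antibodies if config.antibodies is not None
                  else study_antibodies())
    adt_means = adt_mean_table(antibodies, config.isotype_background)
    iso_mask = np.array([ab.is_isotype for ab in antibodies])

    variant_order = list(config.variants)
    var_index = {rec.name: j for j, rec in enumerate(variant_order)}
    germline_idx = [var_index[n] for n in config.germline_het]

    # per-amplicon capture efficiency, shared across the cohort
    amp_mean = 50.0 * rng.lognormal(0.0, 0.35, len(amplicons))
    amp_chrom = np.array([a.chrom for a in amplicons], dtype=object)
    amp_mid = np.array([(a.start + a.end) // 2 for a in amplicons])

    samples: list[Sample] = []
    cell_rows, prop_rows, cnv_rows = [], [], []
    signatures: dict[tuple[str, str], dict[str, int]] = {}
    dynamics: dict[str, str] = {}

    for pat in config.patients:
        clones, props = _clone_proportions(pat, config)
        dynamics[pat.patient_id] = pat.dynamics_pattern
        clone_ids = [c.clone_id for c in clones]
        for c in clones:
            sig = {}
            for vname, zyg in c.signature.items():
                rec = name_map[vname]
                sig[rec.name] = zyg
            signatures[(pat.patient_id, c.clone_id)] = sig
            for (chrom, start, end, copies) in c.cnv_events:
                cnv_rows.append({"patient": pat.patient_id,
                                 "clone_id": c.clone_id, "chrom": chrom,
                                 "start": start, "end": end, "copies": copies})
        # fixed per clone-event allele choice (the same allele is lost or
        # gained in every cell of the clone)
        cnv_allele = {(pat.patient_id, c.clone_id): bool(rng.random() < 0.5)
                      for c in clones if c.cnv_events}

        for tp in ("diagnosis", "post_treatment"):
            fracs = props[tp]
            n = config.n_cells
            counts = rng.multinomial(n, [fracs.get(cid, 0.0) for cid in clone_ids])
            clone_of_cell = np.repeat(np.arange(len(clones)), counts)
            rng.shuffle(clone_of_cell)
            barcodes = np.array([f"{pat.patient_id}_{tp}_c{i:05d}"
                                 for i in range(n)], dtype=object)

            # cell types
            celltype = np.empty(n, dtype=object)
            for ci, clone in enumerate(clones):
                mask = clone_of_cell == ci
                if not mask.any():
                    continue
                mix = clone.celltype_mix or dict(WT_CELLTYPE_MIX)
                types = list(mix)
                pvec = np.array([mix[t] for t in types], dtype=float)
                pvec /= pvec.sum()
                celltype[mask] = rng.choice(types, size=int(mask.sum()), p=pvec)

            # true genotypes: germline hets everywhere + clone signatures
            true_gt = np.zeros((n, len(variant_order)), dtype=np.int8)
            true_gt[:, germline_idx] = GT_HET
            for ci, clone in enumerate(clones):
                mask = clone_of_cell == ci
                for vname, zyg in clone.signature.items():
                    true_gt[mask, var_index[name_map[vname].name]] = zyg

            gt, depth, quality, af = _draw_genotypes(rng, true_gt, config)

            # amplicon counts with planted copy-number scaling
            size_factor = rng.lognormal(0.0, 0.25, n)
            copies = np.full((n, len(amplicons)), 2.0)
            for ci, clone in enumerate(clones):
                if not clone.cnv_events:
                    continue
                mask = clone_of_cell == ci
                for (chrom, start, end, cn) in clone.cnv_events:
                    in_region = (amp_chrom == chrom) & (amp_mid >= start) \
                        & (amp_mid < end)
                    copies[np.ix_(mask, in_region)] = float(cn)
                    # shift germline-het alt fractions inside the region
                    cells = np.flatnonzero(mask)
                    keep_alt = cnv_allele[(pat.patient_id, clone.clone_id)]
                    for gi in germline_idx:
                        rec = variant_order[gi]
                        if rec.chrom == chrom and start <= rec.pos < end:
                            _cnv_allele_shift(rng, gt[:, gi], af[:, gi],
                                              cells, cn, keep_alt)
            mu = size_factor[:, None] * amp_mean[None, :] * (copies / 2.0)
            r = config.depth_dispersion
            amp_counts = rng.negative_binomial(
                r, r / (r + np.maximum(mu, 1e-9))).astype(np.int32)

            # ADT counts: cell-type mean x cell factor + shared background
            adt_factor = rng.lognormal(0.0, 0.3, n)
            mean_mat = adt_means.loc[celltype.tolist()].to_numpy()
            mu_adt = mean_mat * adt_factor[:, None]
            r_adt = config.adt_dispersion
            signal = rng.negative_binomial(
                r_adt, r_adt / (r_adt + np.maximum(mu_adt, 1e-9)))
            bg_mu = config.isotype_background * adt_factor[:, None] \
                * np.ones((1, len(antibodies)))
            background = rng.negative_binomial(
                r_adt, r_adt / (r_adt + bg_mu))
            adt_counts = (signal + background).astype(np.int32)
            adt_counts[:, iso_mask] = background[:, iso_mask]

            meta = SampleMeta(pat.patient_id, tp, pat.response)
            samples.append(Sample(
                meta,
                GenotypeMatrix(barcodes, variant_order, gt, depth, quality, af),
                AmpliconCountMatrix(barcodes.copy(), list(amplicons), amp_counts),
                ADTMatrix(barcodes.copy(), list(antibodies), adt_counts),
            ))
            for i in range(n):
                cell_rows.append((pat.patient_id, tp, barcodes[i],
                                  clone_ids[clone_of_cell[i]], celltype[i]))
            for cid in clone_ids:
                prop_rows.append({"patient": pat.patient_id, "timepoint": tp,
                                  "clone_id": cid,
                                  "fraction": fracs.get(cid, 0.0)})

    truth = TruthBundle(
        cells=pd.DataFrame(cell_rows, columns=["patient", "timepoint",
                                               "barcode", "clone_id",
                                               "cell_type"]),
        clone_signatures=signatures,
        proportions=pd.DataFrame(prop_rows),
        ado_rate=config.ado_rate,
        cnv_events=pd.DataFrame(
            cnv_rows, columns=["patient", "clone_id", "chrom", "start", "end",
                               "copies"]),
        dynamics=dynamics,
    )
    logger.info("simulated %d samples x %d cells", len(samples), config.n_cells)
    return CohortTable(samples), truth


# ---------------------------------------------------------------------------
# table export
# ---------------------------------------------------------------------------


def write_panel_table(path: str | Path,
                      amplicons: list[Amplicon] | None = None) -> None:
    """Write a BED-like panel CSV (chrom, start, end, amplicon_id, gene)."""
    amplicons = amplicons or study_panel()
    pd.DataFrame(
        [{"chrom": a.chrom, "start": a.start, "end": a.end,
          "amplicon_id": a.amplicon_id, "gene": a.gene} for a in amplicons]
    ).to_csv(path, index=False)


def write_antibody_table(path: str | Path,
                         antibodies: list[Antibody] | None = None) -> None:
    antibodies = antibodies or study_antibodies()
    pd.DataFrame(
        [{"name": ab.name, "is_isotype": ab.is_isotype} for ab in antibodies]
    ).to_csv(path, index=False)


def write_truth_tables(truth: TruthBundle, outdir: str | Path) -> None:
    """Dump the truth bundle to tidy CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.cells.to_csv(outdir / "truth_cells.csv", index=False)
    truth.proportions.to_csv(outdir / "truth_proportions.csv", index=False)
    truth.cnv_events.to_csv(outdir / "truth_cnv.csv", index=False)
    sig_rows = [{"patient": p, "clone_id": c, "variant": v, "zygosity": z}
                for (p, c), sig in truth.clone_signatures.items()
                for v, z in sig.items()]
    pd.DataFrame(sig_rows, columns=["patient", "clone_id", "variant",
                                    "zygosity"]).to_csv(
        outdir / "truth_signatures.csv", index=False)
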