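"""Genotype/variant/cell quality control and allele-dropout estimation.

Filtering proceeds in a fixed order — per-call genotype filters, then variant
filters, then cell filters — with every threshold a strict inequality exactly
as printed in the workflow this package reproduces: genotype quality > 30,
read depth > 10, alternate-allele fraction > 20% (non-WT calls only),
variants genotyped in > 50% of cells, variants mutated in >= 1% of cells,
cells with >= 50% of genotypes present, population MAF <= 0.01 unless
whitelisted.

The allele-dropout (ADO) rate of a sample is estimated from germline
heterozygous variants — variants mutated in >= 92% of genotyped cells at both
timepoints with a VAF-by-cell-count close to 50% (49.2–52.7) — as
``100 x (n_WT + n_HOM) / n_genotyped``, averaged over the five such variants
whose VAF is nearest 50.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    DAMAGING_CONSEQUENCES, GT_HET, GT_HOM, GT_MISSING, GT_WT,
    GenotypeMatrix, VariantRecord,
)

logger = logging.getLogger("clonepulse")


@dataclass(frozen=True)
class QCThresholds:
    """All QC cutoffs; defaults are the reproduced workflow's printed values."""

    gq_min: float = 30.0
    dp_min: int = 10
    af_min: float = 0.20
    variant_genotyped_min: float = 0.50
    variant_mutated_min: float = 0.01
    cell_genotyped_min: float = 0.50
    maf_max: float = 0.01

    def __post_init__(self) -> None:
        for name in ("variant_genotyped_min", "variant_mutated_min",
                     "cell_genotyped_min", "maf_max", "af_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class AdoEstimate:
    """Per-variant and sample-level allele-dropout percentages."""

    per_variant: dict[str, float]  # variant name -> ADO %
    sample_ado: float  # mean over the selected variants
    variants_used: list[str] = field(default_factory=list)


class QCError(ValueError):
    pass


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_genotype_calls(gm: GenotypeMatrix,
                          thresholds: QCThresholds = QCThresholds()
                          ) -> GenotypeMatrix:
    """Set calls failing quality/depth/alt-fraction thresholds to MISSING.

    WT calls are exempt from the alternate-allele-fraction criterion (a
    reference call legitimately has no alternate reads).
    """
    out = gm.copy()
    called = out.gt != GT_MISSING
    fail = called & ((out.quality <= thresholds.gq_min)
                     | (out.depth <= thresholds.dp_min))
    non_wt = called & (out.gt != GT_WT)
    fail |= non_wt & ~(out.alt_fraction > thresholds.af_min)
    n_fail = int(fail.sum())
    if n_fail:
        logger.info("genotype-call filter: %d of %d calls set to MISSING",
                    n_fail, int(called.sum()))
    out.gt[fail] = GT_MISSING
    out.depth[fail] = 0
    out.quality[fail] = 0.0
    out.alt_fraction[fail] = np.nan
    return out


def filter_variants(gm: GenotypeMatrix,
                    thresholds: QCThresholds = QCThresholds(),
                    whitelist: set[tuple] | None = None,
                    ) -> tuple[GenotypeMatrix, list[VariantRecord],
                               list[VariantRecord]]:
    """Partition variants into (kept matrix, reported-only, dropped).

    Kept variants are genotyped in > 50% of cells, mutated in >= 1% of cells,
    of a damaging consequence class (exonic nonsynonymous or splicing) and
    rare in the population (MAF <= 0.01) unless whitelisted — the whitelist
    bypasses the MAF filter only. Variants failing only the genotyped-fraction
    rule but showing good per-call quality (median GQ and median alt fraction
    among mutated cells above the call thresholds) are returned as
    reported-only: they appear in reports but never seed a clone.
    """
    if gm.n_cells == 0 or gm.n_variants == 0:
        raise QCError("empty genotype matrix")
    whitelist = whitelist or set()
    n = gm.n_cells
    genotyped = gm.genotyped().sum(axis=0) / n
    mutated_frac = gm.mutated().sum(axis=0) / n

    kept_idx, reported, dropped = [], [], []
    for j, rec in enumerate(gm.variants):
        wl = rec.whitelisted or rec.key in whitelist
        maf = rec.population_maf if rec.population_maf is not None else 0.0
        ok_consequence = rec.consequence in DAMAGING_CONSEQUENCES
        ok_maf = (not maf > thresholds.maf_max) or wl
        ok_mutated = mutated_frac[j] >= thresholds.variant_mutated_min
        if not (ok_consequence and ok_maf and ok_mutated):
            dropped.append(rec)
            continue
        if genotyped[j] > thresholds.variant_genotyped_min:
            kept_idx.append(j)
            continue
        # genotyped-fraction failure: rescue as reported-only if quality holds
        mut_cells = gm.mutated()[:, j]
        if mut_cells.any():
            med_gq = float(np.median(gm.quality[mut_cells, j]))
            med_af = float(np.median(gm.alt_fraction[mut_cells, j]))
            if med_gq > thresholds.gq_min and med_af > thresholds.af_min:
                reported.append(rec)
                continue
        dropped.append(rec)
    logger.info("variant filter: %d kept, %d reported-only, %d dropped",
                len(kept_idx), len(reported), len(dropped))
    return gm.subset(variants=np.array(kept_idx, dtype=int)), reported, dropped


def filter_cells(gm: GenotypeMatrix,
                 thresholds: QCThresholds = QCThresholds()) -> GenotypeMatrix:
    """Drop cells with fewer than half of their genotypes present."""
    if gm.n_variants == 0:
        return gm.copy()
    frac = gm.genotyped().sum(axis=1) / gm.n_variants
    keep = ~(frac < thresholds.cell_genotyped_min)  # strict "<" removal
    if not keep.any():
        raise QCError("cell filter removed every cell")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("cell filter: removed %d of %d cells", n_drop, gm.n_cells)
    return gm.subset(cells=np.flatnonzero(keep))


def apply_qc(gm: GenotypeMatrix,
             thresholds: QCThresholds = QCThresholds(),
             whitelist: set[tuple] | None = None,
             ) -> tuple[GenotypeMatrix, list[VariantRecord],
                        list[VariantRecord]]:
    """Full QC chain: calls -> variants -> cells."""
    gm = filter_genotype_calls(gm, thresholds)
    gm, reported, dropped = filter_variants(gm, thresholds, whitelist)
    if gm.n_variants:
        gm = filter_cells(gm, thresholds)
    return gm, reported, dropped


# ---------------------------------------------------------------------------
# VAF-by-cell-count and germline-het selection
# ---------------------------------------------------------------------------


def vaf_by_cell_count(gt_column: np.ndarray) -> float:
    """Allele frequency from genotype categories, as a percentage.

    ``100 x (n_HET + 2 n_HOM) / (2 n_genotyped)``.
    """
    gt = np.asarray(gt_column)
    n_het = int((gt == GT_HET).sum())
    n_hom = int((gt == GT_HOM).sum())
    n_gen = int((gt != GT_MISSING).sum())
    if n_gen == 0:
        raise QCError("VAF-by-cell-count undefined: no genotyped cells")
    return 100.0 * (n_het + 2 * n_hom) / (2 * n_gen)


GERMLINE_MUTATED_MIN = 0.92
GERMLINE_VAF_WINDOW = (49.2, 52.7)


def select_germline_het(dx: GenotypeMatrix, post: GenotypeMatrix,
                        mutated_min: float = GERMLINE_MUTATED_MIN,
                        vaf_window: tuple[float, float] = GERMLINE_VAF_WINDOW,
                        ) -> list[VariantRecord]:
    """Pick germline heterozygous variants from a patient's paired samples.

    A variant qualifies when it is mutated (HET or HOM) in >= 92% of its
    genotyped cells at BOTH timepoints and its VAF-by-cell-count lies in
    [49.2, 52.7] at both. The mutated-fraction denominator is genotyped cells.
    """
    if dx is None or post is None:
        raise QCError("germline-het selection requires both timepoints")
    names_post = {rec.name: j for j, rec in enumerate(post.variants)}
    lo, hi = vaf_window
    selected = []
    for j, rec in enumerate(dx.variants):
        if rec.name not in names_post:
            continue
        cols = (dx.gt[:, j], post.gt[:, names_post[rec.name]])
        ok = True
        for col in cols:
            n_gen = int((col != GT_MISSING).sum())
            if n_gen == 0:
                ok = False
                break
            mut = int(((col == GT_HET) | (col == GT_HOM)).sum()) / n_gen
            if mut < mutated_min:
                ok = False
                break
            vaf = vaf_by_cell_count(col)
            if not (lo <= vaf <= hi):
                ok = False
                break
        if ok:
            selected.append(rec)
    return selected


# ---------------------------------------------------------------------------
# ADO
# ---------------------------------------------------------------------------

N_ADO_VARIANTS = 5


def ado_rate(dx: GenotypeMatrix, post: GenotypeMatrix,
             selected: list[VariantRecord],
             n_variants: int = N_ADO_VARIANTS) -> AdoEstimate:
    """Estimate a patient's allele-dropout rate from germline het variants.

    Per variant (both timepoints pooled): ``100 x (n_WT + n_HOM) /
    n_genotyped``. The sample estimate averages the ``n_variants`` selected
    variants whose VAF-by-cell-count sits nearest 50%; if fewer qualify, all
    are used with a warning.
    """
    if not selected:
        raise QCError(
            "no germline heterozygous variants selected; cannot estimate ADO "
            f"(need variants mutated in >= {GERMLINE_MUTATED_MIN:.0%} of cells"
            f" with VAF in {GERMLINE_VAF_WINDOW})")
    dx_idx = {rec.name: j for j, rec in enumerate(dx.variants)}
    post_idx = {rec.name: j for j, rec in enumerate(post.variants)}
    per_variant: dict[str, float] = {}
    vaf_dist: dict[str, float] = {}
    for rec in selected:
        col = np.concatenate([dx.gt[:, dx_idx[rec.name]],
                              post.gt[:, post_idx[rec.name]]])
        n_gen = int((col != GT_MISSING).sum())
        n_drop = int(((col == GT_WT) | (col == GT_HOM)).sum())
        per_variant[rec.name] = 100.0 * n_drop / n_gen
        vaf_dist[rec.name] = abs(vaf_by_cell_count(col) - 50.0)
    ranked = sorted(per_variant, key=lambda name: vaf_dist[name])
    if len(ranked) < n_variants:
        logger.warning("only %d germline het variants available for ADO "
                       "(wanted %d); using all", len(ranked), n_variants)
    used = ranked[:n_variants]
    sample_ado = float(np.mean([per_variant[name] for name in used]))
    return AdoEstimate(per_variant=per_variant, sample_ado=sample_ado,
                       variants_used=used)
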