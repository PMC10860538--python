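"""Amplicon-depth normalization and per-clone ploidy against a WT baseline.

Read-depth-based copy number for targeted amplicon panels: amplicons seen in
fewer than half the cells are discarded, each cell's counts are scaled by its
total, each amplicon by its mean across cells, and clone-level ploidy is
``2 x median(clone) / median(WT baseline)`` per amplicon. Region-level calls
use midpoints between integer copy states (loss < 1.5, gain > 2.5).

CNV-defined clones are additionally detectable from genotype data: a copy
change shifts the per-cell alternate-allele fraction of a germline
heterozygous variant inside the region (loss pushes toward 0 or 1, gain
toward 1/3 or 2/3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GT_HET, GT_MISSING, AmpliconCountMatrix, GenotypeMatrix

logger = logging.getLogger("clonepulse")


class PloidyError(ValueError):
    pass


@dataclass
class PloidyTable:
    """Per (clone, amplicon) median ploidy and per (clone, region) calls."""

    ploidy: pd.DataFrame  # index clone_id, columns amplicon_id
    region_calls: pd.DataFrame  # clone_id, chrom, median_ploidy, call


@dataclass
class CnvFlag:
    clone_id: str
    evaluable: bool
    is_cnv: bool
    direction: str | None  # loss | gain | None
    mean_shift: float | None
    p_value: float | None


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def filter_amplicons(acm: AmpliconCountMatrix,
                     min_cell_fraction: float = 0.5) -> AmpliconCountMatrix:
    """Drop amplicons detected (>= 1 read) in fewer than half the cells."""
    detected = (acm.counts > 0).sum(axis=0) / acm.n_cells
    keep = detected >= min_cell_fraction
    if not keep.any():
        raise PloidyError("amplicon filter removed every amplicon")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("amplicon filter: removed %d of %d amplicons", n_drop,
                    keep.size)
    return acm.subset(amplicons=np.flatnonzero(keep))


def normalize_reads(acm: AmpliconCountMatrix
                    ) -> tuple[np.ndarray, AmpliconCountMatrix]:
    """Normalize counts per cell total, then per amplicon mean.

    Returns the normalized (cells x amplicons) float matrix together with the
    (possibly cell-filtered) count matrix it aligns to; zero-total cells are
    removed with a warning.
    """
    totals = acm.counts.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        logger.warning("normalize_reads: removed %d zero-total cells",
                       int((~keep).sum()))
        acm = acm.subset(cells=np.flatnonzero(keep))
        totals = totals[keep]
    x = acm.counts / totals[:, None].astype(float)
    amp_mean = x.mean(axis=0)
    if (amp_mean == 0).any():
        # all-zero amplicons survive only if the amplicon filter was skipped
        amp_mean = np.where(amp_mean == 0, 1.0, amp_mean)
    return x / amp_mean[None, :], acm


# ---------------------------------------------------------------------------
# ploidy
# ---------------------------------------------------------------------------

LOSS_CUTOFF = 1.5
GAIN_CUTOFF = 2.5
MIN_BASELINE_CELLS = 50


def compute_ploidy(normalized: np.ndarray, acm: AmpliconCountMatrix,
                   memberships: dict[str, list[str]], baseline: str = "WT", *,
                   loss_cutoff: float = LOSS_CUTOFF,
                   gain_cutoff: float = GAIN_CUTOFF,
                   min_baseline_cells: int = MIN_BASELINE_CELLS) -> PloidyTable:
    """Per-clone per-amplicon ploidy relative to a diploid baseline clone.

    ``ploidy(clone, amplicon) = 2 x median over clone cells of the
    normalized count / median over baseline cells of the normalized count``,
    so the baseline clone sits at exactly 2.0 on every amplicon by
    construction. Region (chromosome) calls take the median over a region's
    amplicons: loss below ``loss_cutoff``, gain above ``gain_cutoff``.
    """
    if baseline not in memberships:
        raise PloidyError(f"baseline clone {baseline!r} not in memberships")
    bc_index = {b: i for i, b in enumerate(acm.barcodes)}

    def rows(barcodes: list[str]) -> np.ndarray:
        return np.array([bc_index[b] for b in barcodes if b in bc_index],
                        dtype=int)

    base_rows = rows(memberships[baseline])
    if base_rows.size < min_baseline_cells:
        raise PloidyError(
            f"baseline clone {baseline!r} has {base_rows.size} cells "
            f"(< {min_baseline_cells}); choose a larger diploid clone")
    base_ref = np.median(normalized[base_rows], axis=0)
    base_ref = np.where(base_ref == 0, np.nan, base_ref)

    amp_ids = [a.amplicon_id for a in acm.amplicons]
    ploidy_rows = {}
    for clone_id, barcodes in memberships.items():
        r = rows(barcodes)
        if r.size == 0:
            continue
        ploidy_rows[clone_id] = 2.0 * np.median(
            normalized[r] / base_ref[None, :], axis=0)
    ploidy = pd.DataFrame(ploidy_rows, index=amp_ids).T
    ploidy.index.name = "clone_id"

    chroms = np.array([a.chrom for a in acm.amplicons], dtype=object)
    call_rows = []
    for clone_id in ploidy.index:
        for chrom in pd.unique(chroms):
            med = float(np.nanmedian(
                ploidy.loc[clone_id].to_numpy()[chroms == chrom]))
            call = ("loss" if med < loss_cutoff
                    else "gain" if med > gain_cutoff else "neutral")
            call_rows.append({"clone_id": clone_id, "chrom": chrom,
                              "median_ploidy": med, "call": call})
    return PloidyTable(ploidy=ploidy, region_calls=pd.DataFrame(call_rows))


# ---------------------------------------------------------------------------
# CNV-clone detection from heterozygous-VAF shifts
# ---------------------------------------------------------------------------


def detect_cnv_clone(gm: GenotypeMatrix, region: tuple[str, int, int],
                     memberships: dict[str, list[str]], baseline: str = "WT",
                     *, shift_threshold: float = 0.15,
                     alpha: float = 0.01) -> dict[str, CnvFlag]:
    """Flag clones whose het-variant allele fractions shift inside a region.

    For each clone, the per-cell alternate-allele fractions at germline
    heterozygous variants inside ``region`` (chrom, start, end; 1-based
    positions) are compared with the baseline clone's: a CNV is flagged when
    the absolute mean difference exceeds ``shift_threshold`` and a rank-sum
    test confirms it at ``alpha``. Regions without a het variant yield a
    not-evaluable result, distinct from a negative one.
    """
    chrom, start, end = region
    # het variants: heterozygous in the majority of baseline genotyped cells
    bc_index = {b: i for i, b in enumerate(gm.barcodes)}

    def rows(barcodes: list[str]) -> np.ndarray:
        return np.array([bc_index[b] for b in barcodes if b in bc_index],
                        dtype=int)

    base_rows = rows(memberships.get(baseline, []))
    het_cols = []
    for j, rec in enumerate(gm.variants):
        if rec.chrom != chrom or not (start <= rec.pos < end):
            continue
        col = gm.gt[base_rows, j]
        genotyped = col != GT_MISSING
        if genotyped.sum() and (col == GT_HET).sum() / genotyped.sum() > 0.5:
            het_cols.append(j)

    flags: dict[str, CnvFlag] = {}
    if not het_cols:
        for clone_id in memberships:
            flags[clone_id] = CnvFlag(clone_id, evaluable=False, is_cnv=False,
                                      direction=None, mean_shift=None,
                                      p_value=None)
        return flags

    def pooled_af(r: np.ndarray) -> np.ndarray:
        vals = []
        for j in het_cols:
            gt_col = gm.gt[r, j]
            af = gm.alt_fraction[r, j]
            ok = (gt_col != GT_MISSING) & ~np.isnan(af)
            vals.append(af[ok])
        return np.concatenate(vals) if vals else np.array([])

    base_af = pooled_af(base_rows)
    base_mean = float(base_af.mean())
    for clone_id, barcodes in memberships.items():
        if clone_id == baseline:
            flags[clone_id] = CnvFlag(clone_id, True, False, None, 0.0, 1.0)
            continue
        af = pooled_af(rows(barcodes))
        if af.size < 5:
            flags[clone_id] = CnvFlag(clone_id, False, False, None, None, None)
            continue
        # per-cell deviation from the balanced het fraction: a deletion pushes
        # fractions toward 0/1, a gain toward 1/3 or 2/3
        shift = float(np.mean(np.abs(af - 0.5)) -
                      np.mean(np.abs(base_af - 0.5)))
        p = float(stats.mannwhitneyu(np.abs(af - 0.5),
                                     np.abs(base_af - 0.5),
                                     alternative="two-sided").pvalue)
        is_cnv = abs(shift) > shift_threshold and p < alpha
        direction = None
        if is_cnv:
            # loss skews hard toward 0/1; gain sits nearer 1/3 or 2/3
            direction = "loss" if float(np.mean(np.abs(af - 0.5))) > 0.3 \
                else "gain"
        flags[clone_id] = CnvFlag(clone_id, True, is_cnv, direction,
                                  shift, p)
    return flags
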