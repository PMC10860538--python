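import numpy as np
import pytest

from clonepulse.core_io import (
    GT_HET, GT_HOM, GT_WT, GenotypeMatrix, VariantRecord,
)


def make_variant(name="V", gene=None, chrom="chr1", pos=100, **kw):
    """Small helper: a missense variant with controllable annotation."""
    return VariantRecord(chrom=chrom, pos=pos, ref="A", alt="T",
                         gene=gene or name, **kw)


def make_genotype_matrix(gt, variants=None, depth=50, quality=80.0,
                         alt_fraction=None):
    """GenotypeMatrix from a genotype grid with QC layers that pass filters.

    ``alt_fraction`` defaults to values consistent with each call.
    """
    gt = np.asarray(gt, dtype=np.int8)
    n, v = gt.shape
    if variants is None:
        variants = [make_variant(f"V{j}", pos=100 + j) for j in range(v)]
    if alt_fraction is None:
        alt_fraction = np.select(
            [gt == GT_WT, gt == GT_HET, gt == GT_HOM],
            [0.01, 0.5, 0.98], default=np.nan)
    return GenotypeMatrix(
        barcodes=np.array([f"c{i}" for i in range(n)], dtype=object),
        variants=variants,
        gt=gt,
        depth=np.full((n, v), depth, dtype=np.int32),
        quality=np.full((n, v), quality, dtype=float),
        alt_fraction=np.asarray(alt_fraction, dtype=float),
    )


@pytest.fixture(scope="session")
def small_paired_cohort():
    """One paired patient, 2,000 cells/sample, default noise; shared across
    tests to amortize simulation cost."""
    from clonepulse.synthetic_data import simulate_cohort, single_patient_config

    cfg = single_patient_config("shrinkage", n_cells=2000, seed=42)
    return simulate_cohort(cfg)
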