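"""Shared domain types and container IO.

The pipeline operates on per-sample matrix triples from targeted single-cell
DNA + antibody (ADT) sequencing of bone marrow:

* a cells x variants genotype matrix with per-call depth, genotype quality and
  alternate-allele fraction,
* a cells x amplicons read-count matrix tied to a genomic panel definition,
* a cells x antibodies ADT count matrix with isotype-control flags.

Containers are stored as a single HDF5 file per sample with named layers
(``genotype/gt`` etc.), with plain CSV fallbacks for the tabular pieces.
Panel files follow BED conventions (0-based half-open); variant positions are
1-based (VCF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("clonepulse")

# ---------------------------------------------------------------------------
# genotype categories
# ---------------------------------------------------------------------------

GT_WT = 0
GT_HET = 1
GT_HOM = 2
GT_MISSING = 3

GT_LABELS = {GT_WT: "WT", GT_HET: "HET", GT_HOM: "HOM", GT_MISSING: "MISSING"}
GT_CODES = {v: k for k, v in GT_LABELS.items()}

#: genotype categories counted as "mutated" throughout the pipeline
MUTATED = (GT_HET, GT_HOM)

CONSEQUENCES = ("missense", "nonsense", "frameshift", "splice", "synonymous", "other")
#: consequence classes retained by variant filtering (exonic nonsynonymous + splicing)
DAMAGING_CONSEQUENCES = frozenset({"missense", "nonsense", "frameshift", "splice"})

TIMEPOINTS = ("diagnosis", "post_treatment")


class LoadError(ValueError):
    """Raised when a container or table fails validation at load time."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """A targeted variant with its annotation columns.

    ``population_maf`` absent (None) is treated as 0 by the MAF filter;
    ``whitelisted`` marks variants confirmed by bulk NGS which bypass the
    population-frequency filter.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    consequence: str = "missense"
    population_maf: float | None = None
    whitelisted: bool = False
    pathogenicity: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class Amplicon:
    """A panel amplicon in 0-based half-open genomic coordinates."""

    amplicon_id: str
    chrom: str
    start: int
    end: int
    gene: str


@dataclass(frozen=True)
class Antibody:
    name: str
    is_isotype: bool = False


@dataclass
class GenotypeMatrix:
    """Cells x variants categorical genotype calls with per-call QC layers.

    ``gt`` holds integer codes (WT=0, HET=1, HOM=2, MISSING=3); ``depth``,
    ``quality`` and ``alt_fraction`` are aligned float/int layers whose values
    are undefined wherever ``gt`` is MISSING.
    """

    barcodes: np.ndarray  # (n_cells,) str
    variants: list[VariantRecord]
    gt: np.ndarray  # (n_cells, n_variants) int8
    depth: np.ndarray  # int32
    quality: np.ndarray  # float64
    alt_fraction: np.ndarray  # float64

    def __post_init__(self) -> None:
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        n, v = len(self.barcodes), len(self.variants)
        for layer_name in ("gt", "depth", "quality", "alt_fraction"):
            layer = np.asarray(getattr(self, layer_name))
            if layer.shape != (n, v):
                raise LoadError(
                    f"layer '{layer_name}' has shape {layer.shape}, "
                    f"expected ({n}, {v})"
                )
            setattr(self, layer_name, layer)
        if len(set(self.barcodes)) != n:
            raise LoadError("duplicate cell barcodes in genotype matrix")
        keys = [rec.key for rec in self.variants]
        if len(set(keys)) != v:
            raise LoadError("duplicate (chrom,pos,ref,alt) in variant table")
        self.gt = self.gt.astype(np.int8)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def genotyped(self) -> np.ndarray:
        """Boolean mask of non-MISSING calls."""
        return self.gt != GT_MISSING

    def mutated(self) -> np.ndarray:
        """Boolean mask of HET/HOM calls."""
        return (self.gt == GT_HET) | (self.gt == GT_HOM)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.barcodes.copy(), list(self.variants), self.gt.copy(),
            self.depth.copy(), self.quality.copy(), self.alt_fraction.copy(),
        )

    def subset(self, cells: np.ndarray | None = None,
               variants: np.ndarray | None = None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given cell/variant indices."""
        ci = np.arange(self.n_cells) if cells is None else np.asarray(cells)
        vi = np.arange(self.n_variants) if variants is None else np.asarray(variants)
        return GenotypeMatrix(
            self.barcodes[ci],
            [self.variants[j] for j in vi],
            self.gt[np.ix_(ci, vi)],
            self.depth[np.ix_(ci, vi)],
            self.quality[np.ix_(ci, vi)],
            self.alt_fraction[np.ix_(ci, vi)],
        )


@dataclass
class AmpliconCountMatrix:
    barcodes: np.ndarray
    amplicons: list[Amplicon]
    counts: np.ndarray  # (n_cells, n_amplicons) numeric, >= 0

    def __post_init__(self) -> None:
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.barcodes), len(self.amplicons)):
            raise LoadError(
                f"amplicon counts shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} cells x {len(self.amplicons)} amplicons"
            )
        if (self.counts < 0).any():
            raise LoadError("negative amplicon counts")
        ids = [a.amplicon_id for a in self.amplicons]
        if len(set(ids)) != len(ids):
            raise LoadError("duplicate amplicon ids")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def subset(self, cells: np.ndarray | None = None,
               amplicons: np.ndarray | None = None) -> "AmpliconCountMatrix":
        ci = np.arange(self.n_cells) if cells is None else np.asarray(cells)
        ai = (np.arange(len(self.amplicons)) if amplicons is None
              else np.asarray(amplicons))
        return AmpliconCountMatrix(
            self.barcodes[ci], [self.amplicons[j] for j in ai],
            self.counts[np.ix_(ci, ai)],
        )


@dataclass
class ADTMatrix:
    barcodes: np.ndarray
    antibodies: list[Antibody]
    counts: np.ndarray  # (n_cells, n_antibodies) int, >= 0

    def __post_init__(self) -> None:
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.barcodes), len(self.antibodies)):
            raise LoadError("ADT counts shape does not match barcodes x antibodies")
        if (self.counts < 0).any():
            raise LoadError("negative ADT counts")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def isotype_mask(self) -> np.ndarray:
        return np.array([ab.is_isotype for ab in self.antibodies], dtype=bool)

    def subset(self, cells: np.ndarray) -> "ADTMatrix":
        ci = np.asarray(cells)
        return ADTMatrix(self.barcodes[ci], list(self.antibodies), self.counts[ci])


@dataclass(frozen=True)
class SampleMeta:
    patient_id: str
    timepoint: str  # diagnosis | post_treatment
    response: str  # responder | nonresponder
    hi_flag: bool | None = None
    mcr_flag: bool | None = None

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.response not in ("responder", "nonresponder"):
            raise ValueError(f"unknown response {self.response!r}")


@dataclass
class Sample:
    meta: SampleMeta
    genotype: GenotypeMatrix
    amplicon: AmpliconCountMatrix
    adt: ADTMatrix

    @property
    def key(self) -> tuple[str, str]:
        return (self.meta.patient_id, self.meta.timepoint)


@dataclass
class CohortTable:
    """All samples of a cohort, keyed by (patient, timepoint)."""

    samples: list[Sample]

    def __post_init__(self) -> None:
        keys = [s.key for s in self.samples]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise LoadError(f"duplicate (patient, timepoint) samples: {dupes}")

    @property
    def patients(self) -> list[str]:
        return sorted({s.meta.patient_id for s in self.samples})

    @property
    def paired_patients(self) -> list[str]:
        """Patients with both a diagnosis and a post-treatment sample."""
        by_pat: dict[str, set[str]] = {}
        for s in self.samples:
            by_pat.setdefault(s.meta.patient_id, set()).add(s.meta.timepoint)
        return sorted(p for p, tps in by_pat.items() if set(TIMEPOINTS) <= tps)

    def get(self, patient_id: str, timepoint: str) -> Sample:
        for s in self.samples:
            if s.key == (patient_id, timepoint):
                return s
        raise KeyError((patient_id, timepoint))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_GT_LAYERS = ("gt", "depth", "quality", "alt_fraction")


def _encode_str(values: Iterable) -> np.ndarray:
    return np.array([str(v) for v in values], dtype=h5py.string_dtype())


def _decode_str(ds) -> np.ndarray:
    return np.array([v.decode() if isinstance(v, bytes) else str(v) for v in ds[()]],
                    dtype=object)


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a CSV variant table into VariantRecord rows.

    Required columns: chrom, pos, ref, alt, gene. Optional: consequence,
    population_maf (blank -> absent), whitelisted, pathogenicity.
    """
    df = pd.read_csv(path)
    required = {"chrom", "pos", "ref", "alt", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise LoadError(f"variant table missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        maf = getattr(row, "population_maf", None)
        if maf is not None and (isinstance(maf, float) and np.isnan(maf)):
            maf = None
        patho = getattr(row, "pathogenicity", None)
        if isinstance(patho, float) and np.isnan(patho):
            patho = None
        records.append(VariantRecord(
            chrom=str(row.chrom), pos=int(row.pos), ref=str(row.ref),
            alt=str(row.alt), gene=str(row.gene),
            consequence=str(getattr(row, "consequence", "missense")),
            population_maf=None if maf is None else float(maf),
            whitelisted=bool(getattr(row, "whitelisted", False)),
            pathogenicity=patho,
        ))
    return records


def read_genotype_container(path: str | Path,
                            variant_table_path: str | Path) -> GenotypeMatrix:
    """Load a genotype container (HDF5 layers) plus its CSV variant table.

    The container must hold four aligned cells x variants datasets (``gt``,
    ``depth``, ``quality``, ``alt_fraction``) and a ``barcodes`` dataset,
    either at the file root or under a ``genotype/`` group. Unknown genotype
    codes are mapped to MISSING with a logged count.
    """
    variants = read_variant_table(variant_table_path)
    with h5py.File(path, "r") as f:
        grp = f["genotype"] if "genotype" in f else f
        barcodes = _decode_str(grp["barcodes"])
        layers = {}
        shape = None
        for name in _GT_LAYERS:
            if name not in grp:
                raise LoadError(f"container missing layer '{name}'")
            arr = grp[name][()]
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise LoadError(
                    f"layer '{name}' shape {arr.shape} differs from gt {shape}"
                )
            layers[name] = arr
    gt = np.asarray(layers["gt"])
    known = np.isin(gt, (GT_WT, GT_HET, GT_HOM, GT_MISSING))
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.warning("mapped %d unknown genotype codes to MISSING", n_unknown)
        gt = np.where(known, gt, GT_MISSING)
    return GenotypeMatrix(barcodes, variants, gt, layers["depth"],
                          layers["quality"], layers["alt_fraction"])


def read_panel(path: str | Path) -> list[Amplicon]:
    """Read a BED-like amplicon panel (chrom, start, end, amplicon_id, gene).

    Coordinates are 0-based half-open. Accepts tab- or comma-separated input,
    with or without a header line.
    """
    first = Path(path).open().readline()
    sep = "," if "," in first else r"\s+"
    has_header = "chrom" in first or "start" in first
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None,
                     engine="python")
    if not has_header:
        df.columns = ["chrom", "start", "end", "amplicon_id", "gene"][: len(df.columns)]
    amplicons = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if start >= end:
            raise LoadError(
                f"amplicon {row.amplicon_id}: start {start} >= end {end}"
            )
        aid = str(row.amplicon_id)
        if aid in seen:
            raise LoadError(f"duplicate amplicon id {aid}")
        seen.add(aid)
        amplicons.append(Amplicon(aid, str(row.chrom), start, end, str(row.gene)))
    logger.info("read %d amplicons over %d genes from %s", len(amplicons),
                len({a.gene for a in amplicons}), path)
    return amplicons


def read_antibody_table(path: str | Path) -> list[Antibody]:
    """Read a CSV antibody table with columns name, is_isotype."""
    df = pd.read_csv(path)
    if "name" not in df.columns:
        raise LoadError("antibody table missing 'name' column")
    iso = df["is_isotype"].astype(bool) if "is_isotype" in df.columns else \
        pd.Series(False, index=df.index)
    return [Antibody(str(n), bool(i)) for n, i in zip(df["name"], iso)]


def write_sample_container(path: str | Path, sample: Sample) -> None:
    """Write one sample's three matrices + metadata to a single HDF5 file."""
    with h5py.File(path, "w") as f:
        g = f.create_group("genotype")
        g.create_dataset("barcodes", data=_encode_str(sample.genotype.barcodes))
        g.create_dataset("gt", data=sample.genotype.gt.astype(np.int8))
        g.create_dataset("depth", data=sample.genotype.depth.astype(np.int32))
        g.create_dataset("quality", data=sample.genotype.quality.astype(np.float64))
        g.create_dataset("alt_fraction",
                         data=sample.genotype.alt_fraction.astype(np.float64))
        vt = g.create_group("variants")
        recs = sample.genotype.variants
        vt.create_dataset("chrom", data=_encode_str(r.chrom for r in recs))
        vt.create_dataset("pos", data=np.array([r.pos for r in recs], dtype=np.int64))
        vt.create_dataset("ref", data=_encode_str(r.ref for r in recs))
        vt.create_dataset("alt", data=_encode_str(r.alt for r in recs))
        vt.create_dataset("gene", data=_encode_str(r.gene for r in recs))
        vt.create_dataset("consequence", data=_encode_str(r.consequence for r in recs))
        vt.create_dataset("population_maf", data=np.array(
            [np.nan if r.population_maf is None else r.population_maf for r in recs]))
        vt.create_dataset("whitelisted", data=np.array(
            [r.whitelisted for r in recs], dtype=bool))

        a = f.create_group("amplicon")
        a.create_dataset("barcodes", data=_encode_str(sample.amplicon.barcodes))
        a.create_dataset("counts", data=sample.amplicon.counts)
        pt = a.create_group("panel")
        amps = sample.amplicon.amplicons
        pt.create_dataset("amplicon_id", data=_encode_str(x.amplicon_id for x in amps))
        pt.create_dataset("chrom", data=_encode_str(x.chrom for x in amps))
        pt.create_dataset("start", data=np.array([x.start for x in amps], dtype=np.int64))
        pt.create_dataset("end", data=np.array([x.end for x in amps], dtype=np.int64))
        pt.create_dataset("gene", data=_encode_str(x.gene for x in amps))

        p = f.create_group("adt")
        p.create_dataset("barcodes", data=_encode_str(sample.adt.barcodes))
        p.create_dataset("counts", data=sample.adt.counts)
        at = p.create_group("antibodies")
        abs_ = sample.adt.antibodies
        at.create_dataset("name", data=_encode_str(x.name for x in abs_))
        at.create_dataset("is_isotype", data=np.array(
            [x.is_isotype for x in abs_], dtype=bool))

        m = f.create_group("meta")
        m.attrs["patient_id"] = sample.meta.patient_id
        m.attrs["timepoint"] = sample.meta.timepoint
        m.attrs["response"] = sample.meta.response
        if sample.meta.hi_flag is not None:
            m.attrs["hi_flag"] = bool(sample.meta.hi_flag)
        if sample.meta.mcr_flag is not None:
            m.attrs["mcr_flag"] = bool(sample.meta.mcr_flag)


def read_sample_container(path: str | Path) -> Sample:
    """Read a sample container written by :func:`write_sample_container`."""
    with h5py.File(path, "r") as f:
        g = f["genotype"]
        vt = g["variants"]
        maf = vt["population_maf"][()]
        variants = [
            VariantRecord(
                chrom=c, pos=int(p), ref=r, alt=a, gene=gn, consequence=cq,
                population_maf=None if np.isnan(m) else float(m),
                whitelisted=bool(w),
            )
            for c, p, r, a, gn, cq, m, w in zip(
                _decode_str(vt["chrom"]), vt["pos"][()], _decode_str(vt["ref"]),
                _decode_str(vt["alt"]), _decode_str(vt["gene"]),
                _decode_str(vt["consequence"]), maf, vt["whitelisted"][()])
        ]
        genotype = GenotypeMatrix(
            _decode_str(g["barcodes"]), variants, g["gt"][()], g["depth"][()],
            g["quality"][()], g["alt_fraction"][()],
        )

        a = f["amplicon"]
        pt = a["panel"]
        amplicons = [
            Amplicon(i, c, int(s), int(e), gn)
            for i, c, s, e, gn in zip(
                _decode_str(pt["amplicon_id"]), _decode_str(pt["chrom"]),
                pt["start"][()], pt["end"][()], _decode_str(pt["gene"]))
        ]
        amplicon = AmpliconCountMatrix(_decode_str(a["barcodes"]), amplicons,
                                       a["counts"][()])

        p = f["adt"]
        at = p["antibodies"]
        antibodies = [Antibody(n, bool(i)) for n, i in
                      zip(_decode_str(at["name"]), at["is_isotype"][()])]
        adt = ADTMatrix(_decode_str(p["barcodes"]), antibodies, p["counts"][()])

        m = f["meta"].attrs
        meta = SampleMeta(
            patient_id=str(m["patient_id"]), timepoint=str(m["timepoint"]),
            response=str(m["response"]),
            hi_flag=bool(m["hi_flag"]) if "hi_flag" in m else None,
            mcr_flag=bool(m["mcr_flag"]) if "mcr_flag" in m else None,
        )
    return Sample(meta, genotype, amplicon, adt)


def write_counts_mtx(path: str | Path, counts: np.ndarray,
                     barcodes: Iterable, feature_names: Iterable) -> None:
    """MatrixMarket fallback for a counts matrix + sidecar row/column lists."""
    from scipy import io as scipy_io
    from scipy import sparse

    path = Path(path)
    scipy_io.mmwrite(str(path), sparse.csr_matrix(np.asarray(counts)))
    path.with_suffix(".barcodes.txt").write_text(
        "\n".join(str(b) for b in barcodes) + "\n")
    path.with_suffix(".features.txt").write_text(
        "\n".join(str(f) for f in feature_names) + "\n")


def read_counts_mtx(path: str | Path
                    ) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a counts matrix written by :func:`write_counts_mtx`."""
    from scipy import io as scipy_io

    path = Path(path)
    mtx = path if path.suffix == ".mtx" else path.with_suffix(".mtx")
    counts = np.asarray(scipy_io.mmread(str(mtx)).todense())
    barcodes = mtx.with_suffix(".barcodes.txt").read_text().splitlines()
    features = mtx.with_suffix(".features.txt").read_text().splitlines()
    if counts.shape != (len(barcodes), len(features)):
        raise LoadError("MTX shape does not match sidecar barcode/feature lists")
    return counts, barcodes, features


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def assemble_cohort(samples: Sequence[Sample]) -> CohortTable:
    """Intersect barcodes across modalities per sample and build a cohort.

    Cells present in only a subset of modalities are dropped (the DNA and
    protein QC steps legitimately retain different cell sets); drop counts are
    logged per sample. The result is independent of sample input order.
    """
    assembled = []
    for s in sorted(samples, key=lambda x: x.key):
        shared = (set(s.genotype.barcodes) & set(s.amplicon.barcodes)
                  & set(s.adt.barcodes))
        n_drop = (len(s.genotype.barcodes) + len(s.amplicon.barcodes)
                  + len(s.adt.barcodes) - 3 * len(shared))
        if n_drop:
            logger.info("sample %s: dropped %d modality-specific barcodes",
                        s.key, n_drop)
        # keep the genotype matrix's barcode order as canonical
        order = [b for b in s.genotype.barcodes if b in shared]
        gi = {b: i for i, b in enumerate(s.genotype.barcodes)}
        ai = {b: i for i, b in enumerate(s.amplicon.barcodes)}
        pi = {b: i for i, b in enumerate(s.adt.barcodes)}
        assembled.append(Sample(
            meta=s.meta,
            genotype=s.genotype.subset(cells=np.array([gi[b] for b in order], dtype=int)),
            amplicon=s.amplicon.subset(cells=np.array([ai[b] for b in order], dtype=int)),
            adt=s.adt.subset(np.array([pi[b] for b in order], dtype=int)),
        ))
    cohort = CohortTable(assembled)
    logger.info("assembled cohort: %d samples, %d patients (%d paired)",
                len(cohort.samples), len(cohort.patients),
                len(cohort.paired_patients))
    return cohort
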