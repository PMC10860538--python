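"""ADT (surface-protein) QC, CLR normalization, clustering and annotation.

Antibody-derived-tag counts are QC'd on per-cell totals, scaled to counts per
million with a +1 pseudocount, centered-log-ratio (CLR) transformed, and
denoised by subtracting each cell's mean isotype-control CLR (floored at 0).
Cells are clustered on a shared-nearest-neighbor graph built from a PCA
embedding, using seeded modularity-based community detection; flat
("artifact") clusters are dropped, and clusters are annotated by marker
rules into populations and six major compartments. Sample mixing is
quantified with the local inverse Simpson index (LISI): the effective number
of sample labels in each cell's neighborhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .core_io import ADTMatrix

logger = logging.getLogger("clonepulse")

COMPARTMENTS = ("progenitors", "immature_erythroid", "myeloid", "T", "NK",
                "B", "rare", "unassigned")


class ProteinError(ValueError):
    pass


@dataclass
class NormalizedADT:
    """CLR-normalized cells x antibodies matrix.

    Isotype columns are retained until denoising; afterwards ``values`` holds
    target antibodies only and ``denoised`` is True.
    """

    barcodes: np.ndarray
    antibody_names: list[str]
    isotype_mask: np.ndarray  # aligned to antibody_names
    values: np.ndarray  # (cells, antibodies) float
    raw_totals: np.ndarray  # per-cell raw ADT totals
    denoised: bool = False


@dataclass
class MarkerRule:
    """Annotation rule: all high markers above / low markers below cutoffs."""

    population: str
    high: tuple[str, ...]
    low: tuple[str, ...] = ()
    compartment: str = "unassigned"
    high_cutoff: float = 2.0
    low_cutoff: float = 1.3


@dataclass
class CellAnnotation:
    """Per-cell cluster id, population label and compartment."""

    table: pd.DataFrame  # barcode, cluster, population, compartment
    rare_single_sample: list[str] = field(default_factory=list)


@dataclass
class LisiResult:
    per_cell: np.ndarray
    mean: float
    median: float


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------


def qc_adt_cells(adt: ADTMatrix, min_total: int = 200,
                 max_total: int = 100_000) -> ADTMatrix:
    """Drop cells with total ADT counts below 200 or above 100,000.

    Boundaries are kept (the removal comparators are strict).
    """
    totals = adt.counts.sum(axis=1)
    keep = ~((totals < min_total) | (totals > max_total))
    if not keep.any():
        raise ProteinError("ADT cell QC removed every cell")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("ADT QC: removed %d of %d cells", n_drop, adt.n_cells)
    return adt.subset(np.flatnonzero(keep))


def normalize_clr(adt: ADTMatrix) -> NormalizedADT:
    """CPM (+1 pseudocount) followed by the centered log-ratio transform.

    Per cell: ``x' = CPM(x) + 1``; ``clr_i = ln x'_i - mean_j ln x'_j`` over
    all antibody columns including isotypes, so each cell's CLR values sum
    to zero.
    """
    totals = adt.counts.sum(axis=1).astype(float)
    if (totals == 0).any():
        raise ProteinError("zero-total cell reached normalization; run QC first")
    cpm = adt.counts / totals[:, None] * 1e6 + 1.0
    log = np.log(cpm)
    clr = log - log.mean(axis=1, keepdims=True)
    return NormalizedADT(
        barcodes=adt.barcodes.copy(),
        antibody_names=[ab.name for ab in adt.antibodies],
        isotype_mask=adt.isotype_mask,
        values=clr, raw_totals=adt.counts.sum(axis=1),
    )


def denoise_isotypes(norm: NormalizedADT) -> NormalizedADT:
    """Subtract each cell's mean isotype CLR from target CLRs, floor at 0."""
    if norm.denoised:
        raise ProteinError("matrix already denoised")
    iso = norm.isotype_mask
    if not iso.any():
        raise ProteinError("no isotype columns to denoise against")
    background = norm.values[:, iso].mean(axis=1, keepdims=True)
    target = np.maximum(norm.values[:, ~iso] - background, 0.0)
    return NormalizedADT(
        barcodes=norm.barcodes.copy(),
        antibody_names=[n for n, i in zip(norm.antibody_names, iso) if not i],
        isotype_mask=np.zeros(int((~iso).sum()), dtype=bool),
        values=target, raw_totals=norm.raw_totals.copy(), denoised=True,
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _snn_graph(embedding: np.ndarray, k: int) -> ig.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    adj = nn.kneighbors_graph(embedding, mode="connectivity")
    shared = adj @ adj.T  # counts of shared neighbors
    shared = sparse.triu(shared.tocoo(), k=1)
    rows, cols, vals = shared.row, shared.col, shared.data
    jaccard = vals / (2 * k - vals)
    keep = jaccard > 1.0 / 15.0  # prune tenuous links, Seurat-style
    edges = list(zip(rows[keep].tolist(), cols[keep].tolist()))
    g = ig.Graph(n=embedding.shape[0], edges=edges)
    g.es["weight"] = jaccard[keep].tolist()
    return g


def cluster_cells(norm: NormalizedADT, *, n_components: int = 15,
                  k: int = 20, resolution: float = 1.0,
                  seed: int = 0) -> np.ndarray:
    """PCA -> kNN -> SNN graph -> seeded modularity community detection.

    Deterministic given ``seed``. Returns integer cluster labels ordered by
    decreasing cluster size.
    """
    n = norm.values.shape[0]
    if n <= k:
        raise ProteinError(f"need more than k={k} cells, got {n}")
    n_comp = min(n_components, norm.values.shape[1], n - 1)
    emb = PCA(n_components=n_comp, random_state=seed).fit_transform(norm.values)
    g = _snn_graph(emb, k)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition, weights="weight",
        resolution_parameter=resolution, seed=seed, n_iterations=2)
    labels = np.asarray(part.membership)
    # relabel by size for stable downstream naming
    order = pd.Series(labels).value_counts().index.to_list()
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[v] for v in labels], dtype=int)


def subcluster(norm: NormalizedADT, labels: np.ndarray, cluster: int, *,
               resolution: float = 1.0, k: int = 20,
               seed: int = 0) -> np.ndarray:
    """Re-run community detection inside one cluster.

    Returns a copy of ``labels`` where the target cluster is split into
    ``max(labels)+1+i`` sub-labels.
    """
    mask = labels == cluster
    if mask.sum() <= k:
        return labels.copy()
    sub = NormalizedADT(norm.barcodes[mask], list(norm.antibody_names),
                        norm.isotype_mask.copy(), norm.values[mask],
                        norm.raw_totals[mask], norm.denoised)
    sub_labels = cluster_cells(sub, k=k, resolution=resolution, seed=seed)
    out = labels.copy()
    base = labels.max() + 1
    idx = np.flatnonzero(mask)
    keep_first = sub_labels == 0
    out[idx[~keep_first]] = base + sub_labels[~keep_first] - 1
    return out


def drop_artifact_clusters(norm: NormalizedADT, labels: np.ndarray, *,
                           variance_min: float = 0.05) -> np.ndarray:
    """Mark flat-profile clusters (likely technical artifacts) as unassigned.

    A cluster whose across-antibody variance of mean CLR falls below
    ``variance_min`` is removed; its cells get label -1.
    """
    out = labels.copy()
    for cl in np.unique(labels):
        if cl < 0:
            continue
        profile = norm.values[labels == cl].mean(axis=0)
        if float(profile.var()) < variance_min:
            logger.info("dropping artifact cluster %d (%d cells, var %.4f)",
                        cl, int((labels == cl).sum()), float(profile.var()))
            out[labels == cl] = -1
    return out


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def default_marker_rules() -> list[MarkerRule]:
    """Marker rules for the default synthetic bone-marrow populations.

    First-match semantics; compartments follow the six-way rollup
    (progenitors, immature erythroid, myeloid, T, NK, B) plus ``rare``.
    """
    return [
        MarkerRule("CMP", ("CD34", "CD38"), ("CD90", "CD3", "CD19"),
                   "progenitors"),
        MarkerRule("HSPC", ("CD34", "CD90"), ("CD3", "CD19"), "progenitors"),
        MarkerRule("erythroid_immature", ("CD71", "CD235a"),
                   ("CD3", "CD19", "CD11b"), "immature_erythroid"),
        MarkerRule("rare_cd11c", ("CD11c", "CD49d", "CD62P"),
                   ("CD3", "CD19"), "rare"),
        MarkerRule("monocyte", ("CD14", "CD11b", "CD64"), ("CD3",), "myeloid"),
        MarkerRule("nc_monocyte", ("CD16", "CD11b", "HLA-DR"),
                   ("CD3", "CD56", "CD15"), "myeloid"),
        MarkerRule("granulocyte", ("CD15", "CD11b"), ("CD3",), "myeloid"),
        MarkerRule("T", ("CD3",), ("CD19", "CD56"), "T"),
        MarkerRule("NK", ("CD56", "CD16"), ("CD3", "CD19"), "NK"),
        MarkerRule("B", ("CD19", "CD20"), ("CD3",), "B"),
    ]


def annotate(norm: NormalizedADT, labels: np.ndarray,
             rules: list[MarkerRule], *,
             sample_of_cell: np.ndarray | None = None,
             single_sample_max: float = 0.90) -> CellAnnotation:
    """Label clusters by the first marker rule matching their mean profile.

    Clusters matching no rule (or pre-marked -1) become ``unassigned``.
    Populations drawing more than ``single_sample_max`` of their cells from a
    single sample are flagged rare-single-sample and excluded from the
    compartment rollup (compartment set to ``rare``).
    """
    if not rules:
        raise ProteinError("empty marker rule table")
    name_idx = {n: j for j, n in enumerate(norm.antibody_names)}
    population = {}
    compartment = {}
    for cl in np.unique(labels):
        if cl < 0:
            population[cl], compartment[cl] = "unassigned", "unassigned"
            continue
        profile = norm.values[labels == cl].mean(axis=0)
        population[cl], compartment[cl] = "unassigned", "unassigned"
        for rule in rules:
            # a required-high marker missing from the panel fails the rule;
            # a required-low marker missing from the panel is vacuously low
            highs_ok = all(m in name_idx
                           and profile[name_idx[m]] > rule.high_cutoff
                           for m in rule.high)
            lows_ok = all(profile[name_idx[m]] < rule.low_cutoff
                          for m in rule.low if m in name_idx)
            if highs_ok and lows_ok:
                population[cl], compartment[cl] = rule.population, \
                    rule.compartment
                break
    table = pd.DataFrame({
        "barcode": norm.barcodes,
        "cluster": labels,
        "population": [population[c] for c in labels],
        "compartment": [compartment[c] for c in labels],
    })

    rare_flagged: list[str] = []
    if sample_of_cell is not None:
        table["sample"] = sample_of_cell
        for pop, grp in table.groupby("population"):
            if pop == "unassigned":
                continue
            top = grp["sample"].value_counts(normalize=True).iloc[0]
            if top > single_sample_max:
                rare_flagged.append(pop)
                table.loc[table["population"] == pop, "compartment"] = "rare"
        table = table.drop(columns="sample")
        if rare_flagged:
            logger.info("rare single-sample populations excluded from "
                        "compartments: %s", rare_flagged)
    return CellAnnotation(table=table, rare_single_sample=rare_flagged)


# ---------------------------------------------------------------------------
# LISI
# ---------------------------------------------------------------------------


def lisi(embedding: np.ndarray, labels: np.ndarray, *,
         perplexity: float = 30.0) -> LisiResult:
    """Local inverse Simpson index of label mixing per cell.

    Neighbor weights use a Gaussian kernel calibrated per cell to the target
    perplexity (as in t-SNE); the index is ``1 / sum_l p_l^2`` over the
    kernel-weighted label distribution, ranging from 1 (isolated label) to
    the number of labels (perfect local mixing).
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n = embedding.shape[0]
    if uniq.size == 1:
        vals = np.ones(n)
        return LisiResult(vals, 1.0, 1.0)
    k = min(n - 1, int(3 * perplexity))
    if n < 3 * perplexity:
        raise ProteinError(
            f"need at least {int(3 * perplexity)} cells for perplexity "
            f"{perplexity}, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    dist, idx = nn.kneighbors(embedding)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    label_codes = np.searchsorted(uniq, labels)
    target = np.log(perplexity)

    d2 = dist ** 2
    vals = np.empty(n)
    for i in range(n):
        lo, hi = 1e-10, 1e10
        beta = 1.0
        for _ in range(50):
            w = np.exp(-d2[i] * beta)
            s = w.sum()
            if s <= 0:
                entropy = 0.0
            else:
                p = w / s
                nzp = p[p > 0]
                entropy = float(-(nzp * np.log(nzp)).sum())
            if abs(entropy - target) < 1e-5:
                break
            if entropy > target:
                lo = beta
                beta = beta * 2 if hi >= 1e10 else (beta + hi) / 2
            else:
                hi = beta
                beta = beta / 2 if lo <= 1e-10 else (beta + lo) / 2
        w = np.exp(-d2[i] * beta)
        p = w / w.sum() if w.sum() > 0 else np.full(k, 1.0 / k)
        pl = np.bincount(label_codes[idx[i]], weights=p,
                         minlength=uniq.size)
        vals[i] = 1.0 / float((pl ** 2).sum())
    return LisiResult(vals, float(vals.mean()), float(np.median(vals)))
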