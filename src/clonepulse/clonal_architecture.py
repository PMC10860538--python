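"""Clone calling, ADO-clone removal, phylogeny, clone statistics, dynamics.

A clone is a set of cells sharing an identical variant->zygosity signature
over the retained variants. Cells with any MISSING call among retained
variants are set aside as unassigned rather than imputed. Spurious clones
created by allele dropout (one HET->WT or HET->HOM substitution away from a
larger clone, at a size compatible with the sample's dropout rate) are merged
back into their parent.

Phylogenies are rooted at the wild-type clone and ordered by mutation-set
inclusion with zygosity progression: a HET call at a site may precede a HOM
call at the same site, never the reverse. Paired-timepoint clone proportions
are classified into shrinkage / stable / expansion patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .core_io import GT_HET, GT_HOM, GT_MISSING, GenotypeMatrix
from .variant_qc import AdoEstimate, vaf_by_cell_count

logger = logging.getLogger("clonepulse")

Signature = tuple[tuple[str, int], ...]  # sorted (variant name, zygosity)

#: canonical CHIP gene sets
CHIP_CORE3 = frozenset({"TET2", "DNMT3A", "ASXL1"})
CHIP_CORE5 = CHIP_CORE3 | {"SF3B1", "TP53"}


@dataclass
class Clone:
    clone_id: str
    signature: dict[str, int]  # variant name -> GT_HET / GT_HOM
    barcodes: list[str]

    @property
    def is_wt(self) -> bool:
        return not self.signature

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def key(self) -> Signature:
        return tuple(sorted(self.signature.items()))

    def genes(self, gene_map: dict[str, str]) -> set[str]:
        """Genes touched by this clone's signature, via a name->gene map."""
        return {gene_map[n] for n in self.signature if n in gene_map}


@dataclass
class CloneSet:
    clones: list[Clone]
    unassigned: list[str] = field(default_factory=list)  # barcodes
    gene_map: dict[str, str] = field(default_factory=dict)  # variant -> gene

    @property
    def n_assigned(self) -> int:
        return sum(c.n_cells for c in self.clones)

    @property
    def mutant_clones(self) -> list[Clone]:
        """Real mutant clones (the sub-threshold 'minor' pool excluded)."""
        return [c for c in self.clones
                if not c.is_wt and c.clone_id != "minor"]

    @property
    def wt_clone(self) -> Clone | None:
        for c in self.clones:
            if c.is_wt:
                return c
        return None

    def fractions_of_all(self) -> dict[str, float]:
        """Clone fraction of all assigned cells."""
        total = self.n_assigned
        return {c.clone_id: c.n_cells / total for c in self.clones} if total \
            else {}

    def mutant_fractions(self) -> dict[str, float]:
        """Mutant-clone fractions renormalized to mutant cells only."""
        mut = self.mutant_clones
        total = sum(c.n_cells for c in mut)
        return {c.clone_id: c.n_cells / total for c in mut} if total else {}


@dataclass
class Phylogeny:
    graph: nx.DiGraph  # nodes = clone ids, edges parent -> child
    root: str
    topology: str  # linear | branched
    conflicts: list[tuple[str, str]]  # incomparable clone pairs sharing mutations
    clones: dict[str, Clone]
    gene_map: dict[str, str] = field(default_factory=dict)


@dataclass
class DynamicsCall:
    pattern: str  # shrinkage | stable | expansion
    deltas: dict[str, float]  # clone -> post - dx fraction of all cells
    mutant_fraction: dict[str, float]  # timepoint -> mutant fraction of cells
    predominant_fraction: dict[str, float | None]  # timepoint -> fraction


# ---------------------------------------------------------------------------
# clone calling
# ---------------------------------------------------------------------------


def call_clones(gm: GenotypeMatrix, *, min_clone_fraction: float = 0.01,
                whitelist: set[str] | None = None) -> CloneSet:
    """Group cells by identical genotype signatures over retained variants.

    Cells with a MISSING call at any retained variant are reported as
    unassigned. Clones below ``min_clone_fraction`` of assigned cells are
    pooled into a ``minor`` clone, unless they carry a whitelisted variant
    (by name) that no major clone carries — the whitelist guarantees a
    bulk-confirmed variant is never silently pooled away, without promoting
    every dropout/error combination of already-represented variants to clone
    status.
    """
    if gm.n_variants == 0:
        logger.warning("no retained variants: returning a single WT clone")
        return CloneSet([Clone("WT", {}, list(gm.barcodes))],
                        gene_map={r.name: r.gene for r in gm.variants})
    complete = (gm.gt != GT_MISSING).all(axis=1)
    unassigned = [str(b) for b in gm.barcodes[~complete]]
    names = [rec.name for rec in gm.variants]
    gene_map = {rec.name: rec.gene for rec in gm.variants}
    wl_names = whitelist or set()

    groups: dict[Signature, list[str]] = {}
    for i in np.flatnonzero(complete):
        sig = tuple((names[j], int(g)) for j, g in enumerate(gm.gt[i])
                    if g in (GT_HET, GT_HOM))
        groups.setdefault(sig, []).append(str(gm.barcodes[i]))

    n_assigned = sum(len(v) for v in groups.values())
    major_variants: set[str] = set()
    for sig, barcodes in groups.items():
        if n_assigned and len(barcodes) / n_assigned >= min_clone_fraction:
            major_variants |= {name for name, _ in sig}

    clones: list[Clone] = []
    minor: list[str] = []
    mutant_counter = 0
    for sig, barcodes in sorted(groups.items(),
                                key=lambda kv: (-len(kv[1]), kv[0])):
        sig_dict = dict(sig)
        if not sig_dict:
            clones.append(Clone("WT", {}, barcodes))
            continue
        frac = len(barcodes) / n_assigned if n_assigned else 0.0
        rescued = bool((set(sig_dict) & wl_names) - major_variants)
        if frac < min_clone_fraction and not rescued:
            minor.extend(barcodes)
            continue
        mutant_counter += 1
        clones.append(Clone(f"C{mutant_counter}", sig_dict, barcodes))
    if not any(c.is_wt for c in clones):
        clones.insert(0, Clone("WT", {}, []))
    if minor:
        logger.info("pooled %d cells from sub-threshold clones into 'minor'",
                    len(minor))
        clones.append(Clone("minor", {"_minor_pool": GT_HET}, minor))
    return CloneSet(clones=clones, unassigned=unassigned, gene_map=gene_map)


# ---------------------------------------------------------------------------
# ADO-clone removal
# ---------------------------------------------------------------------------


def _single_dropout_parent(child: dict[str, int], parent: dict[str, int]) -> bool:
    """True if ``child`` is ``parent`` after exactly one HET->WT or HET->HOM."""
    # HET -> HOM : same keys, exactly one zygosity raised from HET to HOM
    if set(child) == set(parent):
        diffs = [(k, parent[k], child[k]) for k in parent if parent[k] != child[k]]
        return (len(diffs) == 1 and diffs[0][1] == GT_HET
                and diffs[0][2] == GT_HOM)
    # HET -> WT : one HET key of the parent vanished
    missing = set(parent) - set(child)
    if set(child) < set(parent) and len(missing) == 1:
        (lost,) = missing
        return parent[lost] == GT_HET and all(child[k] == parent[k]
                                              for k in child)
    return False


def flag_ado_clones(clone_set: CloneSet, ado: AdoEstimate, *,
                    safety_factor: float = 1.5) -> CloneSet:
    """Merge dropout-artifact clones into their source clone.

    A clone one HET->WT / HET->HOM substitution away from a larger clone and
    no bigger than that clone's dropout expectation
    (``parent_cells x ado/100 x safety_factor``) is absorbed into it.
    """
    expectation_rate = ado.sample_ado / 100.0 * safety_factor
    clones = sorted(clone_set.clones, key=lambda c: -c.n_cells)
    merged_into: dict[str, str] = {}
    for cand in clones:
        if cand.is_wt:
            continue
        for parent in clones:
            if parent is cand or parent.clone_id in merged_into:
                continue
            if parent.n_cells <= cand.n_cells:
                continue
            if not _single_dropout_parent(cand.signature, parent.signature):
                continue
            if cand.n_cells <= parent.n_cells * expectation_rate:
                merged_into[cand.clone_id] = parent.clone_id
                logger.info("ADO-clone merge: %s (%d cells) -> %s (%d cells)",
                            cand.clone_id, cand.n_cells, parent.clone_id,
                            parent.n_cells)
                break
    if not merged_into:
        return clone_set
    out: dict[str, Clone] = {c.clone_id: Clone(c.clone_id, dict(c.signature),
                                               list(c.barcodes))
                             for c in clones if c.clone_id not in merged_into}
    for child_id, parent_id in merged_into.items():
        child = next(c for c in clones if c.clone_id == child_id)
        out[parent_id].barcodes.extend(child.barcodes)
    return CloneSet(clones=list(out.values()),
                    unassigned=list(clone_set.unassigned),
                    gene_map=dict(clone_set.gene_map))


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------


def _is_ancestor(a: dict[str, int], b: dict[str, int]) -> bool:
    """Ancestry by mutation-set inclusion with zygosity progression.

    ``a`` precedes ``b`` when every mutated site of ``a`` is mutated in ``b``
    with equal or progressed zygosity (HET may deepen to HOM, never the
    reverse) and the signatures differ.
    """
    if a == b:
        return False
    for site, zyg in a.items():
        if site not in b or b[site] < zyg:
            return False
    return True


def build_phylogeny(clone_set: CloneSet) -> Phylogeny:
    """Root the clones at WT and attach each to its largest proper ancestor.

    Incomparable clone pairs sharing mutations not explained by their lowest
    common ancestor are recorded as conflicts (reported, never raised).
    """
    clones = {c.clone_id: c for c in clone_set.clones
              if c.clone_id != "minor"}
    if not any(c.is_wt for c in clones.values()):
        clones["WT"] = Clone("WT", {}, [])
    root = next(cid for cid, c in clones.items() if c.is_wt)

    g = nx.DiGraph()
    g.add_nodes_from(clones)
    parents: dict[str, str] = {}
    for cid, clone in clones.items():
        if cid == root:
            continue
        ancestors = [o for oid, o in clones.items()
                     if _is_ancestor(o.signature, clone.signature)]
        # largest proper ancestor: deepest signature, cell count breaks ties
        parent = max(ancestors, key=lambda o: (len(o.signature), o.n_cells,
                                               o.clone_id))
        parents[cid] = parent.clone_id
        g.add_edge(parent.clone_id, cid)

    # conflicts: incomparable pairs whose shared mutations exceed their LCA
    conflicts: list[tuple[str, str]] = []

    def ancestry_chain(cid: str) -> list[str]:
        chain = [cid]
        while chain[-1] != root:
            chain.append(parents[chain[-1]])
        return chain

    for a_id, b_id in combinations(sorted(set(clones) - {root}), 2):
        a, b = clones[a_id], clones[b_id]
        if _is_ancestor(a.signature, b.signature) or \
                _is_ancestor(b.signature, a.signature):
            continue
        shared = set(a.signature) & set(b.signature)
        if not shared:
            continue
        lca = next(c for c in ancestry_chain(a_id)
                   if c in set(ancestry_chain(b_id)))
        if not shared <= set(clones[lca].signature):
            conflicts.append((a_id, b_id))

    out_degrees = [d for _, d in g.out_degree()]
    topology = "linear" if all(d <= 1 for d in out_degrees) else "branched"
    return Phylogeny(graph=g, root=root, topology=topology,
                     conflicts=conflicts, clones=clones,
                     gene_map=dict(clone_set.gene_map))


# ---------------------------------------------------------------------------
# clone statistics
# ---------------------------------------------------------------------------


def shannon_index(fractions) -> float:
    """H = -sum p ln p over positive fractions (natural log)."""
    p = np.asarray([f for f in fractions if f > 0], dtype=float)
    if p.size == 0:
        raise ValueError("Shannon index undefined for empty composition")
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def clone_stats(clone_set: CloneSet) -> dict:
    """Mutant-clone count, Shannon diversity and predominant-clone size.

    Diversity and predominance are computed over mutant-clone fractions
    renormalized to mutant cells; both are absent (None) without mutant
    clones.
    """
    mut_fracs = clone_set.mutant_fractions()
    n_mut = len(mut_fracs)
    if n_mut == 0:
        return {"n_mutant_clones": 0, "shannon": None,
                "predominant_fraction": None}
    return {
        "n_mutant_clones": n_mut,
        "shannon": shannon_index(mut_fracs.values()),
        "predominant_fraction": max(mut_fracs.values()),
    }


def clone_gene_attribution(phylo: Phylogeny) -> dict:
    """Genes of the first (earliest) and predominant mutant clones.

    The first clone is the set of depth-1 mutant children of the root (ties
    reported as a set and logged); the predominant clone is the largest
    mutant clone.
    """
    first_clones = sorted(phylo.graph.successors(phylo.root))
    if len(first_clones) > 1:
        logger.info("first-clone tie between %s", first_clones)
    mutants = [c for c in phylo.clones.values() if not c.is_wt]
    if not mutants:
        return {"first_clones": [], "first_clone_genes": set(),
                "predominant_clone": None, "predominant_clone_genes": set()}
    predominant = max(mutants, key=lambda c: (c.n_cells, c.clone_id))
    first_genes: set[str] = set()
    for cid in first_clones:
        first_genes |= phylo.clones[cid].genes(phylo.gene_map)
    return {
        "first_clones": first_clones,
        "first_clone_genes": first_genes,
        "predominant_clone": predominant.clone_id,
        "predominant_clone_genes": predominant.genes(phylo.gene_map),
    }


def chip_flags(clone: Clone, definition: str, gene_map: dict[str, str], *,
               driver_genes: set[str] | None = None,
               gm: GenotypeMatrix | None = None,
               vaf_min: float = 2.0) -> bool:
    """CHIP status of a clone under one of three definitions.

    ``core3``: TET2/DNMT3A/ASXL1; ``core5``: adds SF3B1 and TP53;
    ``driver_vaf2``: any driver-gene mutation whose VAF-by-cell-count exceeds
    ``vaf_min`` percent (needs the genotype matrix and a driver list).
    """
    genes = clone.genes(gene_map)
    if definition == "core3":
        return bool(genes & CHIP_CORE3)
    if definition == "core5":
        return bool(genes & CHIP_CORE5)
    if definition == "driver_vaf2":
        if driver_genes is None:
            raise ValueError("driver_vaf2 requires a driver gene list")
        if gm is None:
            raise ValueError("driver_vaf2 requires the genotype matrix")
        name_idx = {rec.name: j for j, rec in enumerate(gm.variants)}
        gene_of = {rec.name: rec.gene for rec in gm.variants}
        for vname in clone.signature:
            if vname not in name_idx:
                continue
            if gene_of[vname] not in driver_genes:
                continue
            if vaf_by_cell_count(gm.gt[:, name_idx[vname]]) > vaf_min:
                return True
        return False
    raise ValueError(f"unknown CHIP definition {definition!r}")


# ---------------------------------------------------------------------------
# paired-timepoint dynamics
# ---------------------------------------------------------------------------


def classify_dynamics(dx: CloneSet, post: CloneSet, *,
                      shrink_factor: float = 0.5,
                      new_clone_min: float = 0.02) -> DynamicsCall:
    """Classify paired clone proportions as shrinkage / stable / expansion.

    Shrinkage: every diagnosis mutant clone's fraction of all cells falls
    below ``shrink_factor`` times its diagnosis value and no new clone at or
    above ``new_clone_min`` appears. Expansion: a new clone >=
    ``new_clone_min`` appears, or a minority clone (below the diagnosis
    predominant clone) more than doubles. Otherwise stable.
    """
    if dx is None or post is None:
        raise ValueError("dynamics classification requires both timepoints")
    dx_frac = {c.key: c.n_cells / dx.n_assigned
               for c in dx.clones if not c.is_wt and c.clone_id != "minor"}
    post_frac = {c.key: c.n_cells / post.n_assigned
                 for c in post.clones if not c.is_wt and c.clone_id != "minor"}

    key_to_id = {c.key: c.clone_id for c in dx.clones}
    key_to_id.update({c.key: c.clone_id for c in post.clones
                      if c.key not in key_to_id})
    deltas = {key_to_id[k]: post_frac.get(k, 0.0) - dx_frac.get(k, 0.0)
              for k in set(dx_frac) | set(post_frac)}

    new_clones = [k for k in post_frac
                  if k not in dx_frac and post_frac[k] >= new_clone_min]
    all_shrunk = bool(dx_frac) and all(
        post_frac.get(k, 0.0) < shrink_factor * f for k, f in dx_frac.items())

    # a doubling minority clone signals expansion only once it reaches a
    # non-trivial size (new_clone_min), so a handful of cells cannot flip
    # the call
    minority_doubled = False
    if dx_frac:
        predominant = max(dx_frac.values())
        for k, f in dx_frac.items():
            post_f = post_frac.get(k, 0.0)
            if f < predominant and post_f > 2.0 * f and post_f >= new_clone_min:
                minority_doubled = True

    if new_clones or minority_doubled:
        pattern = "expansion"
    elif all_shrunk:
        pattern = "shrinkage"
    else:
        pattern = "stable"

    def mutant_fraction(cs: CloneSet) -> float:
        mut = sum(c.n_cells for c in cs.mutant_clones)
        return mut / cs.n_assigned if cs.n_assigned else 0.0

    def predominant_fraction(cs: CloneSet) -> float | None:
        fr = cs.mutant_fractions()
        return max(fr.values()) if fr else None

    return DynamicsCall(
        pattern=pattern, deltas=deltas,
        mutant_fraction={"diagnosis": mutant_fraction(dx),
                         "post_treatment": mutant_fraction(post)},
        predominant_fraction={"diagnosis": predominant_fraction(dx),
                              "post_treatment": predominant_fraction(post)},
    )
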