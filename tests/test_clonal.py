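"""Clone calling, ADO-clone merging, phylogeny and dynamics."""

import math

import numpy as np
import pytest

from clonepulse.clonal_architecture import (
    Clone, CloneSet, build_phylogeny, call_clones, chip_flags,
    classify_dynamics, clone_gene_attribution, clone_stats, flag_ado_clones,
    shannon_index,
)
from clonepulse.core_io import GT_HET, GT_HOM, GT_MISSING, GT_WT
from clonepulse.synthetic_data import simulate_cohort, single_patient_config
from clonepulse.variant_qc import AdoEstimate

from conftest import make_genotype_matrix, make_variant


def _clone(cid, sig, n, gene_map=None):
    return Clone(cid, sig, [f"{cid}_{i}" for i in range(n)])


def _clone_set(clones, gene_map=None):
    return CloneSet(clones, gene_map=gene_map or {})


def _ado(pct):
    return AdoEstimate(per_variant={}, sample_ado=pct)


class TestCallClones:
    def test_three_signatures_three_clones(self):
        gt = np.array([[GT_WT, GT_WT]] * 40 + [[GT_HET, GT_WT]] * 30
                      + [[GT_HET, GT_HET]] * 30)
        cs = call_clones(make_genotype_matrix(gt))
        sigs = sorted(tuple(sorted(c.signature.items())) for c in cs.clones)
        assert len(cs.clones) == 3
        assert sum(c.is_wt for c in cs.clones) == 1
        assert len(cs.mutant_clones) == 2

    def test_all_wt_single_clone(self):
        cs = call_clones(make_genotype_matrix(np.zeros((20, 2), dtype=int)))
        assert len(cs.clones) == 1 and cs.clones[0].is_wt
        assert cs.mutant_clones == []

    def test_missing_cells_unassigned(self):
        gt = np.array([[GT_HET, GT_HET]] * 10 + [[GT_HET, GT_MISSING]] * 3)
        cs = call_clones(make_genotype_matrix(gt))
        assert len(cs.unassigned) == 3
        assert cs.n_assigned == 10

    def test_small_clones_pool_into_minor(self):
        gt = np.array([[GT_WT]] * 150 + [[GT_HET]] * 1)
        cs = call_clones(make_genotype_matrix(gt))
        ids = {c.clone_id for c in cs.clones}
        assert "minor" in ids and len(cs.mutant_clones) == 0

    def test_whitelist_rescues_unrepresented_variant(self):
        v = make_variant("RARE", whitelisted=True)
        gt = np.array([[GT_WT]] * 150 + [[GT_HET]] * 1)
        cs = call_clones(make_genotype_matrix(gt, [v]), whitelist={v.name})
        assert len(cs.mutant_clones) == 1

    def test_no_variants_returns_wt_clone(self):
        gm = make_genotype_matrix(np.zeros((5, 0), dtype=int), variants=[])
        cs = call_clones(gm)
        assert len(cs.clones) == 1 and cs.clones[0].is_wt

    def test_noiseless_simulation_recovers_truth_exactly(self):
        cfg = single_patient_config(
            "stable", n_cells=1000, ado_rate=0.0, genotype_error_rate=0.0,
            missing_rate=0.0, gq_pass_rate=1.0, seed=11, n_amplicons=2)
        cohort, truth = simulate_cohort(cfg)
        gm = cohort.get("P01", "diagnosis").genotype
        # restrict to somatic variants, as the QC chain would
        somatic = [j for j, r in enumerate(gm.variants)
                   if r.name not in cfg.germline_het]
        cs = call_clones(gm.subset(variants=np.array(somatic)))
        cells = truth.cells.query("timepoint == 'diagnosis'") \
            .set_index("barcode").clone_id
        for clone in cs.clones:
            true_ids = {cells[b] for b in clone.barcodes}
            assert len(true_ids) == 1  # each called clone is one true clone
            true_sig = truth.clone_signatures[("P01", true_ids.pop())]
            assert clone.signature == true_sig
        assert len(cs.clones) == 4 and not cs.unassigned


class TestFlagAdoClones:
    def test_dropout_sized_clone_merged(self):
        parent = _clone("P", {"A": GT_HET, "B": GT_HET}, 1000)
        cand = _clone("Q", {"A": GT_HET, "B": GT_HOM}, 40)
        out = flag_ado_clones(_clone_set([parent, cand]), _ado(10.0))
        ids = {c.clone_id: c.n_cells for c in out.clones}
        assert "Q" not in ids and ids["P"] == 1040  # 40 <= 1000*0.1*1.5

    def test_oversized_clone_kept(self):
        parent = _clone("P", {"A": GT_HET, "B": GT_HET}, 1000)
        cand = _clone("Q", {"A": GT_HET, "B": GT_HOM}, 400)
        out = flag_ado_clones(_clone_set([parent, cand]), _ado(10.0))
        assert {c.clone_id for c in out.clones} == {"P", "Q"}

    def test_het_loss_direction_merged(self):
        parent = _clone("P", {"A": GT_HET, "B": GT_HET}, 500)
        cand = _clone("Q", {"A": GT_HET}, 30)
        out = flag_ado_clones(_clone_set([parent, cand]), _ado(10.0))
        assert {c.clone_id for c in out.clones} == {"P"}

    def test_zero_ado_never_merges(self):
        parent = _clone("P", {"A": GT_HET, "B": GT_HET}, 1000)
        cand = _clone("Q", {"A": GT_HET, "B": GT_HOM}, 1)
        out = flag_ado_clones(_clone_set([parent, cand]), _ado(0.0))
        assert {c.clone_id for c in out.clones} == {"P", "Q"}

    def test_never_absorbs_well_populated_true_clone(self):
        """A clone 3x above the dropout expectation always survives."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n_parent = int(rng.integers(300, 2000))
            ado = float(rng.uniform(2, 15))
            floor = int(np.ceil(3 * n_parent * ado / 100 * 1.5)) + 1
            parent = _clone("P", {"A": GT_HET}, n_parent)
            cand = _clone("Q", {"A": GT_HOM}, floor)
            out = flag_ado_clones(_clone_set([parent, cand]), _ado(ado))
            assert "Q" in {c.clone_id for c in out.clones}


class TestBuildPhylogeny:
    def test_linear_chain(self):
        cs = _clone_set([_clone("WT", {}, 50), _clone("A", {"a": 1}, 30),
                         _clone("AB", {"a": 1, "b": 1}, 20),
                         _clone("ABC", {"a": 1, "b": 1, "c": 1}, 10)])
        ph = build_phylogeny(cs)
        assert ph.topology == "linear"
        assert set(ph.graph.edges) == {("WT", "A"), ("A", "AB"),
                                       ("AB", "ABC")}
        assert not ph.conflicts

    def test_branched(self):
        cs = _clone_set([_clone("WT", {}, 50), _clone("A", {"a": 1}, 30),
                         _clone("AB", {"a": 1, "b": 1}, 20),
                         _clone("AC", {"a": 1, "c": 1}, 10)])
        ph = build_phylogeny(cs)
        assert ph.topology == "branched"
        assert set(ph.graph.successors("A")) == {"AB", "AC"}
        assert not ph.conflicts

    def test_zygosity_progression_het_before_hom(self):
        cs = _clone_set([_clone("WT", {}, 50),
                         _clone("Ahet", {"a": GT_HET}, 30),
                         _clone("Ahom", {"a": GT_HOM}, 10)])
        ph = build_phylogeny(cs)
        assert ("Ahet", "Ahom") in ph.graph.edges

    def test_incompatible_signatures_reported_as_conflicts(self):
        cs = _clone_set([_clone("WT", {}, 50),
                         _clone("AB", {"a": 1, "b": 1}, 30),
                         _clone("BC", {"b": 1, "c": 1}, 20),
                         _clone("AC", {"a": 1, "c": 1}, 10)])
        ph = build_phylogeny(cs)
        # brute-force: every incomparable pair shares a mutation their LCA
        # (the root) lacks
        assert sorted(ph.conflicts) == [("AB", "AC"), ("AB", "BC"),
                                        ("AC", "BC")]

    def test_noiseless_topologies_recovered(self):
        """Linear and branched generating hierarchies are recovered as
        graph-identical phylogenies."""
        for topo in ("linear", "branched"):
            cfg = single_patient_config(
                "stable", n_cells=1200, ado_rate=0.0, genotype_error_rate=0.0,
                missing_rate=0.0, gq_pass_rate=1.0, seed=13,
                topology=topo, n_amplicons=2)
            cohort, truth = simulate_cohort(cfg)
            gm = cohort.get("P01", "diagnosis").genotype
            somatic = [j for j, r in enumerate(gm.variants)
                       if r.name not in cfg.germline_het]
            cs = call_clones(gm.subset(variants=np.array(somatic)))
            ph = build_phylogeny(cs)
            assert ph.topology == topo
            # expected parent of each true clone by signature inclusion
            sig_of = {tuple(sorted(truth.clone_signatures[("P01", c)].items())):
                      c for c in truth.cells.clone_id.unique()}
            called = {c.clone_id: tuple(sorted(c.signature.items()))
                      for c in ph.clones.values()}
            truth_parents = {p.clone_id: p.parent_id
                             for p in cfg.patients[0].clones}
            for child, parent in ph.graph.edges:
                pass
            for cid, sig in called.items():
                true_id = sig_of[sig]
                preds = list(ph.graph.predecessors(cid))
                if not preds:
                    assert truth_parents[true_id] is None
                else:
                    assert sig_of[called[preds[0]]] == truth_parents[true_id]


class TestCloneStats:
    def test_single_mutant_clone(self):
        cs = _clone_set([_clone("WT", {}, 50), _clone("A", {"a": 1}, 30)])
        s = clone_stats(cs)
        assert s["n_mutant_clones"] == 1
        assert s["shannon"] == pytest.approx(0.0)
        assert s["predominant_fraction"] == pytest.approx(1.0)

    def test_two_equal_clones_ln2(self):
        cs = _clone_set([_clone("WT", {}, 40), _clone("A", {"a": 1}, 30),
                         _clone("B", {"b": 1}, 30)])
        assert clone_stats(cs)["shannon"] == pytest.approx(math.log(2))

    def test_uneven_fractions(self):
        assert shannon_index([0.7, 0.2, 0.1]) == pytest.approx(0.8018,
                                                               abs=5e-5)

    def test_no_mutant_clones_absent(self):
        s = clone_stats(_clone_set([_clone("WT", {}, 10)]))
        assert s == {"n_mutant_clones": 0, "shannon": None,
                     "predominant_fraction": None}

    def test_shannon_permutation_invariant_and_maximal_at_uniform(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            p = rng.dirichlet([1.0, 1.0, 1.0])
            h = shannon_index(p)
            assert h == pytest.approx(shannon_index(p[::-1]))
            assert h <= math.log(3) + 1e-12


class TestGeneAttribution:
    GENES = {"t": "TET2", "a": "ASXL1", "s": "SF3B1"}

    def test_linear_first_and_predominant(self):
        cs = _clone_set([_clone("WT", {}, 50), _clone("C1", {"t": 1}, 10),
                         _clone("C2", {"t": 1, "a": 1}, 40)],
                        gene_map=self.GENES)
        out = clone_gene_attribution(build_phylogeny(cs))
        assert out["first_clone_genes"] == {"TET2"}
        assert out["predominant_clone"] == "C2"
        assert out["predominant_clone_genes"] == {"TET2", "ASXL1"}

    def test_tied_first_clones_reported_as_set(self):
        cs = _clone_set([_clone("WT", {}, 50), _clone("C1", {"t": 1}, 20),
                         _clone("C2", {"a": 1}, 20)], gene_map=self.GENES)
        out = clone_gene_attribution(build_phylogeny(cs))
        assert out["first_clones"] == ["C1", "C2"]
        assert out["first_clone_genes"] == {"TET2", "ASXL1"}

    def test_wt_only_patient_empty(self):
        out = clone_gene_attribution(build_phylogeny(
            _clone_set([_clone("WT", {}, 50)])))
        assert out["first_clone_genes"] == set()
        assert out["predominant_clone"] is None


class TestChipFlags:
    GENES = {"d": "DNMT3A", "s": "SF3B1", "n": "NRAS"}

    def test_core3_membership(self):
        clone = _clone("C", {"d": 1}, 10)
        assert chip_flags(clone, "core3", self.GENES)

    def test_sf3b1_only_in_core5(self):
        clone = _clone("C", {"s": 1}, 10)
        assert not chip_flags(clone, "core3", self.GENES)
        assert chip_flags(clone, "core5", self.GENES)

    def test_driver_vaf_threshold(self):
        v = make_variant("NRAS_v", gene="NRAS")
        # 1 HET among 100 genotyped cells -> VAF 0.5% <= 2%
        gt = np.array([[GT_HET]] + [[GT_WT]] * 99)
        gm = make_genotype_matrix(gt, [v])
        clone = _clone("C", {v.name: GT_HET}, 1)
        gene_map = {v.name: "NRAS"}
        assert not chip_flags(clone, "driver_vaf2", gene_map,
                              driver_genes={"NRAS"}, gm=gm)
        # 10 HET among 100 -> VAF 5% > 2%
        gt = np.array([[GT_HET]] * 10 + [[GT_WT]] * 90)
        gm = make_genotype_matrix(gt, [v])
        assert chip_flags(clone, "driver_vaf2", gene_map,
                          driver_genes={"NRAS"}, gm=gm)

    def test_driver_without_list_is_error(self):
        with pytest.raises(ValueError, match="driver"):
            chip_flags(_clone("C", {"n": 1}, 5), "driver_vaf2", self.GENES)


class TestClassifyDynamics:
    def _sets(self, dx_counts, post_counts):
        def build(counts):
            clones = [Clone("WT", {}, [f"w{i}" for i in range(counts["WT"])])]
            for cid, n in counts.items():
                if cid == "WT":
                    continue
                clones.append(Clone(cid, {cid: GT_HET},
                                    [f"{cid}{i}" for i in range(n)]))
            return CloneSet(clones)
        return build(dx_counts), build(post_counts)

    def test_uniform_shrinkage(self):
        dx, post = self._sets({"WT": 400, "A": 400, "B": 200},
                              {"WT": 930, "A": 50, "B": 20})
        assert classify_dynamics(dx, post).pattern == "shrinkage"

    def test_identical_fractions_stable(self):
        dx, post = self._sets({"WT": 500, "A": 300, "B": 200},
                              {"WT": 500, "A": 300, "B": 200})
        call = classify_dynamics(dx, post)
        assert call.pattern == "stable"
        assert all(abs(d) < 1e-12 for d in call.deltas.values())

    def test_new_clone_triggers_expansion(self):
        dx, post = self._sets({"WT": 700, "A": 300},
                              {"WT": 600, "A": 300, "C": 100})
        assert classify_dynamics(dx, post).pattern == "expansion"

    def test_doubling_minority_triggers_expansion(self):
        dx, post = self._sets({"WT": 500, "A": 400, "B": 100},
                              {"WT": 400, "A": 350, "B": 250})
        assert classify_dynamics(dx, post).pattern == "expansion"

    def test_simulated_patterns_recovered(self):
        """Pattern recovery across seeds under realistic noise (5% ADO)."""
        from clonepulse.variant_qc import (
            ado_rate, filter_cells, filter_genotype_calls, filter_variants,
            select_germline_het,
        )

        hits = 0
        trials = 0
        for pattern in ("shrinkage", "stable", "expansion"):
            for seed in range(5):
                cfg = single_patient_config(pattern, n_cells=3000,
                                            ado_rate=0.05, seed=seed,
                                            n_amplicons=2)
                cohort, _ = simulate_cohort(cfg)
                sets = {}
                dxc = filter_genotype_calls(
                    cohort.get("P01", "diagnosis").genotype)
                postc = filter_genotype_calls(
                    cohort.get("P01", "post_treatment").genotype)
                ado = ado_rate(dxc, postc, select_germline_het(dxc, postc))
                for tp, gm in (("dx", dxc), ("post", postc)):
                    kept, _, _ = filter_variants(gm)
                    gm2 = filter_cells(kept)
                    wl = {r.name for r in gm2.variants if r.whitelisted}
                    cs = flag_ado_clones(call_clones(gm2, whitelist=wl), ado)
                    sets[tp] = cs
                trials += 1
                hits += classify_dynamics(sets["dx"], sets["post"]).pattern \
                    == pattern
        assert hits == trials

    def test_unpaired_is_error(self):
        dx, _ = self._sets({"WT": 10, "A": 5}, {"WT": 10})
        with pytest.raises(ValueError):
            classify_dynamics(dx, None)
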