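"""ADT normalization, clustering, annotation and LISI diagnostics."""

import numpy as np
import pytest

from clonepulse.core_io import ADTMatrix, Antibody
from clonepulse.protein_phenotype import (
    NormalizedADT, ProteinError, annotate, cluster_cells,
    default_marker_rules, denoise_isotypes, drop_artifact_clusters, lisi,
    normalize_clr, qc_adt_cells, subcluster,
)
from clonepulse.synthetic_data import simulate_cohort, single_patient_config


def _adt(counts, n_iso=1):
    counts = np.asarray(counts)
    n, a = counts.shape
    abs_ = [Antibody(f"T{j}") for j in range(a - n_iso)] \
        + [Antibody(f"iso{j}", True) for j in range(n_iso)]
    return ADTMatrix(np.array([f"c{i}" for i in range(n)], dtype=object),
                     abs_, counts)


class TestQcAdtCells:
    def test_total_band(self):
        adt = _adt([[150, 0], [250, 0], [150000, 0]])
        out = qc_adt_cells(adt)
        assert list(out.barcodes) == ["c1"]

    def test_boundaries_kept(self):
        adt = _adt([[200, 0], [100000, 0]])
        assert qc_adt_cells(adt).n_cells == 2

    def test_compliant_fixture_identity(self):
        adt = _adt(np.full((5, 3), 300))
        np.testing.assert_array_equal(qc_adt_cells(adt).counts, adt.counts)

    def test_all_removed_is_error(self):
        with pytest.raises(ProteinError):
            qc_adt_cells(_adt([[1, 1]]))


class TestNormalizeClr:
    def test_uniform_counts_give_zero(self):
        norm = normalize_clr(_adt(np.full((3, 4), 100)))
        np.testing.assert_allclose(norm.values, 0.0, atol=1e-12)

    def test_zero_sum_per_cell(self):
        rng = np.random.default_rng(0)
        norm = normalize_clr(_adt(rng.integers(1, 500, (50, 10))))
        np.testing.assert_allclose(norm.values.sum(axis=1), 0.0, atol=1e-9)

    def test_known_values(self):
        """CLR of (10, 30, 60) under CPM+1 scaling."""
        counts = np.array([[10, 30, 60]])
        x = counts / 100 * 1e6 + 1
        expected = np.log(x) - np.log(x).mean()
        norm = normalize_clr(_adt(counts, n_iso=0))
        np.testing.assert_allclose(norm.values[0], expected[0], rtol=1e-12)
        np.testing.assert_allclose(
            norm.values[0], [-0.9635, 0.1351, 0.8284], atol=2e-4)


class TestDenoiseIsotypes:
    def test_background_subtraction(self):
        norm = NormalizedADT(
            barcodes=np.array(["c0"], dtype=object),
            antibody_names=["T0", "iso0"],
            isotype_mask=np.array([False, True]),
            values=np.array([[1.0, 0.4]]),
            raw_totals=np.array([100]),
        )
        out = denoise_isotypes(norm)
        assert out.values[0, 0] == pytest.approx(0.6)
        assert out.antibody_names == ["T0"]

    def test_flooring_at_zero(self):
        norm = NormalizedADT(np.array(["c0"], dtype=object), ["T0", "iso0"],
                             np.array([False, True]),
                             np.array([[0.2, 0.9]]), np.array([100]))
        assert denoise_isotypes(norm).values[0, 0] == 0.0

    def test_no_isotypes_is_error(self):
        norm = normalize_clr(_adt(np.full((2, 3), 100), n_iso=0))
        with pytest.raises(ProteinError, match="isotype"):
            denoise_isotypes(norm)

    def test_removes_shared_background_shift(self):
        """Doubling the shared background in half the cells leaves the
        denoised means of a null antibody nearly equal across groups."""
        rng = np.random.default_rng(5)
        n = 600
        base = rng.poisson(50, size=(n, 5)).astype(float)  # 4 targets + iso
        bg = np.where(np.arange(n) < n // 2, 1.0, 2.0)[:, None]
        counts = np.maximum((base * bg).astype(int), 0)
        adt = _adt(counts, n_iso=1)
        den = denoise_isotypes(normalize_clr(adt))
        null_means = den.values[: n // 2, 0].mean(), den.values[n // 2:, 0].mean()
        assert abs(null_means[0] - null_means[1]) < 0.05


class TestClusterCells:
    def _blobs(self, centers, n_per=150, spread=0.3, seed=0, dims=8):
        rng = np.random.default_rng(seed)
        vals = np.vstack([rng.normal(c, spread, size=(n_per, dims))
                          for c in centers])
        labels = np.repeat(range(len(centers)), n_per)
        norm = NormalizedADT(
            np.array([f"c{i}" for i in range(len(vals))], dtype=object),
            [f"T{j}" for j in range(dims)],
            np.zeros(dims, dtype=bool), vals, np.ones(len(vals)),
            denoised=True)
        return norm, labels

    def test_separated_blobs_fully_recovered(self):
        norm, truth = self._blobs([0.0, 20.0])
        labels = cluster_cells(norm, k=15, seed=0)
        assert labels.max() + 1 == 2
        # perfect membership up to label names
        assert len(set(zip(truth.tolist(), labels.tolist()))) == 2

    def test_single_blob_single_cluster(self):
        norm, _ = self._blobs([0.0], n_per=300)
        labels = cluster_cells(norm, k=15, resolution=0.1, seed=0)
        assert labels.max() + 1 == 1

    def test_deterministic_given_seed(self):
        norm, _ = self._blobs([0.0, 5.0, 10.0], seed=4)
        l1 = cluster_cells(norm, seed=7)
        l2 = cluster_cells(norm, seed=7)
        np.testing.assert_array_equal(l1, l2)

    def test_too_few_cells_is_error(self):
        norm, _ = self._blobs([0.0], n_per=10)
        with pytest.raises(ProteinError):
            cluster_cells(norm, k=20)

    def test_subcluster_splits_target_only(self):
        norm, _ = self._blobs([0.0, 30.0], n_per=200, seed=2)
        labels = cluster_cells(norm, k=15, seed=0)
        # make cluster 0 internally bimodal
        vals = norm.values.copy()
        mask = labels == 0
        half = np.flatnonzero(mask)[:100]
        vals[half] += 25.0
        norm2 = NormalizedADT(norm.barcodes, norm.antibody_names,
                              norm.isotype_mask, vals, norm.raw_totals, True)
        out = subcluster(norm2, labels, 0, k=15, seed=0)
        assert len(np.unique(out[mask])) >= 2
        assert (out[~mask] == labels[~mask]).all()

    def test_planted_cell_types_recovered(self):
        """>= 6 planted populations recovered with high agreement on the
        default synthetic ADT model."""
        from sklearn.metrics import adjusted_rand_score

        cfg = single_patient_config("stable", n_cells=2500, seed=11,
                                    n_amplicons=2)
        cohort, truth = simulate_cohort(cfg)
        s = cohort.get("P01", "diagnosis")
        den = denoise_isotypes(normalize_clr(qc_adt_cells(s.adt)))
        labels = cluster_cells(den, seed=0)
        true_types = truth.cells.query("timepoint == 'diagnosis'") \
            .set_index("barcode").cell_type.loc[den.barcodes].to_numpy()
        ann = annotate(den, labels, default_marker_rules())
        agreement = (ann.table.population.to_numpy() == true_types).mean()
        assert len(np.unique(true_types)) >= 6
        assert adjusted_rand_score(
            true_types, ann.table.population.to_numpy()) >= 0.9
        assert agreement >= 0.9


class TestArtifactClusters:
    def _norm(self, vals):
        return NormalizedADT(
            np.array([f"c{i}" for i in range(len(vals))], dtype=object),
            [f"T{j}" for j in range(vals.shape[1])],
            np.zeros(vals.shape[1], dtype=bool), vals,
            np.ones(len(vals)), denoised=True)

    def test_flat_cluster_removed_structured_kept(self):
        rng = np.random.default_rng(1)
        flat = rng.normal(1.0, 0.01, size=(50, 6))
        structured = rng.normal([3, 0, 0, 3, 0, 0], 0.05, size=(50, 6))
        norm = self._norm(np.vstack([flat, structured]))
        labels = np.repeat([0, 1], 50)
        out = drop_artifact_clusters(norm, labels)
        assert (out[:50] == -1).all()
        assert (out[50:] == 1).all()

    def test_zero_threshold_removes_nothing(self):
        rng = np.random.default_rng(2)
        norm = self._norm(rng.normal(1.0, 0.01, size=(30, 4)))
        out = drop_artifact_clusters(norm, np.zeros(30, dtype=int),
                                     variance_min=0.0)
        assert (out == 0).all()


class TestAnnotate:
    def _norm_for(self, profiles):
        names = sorted({m for p in profiles for m in p})
        vals = np.array([[p.get(m, 0.0) for m in names] for p in profiles])
        vals = np.repeat(vals, 20, axis=0)
        norm = NormalizedADT(
            np.array([f"c{i}" for i in range(len(vals))], dtype=object),
            names, np.zeros(len(names), dtype=bool), vals,
            np.ones(len(vals)), denoised=True)
        return norm, np.repeat(range(len(profiles)), 20)

    def test_t_cell_rule(self):
        norm, labels = self._norm_for(
            [{"CD3": 3.0, "CD19": 0.1, "CD56": 0.1}])
        ann = annotate(norm, labels, default_marker_rules())
        assert set(ann.table.population) == {"T"}
        assert set(ann.table.compartment) == {"T"}

    def test_progenitor_rule(self):
        norm, labels = self._norm_for([{"CD34": 3.0, "CD90": 2.5}])
        ann = annotate(norm, labels, default_marker_rules())
        assert set(ann.table.population) == {"HSPC"}
        assert set(ann.table.compartment) == {"progenitors"}

    def test_unmatched_cluster_unassigned(self):
        norm, labels = self._norm_for([{"CD3": 0.0}])
        ann = annotate(norm, labels, default_marker_rules())
        assert set(ann.table.population) == {"unassigned"}

    def test_single_sample_population_excluded_from_compartments(self):
        norm, labels = self._norm_for(
            [{"CD3": 3.0, "CD19": 0.1, "CD56": 0.1},
             {"CD19": 3.0, "CD20": 3.0, "CD3": 0.1, "CD56": 0.1}])
        # the B population comes 100% from sample s1
        samples = np.array(["s1"] * 20 + ["s1"] * 20)
        samples[:20] = [f"s{1 + i % 4}" for i in range(20)]
        ann = annotate(norm, labels, default_marker_rules(),
                       sample_of_cell=samples)
        assert ann.rare_single_sample == ["B"]
        b_rows = ann.table[ann.table.population == "B"]
        assert set(b_rows.compartment) == {"rare"}

    def test_empty_rules_is_error(self):
        norm, labels = self._norm_for([{"CD3": 3.0}])
        with pytest.raises(ProteinError):
            annotate(norm, labels, [])


class TestLisi:
    def test_interleaved_labels_near_two(self):
        x = np.linspace(0, 1, 400)[:, None]
        labels = np.array(["a", "b"] * 200)
        res = lisi(x, labels)
        assert res.mean == pytest.approx(2.0, abs=0.05)

    def test_separated_labels_near_one(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 1, (150, 2)),
                       rng.normal(100, 1, (150, 2))])
        labels = np.array(["a"] * 150 + ["b"] * 150)
        assert lisi(x, labels).mean == pytest.approx(1.0, abs=0.01)

    def test_single_label_returns_ones(self):
        x = np.random.default_rng(1).normal(size=(50, 2))
        res = lisi(x, np.array(["a"] * 50))
        assert (res.per_cell == 1.0).all()

    def test_invariant_to_label_renaming(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(200, 3))
        labels = rng.choice(["a", "b"], 200)
        renamed = np.where(labels == "a", "z", "y")
        np.testing.assert_allclose(lisi(x, labels).per_cell,
                                   lisi(x, renamed).per_cell)

    def test_monotone_along_mixing_path(self):
        """LISI increases as two populations are progressively mixed."""
        rng = np.random.default_rng(3)
        means = []
        for sep in (40.0, 10.0, 3.0, 0.0):
            x = np.vstack([rng.normal(0, 1, (150, 2)),
                           rng.normal(sep, 1, (150, 2))])
            labels = np.array(["a"] * 150 + ["b"] * 150)
            means.append(lisi(x, labels).mean)
        assert means == sorted(means)


class TestClrProperties:
    """CLR transform invariants on arbitrary count matrices."""

    from hypothesis import given, settings, strategies as st

    @given(st.integers(min_value=0, max_value=10 ** 6))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_zero_sum_and_depth_invariance(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 1000, size=(5, 6))
        norm = normalize_clr(_adt(counts, n_iso=0))
        np.testing.assert_allclose(norm.values.sum(axis=1), 0.0, atol=1e-9)
        # scaling a cell's library leaves its CLR values unchanged up to
        # the +1 pseudocount's vanishing contribution
        scaled = counts.copy()
        scaled[0] *= 1000
        norm2 = normalize_clr(_adt(scaled, n_iso=0))
        np.testing.assert_allclose(norm2.values[0], norm.values[0], atol=5e-2)
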