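import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from patchpipe.synthetic import ExpressionDesign, simulate_expression
from patchpipe.transcriptomics import (
    ExpressionMatrix,
    beta_score,
    build_cluster_reference,
    cluster_discreteness,
    cluster_heterogeneity,
    cpm_log,
    deep_marker_selection,
    filter_genes,
    map_cells,
    nms_score,
    select_binary_genes,
)


@pytest.fixture(scope="module")
def ref_design():
    return ExpressionDesign(
        n_clusters=5,
        cells_per_cluster=100,
        n_genes=1500,
        n_markers_per_cluster=50,
        marker_log2_fc=2.0,
        seed=0,
    )


@pytest.fixture(scope="module")
def ref_matrix(ref_design):
    return simulate_expression(ref_design)


class TestCpmLog:
    def test_zero_count_maps_to_zero(self):
        counts = pd.DataFrame({"c1": [0, 10]}, index=["g1", "g2"])
        assert cpm_log(counts).loc["g1", "c1"] == 0.0

    def test_full_library_closed_form(self):
        counts = pd.DataFrame({"c1": [7, 0]}, index=["g1", "g2"])
        assert cpm_log(counts).loc["g1", "c1"] == pytest.approx(np.log2(1e6 + 1))

    def test_library_scale_invariance(self, ref_matrix):
        sub = ref_matrix.counts.iloc[:50, :5]
        doubled = sub * 2
        pd.testing.assert_frame_equal(cpm_log(sub), cpm_log(doubled))

    def test_zero_total_cell_rejected(self):
        counts = pd.DataFrame({"c1": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="zero total"):
            cpm_log(counts)


class TestBetaScore:
    def test_perfectly_binary_marker_scores_one(self):
        p = pd.DataFrame([[1.0, 0.0, 0.0, 0.0, 0.0]], index=["g"])
        # beta = 4 / (4 + eps)
        assert beta_score(p).loc["g"] == pytest.approx(4.0 / (4.0 + 1e-6))
        assert beta_score(p).loc["g"] == pytest.approx(1.0, abs=1e-5)

    def test_constant_proportions_score_zero(self):
        p = pd.DataFrame([[0.4, 0.4, 0.4]], index=["g"])
        assert beta_score(p).loc["g"] == 0.0

    def test_hand_evaluated_half(self):
        p = pd.DataFrame([[1.0, 0.5]], index=["g"])
        assert beta_score(p).loc["g"] == pytest.approx(0.25 / (0.5 + 1e-6))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            beta_score(pd.DataFrame([[1.2, 0.0]]))

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            beta_score(pd.DataFrame([[0.5]]))

    @given(
        arrays(
            float,
            st.tuples(st.integers(1, 20), st.integers(2, 10)),
            elements=st.floats(0.0, 1.0),
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_in_unit_interval(self, p):
        scores = beta_score(pd.DataFrame(p))
        assert ((scores >= 0.0) & (scores <= 1.0)).all()


class TestSelectBinaryGenes:
    def test_markers_dominate_top_slots(self, ref_matrix, ref_design):
        n_markers = ref_design.n_clusters * ref_design.n_markers_per_cluster
        top = set(select_binary_genes(ref_matrix, n=n_markers))
        markers = ref_matrix.gene_meta.index[
            ref_matrix.gene_meta["true_marker_cluster"] >= 0
        ]
        assert np.mean([g in top for g in markers]) >= 0.95

    def test_oversized_request_returns_all_with_warning(self, ref_matrix):
        with pytest.warns(UserWarning):
            out = select_binary_genes(ref_matrix, n=10**6)
        assert len(out) == len(ref_matrix.genes)

    def test_deterministic(self, ref_matrix):
        assert select_binary_genes(ref_matrix, 100) == select_binary_genes(
            ref_matrix, 100
        )


@pytest.fixture(scope="module")
def pair():
    ref = simulate_expression(ExpressionDesign(n_genes=800, seed=1))
    query = simulate_expression(
        ExpressionDesign(n_genes=800, cells_per_cluster=30, seed=2),
        platform="patchseq",
    )
    # force a strong platform difference on one autosomal neuronal gene
    target = ref.gene_meta.index[
        (ref.gene_meta["chromosome"] == "chr1")
        & (ref.gene_meta["class_of_max_expression"] == "neuronal")
    ][0]
    query.counts.loc[target] = 0
    ref.counts.loc[target] = 500
    return ref, query, target


class TestFilterGenes:
    def test_sex_chromosome_genes_removed(self, pair):
        ref, query, _ = pair
        retained, removals = filter_genes(ref, query)
        sex = set(
            ref.gene_meta.index[ref.gene_meta["chromosome"].isin(["chrX", "chrY"])]
        )
        assert removals["sex_chromosome"] == len(sex)
        assert not sex & set(retained)

    def test_mito_and_non_neuronal_removed(self, pair):
        ref, query, _ = pair
        retained, removals = filter_genes(ref, query)
        assert removals["mitochondrial"] > 0
        assert removals["non_neuronal_max"] > 0
        gm = ref.gene_meta.loc[retained]
        assert not gm["is_mito"].any()
        assert (gm["class_of_max_expression"] == "neuronal").all()

    def test_platform_dependent_gene_removed(self, pair):
        ref, query, target = pair
        retained, removals = filter_genes(ref, query)
        assert target not in retained
        assert removals["platform_dependent"] >= 1

    def test_identical_platform_means_retained(self):
        ref = simulate_expression(ExpressionDesign(n_genes=400, seed=3))
        query = ExpressionMatrix(
            ref.counts.copy(), ref.gene_meta.copy(), ref.cell_meta.copy()
        )
        _, removals = filter_genes(ref, query)
        assert removals["platform_dependent"] == 0

    def test_rule_order_independent(self, pair):
        """Rules are independent predicates: the retained set is the shared
        gene list minus the union of per-rule sets, recomputed directly."""
        ref, query, _ = pair
        retained, _ = filter_genes(ref, query)
        gm = ref.gene_meta
        cpm_r = 1e6 * ref.counts / ref.counts.sum(axis=0)
        cpm_q = 1e6 * query.counts / query.counts.sum(axis=0)
        diff = np.abs(
            np.log2(cpm_r.mean(axis=1) + 1e-2) - np.log2(cpm_q.mean(axis=1) + 1e-2)
        )
        expected = [
            g
            for g in ref.genes
            if gm.loc[g, "chromosome"] not in ("chrX", "chrY")
            and not gm.loc[g, "is_mito"]
            and gm.loc[g, "class_of_max_expression"] == "neuronal"
            and diff[g] < 2.0
        ]
        assert retained == expected

    def test_missing_annotation_skips_rule_with_warning(self, pair):
        ref, query, _ = pair
        ref2 = ExpressionMatrix(
            ref.counts, ref.gene_meta.drop(columns=["chromosome"]), ref.cell_meta
        )
        with pytest.warns(UserWarning, match="chromosome"):
            _, removals = filter_genes(ref2, query)
        assert removals["sex_chromosome"] == 0


@pytest.fixture(scope="module")
def nms_setup():
    ref = simulate_expression(
        ExpressionDesign(
            n_clusters=2,
            cells_per_cluster=60,
            n_genes=500,
            n_markers_per_cluster=25,
            marker_p_on=0.9,
            marker_p_off=0.05,
            seed=4,
        )
    )
    gm = ref.gene_meta
    marker_sets = {
        f"cluster_{c}": list(gm.index[gm["true_marker_cluster"] == c])
        for c in (0, 1)
    }
    return ref, marker_sets


class TestNmsScore:
    def test_reference_like_cell_passes_near_one(self, nms_setup):
        ref, marker_sets = nms_setup
        sub = ExpressionMatrix(
            ref.counts.iloc[:, :10], ref.gene_meta, ref.cell_meta.iloc[:10]
        )
        out = nms_score(sub, marker_sets, ref)
        assert (out["nms"] > 0.5).all()
        assert out["pass"].all()

    def test_all_zero_cell_fails(self, nms_setup):
        ref, marker_sets = nms_setup
        counts = ref.counts.iloc[:, :3].copy()
        counts.iloc[:, 0] = 0
        counts.iloc[0, 0] = 1  # avoid zero library
        q = ExpressionMatrix(counts, ref.gene_meta, ref.cell_meta.iloc[:3])
        out = nms_score(q, marker_sets, ref)
        assert out["nms"].iloc[0] < 0.4 and not out["pass"].iloc[0]

    def test_exact_threshold_fails_strictly(self):
        # reference cells: marker CPM 31 -> log2(32) = 5 exactly;
        # query cell: marker CPM 3 -> log2(4) = 2 exactly; score = 2/5 = 0.4
        genes = ["marker", "filler"]
        ref_counts = pd.DataFrame(
            {f"r{i}": [31, 999_969] for i in range(4)}, index=genes
        )
        ref = ExpressionMatrix(
            ref_counts,
            cell_meta=pd.DataFrame(
                {"cluster": ["a"] * 4}, index=ref_counts.columns
            ),
        )
        q = ExpressionMatrix(
            pd.DataFrame({"q0": [3, 999_997]}, index=genes),
            cell_meta=pd.DataFrame(index=["q0"]),
        )
        out = nms_score(q, {"a": ["marker"]}, ref)
        assert out.loc["q0", "nms"] == 0.4
        assert not out.loc["q0", "pass"]

    def test_empty_marker_set_rejected(self, nms_setup):
        ref, _ = nms_setup
        with pytest.raises(ValueError):
            nms_score(ref, {"a": []}, ref)


@pytest.fixture(scope="module")
def reference(ref_matrix):
    panel = select_binary_genes(ref_matrix, 300)
    return build_cluster_reference(ref_matrix, panel)


class TestMapCells:
    def test_centroid_self_maps(self, ref_matrix, reference):
        # feed a centroid back as a query expression vector
        counts = (2.0 ** reference.centroids - 1.0).clip(lower=0.0) * 100
        q = ExpressionMatrix(
            counts.round().astype(int),
            ref_matrix.gene_meta.loc[reference.marker_panel],
            pd.DataFrame(index=counts.columns),
        )
        out = map_cells(q, reference)
        assert list(out["label"]) == list(counts.columns)
        assert (out["confidence"] > 0).all()

    def test_recovery_95_percent(self, ref_matrix, reference, ref_design):
        q = simulate_expression(
            ExpressionDesign(**{**ref_design.__dict__, "cells_per_cluster": 30, "seed": 77}),
            platform="patchseq",
        )
        out = map_cells(q, reference)
        assert (out["label"] == q.cell_meta["cluster"]).mean() >= 0.95

    def test_constant_query_unmapped(self, ref_matrix, reference):
        counts = pd.DataFrame(
            5, index=ref_matrix.genes, columns=["flat"]
        )
        q = ExpressionMatrix(counts, ref_matrix.gene_meta, pd.DataFrame(index=["flat"]))
        out = map_cells(q, reference)
        assert out.loc["flat", "label"] is None
        assert out.loc["flat", "reason"] == "zero_variance"

    def test_library_rescaling_invariance(self, ref_matrix, reference, ref_design):
        q = simulate_expression(
            ExpressionDesign(**{**ref_design.__dict__, "cells_per_cluster": 10, "seed": 5}),
            platform="patchseq",
        )
        out1 = map_cells(q, reference)
        q2 = ExpressionMatrix(q.counts * 3, q.gene_meta, q.cell_meta)
        out2 = map_cells(q2, reference)
        assert (out1["label"] == out2["label"]).all()

    def test_missing_panel_genes_rejected(self, ref_matrix, reference):
        q = ExpressionMatrix(
            ref_matrix.counts.iloc[:10], ref_matrix.gene_meta.iloc[:10], ref_matrix.cell_meta
        )
        with pytest.raises(ValueError, match="marker-panel"):
            map_cells(q, reference)


class TestClusterHeterogeneity:
    def test_null_cluster_within_3sd(self):
        mat = simulate_expression(
            ExpressionDesign(
                n_clusters=1, cells_per_cluster=120, n_genes=400,
                n_markers_per_cluster=0, seed=11,
            )
        )
        out = cluster_heterogeneity(mat, n_perm=50, seed=0)
        z = (out["observed_pc1_pct"] - out["permuted_mean"]) / out["permuted_sd"]
        assert abs(z) < 3.0

    def test_gradient_cluster_exceeds_null(self):
        mat = simulate_expression(
            ExpressionDesign(
                n_clusters=1, cells_per_cluster=120, n_genes=400,
                n_markers_per_cluster=0, gradient_cluster=0, gradient_genes=80,
                gradient_slope=3.0, seed=12,
            )
        )
        out = cluster_heterogeneity(mat, n_perm=50, seed=0)
        z = (out["observed_pc1_pct"] - out["permuted_mean"]) / out["permuted_sd"]
        assert z > 5.0

    def test_permutations_preserve_gene_marginals(self):
        """Shuffling preserves each gene's value multiset exactly."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 6))
        xp = x.copy()
        for j in range(xp.shape[1]):
            rng.shuffle(xp[:, j])
        for j in range(x.shape[1]):
            assert sorted(x[:, j]) == sorted(xp[:, j])
        assert not np.array_equal(x, xp)

    def test_zero_permutations(self):
        mat = simulate_expression(
            ExpressionDesign(n_clusters=1, cells_per_cluster=90, n_genes=200,
                             n_markers_per_cluster=0, seed=13)
        )
        out = cluster_heterogeneity(mat, n_perm=0, seed=0)
        assert np.isnan(out["permuted_mean"]) and len(out["permuted"]) == 0

    def test_too_many_genes_rejected(self):
        mat = simulate_expression(
            ExpressionDesign(n_clusters=1, cells_per_cluster=90, n_genes=50,
                             n_markers_per_cluster=0, seed=14)
        )
        with pytest.raises(ValueError, match="n_genes"):
            cluster_heterogeneity(mat, n_genes=100)

    def test_small_cluster_samples_with_replacement(self):
        mat = simulate_expression(
            ExpressionDesign(n_clusters=1, cells_per_cluster=30, n_genes=200,
                             n_markers_per_cluster=0, seed=15)
        )
        with pytest.warns(UserWarning, match="replacement"):
            out = cluster_heterogeneity(mat, n_cells=80, n_perm=5, seed=0)
        assert out["n_cells"] <= 80


class TestClusterDiscreteness:
    def test_identical_clusters_zero(self):
        mat = simulate_expression(
            ExpressionDesign(n_clusters=2, cells_per_cluster=90, n_genes=400,
                             n_markers_per_cluster=0, marker_log2_fc=0.0, seed=20)
        )
        out = cluster_discreteness(mat, "cluster_0", seed=0)
        assert out["mean_de_genes"] == 0.0

    def test_planted_marker_recovery(self):
        mat = simulate_expression(
            ExpressionDesign(n_clusters=2, cells_per_cluster=100, n_genes=800,
                             n_markers_per_cluster=50, marker_log2_fc=2.0,
                             marker_p_on=0.9, marker_p_off=0.05, seed=21)
        )
        out = cluster_discreteness(mat, "cluster_0", seed=0)
        assert 45 <= out["mean_de_genes"] <= 55

    def test_downregulated_markers_not_counted(self):
        mat = simulate_expression(
            ExpressionDesign(n_clusters=2, cells_per_cluster=100, n_genes=800,
                             n_markers_per_cluster=50, marker_log2_fc=2.0,
                             marker_p_on=0.9, marker_p_off=0.05, seed=22)
        )
        # cluster_1's markers are upregulated in cluster_1, so from
        # cluster_0's perspective they must not be counted
        out0 = cluster_discreteness(mat, "cluster_0", seed=0)
        assert out0["per_pair"]["cluster_1"] <= 55  # only cluster_0's own markers

    def test_null_design_no_de_genes(self):
        mat = simulate_expression(
            ExpressionDesign(n_clusters=3, cells_per_cluster=90, n_genes=500,
                             n_markers_per_cluster=40, marker_log2_fc=0.0, seed=23)
        )
        for target in ("cluster_0", "cluster_1", "cluster_2"):
            assert cluster_discreteness(mat, target, seed=0)["mean_de_genes"] == 0.0

    def test_singleton_cluster_rejected(self, ref_matrix):
        meta = ref_matrix.cell_meta.copy()
        meta.loc[meta.index[0], "cluster"] = "lonely"
        mat = ExpressionMatrix(ref_matrix.counts, ref_matrix.gene_meta, meta)
        with pytest.raises(ValueError, match="fewer than 2"):
            cluster_discreteness(mat, "lonely", seed=0)


@pytest.fixture(scope="module")
def three_cluster():
    return simulate_expression(
        ExpressionDesign(n_clusters=3, cells_per_cluster=80, n_genes=600,
                         n_markers_per_cluster=30, marker_log2_fc=2.0,
                         marker_p_on=0.9, marker_p_off=0.05, seed=30)
    )


class TestDeepMarkerSelection:
    def test_one_cluster_marker_selected(self, three_cluster):
        sel = set(deep_marker_selection(three_cluster))
        markers = three_cluster.gene_meta.index[
            three_cluster.gene_meta["true_marker_cluster"] >= 0
        ]
        assert np.mean([g in sel for g in markers]) > 0.9

    def test_uniform_genes_excluded(self, three_cluster):
        sel = set(deep_marker_selection(three_cluster))
        non_markers = three_cluster.gene_meta.index[
            three_cluster.gene_meta["true_marker_cluster"] < 0
        ]
        assert np.mean([g in sel for g in non_markers]) < 0.1

    def test_two_of_three_marker_selected(self):
        """A gene on in two clusters and off in the third is retained."""
        rng = np.random.default_rng(0)
        n = 60
        counts = pd.DataFrame(
            rng.poisson(20, size=(50, 3 * n)),
            index=[f"G{i}" for i in range(50)],
            columns=[f"C{i}" for i in range(3 * n)],
        )
        counts.iloc[0, : 2 * n] = rng.poisson(200, 2 * n)  # on in clusters 0+1
        counts.iloc[0, 2 * n :] = 0
        meta = pd.DataFrame(
            {"cluster": ["a"] * n + ["b"] * n + ["c"] * n}, index=counts.columns
        )
        mat = ExpressionMatrix(counts, cell_meta=meta)
        assert "G0" in deep_marker_selection(mat)

    def test_requires_exactly_three_clusters(self, ref_matrix):
        with pytest.raises(ValueError, match="3 clusters"):
            deep_marker_selection(ref_matrix)


class TestMtxRoundtrip:
    def test_dir_roundtrip(self, tmp_path):
        mat = simulate_expression(
            ExpressionDesign(n_clusters=2, cells_per_cluster=10, n_genes=50,
                             n_markers_per_cluster=5, seed=40)
        )
        mat.to_dir(tmp_path / "expr")
        back = ExpressionMatrix.from_dir(tmp_path / "expr")
        pd.testing.assert_frame_equal(
            mat.counts.astype(float), back.counts.astype(float)
        )
        assert list(back.cell_meta["cluster"]) == list(mat.cell_meta["cluster"])
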