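import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from bcellpipe.synthetic import (
    DEFAULT_CLUSTER_SOURCES,
    ExpressionConfig,
    default_atlas,
    default_marker_sets,
    simulate_expression,
)
from bcellpipe.transcriptome import (
    ClusterParams,
    cluster_cells,
    find_markers,
    map_genes,
    normalize_counts,
    project_to_atlas,
    signature_zscores,
)


class TestNormalizeCounts:
    def test_single_gene_cell_hits_log1p_target(self):
        counts = pd.DataFrame([[10_000, 0]], columns=["g1", "g2"])
        out = normalize_counts(counts)
        assert out.iloc[0, 0] == pytest.approx(np.log1p(10_000))

    def test_depth_scale_invariance(self):
        a = pd.DataFrame([[10, 20, 30]], columns=list("abc"))
        b = a * 2
        np.testing.assert_allclose(normalize_counts(a).to_numpy(),
                                   normalize_counts(b).to_numpy())

    def test_matches_hand_computation_on_toy_matrix(self):
        counts = pd.DataFrame([[1, 2, 3], [4, 0, 4]], columns=list("abc"))
        expected = np.log1p(counts.to_numpy() / counts.sum(axis=1).to_numpy()[:, None] * 1e4)
        np.testing.assert_allclose(normalize_counts(counts).to_numpy(), expected,
                                   atol=1e-12)

    def test_all_zero_cell_excluded(self):
        counts = pd.DataFrame([[1, 2], [0, 0]], columns=list("ab"),
                              index=["c1", "c2"])
        out = normalize_counts(counts)
        assert list(out.index) == ["c1"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            normalize_counts(pd.DataFrame([[-1, 2]]))


class TestClusterCells:
    def test_three_planted_clusters_recovered(self, expression_fixture):
        _, counts, labels = expression_fixture
        result = cluster_cells(normalize_counts(counts), seed=0)
        assert result.n_clusters == 3
        assert adjusted_rand_score(labels, result.labels) >= 0.9

    def test_null_data_collapse_to_one_cluster(self):
        counts, _ = simulate_expression(ExpressionConfig(effect_lfc=0.0, n_cells=300), seed=0)
        result = cluster_cells(normalize_counts(counts), seed=0)
        assert result.n_clusters == 1

    def test_labels_contiguous_from_one_and_counts_sum(self, expression_fixture):
        _, counts, _ = expression_fixture
        result = cluster_cells(normalize_counts(counts), seed=1)
        assert set(result.labels) == set(range(1, result.n_clusters + 1))
        assert result.counts.sum() == len(counts)

    def test_deterministic_given_seed(self, expression_fixture):
        _, counts, _ = expression_fixture
        norm = normalize_counts(counts)
        r1 = cluster_cells(norm, seed=5)
        r2 = cluster_cells(norm, seed=5)
        assert (r1.labels == r2.labels).all()

    def test_too_few_cells_for_k_rejected(self):
        tiny = pd.DataFrame(np.random.default_rng(0).poisson(2, (4, 10)))
        with pytest.raises(ValueError, match="fewer cells"):
            cluster_cells(normalize_counts(tiny), ClusterParams(k_range=(2, 6)))


class TestFindMarkers:
    def test_exclusive_gene_is_top_marker(self):
        rng = np.random.default_rng(0)
        n = 200
        counts = pd.DataFrame(rng.poisson(5, (n, 20)),
                              columns=[f"g{i}" for i in range(20)])
        labels = np.array([1] * 100 + [2] * 100)
        counts.loc[labels == 2, "g0"] = 0  # expressed only in cluster 1
        markers = find_markers(normalize_counts(counts), labels)
        up1 = markers.up_genes(1)
        assert up1 and up1[0] == "g0"
        row = markers.significant
        assert (row[(row["cluster"] == 1) & (row["gene"] == "g0")]["pvalue"] < 0.05).all()

    def test_default_threshold_is_p05(self):
        markers = find_markers(
            normalize_counts(pd.DataFrame(
                np.random.default_rng(1).poisson(5, (60, 10)))),
            np.array([1] * 30 + [2] * 30))
        assert markers.p_threshold == 0.05

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="2 clusters"):
            find_markers(pd.DataFrame(np.ones((10, 3))), np.ones(10))

    def test_permuted_labels_calibrate_type_i_error(self, expression_fixture):
        # oracle: permutation null — ~5% of raw p-values below 0.05
        _, counts, labels = expression_fixture
        norm = normalize_counts(counts)
        fractions = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            perm = rng.permutation(labels)
            stats = find_markers(norm, perm).stats
            fractions.append((stats["pvalue"] < 0.05).mean())
        assert np.mean(fractions) == pytest.approx(0.05, abs=0.02)


class TestMapGenes:
    def test_52_panel_genes_map_to_50(self):
        atlas = default_atlas(seed=0)
        panel = [g for gs in default_marker_sets().values() for g in gs]
        mapped, unmapped = map_genes(panel, atlas)
        assert len(mapped) == 50
        assert len(unmapped) == 2

    def test_all_present_gives_empty_unmapped(self):
        atlas = default_atlas(seed=0)
        mapped, unmapped = map_genes(["mz_g01", "fo_g01"], atlas)
        assert unmapped == []

    def test_case_insensitive_option(self):
        atlas = default_atlas(seed=0)
        mapped, unmapped = map_genes(["MZ_G01"], atlas, case_insensitive=True)
        assert mapped == ["mz_g01"]
        assert map_genes(["MZ_G01"], atlas)[0] == []

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            map_genes([], default_atlas(seed=0))


class TestProjectToAtlas:
    def test_toy_zscores_match_hand_computation(self):
        # oracle: manual arithmetic on a 3-gene x 4-population table
        atlas = pd.DataFrame(
            {"g1": [1.0, 2.0, 3.0, 4.0],
             "g2": [10.0, 10.0, 10.0, 10.0],
             "g3": [0.0, 0.0, 0.0, 8.0]},
            index=["P1", "P2", "P3", "P4"])
        z, flagged = signature_zscores(atlas, ["g1", "g2", "g3"])
        mu, sd = 2.5, np.std([1, 2, 3, 4])
        np.testing.assert_allclose(
            z.loc["g1"].to_numpy(), (np.array([1, 2, 3, 4.0]) - mu) / sd, atol=1e-12)
        np.testing.assert_allclose(
            z.loc["g3"].to_numpy(),
            (np.array([0, 0, 0, 8.0]) - 2.0) / np.std([0, 0, 0, 8.0]), atol=1e-12)
        assert flagged == ["g2"]
        np.testing.assert_allclose(z.loc["g2"].to_numpy(), 0.0)

    def test_row_normalization_invariant(self):
        atlas = default_atlas(seed=3, n_withheld=0)
        z, _ = signature_zscores(atlas, list(atlas.columns))
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-9)

    def test_planted_clusters_map_to_source_populations(self):
        atlas = default_atlas(seed=0)
        sig = project_to_atlas(default_marker_sets(), atlas)
        for cluster, population in DEFAULT_CLUSTER_SOURCES.items():
            assert sig.assignment[cluster] == population

    def test_end_to_end_from_detected_markers(self, expression_fixture):
        _, counts, truth = expression_fixture
        norm = normalize_counts(counts)
        result = cluster_cells(norm, seed=0)
        markers = find_markers(norm, result.labels)
        sig = project_to_atlas(markers, default_atlas(seed=0))
        # map each predicted cluster to the dominant truth cluster it contains
        for pred in range(1, result.n_clusters + 1):
            truth_mode = pd.Series(truth[result.labels == pred]).mode()[0]
            assert sig.assignment[pred] == DEFAULT_CLUSTER_SOURCES[int(truth_mode)]

    def test_unmapped_markers_never_silently_dropped(self, caplog):
        atlas = default_atlas(seed=0)
        sig = project_to_atlas({1: ["mz_g01", "not_a_gene"]}, atlas)
        assert "not_a_gene" not in sig.z.index
        assert sig.assignment[1] == "MZ"
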