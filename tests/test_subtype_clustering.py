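"""Featurization, WNN fusion, Leiden clustering and cluster statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom
from sklearn.metrics import adjusted_rand_score, silhouette_score

from neurotraj.subtype_clustering import (
    ClusterAssignment,
    JointGraph,
    build_matrices,
    cluster_cohort,
    cluster_graph,
    embed_2d,
    find_markers,
    fisher_overrepresentation,
    normalize_scale_pca,
    subcluster,
    wnn_graph,
)
from neurotraj.synthetic_data import (
    CohortConfig,
    cohort_observations,
    generate_cohort,
    uniform_profile,
)
from neurotraj.trajectory_builder import trajectories_from_observations
from tests.conftest import make_trajectory


class TestBuildMatrices:
    def test_flattened_counts_distinct_years(self):
        trajectory = make_trajectory(
            "d1", [("tremor", 2000), ("tremor", 2003), ("tremor", 2005)],
            death_year=2010, age_at_death=80,
        )
        flat, _ = build_matrices({"d1": trajectory, "d2": make_trajectory("d2", [], 2010, 80)})
        assert flat.loc["d1", "tremor"] == 3

    def test_overlapping_bin_membership(self):
        # observation at age 47 with death at 80 (birth 1930): bins 15-45,
        # 20-50 and 25-55 receive [0, 1, 1]
        trajectory = make_trajectory("d1", [("tremor", 1977)], death_year=2010,
                                     age_at_death=80)
        _, temporal = build_matrices(
            {"d1": trajectory, "d2": make_trajectory("d2", [], 2010, 80)}
        )
        assert temporal.loc["d1", "tremor|15-45"] == 0
        assert temporal.loc["d1", "tremor|20-50"] == 1
        assert temporal.loc["d1", "tremor|25-55"] == 1
        # each concrete age falls in exactly width/step = 6 bins (away from edges)
        bins = [c for c in temporal.columns if temporal.loc["d1", c] > 0]
        assert len(bins) == 6

    def test_empty_control_gives_zero_row(self):
        flat, temporal = build_matrices(
            {"d1": make_trajectory("d1", [("x", 2000)], 2010, 80),
             "c1": make_trajectory("c1", [], 2010, 80)},
            control_donors={"c1"},
        )
        assert flat.loc["c1"].sum() == 0
        assert temporal.loc["c1"].sum() == 0

    def test_unfiltered_empty_noncontrol_rejected(self):
        with pytest.raises(ValueError, match="no concrete-age"):
            build_matrices(
                {"d1": make_trajectory("d1", [("x", 2000)], 2010, 80),
                 "d2": make_trajectory("d2", [], 2010, 80)},
                control_donors=set(),
            )


class TestNormalizeScalePca:
    def test_identical_donors_identical_embeddings(self):
        matrix = pd.DataFrame(
            [[3, 1, 0], [3, 1, 0], [0, 2, 5], [0, 2, 5]],
            index=list("abcd"), columns=list("xyz"),
        )
        embedding = normalize_scale_pca(matrix, n_components=2)
        assert np.allclose(embedding.loc["a"], embedding.loc["b"])
        assert np.allclose(embedding.loc["c"], embedding.loc["d"])

    def test_constant_feature_dropped_silently(self):
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame(rng.poisson(2, (10, 3)), columns=list("xyz"))
        matrix["const"] = 4
        embedding = normalize_scale_pca(matrix, n_components=2)
        assert embedding.shape == (10, 2)

    def test_two_population_structure_separated(self):
        rng = np.random.default_rng(1)
        a = rng.poisson([8, 8, 0, 0], (30, 4))
        b = rng.poisson([0, 0, 8, 8], (30, 4))
        matrix = pd.DataFrame(np.vstack([a, b]))
        embedding = normalize_scale_pca(matrix, n_components=2)
        labels = np.array([0] * 30 + [1] * 30)
        assert silhouette_score(embedding.iloc[:, :1], labels) > 0.5

    def test_excess_components_truncated_with_warning(self):
        matrix = pd.DataFrame(np.random.default_rng(2).poisson(2, (5, 3)))
        with pytest.warns(UserWarning, match="truncated"):
            embedding = normalize_scale_pca(matrix, n_components=10)
        assert embedding.shape[1] <= 4


class TestWnn:
    def _embeddings(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (n // 2, 5)),
                       rng.normal(4, 1, (n // 2, 5))])
        index = pd.Index([f"d{i}" for i in range(n)])
        return pd.DataFrame(X, index=index)

    def test_identical_modalities_equal_weights(self):
        embedding = self._embeddings()
        graph = wnn_graph(embedding, embedding.copy(), k=10)
        assert np.allclose(graph.weights.sum(axis=1), 1.0)
        assert np.allclose(graph.weights["weight_flat"], 0.5, atol=0.05)

    def test_noise_modality_downweighted(self):
        informative = self._embeddings()
        noise = pd.DataFrame(
            np.random.default_rng(9).normal(0, 1, informative.shape),
            index=informative.index,
        )
        graph = wnn_graph(informative, noise, k=10)
        assert graph.weights["weight_flat"].mean() > 0.5

    def test_k_must_be_smaller_than_cohort(self):
        embedding = self._embeddings(10)
        with pytest.raises(ValueError, match="must be smaller"):
            wnn_graph(embedding, embedding, k=10)


class TestClusterGraph:
    def test_two_disconnected_cliques_two_clusters(self):
        edges = []
        for i in range(5):
            for j in range(i + 1, 5):
                edges.append((i, j, 1.0))
                edges.append((i + 5, j + 5, 1.0))
        graph = JointGraph(
            donor_ids=[f"d{i}" for i in range(10)],
            weights=pd.DataFrame(
                0.5, index=[f"d{i}" for i in range(10)],
                columns=["weight_flat", "weight_temporal"],
            ),
            edges=edges, embeddings={}, k=4,
        )
        assignment = cluster_graph(graph, seed=0)
        assert assignment.n_clusters == 2

    def test_tiny_resolution_merges_connected_graph(self):
        edges = [(i, j, 1.0) for i in range(8) for j in range(i + 1, 8)]
        graph = JointGraph(
            donor_ids=[f"d{i}" for i in range(8)],
            weights=pd.DataFrame(0.5, index=[f"d{i}" for i in range(8)],
                                 columns=["weight_flat", "weight_temporal"]),
            edges=edges, embeddings={}, k=4,
        )
        assert cluster_graph(graph, resolution=1e-3, seed=0).n_clusters == 1


class TestEndToEndRecovery:
    def test_six_programs_recovered_with_both_modalities(self, program_cohort):
        """Both modalities recover the six planted programs (ARI >= 0.8);
        the flattened matrix alone cannot split the onset-shifted pair."""
        _, trajectories, truth = program_cohort
        flat, temporal = build_matrices(trajectories)
        both = cluster_cohort(flat, temporal, seed=0)
        ari_both = adjusted_rand_score(truth[both.labels.index], both.labels)
        assert ari_both >= 0.8

        flat_only = cluster_cohort(flat, temporal, seed=0, modalities="flat")
        pair = truth[truth.isin(["P5", "P6"])].index
        ari_pair_flat = adjusted_rand_score(truth[pair], flat_only.labels[pair])
        ari_pair_both = adjusted_rand_score(truth[pair], both.labels[pair])
        assert ari_pair_both >= 0.8
        assert ari_pair_flat < 0.5  # age-shifted pair not split without time

    def test_row_order_invariance(self, program_cohort):
        _, trajectories, truth = program_cohort
        flat, temporal = build_matrices(trajectories)
        shuffled = flat.sample(frac=1.0, random_state=5).index
        a = cluster_cohort(flat, temporal, seed=0)
        b = cluster_cohort(flat.loc[shuffled], temporal.loc[shuffled], seed=0)
        common = a.labels.index
        assert adjusted_rand_score(a.labels[common], b.labels[common]) > 0.95

    def test_umap_coordinates_seeded_and_2d(self, program_cohort):
        _, trajectories, _ = program_cohort
        donors = list(trajectories)[:80]
        flat, temporal = build_matrices(trajectories, donors=donors)
        emb_flat = normalize_scale_pca(flat, 10)
        emb_temporal = normalize_scale_pca(temporal, 10)
        graph = wnn_graph(emb_flat, emb_temporal, k=10)
        coords_a = embed_2d(graph, seed=1)
        coords_b = embed_2d(graph, seed=1)
        assert coords_a.shape == (80, 2)
        pd.testing.assert_frame_equal(coords_a, coords_b)


class TestFisher:
    def test_hypergeometric_enumeration_example(self):
        labels = pd.Series([1] * 5 + [2] * 5, index=[f"d{i}" for i in range(10)])
        categories = pd.Series(["X"] * 5 + ["Y"] * 5, index=labels.index)
        frame = fisher_overrepresentation(labels, categories)
        row = frame[(frame["cluster"] == 1) & (frame["category"] == "X")].iloc[0]
        assert row["p"] == pytest.approx(1 / 252)
        assert row["p"] == pytest.approx(hypergeom.sf(4, 10, 5, 5))

    def test_uniform_category_not_flagged(self):
        rng = np.random.default_rng(0)
        labels = pd.Series(rng.integers(0, 3, 90), index=[f"d{i}" for i in range(90)])
        categories = pd.Series(list("XY" * 45), index=labels.index)
        frame = fisher_overrepresentation(labels, categories)
        assert (frame["q"] > 0.1).all()

    def test_planted_apoe44_cluster_flagged_two_sided(self):
        config = CohortConfig(
            n_donors=300,
            diseases=[
                uniform_profile("EARLY", 0.5, ["dementia"], 50, obs_prob=0.5),
                uniform_profile("CTRL", 0.5, ["fatigue"], 70, obs_prob=0.5),
            ],
            apoe44_prob_by_disease={"EARLY": 0.4, "CTRL": 0.02},
            seed=61,
        )
        cohort = generate_cohort(config)
        labels = pd.Series({d.donor_id: d.nd_codes[0] for d in cohort})
        apoe = pd.Series({d.donor_id: d.apoe_genotype == "4/4" for d in cohort})
        frame = fisher_overrepresentation(labels, apoe.map({True: "4/4", False: "other"}),
                                          alternative="two-sided")
        early = frame[(frame["cluster"] == "EARLY") & (frame["category"] == "4/4")]
        assert early["q"].iloc[0] < 0.05


class TestMarkers:
    def test_enumeration_example_with_ties(self):
        matrix = pd.DataFrame(
            {"attr": [5, 5, 5, 0, 0, 0]}, index=[f"d{i}" for i in range(6)]
        )
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=matrix.index)
        frame = find_markers(matrix, labels)
        row = frame[(frame["cluster"] == 1) & (frame["feature"] == "attr")].iloc[0]
        assert row["p"] == pytest.approx(0.1)
        assert row["direction"] == "up"

    def test_identically_distributed_attribute_not_a_marker(self):
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame({"same": rng.poisson(3, 60),
                               "marker": [5] * 30 + [0] * 30})
        labels = pd.Series([1] * 30 + [2] * 30, index=matrix.index)
        frame = find_markers(matrix, labels)
        same = frame[frame["feature"] == "same"]
        marker = frame[(frame["feature"] == "marker") & (frame["cluster"] == 1)]
        assert (same["q"] > 0.5).all()
        assert marker["q"].iloc[0] < 1e-6 and marker["direction"].iloc[0] == "up"

    def test_singleton_cluster_skipped_with_warning(self):
        matrix = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        labels = pd.Series([1, 2, 2, 2], index=matrix.index)
        with pytest.warns(UserWarning, match="<2 donors"):
            find_markers(matrix, labels)

    def test_planted_cluster_attribute_is_top_marker(self, program_cohort):
        _, trajectories, truth = program_cohort
        flat, _ = build_matrices(trajectories)
        frame = find_markers(flat, truth[flat.index])
        block = frame[(frame["cluster"] == "P1") & (frame["direction"] == "up")]
        top = block.sort_values("q").iloc[0]["feature"]
        assert top.startswith("a1_")


class TestSubcluster:
    def test_whole_cohort_subset_equals_top_level(self, program_cohort):
        _, trajectories, truth = program_cohort
        donors = list(trajectories)[:120]
        flat, temporal = build_matrices(trajectories, donors=donors)
        parent = cluster_cohort(flat, temporal, seed=0)
        nested = subcluster(flat, temporal, parent,
                            clusters=sorted(parent.labels.unique()), seed=0)
        assert adjusted_rand_score(parent.labels[nested.labels.index],
                                   nested.labels) > 0.95

    def test_planted_substructure_split(self, program_cohort):
        """P5 + P6 look like one merged dementia cluster in the flattened
        view; subclustering with both modalities splits them."""
        _, trajectories, truth = program_cohort
        flat, temporal = build_matrices(trajectories)
        pair = list(truth[truth.isin(["P5", "P6"])].index)
        parent = ClusterAssignment(
            labels=pd.Series(0, index=pd.Index(pair, name="donor_id"))
        )
        # resolution matched to the two-subtype question: the default 0.8
        # over-partitions one subtype without mixing the pair boundary
        nested = subcluster(flat, temporal, parent, clusters=[0], seed=0,
                            resolution=0.4)
        assert nested.n_clusters == 2
        assert adjusted_rand_score(truth[nested.labels.index], nested.labels) >= 0.9

    def test_homogeneous_parent_single_subcluster(self):
        config = CohortConfig(
            n_donors=80,
            diseases=[uniform_profile("AD", 1.0, ["dementia", "apathy"], 70,
                                      obs_prob=0.5)],
            seed=71,
        )
        cohort = generate_cohort(config)
        trajectories = trajectories_from_observations(cohort_observations(cohort))
        flat, temporal = build_matrices(trajectories)
        parent = ClusterAssignment(
            labels=pd.Series(0, index=flat.index)
        )
        nested = subcluster(flat, temporal, parent, clusters=[0],
                            resolution=0.1, seed=0)
        assert nested.n_clusters == 1
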