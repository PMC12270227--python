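"""Feature reduction, similarity, embedding and clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

import cpscreen as cp
from cpscreen.reduction_clustering import (
    cluster_hdbscan_euclidean,
    compartment_sorted_columns,
    export_edge_list,
    export_heatmap,
)
from tests.conftest import random_fingerprints


class TestDropZeroVariance:
    def test_constant_column_removed(self, rng):
        m = random_fingerprints(rng)
        m["flat"] = 3.0
        out = cp.drop_zero_variance(m)
        assert "flat" not in out.data.columns
        assert out.provenance["removed_features"] == ["flat"]

    def test_no_constants_is_identity(self, rng):
        m = random_fingerprints(rng)
        assert cp.drop_zero_variance(m).data.equals(m)

    def test_exactly_planted_constants_removed(self, rng):
        m = random_fingerprints(rng, n_cols=20)
        for i, c in enumerate(["k1", "k2", "k3"]):
            m[c] = float(i)
        out = cp.drop_zero_variance(m)
        assert sorted(out.provenance["removed_features"]) == ["k1", "k2", "k3"]
        assert out.data.shape[1] == 20

    def test_all_constant_rejected(self):
        m = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(cp.CPScreenError):
            cp.drop_zero_variance(m)


class TestRemoveCollinear:
    def test_duplicate_column_drops_higher_mean_correlation_member(self, rng):
        base = rng.normal(size=(50, 3))
        m = pd.DataFrame(base, columns=["a", "b", "c"])
        m["dup"] = m["a"] * 1.0
        # "a" and "dup" correlate 1.0; brute-force the victim choice
        out = cp.remove_collinear(m, r_cut=0.8)
        corr = m.corr().abs()
        mean_r = {
            n: corr.loc[n, [c for c in m.columns if c != n]].mean() for n in ("a", "dup")
        }
        expected_victim = "a" if mean_r["a"] > mean_r["dup"] else "dup"
        if np.isclose(mean_r["a"], mean_r["dup"]):
            expected_victim = "dup"
        assert out.provenance["removed_features"] == [expected_victim]

    def test_postcondition_no_pair_above_cut(self, rng):
        base = rng.normal(size=(60, 6))
        cols = {f"f{i}": base[:, i] for i in range(6)}
        cols["g0"] = base[:, 0] + rng.normal(scale=0.1, size=60)
        cols["g1"] = base[:, 1] + rng.normal(scale=0.1, size=60)
        m = pd.DataFrame(cols)
        out = cp.remove_collinear(m, r_cut=0.8)
        corr = out.data.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.8

    def test_idempotent(self, rng):
        base = rng.normal(size=(60, 5))
        m = pd.DataFrame(base, columns=list("abcde"))
        m["a2"] = m["a"] + rng.normal(scale=0.05, size=60)
        once = cp.remove_collinear(m)
        twice = cp.remove_collinear(once.data)
        assert list(twice.data.columns) == list(once.data.columns)
        assert twice.provenance["removed_features"] == []

    def test_independent_columns_untouched(self, rng):
        m = random_fingerprints(rng, n_rows=200, n_cols=30)
        out = cp.remove_collinear(m)
        assert out.provenance["removed_features"] == []

    def test_brute_force_on_toy_matrix(self):
        """Exhaustively verify the greedy choice on a 5-feature toy with a
        known correlation structure."""
        rng = np.random.default_rng(5)
        t = rng.normal(size=100)
        m = pd.DataFrame(
            {
                "x1": t + rng.normal(scale=0.1, size=100),
                "x2": t + rng.normal(scale=0.1, size=100),
                "x3": t + rng.normal(scale=0.12, size=100),
                "y1": rng.normal(size=100),
                "y2": rng.normal(size=100),
            }
        )
        out = cp.remove_collinear(m, r_cut=0.8)
        # the three t-derived columns collapse to one; independents survive
        survivors = set(out.data.columns)
        assert {"y1", "y2"} <= survivors
        assert len(survivors & {"x1", "x2", "x3"}) == 1

    def test_replay_reproduces_reduction(self, rng):
        base = rng.normal(size=(60, 5))
        m = pd.DataFrame(base, columns=list("abcde"))
        m["a2"] = m["a"] + rng.normal(scale=0.05, size=60)
        out = cp.remove_collinear(m)
        assert out.replay(m).equals(out.data)

    def test_invalid_cut_rejected(self, rng):
        with pytest.raises(cp.CPScreenError):
            cp.remove_collinear(random_fingerprints(rng), r_cut=1.5)


class TestConcatConditions:
    def test_column_counts_add(self, rng):
        a = random_fingerprints(rng, n_cols=482)
        b = random_fingerprints(rng, n_cols=482)
        combined = cp.concat_conditions(a, b)
        assert combined.shape[1] == 964

    def test_round_trip_split(self, rng):
        a = random_fingerprints(rng, n_cols=5)
        combined = cp.concat_conditions(a, a)
        from cpscreen.reduction_clustering import split_conditions

        rest, act = split_conditions(combined)
        assert rest.equals(a) and act.equals(a)

    def test_row_mismatch_rejected(self, rng):
        a = random_fingerprints(rng)
        b = random_fingerprints(rng, prefix="other")
        with pytest.raises(cp.CPScreenError, match="row keys"):
            cp.concat_conditions(a, b)


def _two_group_matrix(seed, n_per_group=60, n_features=40, separation=2.0):
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(2, n_features))
    centers[1] = centers[0] + separation * rng.normal(size=n_features) / np.sqrt(n_features) * np.sqrt(n_features)
    rows = np.vstack(
        [centers[g] + rng.normal(size=n_features) for g in range(2) for _ in range(n_per_group)]
    )
    labels = np.repeat([0, 1], n_per_group)
    idx = [f"c{i:03d}" for i in range(2 * n_per_group)]
    return pd.DataFrame(rows, index=idx, columns=[f"f{j}" for j in range(n_features)]), labels


class TestUmapEmbed:
    def test_output_shape(self):
        m, _ = _two_group_matrix(0)
        out = cp.umap_embed(m, n_components=10, seed=1)
        assert out.data.shape == (len(m), 10)
        assert out.provenance["metric"] == "correlation"

    def test_deterministic_under_seed(self):
        m, _ = _two_group_matrix(1)
        a = cp.umap_embed(m, n_components=5, seed=7).data
        b = cp.umap_embed(m, n_components=5, seed=7).data
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_planted_groups_stay_separated(self):
        scores = []
        for seed in range(3):
            m, labels = _two_group_matrix(seed, separation=4.0)
            emb = cp.umap_embed(m, n_components=5, seed=seed).data
            scores.append(silhouette_score(emb.to_numpy(), labels))
        assert np.median(scores) > 0.5

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(cp.CPScreenError):
            cp.umap_embed(random_fingerprints(rng, n_rows=5), n_neighbors=10)


class TestSimilarityMatrix:
    def test_identical_rows_similarity_one(self, rng):
        row = rng.normal(size=20)
        m = pd.DataFrame([row, row], index=["a", "b"])
        sim = cp.similarity_matrix(m)
        assert sim.loc["a", "b"] == pytest.approx(1.0)

    def test_orthogonal_centered_rows_near_zero(self):
        m = pd.DataFrame([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]], index=["a", "b"])
        assert cp.similarity_matrix(m).loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_pairwise(self, rng):
        m = random_fingerprints(rng, n_rows=10, n_cols=20)
        sim = cp.similarity_matrix(m)
        for i, j in itertools.combinations(range(10), 2):
            xi, xj = m.iloc[i].to_numpy(), m.iloc[j].to_numpy()
            r = np.sum((xi - xi.mean()) * (xj - xj.mean())) / (
                np.sqrt(np.sum((xi - xi.mean()) ** 2)) * np.sqrt(np.sum((xj - xj.mean()) ** 2))
            )
            assert sim.iloc[i, j] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_row_flagged_missing(self, rng):
        m = random_fingerprints(rng, n_rows=4, n_cols=10)
        m.iloc[2] = 5.0
        sim = cp.similarity_matrix(m)
        assert sim.iloc[2, 0] != sim.iloc[2, 0]  # NaN
        assert sim.iloc[2, 2] == 1.0


class TestHDBSCAN:
    def test_three_planted_groups_recovered(self):
        aris = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            centers = rng.normal(scale=4.0, size=(3, 30))
            rows = np.vstack(
                [c + 0.3 * rng.normal(size=30) for c in centers for _ in range(20)]
            )
            truth = np.repeat([0, 1, 2], 20)
            m = pd.DataFrame(rows, index=[f"c{i}" for i in range(60)])
            labels = cp.cluster_hdbscan(cp.similarity_matrix(m))
            aris.append(adjusted_rand_score(truth, labels.to_numpy()))
        assert np.median(aris) > 0.9

    def test_pure_noise_mostly_unclustered(self):
        fracs = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            m = pd.DataFrame(rng.normal(size=(40, 30)))
            labels = cp.cluster_hdbscan(cp.similarity_matrix(m))
            fracs.append(float((labels.to_numpy() == -1).mean()))
        assert np.median(fracs) > 0.5

    def test_duplicated_dataset_same_partition(self, rng):
        centers = rng.normal(scale=4.0, size=(2, 20))
        rows = np.vstack([c + 0.2 * rng.normal(size=20) for c in centers for _ in range(10)])
        m = pd.DataFrame(rows, index=[f"c{i}" for i in range(20)])
        a = cp.cluster_hdbscan(cp.similarity_matrix(m)).to_numpy()
        b = cp.cluster_hdbscan(cp.similarity_matrix(m)).to_numpy()
        assert adjusted_rand_score(a, b) == 1.0

    def test_too_few_rows_rejected(self, rng):
        m = random_fingerprints(rng, n_rows=4, n_cols=6)
        with pytest.raises(cp.CPScreenError):
            cp.cluster_hdbscan(cp.similarity_matrix(m))


class TestHierarchicalClustering:
    def test_identical_pair_merges_first(self, rng):
        row = rng.normal(size=15)
        far = rng.normal(size=15)
        m = pd.DataFrame([row, row, far], index=["a", "b", "c"])
        z, order = cp.cluster_hierarchical(m)
        assert set(map(int, z[0, :2])) == {0, 1}  # a and b merge first
        assert order.index("a") + 1 == order.index("b") or order.index("b") + 1 == order.index("a")

    def test_merge_heights_match_brute_force_complete_linkage(self, rng):
        m = random_fingerprints(rng, n_rows=6, n_cols=12)
        z, _ = cp.cluster_hierarchical(m)
        # brute force: complete linkage on 1 - pearson r
        x = m.to_numpy()

        def pearson_dist(i, j):
            return 1.0 - np.corrcoef(x[i], x[j])[0, 1]

        clusters = [{i} for i in range(6)]
        heights = []
        while len(clusters) > 1:
            best = None
            for a, b in itertools.combinations(range(len(clusters)), 2):
                d = max(pearson_dist(i, j) for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
            d, a, b = best
            heights.append(d)
            clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [
                clusters[a] | clusters[b]
            ]
        np.testing.assert_allclose(sorted(z[:, 2]), sorted(heights), atol=1e-12)

    def test_leaf_order_stable_across_runs(self, rng):
        m = random_fingerprints(rng, n_rows=8, n_cols=10)
        _, a = cp.cluster_hierarchical(m)
        _, b = cp.cluster_hierarchical(m)
        assert a == b


class TestExports:
    def test_heatmap_export_round_trips_values(self, tmp_path, rng):
        m = random_fingerprints(rng, n_rows=6, n_cols=5)
        rows = cp.cluster_hierarchical(m, axis="rows")
        cols = cp.cluster_hierarchical(m, axis="columns")
        paths = export_heatmap(m, rows, cols, tmp_path / "hm")
        back = pd.read_csv(paths["matrix"], sep="\t", index_col="key", float_precision="round_trip")
        assert np.array_equal(
            back.loc[m.index, m.columns].to_numpy(), m.to_numpy()
        )
        assert paths["row_tree"].read_text().strip().endswith(";")

    def test_compartment_sort_groups_prefixes(self, tmp_path, rng):
        cols = ["Nuc_001", "ER_001", "Nuc_002", "Mito_001", "ER_002"]
        order = compartment_sorted_columns(cols)
        nuc = [i for i, c in enumerate(order) if c.startswith("Nuc_")]
        assert nuc == list(range(nuc[0], nuc[0] + 2))

    def test_empty_matrix_export_rejected(self, tmp_path):
        m = pd.DataFrame(columns=["a"])
        with pytest.raises(cp.CPScreenError):
            export_heatmap(m, (None, []), (None, []), tmp_path / "hm")

    def test_edge_list_contains_only_above_cut_pairs(self, tmp_path, rng):
        m = random_fingerprints(rng, n_rows=8, n_cols=10)
        sim = cp.similarity_matrix(m)
        edges = export_edge_list(sim, 0.3, tmp_path / "edges.csv")
        assert (edges["similarity"] > 0.3).all()
        expected = sum(
            1
            for i, j in itertools.combinations(range(8), 2)
            if sim.iloc[i, j] > 0.3
        )
        assert len(edges) == expected


class TestEndToEndChain:
    def test_planted_two_group_structure_survives_reduce_embed_cluster(self):
        aris = []
        for seed in range(3):
            m, truth = _two_group_matrix(seed, n_per_group=40, n_features=60, separation=2.0)
            nz = cp.drop_zero_variance(m)
            red = cp.remove_collinear(nz.data)
            emb = cp.umap_embed(red.data, n_components=5, seed=seed).data
            labels = cluster_hdbscan_euclidean(emb)
            aris.append(adjusted_rand_score(truth, labels.to_numpy()))
        assert np.median(aris) > 0.8
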