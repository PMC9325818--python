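import numpy as np
import pytest

from _oracles import brute_force_dpc
from salqsar.chem import BitFingerprint
from salqsar.clusters import (
    QuadrantLabel,
    _distance_matrix,
    assign_quadrant,
    cluster_quadrant,
    dpc_cluster,
    kmeans_fallback,
    quadrant_partition,
)


def fp(bits, n_bits=64):
    return BitFingerprint(frozenset(bits), n_bits)


class TestAssignQuadrant:
    @pytest.mark.parametrize(
        "label, output, expected",
        [
            (1, 0.7, QuadrantLabel.TP),
            (0, 0.7, QuadrantLabel.FP),
            (1, 0.3, QuadrantLabel.FN),
            (0, 0.3, QuadrantLabel.TN),
            (1, 0.5, QuadrantLabel.FN),  # boundary counts as predicted-negative
            (0, 0.5, QuadrantLabel.TN),
        ],
    )
    def test_quadrant_table(self, label, output, expected):
        assert assign_quadrant(label, output) is expected

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            assign_quadrant(2, 0.7)


class TestDPC:
    def test_two_tight_groups_give_two_clusters(self):
        group_a = [fp({1, 2, 3})] * 5
        group_b = [fp({10, 11, 12})] * 5
        res = dpc_cluster(group_a + group_b, d_c=0.5)
        labels = res.assignments
        assert len(set(labels)) == 2
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_all_identical_single_cluster(self):
        res = dpc_cluster([fp({1, 2})] * 7, d_c=0.5)
        assert set(res.assignments) == {0}

    def test_statistics_match_brute_force_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            fps = [
                fp(set(rng.choice(64, size=rng.integers(2, 9), replace=False).tolist()))
                for _ in range(20)
            ]
            dist = _distance_matrix(fps)
            d_c = 0.6
            res = dpc_cluster(fps, d_c=d_c)
            rho, delta, gamma, nearest = brute_force_dpc(dist, d_c)
            np.testing.assert_allclose(res.rho, rho)
            np.testing.assert_allclose(res.delta, delta)
            np.testing.assert_allclose(res.gamma, gamma)
            # every non-center's cluster equals its nearest-higher-density
            # parent's cluster (independent chain-following)
            for i, parent in enumerate(nearest):
                if i not in res.centers and parent >= 0:
                    assert res.assignments[i] == res.assignments[parent]

    def test_forced_center_count(self):
        fps = [fp({1, 2})] * 4 + [fp({10, 11})] * 4 + [fp({20, 21})] * 4
        res = dpc_cluster(fps, d_c=0.5, n_centers=3)
        assert len(set(res.assignments)) == 3


class TestKMeansFallback:
    def test_disjoint_support_perfect_split(self):
        fps = [fp({1, 2, 3})] * 5 + [fp({30, 31, 32})] * 5
        labels = kmeans_fallback(fps, seed=0)
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_two_points_one_each(self):
        labels = kmeans_fallback([fp({1}), fp({2})], seed=0)
        assert sorted(labels) == [0, 1]

    def test_identical_points_degenerate(self):
        assert set(kmeans_fallback([fp({5})] * 4, seed=0)) == {0}

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        fps = [fp(set(rng.choice(64, 5, replace=False).tolist())) for _ in range(12)]
        assert kmeans_fallback(fps, seed=3) == kmeans_fallback(fps, seed=3)


class TestClusterQuadrant:
    def test_quadrant_counts_partition_test_set(self, trained_tiny_model, small_dataset):
        model, split = trained_tiny_model
        test_ids = list(split.test_ids)
        quadrants = quadrant_partition(small_dataset, model, test_ids)
        total = sum(len(v) for v in quadrants.values())
        assert total == len(test_ids)
        flat = [i for v in quadrants.values() for i in v]
        assert sorted(flat) == sorted(test_ids)

    def test_each_fragment_in_exactly_one_cluster(self, trained_tiny_model, small_dataset):
        model, split = trained_tiny_model
        clusters = cluster_quadrant(
            small_dataset, model, QuadrantLabel.TP, list(split.test_ids), seed=0
        )
        assert clusters, "TP quadrant should not be empty on the planted-motif set"
        keys = [
            (mol_id, nbh.center)
            for cl in clusters
            for mol_id, nbh, _ in cl.members
        ]
        assert len(keys) == len(set(keys))
        pops = [cl.population for cl in clusters]
        assert pops == sorted(pops, reverse=True)
        assert [cl.rank for cl in clusters] == list(range(1, len(clusters) + 1))

    def test_sparse_input_triggers_kmeans_fallback(
        self, trained_tiny_model, small_dataset, caplog
    ):
        model, split = trained_tiny_model
        with caplog.at_level("INFO", logger="salqsar.clusters"):
            clusters = cluster_quadrant(
                small_dataset,
                model,
                QuadrantLabel.TP,
                list(split.test_ids),
                min_points=10_000,  # force the sparse path
                seed=0,
            )
        assert 1 <= len(clusters) <= 2
        assert any("fallback" in rec.message for rec in caplog.records)

    def test_empty_quadrant_returns_empty_list(self, trained_tiny_model, small_dataset):
        model, split = trained_tiny_model
        quadrants = quadrant_partition(small_dataset, model, list(split.test_ids))
        empty = [q for q in QuadrantLabel if not quadrants[q]]
        if not empty:
            pytest.skip("every quadrant populated for this fixture")
        assert (
            cluster_quadrant(
                small_dataset, model, empty[0], list(split.test_ids), seed=0
            )
            == []
        )
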