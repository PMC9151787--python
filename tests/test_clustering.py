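"""UPGMA, cophenetic correlation, bootstrap support and ARI verification."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet as scipy_cophenet
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from conftest import pair_counting_ari
from whalesong.clustering import (
    average_linkage,
    bootstrap_support,
    cophenetic_correlation,
    cut_clusters,
    verify_assignments,
)


def four_point_matrix() -> np.ndarray:
    # d(A,B)=0.2, d(C,D)=0.3, all cross pairs 0.9
    d = np.full((4, 4), 0.9)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = 0.2
    d[2, 3] = d[3, 2] = 0.3
    return d


class TestAverageLinkage:
    def test_three_point_forced_merge_order(self):
        d = np.array([[0.0, 0.1, 0.8], [0.1, 0.0, 0.8], [0.8, 0.8, 0.0]])
        dendro = average_linkage(d)
        assert dendro.Z[0, :3].tolist() == [0.0, 1.0, pytest.approx(0.1)]
        assert dendro.Z[1, 2] == pytest.approx(0.8)

    def test_identical_items_merge_at_zero(self):
        d = np.zeros((5, 5))
        dendro = average_linkage(d)
        assert np.allclose(dendro.Z[:, 2], 0.0)

    def test_four_point_hand_computed_upgma(self):
        dendro = average_linkage(four_point_matrix(),
                                 leaf_ids=["A", "B", "C", "D"])
        heights = dendro.Z[:, 2]
        assert heights == pytest.approx([0.2, 0.3, 0.9])
        sets = [frozenset(s) for s in dendro.node_leafsets()]
        assert sets[0] == {0, 1} and sets[1] == {2, 3}

    def test_matches_scipy_average_linkage_cophenetics(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = 8
            x = rng.random((n, 3))
            d = squareform(np.round(
                np.linalg.norm(x[:, None] - x[None], axis=-1), 6), checks=False)
            ours = average_linkage(squareform(d))
            theirs = scipy_linkage(d, method="average")
            assert np.allclose(ours.cophenetic_distances(),
                               scipy_cophenet(theirs), atol=1e-9)

    def test_merge_heights_monotone_nondecreasing(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            d = squareform(rng.random(45))  # 10 items
            dendro = average_linkage(d)
            assert np.all(np.diff(dendro.Z[:, 2]) >= -1e-12)

    def test_cophenetic_matrix_ultrametric(self):
        rng = np.random.default_rng(3)
        d = squareform(rng.random(28))  # 8 items
        coph = squareform(average_linkage(d).cophenetic_distances())
        n = coph.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert coph[i, k] <= max(coph[i, j], coph[j, k]) + 1e-9

    def test_deterministic_tie_break_lexicographic(self):
        # three equidistant points: ids 0 and 1 must merge first
        d = np.ones((3, 3)) - np.eye(3)
        dendro = average_linkage(d)
        assert dendro.Z[0, 0] == 0 and dendro.Z[0, 1] == 1

    def test_nan_distances_rejected(self):
        d = four_point_matrix()
        d[0, 2] = d[2, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            average_linkage(d)


class TestCopheneticCorrelation:
    def test_ultrametric_input_gives_one(self):
        d = four_point_matrix()
        d[0, 1] = d[1, 0] = 0.3  # make the two block heights equal? keep ultrametric
        dendro = average_linkage(d)
        ccc, ok = cophenetic_correlation(d, dendro)
        assert ccc == pytest.approx(1.0)
        assert ok

    def test_four_point_matches_direct_pearson(self):
        d = four_point_matrix()
        dendro = average_linkage(d)
        ccc, _ = cophenetic_correlation(d, dendro)
        orig = squareform(d, checks=False)
        coph = dendro.cophenetic_distances()
        expect = np.corrcoef(orig, coph)[0, 1]
        assert ccc == pytest.approx(expect)

    def test_all_distances_equal_errors(self):
        d = np.ones((4, 4)) - np.eye(4)
        dendro = average_linkage(d)
        with pytest.raises(ValueError, match="zero variance"):
            cophenetic_correlation(d, dendro)


class TestBootstrapSupport:
    def test_two_tight_clusters_get_high_support(self):
        # two well-separated clusters of identical sequences
        items = [("A", "A", "A")] * 5 + [("B", "C", "D")] * 5
        dendro = bootstrap_support(items, None, B=100, seed=0)
        sets = dendro.node_leafsets()
        for k, s in enumerate(sets):
            if s == frozenset(range(5)) or s == frozenset(range(5, 10)):
                assert dendro.support[k] >= 0.95

    def test_single_replicate_gives_binary_supports(self):
        items = [("A",), ("A", "B"), ("C", "D"), ("D", "D")]
        dendro = bootstrap_support(items, None, B=1, seed=42)
        assert set(np.round(dendro.support, 6)) <= {0.0, 1.0}

    def test_deterministic_under_seed(self):
        items = [("A", "B"), ("A", "C"), ("D", "D"), ("C", "D"), ("A", "B", "C")]
        d1 = bootstrap_support(items, None, B=25, seed=9)
        d2 = bootstrap_support(items, None, B=25, seed=9)
        assert np.array_equal(d1.support, d2.support)
        assert np.array_equal(d1.Z, d2.Z)

    def test_zero_replicates_errors(self):
        with pytest.raises(ValueError):
            bootstrap_support([("A",), ("B",)], None, B=0, seed=0)


class TestCutAndVerify:
    def test_threshold_zero_gives_singletons(self):
        dendro = average_linkage(four_point_matrix(),
                                 leaf_ids=["A", "B", "C", "D"])
        assert cut_clusters(dendro, 0.0).n_clusters == 4

    def test_threshold_above_root_gives_one_cluster(self):
        dendro = average_linkage(four_point_matrix())
        assert cut_clusters(dendro, 2.0).n_clusters == 1

    def test_four_point_cut_recovers_pairs(self):
        dendro = average_linkage(four_point_matrix(),
                                 leaf_ids=["A", "B", "C", "D"])
        cut = cut_clusters(dendro, 0.5)
        assert cut.labels["A"] == cut.labels["B"]
        assert cut.labels["C"] == cut.labels["D"]
        assert cut.labels["A"] != cut.labels["C"]

    def test_perfect_agreement_gives_ari_one(self):
        dendro = average_linkage(four_point_matrix(),
                                 leaf_ids=["A", "B", "C", "D"])
        cut = cut_clusters(dendro, 0.5)
        ref = {"A": "t1", "B": "t1", "C": "t2", "D": "t2"}
        report = verify_assignments(cut, ref)
        assert report.ari == pytest.approx(1.0)
        assert all(v == 1.0 for v in report.purity_by_reference.values())

    def test_ari_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(5)
        from whalesong.clustering import ClusterAssignment

        for _ in range(20):
            n = 12
            pred = rng.integers(0, 3, size=n)
            ref_labels = rng.integers(0, 3, size=n)
            items = [f"i{k}" for k in range(n)]
            assignment = ClusterAssignment(
                labels=dict(zip(items, map(int, pred))), threshold=0.0
            )
            ref = dict(zip(items, map(int, ref_labels)))
            got = verify_assignments(assignment, ref).ari
            assert got == pytest.approx(pair_counting_ari(pred, ref_labels))

    def test_random_assignment_ari_near_zero(self):
        rng = np.random.default_rng(1)
        from whalesong.clustering import ClusterAssignment

        n = 400
        items = [f"i{k}" for k in range(n)]
        aris = []
        for _ in range(5):
            assignment = ClusterAssignment(
                labels={i: int(v) for i, v in zip(items, rng.integers(0, 4, n))},
                threshold=0.0,
            )
            ref = {i: int(v) for i, v in zip(items, rng.integers(0, 4, n))}
            aris.append(verify_assignments(assignment, ref).ari)
        assert abs(np.mean(aris)) < 0.05

    def test_mismatched_item_sets_error(self):
        from whalesong.clustering import ClusterAssignment

        assignment = ClusterAssignment(labels={"a": 1}, threshold=0.0)
        with pytest.raises(ValueError, match="different item sets"):
            verify_assignments(assignment, {"b": 1})


class TestNewickExport:
    def test_newick_parses_and_preserves_taxa_and_depth(self):
        dendro = average_linkage(four_point_matrix(),
                                 leaf_ids=["A", "B", "C", "D"])
        tree = dendropy.Tree.get(data=dendro.to_newick(), schema="newick")
        taxa = {t.label for t in tree.taxon_namespace}
        assert taxa == {"A", "B", "C", "D"}
        # leaf depth equals the root merge height
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert depths == pytest.approx([0.9] * 4)

    def test_newick_carries_bootstrap_labels(self):
        items = [("A", "A")] * 3 + [("B", "C")] * 3
        dendro = bootstrap_support(items, None, B=10, seed=0)
        nwk = dendro.to_newick()
        assert nwk.count(")") == len(items) - 1
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        labels = [
            n.label for n in tree.preorder_internal_node_iter() if n.label
        ]
        assert labels  # at least one support value survives parsing
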