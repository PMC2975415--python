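"""Complete linkage, cut selection, gain ratio and permutation tests."""

import itertools
import math
from collections import Counter, defaultdict

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import entropy as scipy_entropy

from histac.cluster import (
    ClusterTree,
    SubClassPartition,
    complete_linkage,
    cut_tree,
    gain_ratio,
    information_gain,
    permute_histone_association_test,
    permute_labels_subclass_test,
    permute_normalization_test,
    permute_spatial_coherence_test,
    select_cut,
)
from histac.io import extract_peptides, merge_adjacent
from histac.metric import DistanceMatrix, distance_matrix
from histac.synthetic import FamilySpec, generate_histone_family

from conftest import random_distance_matrix


def _dm(values, ids=None):
    values = np.asarray(values, float)
    ids = ids or [f"L{i}" for i in range(len(values))]
    return DistanceMatrix(peptide_ids=ids, values=values)


def _partition_sets(cluster_of, ids):
    groups = defaultdict(set)
    for i in ids:
        groups[cluster_of[i]].add(i)
    return sorted(sorted(g) for g in groups.values())


class TestCompleteLinkage:
    def test_two_leaves_merge_at_their_distance(self):
        tree = complete_linkage(_dm([[0, 0.5], [0.5, 0]]))
        assert tree.merges == [(0, 1, 0.5)]

    def test_three_leaf_hand_agglomeration(self):
        tree = complete_linkage(
            _dm([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        )
        heights = [h for _, _, h in tree.merges]
        assert heights == [0.1, 0.9]
        assert set(tree.merges[0][:2]) == {0, 1}

    def test_matches_reference_implementation_on_random_matrices(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            d = random_distance_matrix(rng, 8)
            tree = complete_linkage(_dm(d))
            z = linkage(squareform(d, checks=False), method="complete")
            for h in (0.2, 0.5, 0.8):
                mine = cut_tree(tree, h).cluster_of()
                ref = fcluster(z, t=h, criterion="distance")
                ids = tree.leaves
                assert _partition_sets(mine, ids) == _partition_sets(
                    dict(zip(ids, ref)), ids
                )

    def test_heights_are_monotone_non_decreasing(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            tree = complete_linkage(_dm(random_distance_matrix(rng, 10)))
            h = tree.heights
            assert np.all(np.diff(h) >= -1e-12)

    def test_cluster_diameter_never_exceeds_cut_height(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            d = random_distance_matrix(rng, 9)
            tree = complete_linkage(_dm(d))
            for h in (0.3, 0.6):
                for cluster in cut_tree(tree, h).clusters:
                    idx = [tree.leaves.index(l) for l in cluster]
                    for i, j in itertools.combinations(idx, 2):
                        assert d[i, j] <= h + 1e-9

    def test_single_leaf_errors(self):
        with pytest.raises(ValueError):
            complete_linkage(_dm([[0.0]]))


class TestCutTree:
    def test_cut_at_zero_gives_singletons(self):
        rng = np.random.default_rng(13)
        tree = complete_linkage(_dm(random_distance_matrix(rng, 6)))
        assert cut_tree(tree, 0).n_clusters == 6

    def test_cut_above_max_height_gives_one_cluster(self):
        rng = np.random.default_rng(14)
        tree = complete_linkage(_dm(random_distance_matrix(rng, 6)))
        assert cut_tree(tree, float(tree.heights[-1])).n_clusters == 1

    def test_cluster_count_weakly_decreases_with_height(self):
        rng = np.random.default_rng(15)
        tree = complete_linkage(_dm(random_distance_matrix(rng, 12)))
        counts = [cut_tree(tree, h).n_clusters for h in np.linspace(0, 1, 30)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


def _oracle_gain_ratio(clusters, labels):
    """Direct entropy arithmetic via scipy.stats.entropy (base 2)."""
    leaves = [l for c in clusters for l in c]
    n = len(leaves)

    def H(items):
        counts = np.array(list(Counter(items).values()), float)
        return scipy_entropy(counts / counts.sum(), base=2)

    ig = H([labels[l] for l in leaves]) - sum(
        len(c) / n * H([labels[l] for l in c]) for c in clusters
    )
    if ig <= 0:
        return 0.0
    split = scipy_entropy(np.array([len(c) / n for c in clusters]), base=2)
    return 0.0 if split == 0 else min(ig / split, 1.0)


class TestGainRatio:
    def _partition(self, clusters):
        return SubClassPartition(cut_height=0.5, clusters=[frozenset(c) for c in clusters])

    def test_perfect_split_scores_one(self):
        part = self._partition([{"1", "2"}, {"3", "4"}])
        labels = {"1": "P", "2": "P", "3": "N", "4": "N"}
        assert gain_ratio(part, labels) == pytest.approx(1.0)

    def test_single_class_labels_score_zero(self):
        part = self._partition([{"1", "2"}, {"3", "4"}])
        assert gain_ratio(part, {k: "P" for k in "1234"}) == 0.0

    def test_uninformative_split_scores_zero(self):
        part = self._partition([{"1", "2"}, {"3", "4"}])
        labels = {"1": "P", "2": "N", "3": "P", "4": "N"}
        assert gain_ratio(part, labels) == 0.0

    def test_invariant_under_label_swap(self):
        rng = np.random.default_rng(16)
        ids = [str(i) for i in range(8)]
        for _ in range(20):
            labels = {i: rng.choice(["P", "N"]) for i in ids}
            swapped = {i: ("P" if l == "N" else "N") for i, l in labels.items()}
            part = self._partition([set(ids[:3]), set(ids[3:6]), set(ids[6:])])
            assert gain_ratio(part, labels) == pytest.approx(
                gain_ratio(part, swapped)
            )

    def test_matches_direct_entropy_on_all_six_leaf_partitions(self):
        """Gain ratio equals direct entropy arithmetic over every partition
        of a 6-leaf set (Bell(6) = 203 partitions, several labelings)."""
        ids = [str(i) for i in range(6)]

        def set_partitions(collection):
            if len(collection) == 1:
                yield [collection]
                return
            first, *rest = collection
            for smaller in set_partitions(rest):
                for k, subset in enumerate(smaller):
                    yield smaller[:k] + [[first] + subset] + smaller[k + 1:]
                yield [[first]] + smaller

        partitions = list(set_partitions(ids))
        assert len(partitions) == 203
        rng = np.random.default_rng(17)
        labelings = [
            {i: ("P" if int(i) < 3 else "N") for i in ids},
            {i: ("P" if int(i) % 2 else "N") for i in ids},
            {i: str(rng.choice(["P", "N"])) for i in ids},
        ]
        for clusters in partitions:
            part = self._partition([set(c) for c in clusters])
            for labels in labelings:
                assert gain_ratio(part, labels) == pytest.approx(
                    _oracle_gain_ratio([set(c) for c in clusters], labels)
                )

    def test_unlabeled_leaf_is_an_error(self):
        part = self._partition([{"1"}, {"2"}])
        with pytest.raises(ValueError):
            gain_ratio(part, {"1": "P", "2": "U"})


class TestSelectCut:
    def test_two_pure_pairs_select_the_two_cluster_cut(self):
        d = np.array(
            [
                [0.0, 0.1, 0.9, 0.95],
                [0.1, 0.0, 0.92, 0.9],
                [0.9, 0.92, 0.0, 0.1],
                [0.95, 0.9, 0.1, 0.0],
            ]
        )
        tree = complete_linkage(_dm(d))
        labels = {"L0": "P", "L1": "P", "L2": "N", "L3": "N"}
        cut = select_cut(tree, labels)
        assert cut.n_clusters == 2
        assert cut.gain_ratio == pytest.approx(1.0)
        assert not cut.degenerate

    def test_exhaustive_cut_evaluation_oracle(self):
        rng = np.random.default_rng(18)
        for _ in range(10):
            d = random_distance_matrix(rng, 7)
            tree = complete_linkage(_dm(d))
            labels = {l: str(rng.choice(["P", "N"])) for l in tree.leaves}
            got = select_cut(tree, labels)
            # oracle: evaluate every candidate cut directly
            best = None
            hs = sorted(set(tree.heights.tolist()))
            cands = [0.0] + [(a + b) / 2 for a, b in zip(hs, hs[1:])]
            for h in cands:
                part = cut_tree(tree, h)
                key = (-gain_ratio(part, labels), part.n_clusters, -h)
                if best is None or key < best:
                    best = key
            if got.degenerate:
                assert best[0] == 0.0
            else:
                assert -best[0] == pytest.approx(got.gain_ratio)
                assert best[1] == got.n_clusters

    def test_mixed_labels_flagged_degenerate(self):
        d = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        tree = complete_linkage(_dm(d))
        labels = {"L0": "P", "L1": "P", "L2": "P"}
        cut = select_cut(tree, labels)
        assert cut.degenerate and cut.gain_ratio == 0.0

    def test_motif_family_cut_is_label_pure_and_tree_separates_motifs(self):
        spec = FamilySpec(
            n_proteins=3, n_lysines=8, mutation_rate=0.03, seed=1,
            motifs_p=("AAGGKSTGG", "LLDEKDELL"), motifs_n=("WWTPKPLLW",),
        )
        prots, _ = generate_histone_family(spec)
        peps = []
        for p in prots:
            peps += merge_adjacent(p, extract_peptides(p, 12), 3, 12)
        dm = distance_matrix(peps)
        tree = complete_linkage(dm)
        labels = {p.peptide_id: p.label for p in peps}
        cut = select_cut(tree, labels)
        for cluster in cut.partition.clusters:
            assert len({labels[l] for l in cluster}) == 1
        # ground-truth motif groups are recoverable at some height
        motif_of = {}
        for p in peps:
            win = p.window
            motif_of[p.peptide_id] = ("N" if "WWTPK" in win or "TPKPL" in win
                                      else ("A" if "GGKST" in win else "L"))
        found = False
        for h in sorted(set(tree.heights.tolist())):
            part = cut_tree(tree, h - 1e-9)
            if part.n_clusters == 3 and all(
                len({motif_of[l] for l in c}) == 1 for c in part.clusters
            ):
                found = True
                break
        assert found


class TestInsertionInvariance:
    """Complete-linkage behaviour under adding new samples.

    Two universally valid facts are asserted on arbitrary random
    matrices; full membership preservation is asserted in the separated
    regime the predictor assumes (compact sub-classes below the cut,
    separation above it, queries that do not bridge sub-classes).
    """

    def _separated_instance(self, rng):
        k = int(rng.integers(2, 5))
        sizes = rng.integers(2, 5, size=k)
        n = int(sizes.sum())
        blob = np.repeat(np.arange(k), sizes)
        m = int(rng.integers(1, 4))
        q_blob = [int(rng.integers(0, k + 1)) for _ in range(m)]  # k = far
        N = n + m

        def group(i):
            return blob[i] if i < n else q_blob[i - n]

        d = np.zeros((N, N))
        for i in range(N):
            for j in range(i + 1, N):
                if group(i) == group(j) and group(i) != k:
                    d[i, j] = rng.uniform(0.01, 0.1)
                else:
                    d[i, j] = rng.uniform(0.5, 1.0)
                d[j, i] = d[i, j]
        return d, n

    def test_between_cluster_distance_monotone_under_absorption(self):
        # D(r U {k}, s) >= D(r, s): the max over a superset of pairs
        rng = np.random.default_rng(19)
        for _ in range(50):
            d = random_distance_matrix(rng, 8)
            r = [0, 1, 2]
            s = [3, 4]
            new = 5
            D_rs = max(d[i, j] for i in r for j in s)
            D_rk_s = max(d[i, j] for i in r + [new] for j in s)
            assert D_rk_s >= D_rs

    def test_membership_preserved_for_separated_subclasses(self):
        rng = np.random.default_rng(20)
        for _ in range(100):
            d, n = self._separated_instance(rng)
            ids = [f"x{i}" for i in range(len(d))]
            h = 0.3
            old = cut_tree(
                complete_linkage(_dm(d[:n, :n], ids[:n])), h
            ).cluster_of()
            new = cut_tree(complete_linkage(_dm(d, ids)), h).cluster_of()
            for i in range(n):
                for j in range(i + 1, n):
                    a, b = ids[i], ids[j]
                    assert (old[a] == old[b]) == (new[a] == new[b])


class TestPermutationTests:
    def _spatial_toy(self):
        part = SubClassPartition(
            cut_height=0.5, clusters=[frozenset({"a", "b"}), frozenset({"c"})]
        )
        coords = {
            "a": np.array([0.0, 0, 0]),
            "b": np.array([1.0, 0, 0]),
            "c": np.array([50.0, 0, 0]),
        }
        return part, coords

    def test_spatial_exhaustive_p_on_three_point_toy(self):
        part, coords = self._spatial_toy()
        res = permute_spatial_coherence_test(part, coords, method="exhaustive")
        assert res.p_value == pytest.approx(1 / 3)

    def test_spatial_monte_carlo_close_to_exhaustive(self):
        part, coords = self._spatial_toy()
        res = permute_spatial_coherence_test(part, coords, n_perm=2000, seed=1)
        assert abs(res.p_value - 1 / 3) < 0.05

    def test_plus_one_convention_never_gives_zero(self):
        part, coords = self._spatial_toy()
        res = permute_spatial_coherence_test(part, coords, n_perm=99, seed=2)
        assert res.p_value >= 1 / 100

    def test_histone_association_exhaustive_vs_monte_carlo(self):
        part = SubClassPartition(
            cut_height=0.5,
            clusters=[frozenset({"a", "b"}), frozenset({"c", "d"})],
        )
        types = {"a": "H3", "b": "H3", "c": "H4", "d": "H4"}
        ex = permute_histone_association_test(part, types, method="exhaustive")
        mc = permute_histone_association_test(part, types, n_perm=3000, seed=3)
        assert abs(ex.p_value - mc.p_value) < 0.05
        # perfectly aligned types are maximally significant
        assert ex.observed_statistic == pytest.approx(1.0)

    def test_label_permutation_is_seed_reproducible(self):
        spec = FamilySpec(n_proteins=2, n_lysines=5, mutation_rate=0.02, seed=5)
        prots, _ = generate_histone_family(spec)
        r1 = permute_labels_subclass_test(prots, n_perm=30, seed=7)
        r2 = permute_labels_subclass_test(prots, n_perm=30, seed=7)
        assert r1.null_statistics == r2.null_statistics
        assert r1.p_value == r2.p_value
        r3 = permute_labels_subclass_test(prots, n_perm=30, seed=8)
        assert r3.null_statistics != r1.null_statistics or r3.p_value != r1.p_value

    def test_normalization_noop_when_lengths_equal(self):
        spec = FamilySpec(n_proteins=2, n_lysines=6, mutation_rate=0.02, seed=9)
        prots, _ = generate_histone_family(spec)
        # interior lysines only -> all windows share one length
        peps = []
        for p in prots:
            peps += [
                q for q in extract_peptides(p, 12)
                if len(q.window) == 25
            ]
        res = permute_normalization_test(peps, n_perm=30, seed=0)
        assert res.observed_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)


def test_newick_and_linkage_matrix_roundtrip():
    rng = np.random.default_rng(21)
    tree = complete_linkage(_dm(random_distance_matrix(rng, 5)))
    nwk = tree.to_newick()
    assert nwk.endswith(";") and nwk.count("(") == 4
    z = tree.to_linkage_matrix()
    assert z.shape == (4, 4)
    assert z[-1, 3] == 5  # root covers all leaves
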