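"""Complete-linkage clustering of lysine peptides and partition scoring.

The peptide distance matrix is agglomerated under complete (maximum)
linkage, whose merge heights are monotone non-decreasing.  Cutting the
dendrogram at a height yields *sub-classes*; cuts are scored by the
information gain ratio of the acetylation labels given the partition, and
the selected cut balances few sub-classes against label purity.  A family
of permutation tests attaches empirical significance to the observed
sub-class structure.

Complete linkage has a property this package relies on for prediction:
adding new samples can only *increase* between-cluster linkage distances,
so two peptides separated at a given cut height remain separated after any
insertion.  (Insertions may still merge or locally rearrange clusters; see
the prediction module.)
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .io import HistoneProtein, extract_peptides, merge_adjacent
from .metric import (
    AlignmentParams,
    DistanceMatrix,
    distance_matrix,
    normalized_distance,
    sw_score,
)

logger = logging.getLogger(__name__)


@dataclass
class ClusterTree:
    """Agglomerative dendrogram: leaves plus an ordered merge list.

    Node ids: leaf ``i`` is node ``i`` (0-based into ``leaves``); the
    ``k``-th merge creates node ``n_leaves + k``.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValueError("a tree over n leaves needs exactly n-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def to_linkage_matrix(self) -> np.ndarray:
        """Scipy-format (n-1, 4) linkage matrix (for dendrogram plotting)."""
        n = len(self.leaves)
        sizes = {i: 1 for i in range(n)}
        z = np.zeros((n - 1, 4))
        for k, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[n + k] = size
            z[k] = [a, b, h, size]
        return z

    def to_newick(self) -> str:
        n = len(self.leaves)
        height_of: dict[int, float] = {i: 0.0 for i in range(n)}
        text: dict[int, str] = {i: self.leaves[i].replace(" ", "_") for i in range(n)}
        for k, (a, b, h) in enumerate(self.merges):
            node = n + k
            la, lb = h - height_of[a], h - height_of[b]
            text[node] = f"({text[a]}:{la:.6f},{text[b]}:{lb:.6f})"
            height_of[node] = h
        return text[n + len(self.merges) - 1] + ";"


@dataclass
class SubClassPartition:
    """Disjoint leaf clusters obtained by cutting the tree at a height."""

    cut_height: float
    clusters: list[frozenset[str]]

    def __post_init__(self) -> None:
        all_leaves = [l for c in self.clusters for l in c]
        if len(all_leaves) != len(set(all_leaves)):
            raise ValueError("clusters must be disjoint")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self) -> dict[str, int]:
        return {leaf: i for i, c in enumerate(self.clusters) for leaf in c}

    def label_summary(self, labels: dict[str, str]) -> list[Counter]:
        return [Counter(labels.get(leaf, "U") for leaf in c) for c in self.clusters]


def complete_linkage(dm: DistanceMatrix) -> ClusterTree:
    """Agglomerate a distance matrix under maximum linkage.

    Ties in the minimal linkage distance are broken deterministically by
    the lexicographically smallest pair of leaf-id-sorted clusters.
    """
    n = len(dm)
    if n < 2:
        raise ValueError("need >= 2 leaves")
    d = dm.values.copy()
    np.fill_diagonal(d, np.inf)
    active = np.ones(n, dtype=bool)
    node_of = list(range(n))  # row index -> current tree node id
    members: list[tuple[str, ...]] = [(leaf,) for leaf in dm.peptide_ids]
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        sub = np.where(active)[0]
        block = d[np.ix_(sub, sub)]
        m = block.min()
        ti, tj = np.where(block <= m + 1e-12)
        candidates = []
        for a, b in zip(sub[ti], sub[tj]):
            if a < b:
                pair = tuple(sorted((members[a], members[b])))
                candidates.append((pair, a, b))
        candidates.sort(key=lambda t: t[0])
        _, r, s = candidates[0]
        height = float(d[r, s])
        merges.append((node_of[r], node_of[s], height))
        # complete linkage update: D(new, t) = max(D(r, t), D(s, t))
        new_row = np.maximum(d[r], d[s])
        d[r], d[:, r] = new_row, new_row
        d[r, r] = np.inf
        active[s] = False
        node_of[r] = n + step
        members[r] = tuple(sorted(members[r] + members[s]))
    return ClusterTree(leaves=list(dm.peptide_ids), merges=merges)


def cut_tree(tree: ClusterTree, h: float) -> SubClassPartition:
    """Clusters = connected components using only merges at height <= h."""
    if h < 0:
        raise ValueError("cut height must be >= 0")
    n = tree.n_leaves
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (a, b, height) in enumerate(tree.merges):
        if height <= h + 1e-12:
            node = n + k
            parent[find(a)] = node
            parent[find(b)] = node
    groups: dict[int, list[str]] = {}
    for i, leaf in enumerate(tree.leaves):
        groups.setdefault(find(i), []).append(leaf)
    clusters = sorted(
        (frozenset(v) for v in groups.values()), key=lambda c: sorted(c)
    )
    return SubClassPartition(cut_height=float(h), clusters=list(clusters))


def _entropy(counts) -> float:
    total = sum(counts)
    if total == 0:
        return 0.0
    return -sum(
        (c / total) * math.log2(c / total) for c in counts if c > 0
    )


def information_gain(partition: SubClassPartition, labels: dict[str, str]) -> float:
    """Information gain of the label variable given the partition."""
    leaves = [l for c in partition.clusters for l in c]
    n = len(leaves)
    h0 = _entropy(Counter(labels[l] for l in leaves).values())
    h_cond = 0.0
    for cluster in partition.clusters:
        h_cond += (len(cluster) / n) * _entropy(
            Counter(labels[l] for l in cluster).values()
        )
    return h0 - h_cond


def gain_ratio(partition: SubClassPartition, labels: dict[str, str]) -> float:
    """Quinlan gain ratio: information gain over split information.

    Returns 0 by convention when the gain is 0 or the partition is a
    single cluster (split information 0).
    """
    leaves = [l for c in partition.clusters for l in c]
    bad = {l for l in leaves if labels.get(l) not in ("P", "N")}
    if bad:
        raise ValueError(f"leaves without P/N label: {sorted(bad)[:5]}")
    ig = information_gain(partition, labels)
    if ig <= 0:
        return 0.0
    split_info = _entropy([len(c) for c in partition.clusters])
    if split_info == 0:
        logger.warning("single-cluster partition: gain ratio defined as 0")
        return 0.0
    return float(min(ig / split_info, 1.0))


@dataclass
class SelectedCut:
    height: float
    partition: SubClassPartition
    gain_ratio: float
    degenerate: bool = False

    @property
    def n_clusters(self) -> int:
        return self.partition.n_clusters


def candidate_heights(tree: ClusterTree) -> list[float]:
    """Cut heights to evaluate: 0 plus midpoints between distinct merge heights."""
    hs = sorted(set(float(h) for h in tree.heights))
    cands = [0.0]
    cands += [(a + b) / 2 for a, b in zip(hs, hs[1:])]
    return cands


def select_cut(tree: ClusterTree, labels: dict[str, str]) -> SelectedCut:
    """Pick the cut with maximal gain ratio, then fewest clusters, then height.

    When every cut scores 0 (e.g. one-class labels) the single-cluster cut
    at the maximal height is returned flagged degenerate.
    """
    best: SelectedCut | None = None
    for h in candidate_heights(tree):
        part = cut_tree(tree, h)
        gr = gain_ratio(part, labels)
        cand = SelectedCut(height=h, partition=part, gain_ratio=gr)
        if best is None:
            best = cand
            continue
        key = (-cand.gain_ratio, cand.n_clusters, -cand.height)
        best_key = (-best.gain_ratio, best.n_clusters, -best.height)
        if key < best_key:
            best = cand
    assert best is not None
    if best.gain_ratio == 0.0:
        top = float(tree.heights[-1]) if len(tree.merges) else 0.0
        return SelectedCut(
            height=top, partition=cut_tree(tree, top), gain_ratio=0.0, degenerate=True
        )
    return best


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null, and the empirical p-value."""

    observed_statistic: float
    null_statistics: list[float]
    p_value: float
    seed: int | None
    n_permutations: int
    tail: str = "le"
    extra: dict = field(default_factory=dict)


def _p_value(observed: float, null: list[float], tail: str, exhaustive: bool) -> float:
    if tail == "le":
        hits = sum(1 for x in null if x <= observed + 1e-12)
    elif tail == "ge":
        hits = sum(1 for x in null if x >= observed - 1e-12)
    else:
        raise ValueError(tail)
    if exhaustive:
        return hits / len(null)
    return (hits + 1) / (len(null) + 1)


def _coerced_labels(peptides) -> dict[str, str]:
    return {
        p.peptide_id: ("P" if p.label == "P" else "N") for p in peptides
    }


def subclass_count_for_proteins(
    proteins: list[HistoneProtein],
    *,
    flank: int = 12,
    max_gap: int = 3,
    mode: str = "raw",
    params: AlignmentParams = AlignmentParams(),
    transform: str = "min_self",
) -> SelectedCut:
    """Extract, merge, cluster and cut: the sub-class count pipeline stage."""
    peptides = []
    for prot in proteins:
        peptides += merge_adjacent(
            prot, extract_peptides(prot, flank), max_gap=max_gap, flank=flank
        )
    dm = distance_matrix(peptides, mode=mode, params=params, transform=transform)
    tree = complete_linkage(dm)
    return select_cut(tree, _coerced_labels(peptides))


def permute_labels_subclass_test(
    proteins: list[HistoneProtein],
    n_perm: int = 1000,
    seed: int = 0,
    *,
    flank: int = 12,
    max_gap: int = 3,
    mode: str = "raw",
    params: AlignmentParams = AlignmentParams(),
    transform: str = "min_self",
) -> PermutationResult:
    """Can label structure alone explain how few sub-classes the cut finds?

    Lysine labels are permuted across all proteins; each permutation
    re-runs adjacent-lysine merging (which depends on labels), clustering
    and cut selection.  Small p: the observed sub-class count is lower
    than chance labelings allow.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = subclass_count_for_proteins(
        proteins, flank=flank, max_gap=max_gap, mode=mode,
        params=params, transform=transform,
    ).n_clusters
    slots = [
        (prot.id, pos) for prot in proteins for pos in prot.lysine_positions
    ]
    base_labels = {
        (prot.id, pos): prot.label_at(pos)
        for prot in proteins
        for pos in prot.lysine_positions
    }
    pool = [base_labels[s] for s in slots]
    rng = np.random.default_rng(seed)
    null = []
    for _ in range(n_perm):
        shuffled = list(rng.permutation(pool))
        assigned = dict(zip(slots, shuffled))
        permuted = [
            HistoneProtein(
                id=p.id, species=p.species, family=p.family, variant=p.variant,
                sequence=p.sequence,
                labels={
                    pos: assigned[(p.id, pos)]
                    for pos in p.lysine_positions
                    if assigned[(p.id, pos)] != "U"
                },
            )
            for p in proteins
        ]
        null.append(
            subclass_count_for_proteins(
                permuted, flank=flank, max_gap=max_gap, mode=mode,
                params=params, transform=transform,
            ).n_clusters
        )
    p = _p_value(observed, null, "le", exhaustive=False)
    return PermutationResult(
        observed_statistic=float(observed), null_statistics=[float(x) for x in null],
        p_value=p, seed=seed, n_permutations=n_perm, tail="le",
    )


def permute_normalization_test(
    peptides,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    params: AlignmentParams = AlignmentParams(),
    transform: str = "min_self",
) -> PermutationResult:
    """Does length normalization reduce sub-classes beyond chance?

    The statistic is the drop in selected sub-class count going from the
    raw to the length-normalized distance.  The null shuffles the per-pair
    length factors (min of the two peptide lengths) across pairs before
    recomputing the normalized matrix.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(peptides) < 3:
        raise ValueError("need >= 3 peptides")
    labels = _coerced_labels(peptides)
    dm_raw = distance_matrix(peptides, mode="raw", params=params, transform=transform)
    n_raw = select_cut(complete_linkage(dm_raw), labels).n_clusters

    ids = [p.peptide_id for p in peptides]
    windows = [p.window for p in peptides]
    pairs = [(i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    lmins = np.array([min(len(windows[i]), len(windows[j])) for i, j in pairs], float)

    def norm_count(factors: np.ndarray) -> int:
        n = len(ids)
        values = np.zeros((n, n))
        for (i, j), f in zip(pairs, factors):
            d = normalized_distance(
                windows[i], windows[j], params, transform, length_factor=float(f)
            )
            values[i, j] = values[j, i] = d
        dm = DistanceMatrix(
            peptide_ids=list(ids), values=values, mode="length_normalized",
            windows=dict(zip(ids, windows)),
        )
        return select_cut(complete_linkage(dm), labels).n_clusters

    observed = n_raw - norm_count(lmins)
    rng = np.random.default_rng(seed)
    null = [n_raw - norm_count(rng.permutation(lmins)) for _ in range(n_perm)]
    p = _p_value(observed, null, "ge", exhaustive=False)
    return PermutationResult(
        observed_statistic=float(observed),
        null_statistics=[float(x) for x in null],
        p_value=p, seed=seed, n_permutations=n_perm, tail="ge",
        extra={"n_subclasses_raw": n_raw},
    )


def permute_histone_association_test(
    partition: SubClassPartition,
    histone_types: dict[str, str],
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "monte_carlo",
) -> PermutationResult:
    """Are histone families non-randomly distributed over sub-classes?

    Statistic: information gain of the histone-family variable given the
    partition; null permutes family labels over leaves.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    leaves = [l for c in partition.clusters for l in c]
    types = [histone_types[l] for l in leaves]

    def stat(assignment: list[str]) -> float:
        lab = dict(zip(leaves, assignment))
        return information_gain(partition, lab)

    observed = stat(types)
    if method == "exhaustive":
        null = [stat(list(p)) for p in itertools.permutations(types)]
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        null = [stat(list(rng.permutation(types))) for _ in range(n_perm)]
        exhaustive = False
    p = _p_value(observed, null, "ge", exhaustive)
    return PermutationResult(
        observed_statistic=float(observed),
        null_statistics=[float(x) for x in null],
        p_value=p, seed=seed, n_permutations=len(null), tail="ge",
    )


def permute_spatial_coherence_test(
    partition: SubClassPartition,
    coords: dict[str, np.ndarray],
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "monte_carlo",
) -> PermutationResult:
    """Are same-sub-class lysines spatially compact in the nucleosome?

    Statistic: mean Euclidean distance between epsilon-N positions of
    leaves sharing a sub-class; null permutes the coordinate assignment.
    Small p means within-sub-class compactness.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    leaves_all = [l for c in partition.clusters for l in c]
    missing = [l for l in leaves_all if l not in coords]
    if missing:
        logger.warning("dropping %d leaves without coordinates", len(missing))
    kept = [l for l in leaves_all if l in coords]
    cluster_of = partition.cluster_of()
    pts = np.array([np.asarray(coords[l], float) for l in kept])
    cl = np.array([cluster_of[l] for l in kept])
    pair_idx = [
        (i, j)
        for i in range(len(kept))
        for j in range(i + 1, len(kept))
        if cl[i] == cl[j]
    ]
    if not pair_idx:
        raise ValueError("no within-cluster pairs with coordinates")

    def stat(points: np.ndarray) -> float:
        return float(
            np.mean([np.linalg.norm(points[i] - points[j]) for i, j in pair_idx])
        )

    observed = stat(pts)
    if method == "exhaustive":
        null = [stat(pts[list(perm)]) for perm in itertools.permutations(range(len(kept)))]
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        null = [stat(pts[rng.permutation(len(kept))]) for _ in range(n_perm)]
        exhaustive = False
    p = _p_value(observed, null, "le", exhaustive)
    return PermutationResult(
        observed_statistic=observed,
        null_statistics=[float(x) for x in null],
        p_value=p, seed=seed, n_permutations=len(null), tail="le",
        extra={"n_dropped_no_coords": len(missing)},
    )
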