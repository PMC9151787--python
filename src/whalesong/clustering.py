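"""Average-linkage clustering of LSI matrices and its validation.

Dendrograms over song cycles (or phrases) are built by UPGMA on distances
``1 - LSI``.  Three validation tools mirror standard practice in vocal
sequence analysis: the cophenetic correlation coefficient (CCC, with > 0.8
read as a good representation of the distance structure), bootstrap support
for internal nodes by resampling items with replacement, and agreement of a
dendrogram cut with reference labels via the adjusted Rand index.

The UPGMA implementation is deliberately in-package: merge ties are broken by
the lexicographically smallest cluster-id pair, so identical inputs always
yield bit-identical merge tables (a requirement the usual library routines do
not guarantee across versions).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .similarity import SimilarityMatrix, SubstitutionCosts, pairwise_lsi_matrix

__all__ = [
    "Dendrogram",
    "ClusterAssignment",
    "AgreementReport",
    "average_linkage",
    "cophenetic_correlation",
    "bootstrap_support",
    "cut_clusters",
    "verify_assignments",
]


@dataclass(frozen=True)
class Dendrogram:
    """A UPGMA merge tree in scipy linkage-matrix form.

    ``Z[k] = (id_a, id_b, height, size)`` with leaves ``0..n-1`` and the
    k-th merge creating node ``n + k``.  ``support[k]``, when present, is the
    bootstrap support of that merge's cluster in [0, 1].
    """

    leaf_ids: tuple[str, ...]
    Z: np.ndarray
    support: np.ndarray | None = None

    def __post_init__(self) -> None:
        Z = np.asarray(self.Z, dtype=float)
        n = len(self.leaf_ids)
        if Z.shape != (n - 1, 4):
            raise ValueError("linkage matrix shape must be (n-1, 4)")
        heights = Z[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")
        object.__setattr__(self, "Z", Z)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def node_leafsets(self) -> list[frozenset[int]]:
        """Leaf-index set of each internal node, in merge order."""
        n = self.n_leaves
        sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        out = []
        for k, (a, b, _, _) in enumerate(self.Z):
            s = sets[int(a)] | sets[int(b)]
            sets[n + k] = s
            out.append(s)
        return out

    def cophenetic_distances(self) -> np.ndarray:
        """Condensed vector of merge-height distances between leaves."""
        return cophenet(self.Z)

    def to_newick(self, digits: int = 6) -> str:
        """Newick string: support as internal node labels, branch lengths in
        distance units (parent height minus child height)."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        for k, row in enumerate(self.Z):
            height[n + k] = float(row[2])

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - height[node]
            if node < n:
                return f"{self.leaf_ids[node]}:{bl:.{digits}f}"
            k = node - n
            a, b = int(self.Z[k, 0]), int(self.Z[k, 1])
            inner = f"({render(a, height[node])},{render(b, height[node])})"
            label = "" if self.support is None else f"{self.support[k]:.3f}"
            return f"{inner}{label}:{bl:.{digits}f}"

        root = 2 * n - 2
        k = root - n
        a, b = int(self.Z[k, 0]), int(self.Z[k, 1])
        h = height[root]
        label = "" if self.support is None else f"{self.support[k]:.3f}"
        return f"({render(a, h)},{render(b, h)}){label}:0.0;"


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat cluster labels from cutting a dendrogram at a distance."""

    labels: dict[str, int]
    threshold: float
    notes: str = ""

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


@dataclass
class AgreementReport:
    """Agreement between a cluster assignment and reference labels."""

    ari: float
    contingency: pd.DataFrame
    purity_by_reference: dict[object, float] = field(default_factory=dict)


def _as_distance_matrix(dist) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(dist, SimilarityMatrix):
        return dist.to_distances(), dist.item_ids
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    return d, tuple(f"item{i}" for i in range(d.shape[0]))


def average_linkage(dist, leaf_ids: Sequence[str] | None = None) -> Dendrogram:
    """UPGMA on a distance matrix (or a SimilarityMatrix, via 1 - LSI).

    The inter-cluster distance is the unweighted mean over all cross pairs;
    among equal-height candidate merges the pair with the lexicographically
    smallest (min id, max id) merges first.
    """
    d, default_ids = _as_distance_matrix(dist)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    ids = tuple(leaf_ids) if leaf_ids is not None else default_ids
    n = d.shape[0]
    if len(ids) != n:
        raise ValueError("leaf_ids length does not match matrix")
    if n < 2:
        raise ValueError("need at least 2 items to cluster")

    # active cluster id -> (member leaf indices, size)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    # pairwise average distances between active clusters
    D: dict[tuple[int, int], float] = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        (a, b), h = min(D.items(), key=lambda kv: (kv[1], kv[0]))
        na, nb = sizes[a], sizes[b]
        for c in list(members):
            if c in (a, b):
                continue
            da = D[(min(a, c), max(a, c))]
            db = D[(min(b, c), max(b, c))]
            D[(min(c, next_id), max(c, next_id))] = (na * da + nb * db) / (na + nb)
            del D[(min(a, c), max(a, c))]
            del D[(min(b, c), max(b, c))]
        del D[(a, b)]
        members[next_id] = members.pop(a) + members.pop(b)
        sizes[next_id] = na + nb
        Z[step] = (a, b, h, na + nb)
        next_id += 1
    return Dendrogram(leaf_ids=ids, Z=Z)


def cophenetic_correlation(dist, dendrogram: Dendrogram) -> tuple[float, bool]:
    """Pearson correlation between original and cophenetic distances.

    Returns ``(ccc, ccc > 0.8)``; the flag marks the conventional threshold
    for a dendrogram that represents its distance matrix well.
    """
    d, _ = _as_distance_matrix(dist)
    orig = squareform(d, checks=False)
    coph = dendrogram.cophenetic_distances()
    if np.std(orig) == 0 or np.std(coph) == 0:
        raise ValueError(
            "cophenetic correlation undefined: zero variance in distances"
        )
    ccc = float(np.corrcoef(orig, coph)[0, 1])
    return ccc, ccc > 0.8


def bootstrap_support(
    items: Sequence[Sequence],
    costs: SubstitutionCosts | None,
    B: int,
    seed: int,
    item_ids: Sequence[str] | None = None,
) -> Dendrogram:
    """UPGMA dendrogram with ordinary bootstrap support on internal nodes.

    Each replicate resamples items with replacement, recomputes the LSI
    distance matrix on the resampled multiset, reclusters, and scores each
    original internal node by the fraction of replicates containing a cluster
    whose leaf set equals the node's leaf set restricted to the sampled
    leaves.  Replicates whose sample misses a node's leaves entirely are
    uninformative for that node and are excluded from its denominator.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    sim = pairwise_lsi_matrix(items, costs, item_ids=item_ids)
    base = average_linkage(sim)
    node_sets = base.node_leafsets()
    n = base.n_leaves
    dist = sim.to_distances()

    rng = np.random.default_rng(seed)
    hits = np.zeros(n - 1)
    informative = np.zeros(n - 1)
    for _ in range(B):
        idx = np.sort(rng.integers(0, n, size=n))
        sampled = frozenset(int(i) for i in idx)
        # LSI on the resampled multiset == indexing the precomputed matrix
        sub = dist[np.ix_(idx, idx)]
        rep = average_linkage(sub)
        rep_sets = {
            frozenset(int(idx[i]) for i in s) for s in rep.node_leafsets()
        }
        rep_sets.update(frozenset([int(i)]) for i in idx)
        for k, s in enumerate(node_sets):
            restricted = s & sampled
            if not restricted:
                continue
            informative[k] += 1
            if restricted in rep_sets:
                hits[k] += 1
    support = np.where(informative > 0, hits / np.maximum(informative, 1), 0.0)
    return Dendrogram(leaf_ids=base.leaf_ids, Z=base.Z, support=support)


def cut_clusters(dendrogram: Dendrogram, threshold: float) -> ClusterAssignment:
    """Flat clusters: components whose cophenetic distance is <= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    flat = fcluster(dendrogram.Z, t=threshold, criterion="distance")
    labels = {lid: int(c) for lid, c in zip(dendrogram.leaf_ids, flat)}
    return ClusterAssignment(
        labels=labels, threshold=float(threshold),
        notes="connected components of merges at or below threshold",
    )


def verify_assignments(
    assignment: ClusterAssignment, reference: dict[str, object]
) -> AgreementReport:
    """Score an assignment against reference labels.

    Returns the contingency table, the adjusted Rand index and, per reference
    label, the purity (largest fraction of its items falling in one cluster).
    """
    if set(assignment.labels) != set(reference):
        raise ValueError("assignment and reference cover different item sets")
    items = sorted(assignment.labels)
    pred = [assignment.labels[i] for i in items]
    ref = [reference[i] for i in items]
    ari = float(adjusted_rand_score(ref, pred))
    table = pd.crosstab(
        pd.Series(ref, name="reference"), pd.Series(pred, name="cluster")
    )
    purity = {
        lab: float(row.max() / row.sum()) for lab, row in table.iterrows()
    }
    return AgreementReport(ari=ari, contingency=table, purity_by_reference=purity)
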