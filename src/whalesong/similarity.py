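"""Acoustic unit similarity and the Levenshtein-distance similarity index.

The LSI between two symbol sequences is ``1 - WLD(a, b) / max(|a|, |b|)``,
where WLD is an edit distance with unit insertion/deletion cost and a
substitution cost that may be *weighted* by acoustic similarity of the units:
features are z-scored across the dictionary, pairwise Euclidean distances are
normalised by their maximum, and the substitution cost is that normalised
distance raised to an exponent ``beta`` (``beta = 1`` for the weighted
analysis; ``costs=None`` gives the classic unweighted index used on theme
sequences).  Substituting acoustically similar units is therefore cheap, so
copy errors between similar units barely reduce phrase similarity.
"""

from __future__ import annotations

import warnings
from collections.abc import Hashable, Sequence
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .song_model import UnitDictionary

__all__ = [
    "SubstitutionCosts",
    "SimilarityMatrix",
    "unit_similarity_costs",
    "weighted_levenshtein",
    "lsi",
    "pairwise_lsi_matrix",
]


@dataclass(frozen=True)
class SubstitutionCosts:
    """Symmetric unit-substitution cost matrix in [0, 1], zero diagonal."""

    labels: tuple[str, ...]
    cost: np.ndarray
    beta: float = 1.0

    def __post_init__(self) -> None:
        c = np.asarray(self.cost, dtype=float)
        if c.shape != (len(self.labels), len(self.labels)):
            raise ValueError("cost matrix shape does not match labels")
        if not np.allclose(c, c.T):
            raise ValueError("cost matrix must be symmetric")
        if not np.allclose(np.diag(c), 0.0):
            raise ValueError("cost matrix diagonal must be zero")
        if c.min() < -1e-12 or c.max() > 1 + 1e-12:
            raise ValueError("cost entries must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        object.__setattr__(self, "cost", c)
        object.__setattr__(
            self, "_index", {l: i for i, l in enumerate(self.labels)}
        )

    def __call__(self, a: str, b: str) -> float:
        idx = self._index
        try:
            return float(self.cost[idx[a], idx[b]])
        except KeyError as e:
            raise KeyError(f"unit label {e.args[0]!r} not covered by costs") from e


@dataclass(frozen=True)
class SimilarityMatrix:
    """Full pairwise LSI matrix over phrases or theme sequences."""

    item_ids: tuple[str, ...]
    values: np.ndarray
    level: str  # "phrase_weighted" | "theme_sequence_unweighted"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.item_ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match item_ids")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity matrix diagonal must be 1")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("similarities must lie in [0, 1]")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))

    def to_distances(self) -> np.ndarray:
        """1 - LSI, the dissimilarity the clustering consumes."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d

    def to_tsv(self, path) -> None:
        """Lower triangle + diagonal, 6 decimals, ids as header row/column."""
        with open(path, "w") as fh:
            fh.write("item_id\t" + "\t".join(self.item_ids) + "\n")
            for i, iid in enumerate(self.item_ids):
                cells = [f"{self.values[i, j]:.6f}" for j in range(i + 1)]
                fh.write(iid + "\t" + "\t".join(cells) + "\n")


def unit_similarity_costs(
    dictionary: UnitDictionary, beta: float = 1.0
) -> SubstitutionCosts:
    """Substitution costs from acoustic feature similarity.

    Features are z-scored per feature across the dictionary; the pairwise
    Euclidean distance is divided by its maximum so the most dissimilar unit
    pair costs exactly 1; the result is raised to ``beta``.  Zero-variance
    features carry no information and are dropped with a warning.
    """
    X = dictionary.feature_matrix()
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all features have zero variance across the dictionary")
    if not keep.all():
        dropped = [n for n, k in zip(dictionary.feature_names, keep) if not k]
        warnings.warn(
            f"dropping zero-variance features {dropped}", stacklevel=2
        )
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    d = squareform(pdist(Z, metric="euclidean"))
    dmax = d.max()
    if dmax == 0:
        # all units acoustically identical: every substitution is free
        cost = np.zeros_like(d)
    else:
        cost = (d / dmax) ** beta if beta > 0 else (d > 0).astype(float)
    np.fill_diagonal(cost, 0.0)
    cost = (cost + cost.T) / 2.0
    return SubstitutionCosts(labels=dictionary.labels, cost=cost, beta=beta)


def weighted_levenshtein(
    a: Sequence[Hashable],
    b: Sequence[Hashable],
    costs: SubstitutionCosts | None = None,
) -> float:
    """Edit distance with indel cost 1 and weighted substitution cost.

    With ``costs=None`` every substitution between distinct symbols costs 1
    and the result is the classic Levenshtein distance.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return float(n + m)
    if costs is None:
        def sub(x, y):
            return 0.0 if x == y else 1.0
    else:
        sub = costs
    prev = [float(j) for j in range(m + 1)]
    cur = [0.0] * (m + 1)
    for i in range(1, n + 1):
        cur[0] = float(i)
        ai = a[i - 1]
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1.0,               # delete a[i-1]
                cur[j - 1] + 1.0,            # insert b[j-1]
                prev[j - 1] + sub(ai, b[j - 1]),
            )
        prev, cur = cur, prev
    return prev[m]


def lsi(
    a: Sequence[Hashable],
    b: Sequence[Hashable],
    costs: SubstitutionCosts | None = None,
) -> float:
    """Levenshtein-distance similarity index in [0, 1].

    ``1 - WLD(a, b) / max(|a|, |b|)``; 1 means identical, 0 means no
    structural similarity.  Normalisation by the longer sequence keeps the
    index comparable across sequence lengths.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("LSI is undefined for empty sequences")
    d = weighted_levenshtein(a, b, costs)
    return 1.0 - d / max(len(a), len(b))


def pairwise_lsi_matrix(
    items: Sequence[Sequence[Hashable]],
    costs: SubstitutionCosts | None = None,
    item_ids: Sequence[str] | None = None,
    level: str | None = None,
) -> SimilarityMatrix:
    """Full symmetric LSI matrix: each unordered pair computed once.

    Identical sequences share one distance computation (they are common in
    high-fidelity song corpora, where many phrases are exact copies).
    """
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 items for a pairwise matrix")
    if item_ids is None:
        item_ids = tuple(f"item{i}" for i in range(n))
    if len(item_ids) != n:
        raise ValueError("item_ids length does not match items")
    if level is None:
        level = "phrase_weighted" if costs is not None else "theme_sequence_unweighted"

    keys = [tuple(it) for it in items]
    values = np.eye(n)
    cache: dict[tuple[tuple, tuple], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            k = (keys[i], keys[j]) if keys[i] <= keys[j] else (keys[j], keys[i])
            if k not in cache:
                cache[k] = 1.0 if k[0] == k[1] else lsi(k[0], k[1], costs)
            values[i, j] = values[j, i] = cache[k]
    return SimilarityMatrix(item_ids=tuple(item_ids), values=values, level=level)
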