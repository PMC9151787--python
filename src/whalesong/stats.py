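"""Rank-sum comparisons and theme-occupancy tallies.

Population comparisons of complexity scores use the exact Mann–Whitney /
Wilcoxon rank-sum test: for the small samples here (six song types per
population) the exact null distribution of U is computed by partition
counting — the number of rank arrangements with ``U = k`` equals the number
of partitions of ``k`` into at most ``n1`` parts each at most ``n2`` — and
the two-sided p-value doubles the smaller tail (capped at 1).  With ties the
test falls back to the tie-corrected normal approximation with continuity
correction, and says so in the result's ``method`` field.

Occupancy tallies classify each theme of each song type as shared between
the two populations or unique to one, and measure how much singing time the
unique themes actually account for (their share of phrase repetitions).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .complexity import ComplexityTable
from .song_model import SongCorpus

__all__ = [
    "RankTestResult",
    "OccupancyTable",
    "exact_mann_whitney",
    "mann_whitney_null_counts",
    "compare_population_complexity",
    "theme_occupancy",
    "unique_theme_phrase_proportion",
]


@dataclass(frozen=True)
class RankTestResult:
    """Result of a two-sample rank-sum test.

    ``U`` is the Mann–Whitney statistic of the first sample (its rank sum
    minus ``n1 (n1 + 1) / 2``); with no ties it is an integer and ``method``
    is "exact", otherwise the tie-corrected normal approximation is used.
    """

    U: float
    n1: int
    n2: int
    p_two_sided: float
    method: str

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.U <= self.n1 * self.n2 + 1e-9):
            raise ValueError("U out of range [0, n1*n2]")
        if not (0 < self.p_two_sided <= 1):
            raise ValueError("p-value must lie in (0, 1]")


@lru_cache(maxsize=None)
def _null_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Counts of rank arrangements for each U in 0..n1*n2.

    c(u; n1, n2) = c(u - n2; n1 - 1, n2) + c(u; n1, n2 - 1): a partition of u
    into at most n1 parts each at most n2 either has a part equal to n2 or
    fits within n2 - 1.
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    a = _null_counts(n1 - 1, n2)
    b = _null_counts(n1, n2 - 1)
    out = [0] * (n1 * n2 + 1)
    for u, c in enumerate(a):
        out[u + n2] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def mann_whitney_null_counts(n1: int, n2: int) -> np.ndarray:
    """Exact null distribution of U as arrangement counts, index = U value.

    The counts sum to C(n1 + n2, n1) and are symmetric about n1*n2/2.
    """
    return np.array(_null_counts(n1, n2), dtype=float)


def exact_mann_whitney(x, y) -> RankTestResult:
    """Two-sided Mann–Whitney/Wilcoxon rank-sum test of two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    R1 = ranks[:n1].sum()
    U = R1 - n1 * (n1 + 1) / 2.0

    has_ties = len(np.unique(pooled)) < n1 + n2
    if not has_ties:
        counts = mann_whitney_null_counts(n1, n2)
        total = counts.sum()
        u = int(round(U))
        p_le = counts[: u + 1].sum() / total
        p_ge = counts[u:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return RankTestResult(U=float(u), n1=n1, n2=n2, p_two_sided=p,
                              method="exact")

    # tie-corrected normal approximation with continuity correction
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        # all values identical: no evidence either way
        return RankTestResult(U=float(U), n1=n1, n2=n2, p_two_sided=1.0,
                              method="normal_approx_tie_corrected")
    z = (abs(U - mu) - 0.5) / np.sqrt(sigma2)
    p = min(1.0, float(2.0 * norm.sf(max(z, 0.0))))
    p = max(p, np.finfo(float).tiny)
    return RankTestResult(U=float(U), n1=n1, n2=n2, p_two_sided=p,
                          method="normal_approx_tie_corrected")


def compare_population_complexity(
    table: ComplexityTable,
    level: str = "song_type",
    shared_only: bool = True,
) -> dict[str, RankTestResult]:
    """Rank-sum comparison of complexity scores between the two populations.

    ``level="song_type"``: one test of the per-song-type mean scores of one
    population against the other's (the 6-vs-6 comparison).  ``level=
    "theme_within_song_type"``: ``table`` must be a theme-level table for one
    song type; one test per song type, by default over themes shared by both
    populations.
    """
    df = table.table
    pops = sorted(df["population"].unique())
    if len(pops) != 2:
        raise ValueError(f"need exactly 2 populations, found {pops}")
    a, b = pops
    if level == "song_type":
        x = df[df["population"] == a].set_index("song_type")["pc1_score"]
        y = df[df["population"] == b].set_index("song_type")["pc1_score"]
        common = sorted(set(x.index) & set(y.index))
        return {"song_type": exact_mann_whitney(x[common], y[common])}
    if level == "theme_within_song_type":
        out: dict[str, RankTestResult] = {}
        for st, g in df.groupby("song_type", sort=True):
            piv = g.pivot(index="theme_id", columns="population",
                          values="pc1_score")
            if shared_only:
                piv = piv.dropna()
            xa = piv[a].dropna().to_numpy()
            xb = piv[b].dropna().to_numpy()
            if len(xa) == 0 or len(xb) == 0:
                raise ValueError(f"song type {st!r}: a population has no themes")
            out[str(st)] = exact_mann_whitney(xa, xb)
        return out
    raise ValueError(f"unknown level {level!r}")


@dataclass
class OccupancyTable:
    """Per (song type, theme) population presence and phrase-rep counts.

    ``table`` columns: song_type, theme_id, one presence flag and one
    phrase-repetition count per population, and ``unique`` (the asterisk of a
    published presence table: recorded in exactly one population).
    """

    table: pd.DataFrame
    populations: tuple[str, str]

    @property
    def counts(self) -> dict:
        uniq = self.table[self.table["unique"]]
        by_pop = {
            p: int((uniq[f"in_{p}"]).sum()) for p in self.populations
        }
        return {
            "total": int(len(self.table)),
            "shared": int((~self.table["unique"]).sum()),
            "unique": int(self.table["unique"].sum()),
            "unique_by_population": by_pop,
        }

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["marker"] = np.where(out["unique"], "*", "")
        out.to_csv(path, index=False)


def theme_occupancy(
    corpus: SongCorpus | None = None,
    presence: pd.DataFrame | None = None,
    populations: tuple[str, str] | None = None,
) -> OccupancyTable:
    """Tally which themes each population sings, per song type.

    Either derive presence from a (filtered) corpus — a theme counts as
    present in a population if it has at least one occurrence there — or
    accept an encoded presence table with columns ``song_type``,
    ``theme_id`` and one boolean ``in_<population>`` column per population.
    """
    if (corpus is None) == (presence is None):
        raise ValueError("provide exactly one of corpus or presence")
    if corpus is not None:
        pops = populations or tuple(
            sorted({c.population for c in corpus.cycles})
        )
        if len(pops) != 2:
            raise ValueError(f"need exactly 2 populations, found {pops}")
        recs: dict[tuple[str, int], dict[str, int]] = {}
        for c in corpus.cycles:
            for t in c.themes:
                key = (c.song_type, t.theme_id)
                d = recs.setdefault(key, {p: 0 for p in pops})
                d[c.population] += t.n_repetitions
        rows = [
            {
                "song_type": st,
                "theme_id": tid,
                **{f"in_{p}": d[p] > 0 for p in pops},
                **{f"reps_{p}": d[p] for p in pops},
            }
            for (st, tid), d in sorted(recs.items())
        ]
        df = pd.DataFrame(rows)
    else:
        df = presence.copy()
        pops = populations or tuple(
            sorted(c[3:] for c in df.columns if c.startswith("in_"))
        )
        if len(pops) != 2:
            raise ValueError(f"need exactly 2 populations, found {pops}")
        for p in pops:
            df[f"in_{p}"] = df[f"in_{p}"].astype(bool)
            if f"reps_{p}" not in df.columns:
                df[f"reps_{p}"] = df[f"in_{p}"].astype(int)
    present_cols = [f"in_{p}" for p in pops]
    if (~df[present_cols].any(axis=1)).any():
        raise ValueError("a theme with zero occurrences in either population")
    df["unique"] = df[present_cols].sum(axis=1) == 1
    return OccupancyTable(table=df.reset_index(drop=True), populations=pops)


def unique_theme_phrase_proportion(
    corpus: SongCorpus, occupancy: OccupancyTable
) -> pd.Series:
    """Percentage of phrase repetitions sung in single-population themes.

    For each song type: 100 x (phrase repetitions belonging to unique
    themes) / (all phrase repetitions in that song type, both populations).
    """
    uniq = {
        (r["song_type"], r["theme_id"])
        for _, r in occupancy.table.iterrows()
        if r["unique"]
    }
    totals: dict[str, int] = {}
    in_unique: dict[str, int] = {}
    for c in corpus.cycles:
        for t in c.themes:
            totals[c.song_type] = totals.get(c.song_type, 0) + t.n_repetitions
            if (c.song_type, t.theme_id) in uniq:
                in_unique[c.song_type] = (
                    in_unique.get(c.song_type, 0) + t.n_repetitions
                )
    if any(v == 0 for v in totals.values()):
        raise ValueError("a song type has zero phrase repetitions")
    return pd.Series(
        {
            st: 100.0 * in_unique.get(st, 0) / totals[st]
            for st in sorted(totals)
        },
        name="unique_theme_phrase_pct",
    )
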