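"""Shared fixtures: toy dictionaries, corpora, and independent oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from whalesong.song_model import (
    Phrase,
    SongCorpus,
    SongCycle,
    ThemeOccurrence,
    UnitDictionary,
    UnitType,
)


def alignment_oracle_wld(a, b, cost_fn) -> float:
    """Weighted edit distance by exhaustive enumeration of alignments.

    Every edit script corresponds to a monotone matching between positions
    of ``a`` and ``b``: matched pairs are substitutions (or free matches),
    unmatched symbols are indels.  Minimising total cost over all monotone
    matchings is an independent formulation of the DP recurrence.
    """
    n, m = len(a), len(b)
    best = float(n + m)
    for k in range(1, min(n, m) + 1):
        for ia in combinations(range(n), k):
            for ib in combinations(range(m), k):
                sub = sum(cost_fn(a[i], b[j]) for i, j in zip(ia, ib))
                best = min(best, sub + (n - k) + (m - k))
    return best


def pair_counting_ari(labels_a, labels_b) -> float:
    """Adjusted Rand index from explicit pair counting (oracle)."""
    n = len(labels_a)
    ss = sd = ds = dd = 0
    for i, j in combinations(range(n), 2):
        same_a = labels_a[i] == labels_a[j]
        same_b = labels_b[i] == labels_b[j]
        if same_a and same_b:
            ss += 1
        elif same_a:
            sd += 1
        elif same_b:
            ds += 1
        else:
            dd += 1
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    maximum = ((ss + sd) + (ss + ds)) / 2
    if maximum == expected:
        return 1.0
    return (ss - expected) / (maximum - expected)


def enumerate_u_distribution(n1: int, n2: int) -> np.ndarray:
    """Null counts of the rank-sum U statistic by full enumeration."""
    counts = np.zeros(n1 * n2 + 1)
    for ranks in combinations(range(1, n1 + n2 + 1), n1):
        u = sum(ranks) - n1 * (n1 + 1) // 2
        counts[u] += 1
    return counts


@pytest.fixture(scope="session")
def toy_dictionary() -> UnitDictionary:
    """Four units with simple, well-separated acoustic features."""
    return UnitDictionary(
        units=(
            UnitType("A", (0.5, 200.0, 10.0)),
            UnitType("B", (0.6, 300.0, 20.0)),
            UnitType("C", (1.5, 2000.0, 500.0)),
            UnitType("D", (2.0, 3500.0, 900.0)),
        ),
        feature_names=("duration_s", "peak_frequency_hz", "fm_extent_hz"),
    )


@pytest.fixture(scope="session")
def line_dictionary() -> UnitDictionary:
    """Three units whose single feature places them on a line at 0, 1, 2."""
    return UnitDictionary(
        units=(
            UnitType("U1", (0.0,)),
            UnitType("U2", (1.0,)),
            UnitType("U3", (2.0,)),
        ),
        feature_names=("x",),
    )


def _cycle(cid, pop, year, song_type, themes, singer=None) -> SongCycle:
    occs = tuple(
        ThemeOccurrence(
            tid, tuple(Phrase(tuple(p), duration_s=d) for p, d in phrases)
        )
        for tid, phrases in themes
    )
    dur = sum(p.duration_s for o in occs for p in o.phrases) + 2.0
    return SongCycle(
        cycle_id=cid,
        singer_id=singer or f"s_{cid}",
        population=pop,
        year=year,
        song_type=song_type,
        themes=occs,
        duration_s=dur,
    )


@pytest.fixture()
def toy_corpus(toy_dictionary) -> SongCorpus:
    """Three hand-built cycles over two populations, one song type."""
    cycles = (
        _cycle(
            "ea1", "EA", 2009, "Purple",
            [
                (1, [(("A", "B"), 3.0), (("A", "B"), 3.0)]),
                (2, [(("C", "D", "C"), 5.0), (("C", "D", "C"), 5.0)]),
            ],
        ),
        _cycle(
            "ea2", "EA", 2009, "Purple",
            [
                (1, [(("A", "B"), 3.0), (("A", "B"), 3.0), (("A", "B"), 3.0)]),
                (2, [(("C", "D", "C"), 5.0), (("C", "C", "C"), 5.0)]),
            ],
        ),
        _cycle(
            "nc1", "NC", 2010, "Purple",
            [
                (1, [(("A", "B"), 3.0), (("A", "B"), 3.0)]),
                (3, [(("D", "D"), 4.0), (("D", "D"), 4.0)]),
            ],
        ),
    )
    return SongCorpus(dictionary=toy_dictionary, cycles=cycles)


def make_cycle(cid, pop, year, song_type, themes, singer=None) -> SongCycle:
    """Public helper mirroring the fixture's cycle builder."""
    return _cycle(cid, pop, year, song_type, themes, singer)
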