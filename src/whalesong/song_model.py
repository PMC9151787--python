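"""Hierarchical song structure: units, phrases, themes, song cycles.

Humpback whale song is hierarchical: discrete sounds ("units") form ordered
sequences ("phrases"); a phrase repeated consecutively is a "theme"; themes
sung in a stereotyped order make one "song cycle".  These types carry that
hierarchy plus the metadata the downstream analyses need (singer, population,
year, song-type label), together with CSV readers/writers and the corpus
filtering rules (transitional-theme removal, minimum-singer flagging).

Time is in seconds everywhere.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "UnitType",
    "UnitDictionary",
    "Phrase",
    "ThemeOccurrence",
    "SongCycle",
    "SongCorpus",
    "FilterReport",
    "SongFormatError",
    "load_unit_dictionary",
    "write_unit_dictionary",
    "read_transcriptions",
    "write_transcriptions",
    "filter_corpus",
]

TRANSCRIPTION_COLUMNS = [
    "cycle_id",
    "singer_id",
    "population",
    "year",
    "song_type",
    "theme_id",
    "phrase_index",
    "unit_sequence",
    "phrase_duration_s",
    "cycle_duration_s",
]


class SongFormatError(ValueError):
    """Raised when a corpus or dictionary file violates the format contract."""


@dataclass(frozen=True)
class UnitType:
    """One entry of the acoustic dictionary.

    ``features`` holds real acoustic measurements; by convention the first
    three are duration (s), peak frequency (Hz) and frequency-modulation
    extent (Hz), but any finite feature set is accepted.
    """

    label: str
    features: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("unit label must be non-empty")
        feats = np.asarray(self.features, dtype=float)
        if not np.all(np.isfinite(feats)):
            raise ValueError(f"unit {self.label!r}: features must be finite")


@dataclass(frozen=True)
class UnitDictionary:
    """The alphabet of unit types and their shared acoustic feature space."""

    units: tuple[UnitType, ...]
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.units) < 2:
            raise ValueError("a unit dictionary needs at least 2 units")
        labels = [u.label for u in self.units]
        dupes = [l for l, c in Counter(labels).items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate unit labels: {sorted(dupes)}")
        k = len(self.feature_names)
        for u in self.units:
            if len(u.features) != k:
                raise ValueError(
                    f"unit {u.label!r} has {len(u.features)} features, "
                    f"expected {k}"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(u.label for u in self.units)

    def feature_matrix(self) -> np.ndarray:
        """Units x features array, in dictionary order."""
        return np.array([u.features for u in self.units], dtype=float)

    def __contains__(self, label: str) -> bool:
        return label in set(self.labels)

    def __len__(self) -> int:
        return len(self.units)


@dataclass(frozen=True)
class Phrase:
    """An ordered unit-label sequence with its duration in seconds."""

    units: tuple[str, ...]
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        if len(self.units) == 0:
            raise ValueError("a phrase must contain at least one unit")
        if self.duration_s < 0:
            raise ValueError("phrase duration must be >= 0")

    def __len__(self) -> int:
        return len(self.units)


@dataclass(frozen=True)
class ThemeOccurrence:
    """Consecutive repetitions of one theme's phrase within a song cycle."""

    theme_id: int
    phrases: tuple[Phrase, ...]

    def __post_init__(self) -> None:
        if len(self.phrases) == 0:
            raise ValueError("a theme occurrence needs at least one phrase")

    @property
    def n_repetitions(self) -> int:
        return len(self.phrases)


@dataclass(frozen=True)
class SongCycle:
    """One complete pass through the ordered themes by one singer."""

    cycle_id: str
    singer_id: str
    population: str
    year: int
    song_type: str
    themes: tuple[ThemeOccurrence, ...]
    duration_s: float

    def __post_init__(self) -> None:
        if len(self.themes) == 0:
            raise ValueError(f"cycle {self.cycle_id!r} has no themes")
        if self.duration_s <= 0:
            raise ValueError(f"cycle {self.cycle_id!r}: duration must be > 0")
        ids = [t.theme_id for t in self.themes]
        for a, b in zip(ids, ids[1:]):
            if a == b:
                raise ValueError(
                    f"cycle {self.cycle_id!r}: adjacent occurrences of theme "
                    f"{a} must be merged"
                )

    @property
    def theme_sequence(self) -> tuple[int, ...]:
        """Ordered theme ids, one symbol per occurrence."""
        return tuple(t.theme_id for t in self.themes)

    def all_phrases(self) -> list[Phrase]:
        return [p for t in self.themes for p in t.phrases]


@dataclass(frozen=True)
class SongCorpus:
    """A collection of song cycles over a fixed unit dictionary."""

    dictionary: UnitDictionary
    cycles: tuple[SongCycle, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        known = set(self.dictionary.labels)
        for c in self.cycles:
            for t in c.themes:
                for p in t.phrases:
                    unknown = set(p.units) - known
                    if unknown:
                        raise ValueError(
                            f"cycle {c.cycle_id!r}, theme {t.theme_id}: unit "
                            f"labels not in dictionary: {sorted(unknown)}"
                        )
        repeats = [
            c.cycle_id
            for c in self.cycles
            if len(set(c.theme_sequence)) < len(c.theme_sequence)
        ]
        if repeats:
            warnings.warn(
                "themes reappear non-consecutively within cycles "
                f"{repeats[:5]} (themes are normally sung in a consistent "
                "order without repetition)",
                stacklevel=2,
            )

    def strata(self) -> dict[tuple[str, int], list[SongCycle]]:
        """(population, year) -> cycles, in corpus order."""
        out: dict[tuple[str, int], list[SongCycle]] = {}
        for c in self.cycles:
            out.setdefault((c.population, c.year), []).append(c)
        return out

    def __len__(self) -> int:
        return len(self.cycles)


@dataclass
class FilterReport:
    """What :func:`filter_corpus` removed or flagged."""

    removed_occurrences: list[tuple[str, int, int]] = field(default_factory=list)
    dropped_cycles: list[str] = field(default_factory=list)
    low_singer_strata: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed_occurrences)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_unit_dictionary(path) -> UnitDictionary:
    """Read a unit dictionary CSV: a ``label`` column plus one numeric column
    per acoustic feature, header required."""
    df = pd.read_csv(path, dtype={"label": str})
    if "label" not in df.columns:
        raise SongFormatError(f"{path}: missing required 'label' column")
    feature_names = [c for c in df.columns if c != "label"]
    if not feature_names:
        raise SongFormatError(f"{path}: no feature columns")
    dupes = df["label"][df["label"].duplicated()].tolist()
    if dupes:
        raise SongFormatError(f"{path}: duplicate unit labels {sorted(set(dupes))}")
    feats = df[feature_names].apply(pd.to_numeric, errors="coerce")
    if feats.isna().any().any():
        bad = feats.columns[feats.isna().any()].tolist()
        raise SongFormatError(f"{path}: non-numeric feature values in {bad}")
    if len(df) < 2:
        raise SongFormatError(f"{path}: a dictionary needs at least 2 units")
    units = tuple(
        UnitType(label=row["label"], features=tuple(feats.iloc[i]))
        for i, (_, row) in enumerate(df.iterrows())
    )
    return UnitDictionary(units=units, feature_names=tuple(feature_names))


def write_unit_dictionary(dictionary: UnitDictionary, path) -> None:
    df = pd.DataFrame(
        dictionary.feature_matrix(), columns=list(dictionary.feature_names)
    )
    df.insert(0, "label", list(dictionary.labels))
    df.to_csv(path, index=False)


def read_transcriptions(path, dictionary: UnitDictionary) -> SongCorpus:
    """Read a transcription CSV (one row per phrase) into a corpus.

    Adjacent rows of the same theme within a cycle are grouped into one
    :class:`ThemeOccurrence`; ``phrase_index`` must be 0-based and contiguous
    within each occurrence.
    """
    df = pd.read_csv(path, dtype={"cycle_id": str, "singer_id": str,
                                  "population": str, "song_type": str})
    missing = [c for c in TRANSCRIPTION_COLUMNS if c not in df.columns]
    if missing:
        raise SongFormatError(f"{path}: missing columns {missing}")
    known = set(dictionary.labels)

    cycles: list[SongCycle] = []
    # groupby(sort=False) keeps file order for cycles
    for cycle_id, g in df.groupby("cycle_id", sort=False):
        if g.empty:
            raise SongFormatError(f"{path}: empty cycle {cycle_id!r}")
        meta = g.iloc[0]
        themes: list[ThemeOccurrence] = []
        cur_theme: int | None = None
        cur_phrases: list[Phrase] = []
        cur_indices: list[int] = []

        def flush():
            nonlocal cur_theme, cur_phrases, cur_indices
            if cur_theme is None:
                return
            if cur_indices != list(range(len(cur_indices))):
                raise SongFormatError(
                    f"{path}: cycle {cycle_id!r}, theme {cur_theme}: "
                    f"phrase indices {cur_indices} are not contiguous from 0"
                )
            themes.append(ThemeOccurrence(int(cur_theme), tuple(cur_phrases)))
            cur_theme, cur_phrases, cur_indices = None, [], []

        for rownum, row in g.iterrows():
            labels = tuple(str(row["unit_sequence"]).split())
            unknown = set(labels) - known
            if unknown:
                raise SongFormatError(
                    f"{path}: row {rownum}: unit labels {sorted(unknown)} "
                    "not in dictionary"
                )
            tid = int(row["theme_id"])
            if tid != cur_theme:
                flush()
                cur_theme = tid
            cur_phrases.append(
                Phrase(units=labels, duration_s=float(row["phrase_duration_s"]))
            )
            cur_indices.append(int(row["phrase_index"]))
        flush()
        cycles.append(
            SongCycle(
                cycle_id=str(cycle_id),
                singer_id=str(meta["singer_id"]),
                population=str(meta["population"]),
                year=int(meta["year"]),
                song_type=str(meta["song_type"]),
                themes=tuple(themes),
                duration_s=float(meta["cycle_duration_s"]),
            )
        )
    if not cycles:
        raise SongFormatError(f"{path}: no cycles found")
    return SongCorpus(dictionary=dictionary, cycles=tuple(cycles),
                      provenance=f"read from {path}")


def write_transcriptions(corpus: SongCorpus, path) -> None:
    """Write the canonical one-row-per-phrase transcription CSV."""
    rows = []
    for c in corpus.cycles:
        for t in c.themes:
            for i, p in enumerate(t.phrases):
                rows.append(
                    {
                        "cycle_id": c.cycle_id,
                        "singer_id": c.singer_id,
                        "population": c.population,
                        "year": c.year,
                        "song_type": c.song_type,
                        "theme_id": t.theme_id,
                        "phrase_index": i,
                        "unit_sequence": " ".join(p.units),
                        "phrase_duration_s": p.duration_s,
                        "cycle_duration_s": c.duration_s,
                    }
                )
    pd.DataFrame(rows, columns=TRANSCRIPTION_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_corpus(
    corpus: SongCorpus,
    min_phrase_reps: int = 2,
    min_singers_per_stratum: int = 6,
) -> tuple[SongCorpus, FilterReport]:
    """Apply the corpus inclusion rules.

    Theme occurrences with fewer than ``min_phrase_reps`` phrase repetitions
    are removed — these are "transitional" themes, too rare and unstereotyped
    to analyse.  Strata (population x year) recorded from fewer than
    ``min_singers_per_stratum`` singers are flagged in the report but kept;
    field datasets sometimes fall short in a year and are still informative.
    """
    report = FilterReport()
    kept_cycles: list[SongCycle] = []
    for c in corpus.cycles:
        kept: list[ThemeOccurrence] = []
        for t in c.themes:
            if t.n_repetitions >= min_phrase_reps:
                kept.append(t)
            else:
                report.removed_occurrences.append(
                    (c.cycle_id, t.theme_id, t.n_repetitions)
                )
        # removing an interior occurrence can leave equal neighbours: merge
        merged: list[ThemeOccurrence] = []
        for t in kept:
            if merged and merged[-1].theme_id == t.theme_id:
                merged[-1] = ThemeOccurrence(
                    t.theme_id, merged[-1].phrases + t.phrases
                )
            else:
                merged.append(t)
        if merged:
            kept_cycles.append(replace(c, themes=tuple(merged)))
        else:
            report.dropped_cycles.append(c.cycle_id)
    if not kept_cycles:
        raise ValueError("filtering removed every cycle from the corpus")
    filtered = SongCorpus(
        dictionary=corpus.dictionary,
        cycles=tuple(kept_cycles),
        provenance=corpus.provenance,
    )
    for (pop, year), cycles in filtered.strata().items():
        n_singers = len({c.singer_id for c in cycles})
        if n_singers < min_singers_per_stratum:
            report.low_singer_strata.append((pop, year, n_singers))
    return filtered, report
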