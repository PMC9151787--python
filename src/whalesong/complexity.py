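"""PCA-based composite complexity scores for songs and themes.

Song complexity is summarised by reducing a panel of positively correlated
structural variables to their first principal component (correlation-matrix
PCA, i.e. variables z-scored first).  Two panels are used:

* per song cycle (six variables): total units, unique unit types, cycle
  duration, number of themes, mean phrase duration, and the mean complexity
  of the themes present;
* per theme within a population (three variables): mean units per phrase,
  mean distinct units per phrase, mean phrase duration.

The PC1 score is oriented so that the loading on the unit-count variable is
positive — higher score means higher relative complexity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .song_model import SongCorpus, SongCycle

__all__ = [
    "CycleVariables",
    "ThemeVariables",
    "ComplexityTable",
    "cycle_variables",
    "pc1_scores",
    "theme_complexity",
    "song_type_complexity",
]

CYCLE_VARIABLE_NAMES = [
    "total_units",
    "unique_units",
    "song_duration_s",
    "n_themes",
    "mean_phrase_duration_s",
    "mean_theme_complexity",
]
THEME_VARIABLE_NAMES = [
    "mean_units_per_phrase",
    "mean_unique_units_per_phrase",
    "mean_phrase_duration_s",
]


@dataclass(frozen=True)
class CycleVariables:
    """The six song-cycle-level structural variables."""

    total_units: int
    unique_units: int
    song_duration_s: float
    n_themes: int
    mean_phrase_duration_s: float
    mean_theme_complexity: float

    def __post_init__(self) -> None:
        if self.unique_units > self.total_units:
            raise ValueError("unique_units cannot exceed total_units")
        if self.n_themes < 1:
            raise ValueError("a cycle must contain at least one theme")
        if self.song_duration_s <= 0 or self.mean_phrase_duration_s < 0:
            raise ValueError("durations must be positive")


@dataclass(frozen=True)
class ThemeVariables:
    """The three theme-level structural variables (phrase averages)."""

    mean_units_per_phrase: float
    mean_unique_units_per_phrase: float
    mean_phrase_duration_s: float

    def __post_init__(self) -> None:
        if self.mean_unique_units_per_phrase > self.mean_units_per_phrase + 1e-9:
            raise ValueError("unique units per phrase cannot exceed total")


@dataclass
class ComplexityTable:
    """Entities x variables with their PC1 complexity scores.

    ``table`` holds one row per entity: its identifying columns, the raw
    variables, and ``pc1_score``.  ``loadings`` and ``explained_variance``
    describe the fitted component; ``oriented_on`` names the variable whose
    positive loading fixes the score's sign.
    """

    table: pd.DataFrame
    loadings: pd.Series
    explained_variance: float
    oriented_on: str
    cycle_scores: pd.DataFrame | None = None

    def to_csv(self, path, sidecar_json=None) -> None:
        self.table.to_csv(path, index=False)
        if sidecar_json is not None:
            with open(sidecar_json, "w") as fh:
                json.dump(
                    {
                        "loadings": self.loadings.to_dict(),
                        "explained_variance": self.explained_variance,
                        "oriented_on": self.oriented_on,
                    },
                    fh,
                    indent=2,
                )


def _theme_variables_from_phrases(phrases) -> ThemeVariables:
    return ThemeVariables(
        mean_units_per_phrase=float(np.mean([len(p) for p in phrases])),
        mean_unique_units_per_phrase=float(
            np.mean([len(set(p.units)) for p in phrases])
        ),
        mean_phrase_duration_s=float(np.mean([p.duration_s for p in phrases])),
    )


def cycle_variables(
    cycle: SongCycle, theme_scores: dict[int, float] | None = None
) -> CycleVariables:
    """Compute the six structural variables for one song cycle.

    ``theme_scores`` maps theme_id to its theme-level PC1 score (for this
    cycle's population); when omitted, ``mean_theme_complexity`` is 0, which
    is only appropriate for intermediate tallies.
    """
    phrases = cycle.all_phrases()
    all_units = [u for p in phrases for u in p.units]
    if theme_scores is None:
        mtc = 0.0
    else:
        mtc = float(
            np.mean([theme_scores[t.theme_id] for t in cycle.themes])
        )
    return CycleVariables(
        total_units=len(all_units),
        unique_units=len(set(all_units)),
        song_duration_s=cycle.duration_s,
        n_themes=len(cycle.themes),
        mean_phrase_duration_s=float(np.mean([p.duration_s for p in phrases])),
        mean_theme_complexity=mtc,
    )


def pc1_scores(
    matrix: pd.DataFrame, orient_on: str | None = None
) -> tuple[np.ndarray, pd.Series, float]:
    """First-principal-component scores of a standardized variable matrix.

    Variables are z-scored (correlation-matrix PCA), so the result is
    invariant to each variable's raw units.  Zero-variance variables are
    dropped with a warning.  The component sign is flipped, if needed, so the
    loading on ``orient_on`` (default: the first retained column) is
    positive.  Returns ``(scores, loadings, explained_variance_ratio)``.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 entities")
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("variable matrix contains missing values")
    sd = X.std(axis=0)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-degenerate variables")
    if not keep.all():
        dropped = matrix.columns[~keep].tolist()
        warnings.warn(f"dropping zero-variance variables {dropped}", stacklevel=2)
    cols = matrix.columns[keep]
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=1)
    scores = pca.fit_transform(Z)[:, 0]
    loadings = pd.Series(pca.components_[0], index=cols)
    if orient_on is None or orient_on not in cols:
        orient_on = cols[0]
    if loadings[orient_on] < 0:
        scores = -scores
        loadings = -loadings
    return scores, loadings, float(pca.explained_variance_ratio_[0])


def _pc1_or_fallback(
    matrix: pd.DataFrame, orient_on: str
) -> tuple[np.ndarray, pd.Series, float]:
    """PC1 scores with graceful degenerate handling.

    When fewer than two variables vary the PCA is undefined: with exactly one
    varying variable its z-score is the natural one-dimensional composite;
    with none, every entity is identical and all scores are 0.
    """
    X = matrix.to_numpy(dtype=float)
    varying = (X.std(axis=0) > 0).sum()
    if varying >= 2:
        return pc1_scores(matrix, orient_on=orient_on)
    if varying == 1:
        col = matrix.columns[X.std(axis=0) > 0][0]
        warnings.warn(
            f"only {col!r} varies: complexity score is its z-score",
            stacklevel=2,
        )
        v = X[:, matrix.columns.get_loc(col)]
        scores = (v - v.mean()) / v.std()
        return scores, pd.Series({col: 1.0}), 1.0
    warnings.warn("all variables constant: complexity scores are 0", stacklevel=2)
    return np.zeros(len(matrix)), pd.Series(dtype=float), float("nan")


def theme_complexity(corpus: SongCorpus) -> dict[str, ComplexityTable]:
    """Theme-level complexity scores per (theme, population), by song type.

    For each song type, the three theme variables are averaged over every
    phrase of every occurrence of that theme in that population, and one PCA
    is fitted across all of the song type's (theme, population) rows so its
    theme scores share an axis.
    """
    rows: list[dict] = []
    for c in corpus.cycles:
        for t in c.themes:
            for p in t.phrases:
                rows.append(
                    {
                        "song_type": c.song_type,
                        "population": c.population,
                        "theme_id": t.theme_id,
                        "units": len(p),
                        "unique": len(set(p.units)),
                        "dur": p.duration_s,
                    }
                )
    df = pd.DataFrame(rows)
    out: dict[str, ComplexityTable] = {}
    for song_type, g in df.groupby("song_type", sort=True):
        agg = (
            g.groupby(["theme_id", "population"], sort=True)
            .agg(
                mean_units_per_phrase=("units", "mean"),
                mean_unique_units_per_phrase=("unique", "mean"),
                mean_phrase_duration_s=("dur", "mean"),
            )
            .reset_index()
        )
        # stabilise against summation-order noise: byte-identical inputs in
        # differently sized strata must yield identical variables
        agg[THEME_VARIABLE_NAMES] = agg[THEME_VARIABLE_NAMES].round(9)
        scores, loadings, ev = _pc1_or_fallback(
            agg[THEME_VARIABLE_NAMES], orient_on="mean_units_per_phrase"
        )
        agg.insert(0, "song_type", song_type)
        agg["pc1_score"] = np.round(scores, 9)
        out[song_type] = ComplexityTable(
            table=agg,
            loadings=loadings,
            explained_variance=ev,
            oriented_on="mean_units_per_phrase",
        )
    return out


def song_type_complexity(
    corpus: SongCorpus, pooled: bool = True
) -> ComplexityTable:
    """Song-type complexity per population from per-cycle PC1 scores.

    Cycle variables (including the mean theme-level complexity of the themes
    present, from :func:`theme_complexity`) are computed per cycle; a PCA is
    fitted either pooled over all cycles (default, so song types share one
    score axis) or per song type; the per-cycle PC1 scores are then averaged
    within (song type, population).
    """
    theme_tables = theme_complexity(corpus)
    # (song_type, population, theme_id) -> theme PC1 score
    tscore: dict[tuple[str, str], dict[int, float]] = {}
    for st, tab in theme_tables.items():
        for _, r in tab.table.iterrows():
            tscore.setdefault((st, r["population"]), {})[int(r["theme_id"])] = (
                float(r["pc1_score"])
            )

    recs = []
    for c in corpus.cycles:
        cv = cycle_variables(c, theme_scores=tscore[(c.song_type, c.population)])
        recs.append(
            {
                "cycle_id": c.cycle_id,
                "song_type": c.song_type,
                "population": c.population,
                **{name: getattr(cv, name) for name in CYCLE_VARIABLE_NAMES},
            }
        )
    cycles_df = pd.DataFrame(recs)
    cycles_df[CYCLE_VARIABLE_NAMES] = cycles_df[CYCLE_VARIABLE_NAMES].round(9)

    if pooled:
        scores, loadings, ev = _pc1_or_fallback(
            cycles_df[CYCLE_VARIABLE_NAMES], orient_on="total_units"
        )
        cycles_df["pc1_score"] = scores
    else:
        parts = []
        loadings, ev = None, float("nan")
        for _, g in cycles_df.groupby("song_type", sort=True):
            s, loadings, ev = _pc1_or_fallback(
                g[CYCLE_VARIABLE_NAMES], orient_on="total_units"
            )
            g = g.copy()
            g["pc1_score"] = s
            parts.append(g)
        cycles_df = pd.concat(parts, ignore_index=True)

    agg = (
        cycles_df.groupby(["song_type", "population"], sort=True)
        .agg(
            **{name: (name, "mean") for name in CYCLE_VARIABLE_NAMES},
            pc1_score=("pc1_score", "mean"),
            n_cycles=("cycle_id", "count"),
        )
        .reset_index()
    )
    num_cols = CYCLE_VARIABLE_NAMES + ["pc1_score"]
    agg[num_cols] = agg[num_cols].round(9)
    return ComplexityTable(
        table=agg,
        loadings=loadings,
        explained_variance=ev,
        oriented_on="total_units",
        cycle_scores=cycles_df,
    )
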