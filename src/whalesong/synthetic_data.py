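"""Synthetic two-population song-culture generator.

Emulates the statistical structure of a transcribed humpback-whale song
corpus shared between a source population (EA) and a receiving population
(NC) with a one-year transmission lag: each year the source sings the
current song type while the receiver sings the previous year's type.  Song
types follow one of two lineages — "revolution" types are drawn fresh, while
"evolution" types derive from the previous type by theme insertions and
deletions plus unit-level edits.  Cycles are rendered from the type's theme
templates with high-fidelity copy error: each unit is substituted with a
small probability, and the substitute is drawn preferentially among
acoustically *similar* units (probability proportional to
``exp(-bias * substitution_cost)``), the dominant copy-error mode observed
in real song.  Populations occasionally embellish the pattern with their own
unique themes, more often in evolution-lineage types.

Everything is a pure function of (config, seed): fixed seeds give
byte-identical corpora, and every generated fact (templates, lineages,
shared/unique status, mutation events, per-cycle labels) is logged in a
:class:`SyntheticTruth` so analyses can be scored against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .similarity import lsi, unit_similarity_costs
from .song_model import (
    Phrase,
    SongCorpus,
    SongCycle,
    ThemeOccurrence,
    UnitDictionary,
    UnitType,
    write_transcriptions,
    write_unit_dictionary,
)

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "make_unit_inventory",
    "simulate_song_culture",
    "render_fixture_suite",
    "preset",
    "PRESET_NAMES",
]

_DEFAULT_NAMES = ("Purple", "Light Purple", "Brown", "Light Brown", "Teal",
                  "Orange")
_DEFAULT_LINEAGES = ("revolution", "evolution", "revolution", "evolution",
                     "revolution", "revolution")


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    Ranges are inclusive ``(low, high)`` pairs.  Defaults emulate the field
    study's corpus shape: six song types (four revolutions, two evolutions),
    two populations, 10-36 cycles per population-year stratum, a one-year
    transmission lag, a low per-unit copy-error rate biased toward
    acoustically similar units, and rare population-unique themes
    concentrated in evolution-lineage types.
    """

    n_unit_types: int = 30
    feature_dims: int = 3
    n_unit_clusters: int = 6
    n_song_types: int = 6
    song_type_names: tuple[str, ...] = _DEFAULT_NAMES
    lineages: tuple[str, ...] = _DEFAULT_LINEAGES
    start_year: int = 2009
    populations: tuple[str, str] = ("EA", "NC")
    cycles_per_stratum: tuple[int, int] = (10, 36)
    total_cycle_budget: int | None = None
    phrase_reps_per_theme: tuple[int, int] = (2, 6)
    themes_per_song: tuple[int, int] = (4, 8)
    phrase_length: tuple[int, int] = (3, 10)
    complexity_gradient: bool = True
    unit_substitution_rate: float = 0.02
    similar_substitution_bias: float = 4.0
    theme_dropout_prob: float = 0.01
    unique_theme_injection_prob: float = 0.1
    unique_theme_candidates: int = 5
    evolution_unique_multiplier: float = 2.0
    unique_theme_presence_prob: float = 1.0
    theme_insert_delete_prob: float = 0.3
    template_mutation_rate: float = 0.05
    template_min_distance: float = 0.4
    transmission_lag_years: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "unit_substitution_rate",
            "theme_dropout_prob",
            "unique_theme_injection_prob",
            "unique_theme_presence_prob",
            "theme_insert_delete_prob",
            "template_mutation_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("cycles_per_stratum", "phrase_reps_per_theme",
                     "themes_per_song", "phrase_length"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name}: empty or invalid range ({lo}, {hi})")
        if self.n_unit_types < 2:
            raise ValueError("need at least 2 unit types")
        if len(self.lineages) != self.n_song_types:
            raise ValueError("lineages length must equal n_song_types")
        if len(self.song_type_names) != self.n_song_types:
            raise ValueError("song_type_names length must equal n_song_types")
        if self.similar_substitution_bias < 0:
            raise ValueError("similar_substitution_bias must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated corpus."""

    theme_templates: dict[int, tuple[str, ...]]
    theme_song_type: dict[int, str]
    theme_status: dict[str, dict[int, str]]  # song_type -> theme -> status
    designed_complexity: dict[str, float]
    mutation_events: list[dict] = field(default_factory=list)
    cycle_labels: dict[str, dict] = field(default_factory=dict)
    seed: int = 0

    def unique_theme_count(self, song_type: str | None = None) -> int:
        types = [song_type] if song_type else list(self.theme_status)
        return sum(
            1
            for st in types
            for status in self.theme_status[st].values()
            if status.startswith("unique")
        )

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "theme_templates": {
                str(k): list(v) for k, v in self.theme_templates.items()
            },
            "theme_song_type": {str(k): v for k, v in self.theme_song_type.items()},
            "theme_status": {
                st: {str(k): v for k, v in d.items()}
                for st, d in self.theme_status.items()
            },
            "designed_complexity": self.designed_complexity,
            "mutation_events": self.mutation_events,
            "cycle_labels": self.cycle_labels,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def make_unit_inventory(config: SimConfig, seed: int | None = None) -> UnitDictionary:
    """Draw a unit dictionary with clustered acoustic features.

    Units fall into ``n_unit_clusters`` acoustic clusters (so "similar" units
    exist for the biased copy-error model).  Features are duration (s), peak
    frequency (Hz) and frequency-modulation extent (Hz), padded with further
    generic features if ``feature_dims > 3``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    k = min(config.n_unit_clusters, config.n_unit_types)
    d = config.feature_dims
    # cluster centres spread across realistic acoustic ranges
    centers = np.column_stack(
        [
            rng.uniform(0.3, 2.5, size=k),        # duration s
            rng.uniform(100.0, 4000.0, size=k),   # peak frequency Hz
            rng.uniform(0.0, 1500.0, size=k),     # FM extent Hz
        ]
        + [rng.uniform(0.0, 1.0, size=k) for _ in range(d - 3)]
    )[:, :d]
    scale = np.maximum(np.abs(centers).max(axis=0) * 0.05, 1e-3)
    units = []
    for i in range(config.n_unit_types):
        c = centers[i % k]
        f = c + rng.normal(0.0, scale, size=d)
        f[0] = max(f[0], 0.05)              # duration > 0
        if d > 1:
            f[1] = max(f[1], 20.0)          # frequency >= 0
        if d > 2:
            f[2] = max(f[2], 0.0)
        units.append(UnitType(label=f"U{i + 1}", features=tuple(f)))
    names = ["duration_s", "peak_frequency_hz", "fm_extent_hz"][:d] + [
        f"feature_{j}" for j in range(4, d + 1)
    ]
    return UnitDictionary(units=tuple(units), feature_names=tuple(names[:d]))


def _stratum_counts(rng, n_strata: int, lo: int, hi: int,
                    total: int | None) -> list[int]:
    counts = list(rng.integers(lo, hi + 1, size=n_strata))
    if total is None:
        return [int(c) for c in counts]
    if not n_strata * lo <= total <= n_strata * hi:
        raise ValueError("total_cycle_budget infeasible for cycles_per_stratum")
    # nudge random strata until the budget is met, staying in range
    while sum(counts) != total:
        i = int(rng.integers(0, n_strata))
        if sum(counts) < total and counts[i] < hi:
            counts[i] += 1
        elif sum(counts) > total and counts[i] > lo:
            counts[i] -= 1
    return [int(c) for c in counts]


class _TemplateFactory:
    """Draws theme templates kept mutually distinguishable.

    True themes must be acoustically tellable-apart for recovery to be
    well-posed: every new template is resampled until its weighted LSI
    distance to every existing template is at least ``template_min_distance``.
    """

    def __init__(self, rng, labels, config: SimConfig, costs):
        self.rng = rng
        self.labels = list(labels)
        self.config = config
        self.costs = costs
        self.used: set[tuple[str, ...]] = set()
        self.next_theme_id = 1

    def _min_distance(self, seq: tuple[str, ...]) -> float:
        if not self.used:
            return float("inf")
        return min(1.0 - lsi(seq, other, self.costs) for other in self.used)

    def new_phrase(self, length: int, attempts: int = 200) -> tuple[str, ...]:
        # rejection-sample up to the separation target; short phrases in a
        # crowded template space may not reach it, in which case the most
        # separated distinct candidate is used
        best: tuple[str, ...] | None = None
        best_d = -1.0
        for _ in range(attempts):
            seq = tuple(
                self.labels[i]
                for i in self.rng.integers(0, len(self.labels), size=length)
            )
            if seq in self.used:
                continue
            d = self._min_distance(seq)
            if d >= self.config.template_min_distance:
                self.used.add(seq)
                return seq
            if d > best_d:
                best, best_d = seq, d
        if best is None or best_d <= 0:
            raise RuntimeError(
                "could not draw a distinct phrase template; raise "
                "n_unit_types or phrase_length"
            )
        self.used.add(best)
        return best

    def new_id(self) -> int:
        tid = self.next_theme_id
        self.next_theme_id += 1
        return tid

    def new_theme(self, length: int) -> tuple[int, tuple[str, ...]]:
        return self.new_id(), self.new_phrase(length)


def simulate_song_culture(
    config: SimConfig,
) -> tuple[SongCorpus, SyntheticTruth]:
    """Simulate the two-population corpus; see the module docstring."""
    rng = np.random.default_rng(config.seed)
    dictionary = make_unit_inventory(config, seed=int(rng.integers(2**31)))
    costs = unit_similarity_costs(dictionary, beta=1.0)
    labels = list(dictionary.labels)
    idx = {l: i for i, l in enumerate(labels)}
    # substitution kernel: row u -> probability of substitute v (v != u)
    kernel = np.exp(-config.similar_substitution_bias * costs.cost)
    np.fill_diagonal(kernel, 0.0)
    kernel = kernel / kernel.sum(axis=1, keepdims=True)

    factory = _TemplateFactory(rng, labels, config, costs)
    truth = SyntheticTruth(
        theme_templates={}, theme_song_type={}, theme_status={},
        designed_complexity={}, seed=config.seed,
    )

    lo_t, hi_t = config.themes_per_song
    lo_l, hi_l = config.phrase_length
    n_types = config.n_song_types

    def design_level(s: int) -> tuple[int, int]:
        """(n_themes, phrase length) for song type s under the gradient."""
        if not config.complexity_gradient or n_types == 1:
            return int(rng.integers(lo_t, hi_t + 1)), int(
                rng.integers(lo_l, hi_l + 1)
            )
        frac = s / (n_types - 1)
        return (
            int(round(lo_t + frac * (hi_t - lo_t))),
            int(round(lo_l + frac * (hi_l - lo_l))),
        )

    # --- build song-type templates (ordered theme lists) -------------------
    templates: dict[str, list[int]] = {}
    prev: list[int] | None = None
    for s, (name, lineage) in enumerate(
        zip(config.song_type_names, config.lineages)
    ):
        n_themes, plen = design_level(s)

        def theme_len() -> int:
            # per-theme jitter around the song type's design level
            return int(np.clip(plen + rng.integers(-1, 2), lo_l, hi_l))

        if lineage == "revolution" or prev is None:
            themes = []
            for _ in range(n_themes):
                tid, phrase = factory.new_theme(theme_len())
                truth.theme_templates[tid] = phrase
                themes.append(tid)
            truth.mutation_events.append(
                {"song_type": name, "event": "revolution", "themes": list(themes)}
            )
        else:
            themes = list(prev)
            if rng.random() < config.theme_insert_delete_prob and len(themes) > 2:
                gone = themes.pop(int(rng.integers(0, len(themes))))
                truth.mutation_events.append(
                    {"song_type": name, "event": "theme_deletion", "theme": gone}
                )
            if rng.random() < config.theme_insert_delete_prob or len(themes) < n_themes:
                target = max(n_themes, len(themes) + 1)
                while len(themes) < target:
                    tid, phrase = factory.new_theme(theme_len())
                    truth.theme_templates[tid] = phrase
                    themes.insert(int(rng.integers(0, len(themes) + 1)), tid)
                    truth.mutation_events.append(
                        {"song_type": name, "event": "theme_insertion",
                         "theme": tid}
                    )
            # unit-level template edits on inherited themes
            edited = []
            for tid in themes:
                phrase = list(truth.theme_templates[tid])
                changed = False
                for j, u in enumerate(phrase):
                    if rng.random() < config.template_mutation_rate:
                        phrase[j] = labels[
                            int(rng.choice(len(labels), p=kernel[idx[u]]))
                        ]
                        changed = True
                if changed:
                    tid2 = factory.new_id()
                    factory.used.add(tuple(phrase))
                    truth.theme_templates[tid2] = tuple(phrase)
                    truth.mutation_events.append(
                        {"song_type": name, "event": "theme_unit_edit",
                         "parent_theme": tid, "theme": tid2}
                    )
                    edited.append(tid2)
                else:
                    edited.append(tid)
            themes = edited
        templates[name] = themes
        for tid in themes:
            truth.theme_song_type[tid] = name
        truth.designed_complexity[name] = float(
            sum(len(truth.theme_templates[t]) for t in themes)
        )

    # --- population-unique theme injections --------------------------------
    # per (song type, population): Bernoulli draws over candidate slots,
    # at a higher rate for evolution-lineage types
    unique_themes: dict[tuple[str, str], list[int]] = {}
    for name, lineage in zip(config.song_type_names, config.lineages):
        p = config.unique_theme_injection_prob
        if lineage == "evolution":
            p = min(1.0, p * config.evolution_unique_multiplier)
        for pop in config.populations:
            injected = []
            for _ in range(config.unique_theme_candidates):
                if rng.random() < p:
                    _, plen_u = design_level(config.song_type_names.index(name))
                    tid, phrase = factory.new_theme(plen_u)
                    truth.theme_templates[tid] = phrase
                    truth.theme_song_type[tid] = name
                    injected.append(tid)
                    truth.mutation_events.append(
                        {"song_type": name, "event": "unique_theme_injection",
                         "population": pop, "theme": tid}
                    )
            unique_themes[(name, pop)] = injected

    for name in config.song_type_names:
        status: dict[int, str] = {t: "shared" for t in templates[name]}
        for pop in config.populations:
            for t in unique_themes[(name, pop)]:
                status[t] = f"unique_{pop}"
        truth.theme_status[name] = status

    # --- render cycles ------------------------------------------------------
    source, receiver = config.populations
    lag = config.transmission_lag_years
    strata: list[tuple[str, int, str]] = []  # (population, year, song_type)
    for s, name in enumerate(config.song_type_names):
        strata.append((source, config.start_year + s, name))
        strata.append((receiver, config.start_year + s + lag, name))
    counts = _stratum_counts(
        rng, len(strata), *config.cycles_per_stratum, config.total_cycle_budget
    )

    unit_duration = {
        u.label: float(u.features[0]) for u in dictionary.units
    }
    lo_r, hi_r = config.phrase_reps_per_theme

    def render_phrase(template: tuple[str, ...]) -> Phrase:
        out = []
        for u in template:
            if rng.random() < config.unit_substitution_rate:
                out.append(labels[int(rng.choice(len(labels), p=kernel[idx[u]]))])
            else:
                out.append(u)
        dur = sum(unit_duration[u] for u in out) + 0.3 * (len(out) - 1)
        return Phrase(units=tuple(out), duration_s=round(dur, 3))

    cycles: list[SongCycle] = []
    for (pop, year, name), n_cycles in zip(strata, counts):
        n_singers = int(rng.integers(min(6, n_cycles), min(12, n_cycles) + 1))
        # fixed within-stratum order: shared template with this population's
        # unique themes spliced in at stable positions
        order: list[tuple[int, bool]] = [(t, False) for t in templates[name]]
        for t in unique_themes[(name, pop)]:
            pos = int(rng.integers(0, len(order) + 1))
            order.insert(pos, (t, True))
        # each singer keeps a stereotyped rendition: whether they adopted the
        # population's unique themes is drawn once per singer (conformal
        # adoption: by default every singer sings them); shared-theme
        # omissions are rare per-cycle events — corpora of *complete* song
        # cycles show nearly uniform theme sequences within a stratum
        renditions: list[list[tuple[int, bool]]] = []
        for _ in range(n_singers):
            kept = [
                (tid, uniq)
                for tid, uniq in order
                if not uniq or rng.random() < config.unique_theme_presence_prob
            ]
            renditions.append(kept)
        for i in range(n_cycles):
            cid = f"{pop}{year}_c{i:03d}"
            occs: list[ThemeOccurrence] = []
            sung: list[int] = []
            rendition = renditions[i % n_singers]
            for tid, is_unique in rendition:
                if is_unique:
                    # unique embellishments are rarely sung: rendered at the
                    # minimum repetition count that survives filtering
                    reps = lo_r
                else:
                    if (
                        config.theme_dropout_prob > 0
                        and len(rendition) > 1
                        and rng.random() < config.theme_dropout_prob
                    ):
                        continue
                    reps = int(rng.integers(lo_r, hi_r + 1))
                phrases = tuple(
                    render_phrase(truth.theme_templates[tid])
                    for _ in range(reps)
                )
                occs.append(ThemeOccurrence(theme_id=tid, phrases=phrases))
                sung.append(tid)
            if not occs:  # every theme dropped: sing the first shared theme
                tid = templates[name][0]
                reps = int(rng.integers(lo_r, hi_r + 1))
                occs = [ThemeOccurrence(
                    tid, tuple(render_phrase(truth.theme_templates[tid])
                               for _ in range(reps)))]
                sung = [tid]
            dur = sum(p.duration_s for o in occs for p in o.phrases)
            dur += 2.0 * (len(occs) - 1) + 1.0
            cycles.append(
                SongCycle(
                    cycle_id=cid,
                    singer_id=f"{pop}{year}_s{i % n_singers:02d}",
                    population=pop,
                    year=year,
                    song_type=name,
                    themes=tuple(occs),
                    duration_s=round(dur, 3),
                )
            )
            truth.cycle_labels[cid] = {
                "song_type": name,
                "population": pop,
                "year": year,
                "themes": sung,
            }

    corpus = SongCorpus(
        dictionary=dictionary,
        cycles=tuple(cycles),
        provenance=f"synthetic corpus, seed={config.seed}",
    )
    return corpus, truth


# ---------------------------------------------------------------------------
# Presets and fixture rendering
# ---------------------------------------------------------------------------

PRESET_NAMES = ("clean", "noisy", "paper_scale")


def preset(name: str, seed: int = 0) -> SimConfig:
    """Named study conditions.

    * ``clean`` — no copy error, no dropout, no unique themes, fixed phrase
      repetitions: the receiving population renders cycles identical to the
      source's templates (noise-free recovery tests).
    * ``noisy`` — the default low-noise conditions at a small corpus size.
    * ``paper_scale`` — the full corpus shape: 6 song types, 2 populations,
      10-36 cycles per stratum with a 353-cycle total budget.
    """
    if name == "clean":
        return SimConfig(
            n_unit_types=16,
            n_song_types=4,
            song_type_names=_DEFAULT_NAMES[:4],
            lineages=_DEFAULT_LINEAGES[:4],
            cycles_per_stratum=(4, 6),
            phrase_reps_per_theme=(3, 3),
            themes_per_song=(3, 6),
            phrase_length=(3, 8),
            unit_substitution_rate=0.0,
            theme_dropout_prob=0.0,
            unique_theme_injection_prob=0.0,
            template_mutation_rate=0.0,
            theme_insert_delete_prob=0.3,
            seed=seed,
        )
    if name == "noisy":
        return SimConfig(
            n_song_types=4,
            song_type_names=_DEFAULT_NAMES[:4],
            lineages=_DEFAULT_LINEAGES[:4],
            cycles_per_stratum=(6, 10),
            seed=seed,
        )
    if name == "paper_scale":
        return SimConfig(total_cycle_budget=353, seed=seed)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def render_fixture_suite(
    out_dir, presets=PRESET_NAMES, seed: int = 0, force: bool = False
) -> dict[str, dict[str, Path]]:
    """Write transcription CSV + unit-dictionary CSV + truth JSON per preset."""
    out_dir = Path(out_dir)
    written: dict[str, dict[str, Path]] = {}
    for name in presets:
        target = out_dir / name
        if target.exists() and any(target.iterdir()) and not force:
            raise FileExistsError(
                f"{target} exists and is non-empty (use force=True)"
            )
        target.mkdir(parents=True, exist_ok=True)
        corpus, truth = simulate_song_culture(preset(name, seed=seed))
        paths = {
            "transcriptions": target / "transcriptions.csv",
            "units": target / "units.csv",
            "truth": target / "truth.json",
        }
        write_transcriptions(corpus, paths["transcriptions"])
        write_unit_dictionary(corpus.dictionary, paths["units"])
        truth.to_json(paths["truth"])
        written[name] = paths
    return written
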