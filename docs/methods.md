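# Methods

This note documents the models and procedures `whalesong` implements, the
parameters that matter, and the choices made where the design was genuinely
open.

## The data model

Humpback whale song is hierarchical: discrete sounds (**units**, the atomic
symbols) form ordered sequences (**phrases**); a phrase repeated
consecutively is a **theme**; themes sung in a stereotyped order form one
**song cycle**; the population-wide arrangement in a given period is a
**song type** (named by colour). A corpus is a set of transcribed song
cycles over a fixed unit dictionary — a table mapping each unit label to
acoustic measurements (by default duration in s, peak frequency in Hz,
frequency-modulation extent in Hz; the feature set is configurable because
transcription practice varies).

Transcriptions travel as a flat CSV, one row per phrase
(`cycle_id, singer_id, population, year, song_type, theme_id, phrase_index,
unit_sequence, phrase_duration_s, cycle_duration_s`). Adjacent rows with the
same theme are merged into one theme occurrence at parse time; a theme
reappearing non-consecutively is kept as a second occurrence but triggers a
warning, since themes are normally sung in a consistent order without
repetition. All times are in seconds; `phrase_index` is 0-based and
contiguous within an occurrence.

**Filtering.** Theme occurrences with fewer than 2 phrase repetitions are
removed: such "transitional" themes are too rare and unstereotyped to
analyse. Population-year strata recorded from fewer than 6 singers are
flagged in the filter report but retained — field datasets occasionally fall
short in a year and remain informative.

## Sequence similarity (LSI)

The Levenshtein-distance similarity index between sequences `a`, `b` is

    LSI(a, b) = 1 − WLD(a, b) / max(|a|, |b|)

where WLD is a dynamic-programming edit distance with insertion and deletion
cost 1 and substitution cost in [0, 1]. Weighted substitution costs come
from the unit dictionary: features are z-scored per feature across the
dictionary, pairwise Euclidean distances are divided by their maximum, and
the cost is that normalised distance raised to an exponent **β** (default
1). Identical units substitute for free; the most dissimilar pair costs 1;
β = 0 recovers the classic unweighted distance. Zero-variance features are
dropped with a warning.

Two levels are analysed:

* **phrase level, weighted (β = 1)** — unit-label sequences; used to verify
  theme identities. Phrase durations deliberately do not enter the distance
  (they enter the complexity scores instead): the weighting is by acoustic
  similarity of units, not timing.
* **theme-sequence level, unweighted** — the ordered theme ids of each
  cycle, one symbol per occurrence; used to verify song types. Working on
  theme sequences avoids the length skewing that unit-level comparisons of
  whole cycles suffer.

Normalisation by the *longer* sequence length is a fixed design choice: it
keeps LSI in [0, 1] and reduces to the unweighted index in the limit.
Alternatives (mean length, alignment length) are not offered.

## Clustering and its validation

Distances `1 − LSI` are clustered by **average linkage (UPGMA)**. The
implementation is in-package with a fixed tie-break (among equal-height
candidate merges, the lexicographically smallest cluster-id pair merges
first) so identical inputs give bit-identical merge tables; it is
cross-checked against `scipy.cluster.hierarchy.linkage(..., "average")` in
the tests. Merge heights are asserted non-decreasing on every build.

Three validations:

* **Cophenetic correlation coefficient (CCC)** — Pearson correlation between
  the original distances and the dendrogram's merge-height distances;
  CCC > 0.8 is reported as a good representation. A matrix with zero
  distance variance (every item identical) is trivially perfectly
  represented by its flat dendrogram; that degenerate case is reported as
  CCC = 1 with a flag rather than an error.
* **Bootstrap support** — B replicates resample items (sequences) with
  replacement, recompute the distance matrix on the resampled multiset,
  recluster, and score each original internal node by the fraction of
  replicates containing a cluster whose leaf set equals the node's leaf set
  restricted to the sampled leaves. Replicates that miss a node's leaves
  entirely are excluded from that node's denominator. Note this is an
  ordinary object bootstrap, not a multiscale/approximately-unbiased
  bootstrap: resampling feature columns is undefined for edit distances, so
  support values here play the same interpretive role but are not AU
  p-values.
* **Agreement with reference labels** — dendrograms are cut at a distance
  threshold (flat clusters = components of merges at or below the
  threshold) and compared with transcribed labels by contingency table,
  adjusted Rand index, and per-label purity.

Cut thresholds live in the pipeline configuration, not in code. The
defaults (0.35 for weighted phrase distances, 0.5 for theme-sequence
distances) were calibrated on synthetic corpora: phrases of one theme differ
only by a few cheap similar-unit substitutions, while distinct theme
templates are kept at weighted distance ≥ 0.4 by construction; cycles of one
song type share most of their theme sequence, while different song types
share none of it.

## Complexity scores

A composite complexity score is the first principal component of a panel of
positively correlated structural variables (correlation-matrix PCA:
variables z-scored, so scores are invariant to raw units), with the sign
oriented so that the loading on the unit-count variable is positive —
higher score = higher relative complexity. The explained-variance fraction
and loadings are reported alongside every score table.

* **Song-cycle panel (6 variables):** total units, distinct unit types,
  cycle duration (s), number of themes, mean phrase duration (s), and mean
  theme-level complexity of the themes present.
* **Theme panel (3 variables), per theme × population:** mean units per
  phrase, mean distinct units per phrase, mean phrase duration (s),
  averaged over every phrase of every occurrence. The exact theme-level
  panel is not fully standardised in the literature; these three are the
  theme-level analogues of the song-level triple and are fixed here as a
  documented choice.

One PCA is fitted per song type across its (theme, population) rows — the
theme scores that feed both the theme-level population comparison and the
`mean_theme_complexity` cycle variable. For song-type scores, one PCA is
fitted *pooled* over all cycles of all song types (configurable to
per-song-type), and per-cycle scores are averaged within song type ×
population; pooling makes scores comparable across song types on one axis.

Numerical choices: aggregated variables and scores are rounded to 9
decimals before and after the PCA so that byte-identical inputs appearing
in differently sized strata yield identical scores (floating-point
summation order would otherwise leave ~1e-16 dust that breaks exact ties in
the rank tests). If fewer than two variables vary, the PCA is undefined:
with exactly one varying variable its z-score is used as the composite
(with a warning); with none, all scores are 0.

## Rank-sum comparisons

Population comparisons use the two-sided Mann–Whitney/Wilcoxon rank-sum
test. With no ties the null distribution of U is computed exactly by
partition counting — the number of rank arrangements with U = k equals the
number of partitions of k into at most n₁ parts each at most n₂ — and the
p-value doubles the smaller tail, capped at 1. With ties the test falls
back to the tie-corrected normal approximation with continuity correction
and records the method in the result. The implementation is cross-checked
against full enumeration of all rank assignments for every n₁, n₂ ≤ 7 and
against `scipy.stats.mannwhitneyu`.

Two comparisons are wired into the pipeline: one test of the per-song-type
mean scores (one population's vector against the other's), and one test per
song type over theme-level scores, by default restricted to themes present
in both populations (a configuration switch admits all themes).

## Theme occupancy

A theme counts as present in a population if it has at least one filtered
(≥ 2 repetition) occurrence there. Themes present in exactly one population
are "unique"; the occupancy table mirrors the usual published layout (song
type, theme id, per-population presence, asterisk marker) and the
per-song-type percentage of phrase repetitions falling in unique themes
measures how much singing time embellishments actually occupy.

The package also ships a *synthetic reconstruction* of a published
two-population presence table (`synthetic_reference.py`): the row-level
layout is constructed, but it satisfies every published aggregate (40
themes over six song types, 29 shared, 11 single-population, unique themes
concentrated in the two evolution-lineage types and in the receiving
population).

## The synthetic song-culture generator

The generator emulates the statistical structure of a two-population field
corpus; it is a pure function of (config, seed) and logs complete ground
truth (templates, lineages, shared/unique status, mutation events,
per-cycle labels).

Mechanisms and defaults, with rationale:

* **Transmission lag** (1 year): the source population sings the current
  song type; the receiver sings the previous year's type.
* **Lineages**: "revolution" types draw a fresh template; "evolution" types
  derive from the previous type by theme insertion/deletion (probability
  0.3 each) and unit-level template edits (rate 0.05 per unit, producing a
  new theme id linked to its parent in the mutation log).
* **Copy error** (rate 0.02 per unit): a substituted unit is drawn with
  probability ∝ exp(−bias · cost), bias 4, so errors fall overwhelmingly on
  acoustically similar units — the dominant error mode in real song, and
  the reason weighted and unweighted LSI behave differently.
* **Theme templates** are kept mutually distinguishable (weighted LSI
  distance ≥ 0.4, by rejection sampling with a best-candidate fallback for
  short phrases): true themes must be tellable-apart for recovery to be
  well-posed.
* **Corpus shape**: 6 song types (4 revolutions, 2 evolutions), 2
  populations, 10–36 cycles per population-year stratum (the paper-scale
  preset pins the total at 353 cycles), 2–6 phrase repetitions per theme,
  4–8 themes per song, phrase lengths 3–10 with ±1 per-theme jitter, 30
  unit types in 6 acoustic clusters.
* **Complexity gradient**: theme counts and phrase lengths increase
  linearly across song types, giving a designed complexity ordering
  (recorded per type as total template units) for recovery testing.
* **Unique themes**: per song type and population, 5 candidate slots each
  injected with probability 0.1 (doubled for evolution-lineage types,
  mirroring where embellishment is observed). Adoption is conformal —
  by default every singer of the population sings an injected theme — and
  unique themes are rendered at the minimum repetition count (they are
  rarely sung, a small share of phrase repetitions).
* **Within-stratum variation**: phrase-repetition counts jitter uniformly
  per occurrence; a shared theme is omitted from a cycle with probability
  0.01. The omission rate is deliberately low: transcribed corpora of this
  kind consist of *complete* song cycles, so theme sequences within a
  stratum are nearly uniform, and within-song-type distance structure is
  dominated by the population split rather than by unstructured noise.

What the generator does **not** emulate: acoustic waveforms, within-season
song drift, population-size-dependent novelty, singer-specific stylistic
biases, or recording noise/quality effects. Passing recovery tests on this
generator therefore shows the analysis chain is correct under its
statistical assumptions, not that those assumptions exhaust real field
data.

Presets: `clean` (no copy error, no omissions, no injections, fixed
repetition counts — the receiver is an exact copy of the source;
recovery must be perfect), `noisy` (default rates at a small corpus size),
`paper_scale` (the full 353-cycle shape).

## Pipeline and determinism

`run_pipeline` chains filter → phrase-LSI theme verification →
theme-sequence LSI song-type verification (with per-song-type bootstrap
dendrograms, Newick export, CCC) → complexity tables → rank tests →
occupancy, writing stage artifacts and a machine-readable summary. All
randomness flows from the configured seed; reruns with the same
configuration and seed produce byte-identical summaries (the configuration
hash embedded in the summary excludes output paths). Logging goes to
stderr; results never do.

Problem sizes: the shipped analyses run on corpora up to the 353-cycle
paper scale, where the full pipeline (bootstrap B = 100) completes in well
under a minute on one core; phrase-level verification clusters the distinct
phrase forms per song type rather than every phrase token, which is
equivalent for recovery and far smaller.

## Known limitations

* The exact rank-sum path requires tie-free samples; heavy ties push all
  comparisons to the normal approximation, which is conservative at n ≤ 6.
* Bootstrap support values are ordinary bootstrap proportions, known to be
  conservative for well-separated clusters; they are not AU p-values.
* Edit distances are additive, never exactly ultrametric, so CCC < 1
  whenever within-group variation exists; the 0.8/0.9 reading thresholds
  are conventions, not tests.
* The theme-level PCA panel is a fixed three-variable choice; other panels
  from the literature would shift absolute scores (though rarely
  orderings).
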