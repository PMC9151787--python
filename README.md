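# whalesong

Quantitative analysis of song transmission between whale populations:
weighted Levenshtein similarity over hierarchical vocal sequences,
average-linkage cluster verification with bootstrap support and cophenetic
correlation, PCA composite complexity scores, exact rank-sum population
comparisons, and a synthetic two-population song-culture generator with
full ground truth.

## Who this is for

Bioacousticians and cultural-evolution researchers working with transcribed
humpback-whale song (or any hierarchically structured vocal sequence data:
units → phrases → themes → song cycles) who need to ask: *when a song
pattern moves from one population to another, how accurately is it copied,
and is its complexity preserved?*

## The methods at its core

**Similarity.** The Levenshtein-distance similarity index between two
sequences is `LSI(a, b) = 1 − WLD(a, b) / max(|a|, |b|)`, where WLD is an
edit distance with unit indel cost and substitution cost
`(normalised acoustic distance)^β` between unit types (β = 1 for the
weighted phrase-level analysis; unweighted for theme sequences). Acoustic
distances come from a unit dictionary: z-scored feature vectors, pairwise
Euclidean distance, normalised by the maximum pair.

**Verification.** Pairwise LSI matrices are clustered by average linkage
(UPGMA, deterministic tie-breaking). Dendrograms are validated by the
cophenetic correlation coefficient (CCC > 0.8 read as a good
representation), bootstrap support over resampled items, and the adjusted
Rand index of a dendrogram cut against transcribed theme / song-type
labels.

**Complexity.** A song's complexity score is the first principal component
of six standardized structural variables (total units, distinct unit
types, cycle duration, number of themes, mean phrase duration, mean
theme-level complexity), oriented so more/longer/more-varied ⇒ higher
score. Theme-level scores use the three phrase-level analogues.

**Comparison.** Populations are compared with the exact two-sided
Mann–Whitney/Wilcoxon rank-sum test (partition-counting null, tie-corrected
normal fallback), plus theme-occupancy tallies: which themes are shared
between populations, which are unique to one, and what share of phrase
repetitions the unique themes occupy.

See `docs/methods.md` for the full account.

## Worked example

Simulate a small two-population corpus (four song types, one-year
transmission lag, low copy error) and run the full analysis:

```python
from whalesong.pipeline import PipelineConfig, run_pipeline

rep = run_pipeline(PipelineConfig(preset="noisy", seed=0,
                                  bootstrap_replicates=100))
s = rep.summary
print({k: round(v, 3) for k, v in s["ccc_by_song_type"].items()})
print(s["song_type_verification_ari"])
print(s["theme_occupancy"])
print(s["tests"]["song_type"])
```

which prints:

```
{'Brown': 0.997, 'Light Brown': 0.952, 'Light Purple': 1.0, 'Purple': 1.0}
1.0
{'total': 30, 'shared': 24, 'unique': 6, 'unique_by_population': {'EA': 3, 'NC': 3}}
{'U': 9.0, 'n1': 4, 'n2': 4, 'p': 0.885714, 'method': 'exact'}
```

Reading the output: every song type's theme-sequence dendrogram represents
its LSI matrix well (all CCC ≥ 0.95); cutting the pooled dendrogram
recovers the four song types exactly (ARI = 1); of 30 themes, 24 are sung
by both populations and 6 by only one; and the rank-sum test finds no
complexity difference between the source and receiving populations
(U = 9, n = 4 vs 4, p = 0.886) — the song patterns crossed between
populations with their relative complexity intact.

The same stages are available from a shell via the `whalesong` CLI
(`simulate`, `verify-themes`, `verify-songs`, `complexity`, `compare`,
`occupancy`, `report`); `report --config config.yaml` runs everything and
emits a machine-readable summary JSON plus similarity TSVs, Newick trees
with bootstrap supports, and CSV score tables.

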