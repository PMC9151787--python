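"""Exact rank-sum test against enumeration, and theme occupancy tallies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from conftest import enumerate_u_distribution, make_cycle
from whalesong.complexity import ComplexityTable, song_type_complexity
from whalesong.song_model import SongCorpus
from whalesong.stats import (
    compare_population_complexity,
    exact_mann_whitney,
    mann_whitney_null_counts,
    theme_occupancy,
    unique_theme_phrase_proportion,
)
from whalesong.synthetic_reference import synthetic_theme_presence


class TestNullDistribution:
    @pytest.mark.parametrize("n1", range(1, 8))
    @pytest.mark.parametrize("n2", range(1, 8))
    def test_partition_counts_match_full_enumeration(self, n1, n2):
        got = mann_whitney_null_counts(n1, n2)
        assert np.array_equal(got, enumerate_u_distribution(n1, n2))

    def test_counts_sum_to_binomial_and_are_symmetric(self):
        from math import comb

        for n1, n2 in [(3, 4), (6, 6), (5, 2)]:
            c = mann_whitney_null_counts(n1, n2)
            assert c.sum() == comb(n1 + n2, n1)
            assert np.array_equal(c, c[::-1])


class TestExactMannWhitney:
    def test_u28_six_vs_six_p_0132(self):
        # sample ranks {4,6,8,9,10,12}: rank sum 49, U = 49 - 21 = 28
        x = [1.0, 2.0, 3.0, 5.0, 7.0, 11.0]
        y = [4.0, 6.0, 8.0, 9.0, 10.0, 12.0]
        res = exact_mann_whitney(y, x)
        assert res.U == 28
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(0.132, abs=5e-4)

    def test_complete_separation_six_vs_six(self):
        res = exact_mann_whitney(range(7, 13), range(1, 7))
        assert res.U == 36
        assert res.p_two_sided == pytest.approx(2 / 924)

    def test_balanced_u_gives_p_one(self):
        # symmetric distribution about n1*n2/2 = 18
        x = [1.0, 4.0, 5.0, 8.0, 9.0, 12.0]
        y = [2.0, 3.0, 6.0, 7.0, 10.0, 11.0]
        res = exact_mann_whitney(x, y)
        assert res.U == 18
        assert res.p_two_sided == 1.0

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 6), (5, 5), (7, 2)])
    def test_matches_scipy_exact_on_random_tie_free_samples(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(20):
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = pooled[:n1], pooled[n1:]
            ours = exact_mann_whitney(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.U == ref.statistic
            assert ours.p_two_sided == pytest.approx(ref.pvalue)

    def test_ties_fall_back_to_normal_approximation(self):
        res = exact_mann_whitney([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
        assert res.method == "normal_approx_tie_corrected"
        ref = mannwhitneyu([1.0, 2.0, 2.0], [2.0, 3.0, 4.0],
                           alternative="two-sided", method="asymptotic",
                           use_continuity=True)
        assert res.p_two_sided == pytest.approx(ref.pvalue)

    def test_identical_samples_p_one(self):
        res = exact_mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_two_sided == 1.0

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            exact_mann_whitney([], [1.0])


class TestComparePopulations:
    def _table(self, ea, nc):
        rows = []
        for i, (a, b) in enumerate(zip(ea, nc)):
            rows.append({"song_type": f"t{i}", "population": "EA",
                         "pc1_score": a})
            rows.append({"song_type": f"t{i}", "population": "NC",
                         "pc1_score": b})
        return ComplexityTable(
            table=pd.DataFrame(rows), loadings=pd.Series(dtype=float),
            explained_variance=1.0, oriented_on="pc1_score",
        )

    def test_identical_vectors_give_p_one(self):
        scores = [0.1, 0.5, -0.3, 1.2, 0.9, -1.1]
        res = compare_population_complexity(self._table(scores, scores))
        assert res["song_type"].p_two_sided == 1.0

    def test_engineered_u28_reproduces_p_0132(self):
        ea = [4.0, 6.0, 8.0, 9.0, 10.0, 12.0]
        nc = [1.0, 2.0, 3.0, 5.0, 7.0, 11.0]
        res = compare_population_complexity(self._table(ea, nc))["song_type"]
        assert res.U == 28
        assert res.p_two_sided == pytest.approx(0.132, abs=5e-4)

    def test_missing_population_errors(self):
        tab = self._table([1.0], [2.0])
        tab.table = tab.table[tab.table["population"] == "EA"]
        with pytest.raises(ValueError, match="2 populations"):
            compare_population_complexity(tab)


def _occupancy_corpus(toy_dictionary):
    cycles = (
        make_cycle("e1", "EA", 2009, "Purple",
                   [(1, [(("A", "B"), 2.0)] * 3), (2, [(("C", "D"), 2.0)] * 2)]),
        make_cycle("n1", "NC", 2010, "Purple",
                   [(1, [(("A", "B"), 2.0)] * 5)]),
    )
    return SongCorpus(dictionary=toy_dictionary, cycles=cycles)


class TestThemeOccupancy:
    def test_toy_counts_from_corpus(self, toy_dictionary):
        occ = theme_occupancy(corpus=_occupancy_corpus(toy_dictionary))
        assert occ.counts == {
            "total": 2, "shared": 1, "unique": 1,
            "unique_by_population": {"EA": 1, "NC": 0},
        }

    def test_identical_populations_have_no_unique_themes(self, toy_dictionary):
        themes = [(1, [(("A", "B"), 2.0)] * 2), (2, [(("C",), 1.0)] * 2)]
        cycles = (
            make_cycle("e1", "EA", 2009, "P", themes),
            make_cycle("n1", "NC", 2010, "P", themes),
        )
        corpus = SongCorpus(dictionary=toy_dictionary, cycles=cycles)
        occ = theme_occupancy(corpus=corpus)
        assert occ.counts["unique"] == 0

    def test_published_presence_encoding_tallies(self):
        occ = theme_occupancy(presence=synthetic_theme_presence())
        counts = occ.counts
        assert counts["total"] == 40
        assert counts["shared"] == 29
        assert counts["unique"] == 11
        # single-population themes skew toward NC and evolution song types
        assert counts["unique_by_population"]["NC"] > \
            counts["unique_by_population"]["EA"]
        tab = occ.table
        evo = tab[tab["song_type"].isin(["Light Purple", "Light Brown"])]
        assert evo["unique"].sum() > tab[~tab.index.isin(evo.index)]["unique"].sum()

    def test_shared_plus_unique_equals_total(self):
        occ = theme_occupancy(presence=synthetic_theme_presence())
        c = occ.counts
        assert c["shared"] + sum(c["unique_by_population"].values()) == c["total"]

    def test_csv_export_marks_unique_with_asterisk(self, tmp_path):
        occ = theme_occupancy(presence=synthetic_theme_presence())
        p = tmp_path / "occ.csv"
        occ.to_csv(p)
        df = pd.read_csv(p)
        assert (df["marker"].fillna("") == "*").sum() == 11


class TestUniquePhraseProportion:
    def test_direct_ratio(self, toy_dictionary):
        corpus = _occupancy_corpus(toy_dictionary)
        occ = theme_occupancy(corpus=corpus)
        pct = unique_theme_phrase_proportion(corpus, occ)
        # theme 2 is EA-only with 2 reps out of 10 total
        assert pct["Purple"] == pytest.approx(20.0)

    def test_no_unique_themes_gives_zero(self, toy_dictionary):
        themes = [(1, [(("A",), 1.0)] * 2)]
        cycles = (
            make_cycle("e1", "EA", 2009, "P", themes),
            make_cycle("n1", "NC", 2010, "P", themes),
        )
        corpus = SongCorpus(dictionary=toy_dictionary, cycles=cycles)
        occ = theme_occupancy(corpus=corpus)
        assert unique_theme_phrase_proportion(corpus, occ)["P"] == 0.0
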