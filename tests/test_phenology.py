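"""Seasonal statistics: monthly aggregation, Steel-Dwass, letters, Kendall W,
relative-richness profiles."""

import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from mycophen.io import DetectionMatrix
from mycophen.phenology import (MonthlySamples, PairwiseComparisonSet,
                                _insert_absorb, compact_letters, kendall_w,
                                monthly_rank_matrix, monthly_samples,
                                relative_richness, steel_dwass)


def _matrix_from_counts(counts_by_date, group="ECM"):
    dates = sorted(counts_by_date)
    D = np.array([[counts_by_date[d]] for d in dates])
    return DetectionMatrix(D=D, N=np.array([max(counts_by_date.values())]),
                           groups=[group], dates=dates,
                           survey_ids=list(range(1, len(dates) + 1)))


def _samples(group="g", **by_month):
    data = {int(m): np.asarray(v, dtype=float) for m, v in by_month.items()}
    return MonthlySamples(group=group, samples=data)


def _comp(months, sig_pairs, group="g", alpha=0.05):
    rows = [{"month_a": a, "month_b": b, "n_a": 2, "n_b": 2, "rank_sum": 0.0,
             "t": 0.0, "p": 0.0 if frozenset((a, b)) in sig_pairs else 1.0,
             "significant": frozenset((a, b)) in sig_pairs}
            for a, b in itertools.combinations(months, 2)]
    return PairwiseComparisonSet(group=group, months=list(months),
                                 table=pd.DataFrame(rows), alpha=alpha,
                                 method="asymptotic")


class TestMonthlySamples:
    def test_complete_two_year_census_gives_two_per_month(self):
        counts = {dt.date(1990 + y, m, 15): 10 * y + m
                  for y in range(2) for m in range(1, 13)}
        ms = monthly_samples(_matrix_from_counts(counts), "ECM")
        assert all(len(ms.samples[m]) == 2 for m in range(1, 13))

    def test_missing_survey_passes_through(self):
        counts = {dt.date(1990 + y, m, 15): m
                  for y in range(2) for m in range(1, 13)
                  if not (y == 1 and m == 7)}
        ms = monthly_samples(_matrix_from_counts(counts), "ECM")
        assert len(ms.samples[7]) == 1
        assert len(ms.samples[6]) == 2

    def test_counts_are_conserved(self):
        rng = np.random.default_rng(2)
        counts = {dt.date(1990 + y, m, 15): int(rng.integers(0, 30))
                  for y in range(3) for m in range(1, 13)}
        mat = _matrix_from_counts(counts)
        ms = monthly_samples(mat, "ECM")
        assert sum(v.sum() for v in ms.samples.values()) == mat.D[:, 0].sum()

    def test_unknown_group_rejected(self):
        mat = _matrix_from_counts({dt.date(1990, 1, 15): 3})
        with pytest.raises(KeyError):
            monthly_samples(mat, "nope")


class TestSteelDwass:
    def test_identical_samples_not_significant(self):
        ms = _samples(**{"1": [1, 2, 3, 4], "2": [1, 2, 3, 4]})
        res = steel_dwass(ms)
        row = res.table.iloc[0]
        assert row["t"] == 0.0 and row["p"] == 1.0
        assert not row["significant"]

    def test_fully_separated_samples_closed_form(self):
        ms = _samples(**{"1": np.arange(1, 11), "2": np.arange(101, 111)})
        res = steel_dwass(ms)
        row = res.table.iloc[0]
        # ranks 1..10 vs 11..20: R_a=55, E=105, V = 100/(20*19)*665 = 175
        assert row["rank_sum"] == 55.0
        assert row["t"] == pytest.approx(-50 / np.sqrt(175))
        # k=2: the studentized-range p reduces to 2*(1-Phi(|t|))
        assert row["p"] == pytest.approx(2 * norm.sf(50 / np.sqrt(175)),
                                         rel=1e-6)
        assert row["p"] < 0.01 and row["significant"]

    def test_rank_based_monotone_invariance(self):
        rng = np.random.default_rng(4)
        raw = {m: rng.normal(m / 3, 1, 10) for m in (1, 5, 9)}
        r1 = steel_dwass(_samples(**{str(m): v for m, v in raw.items()}))
        r2 = steel_dwass(_samples(**{str(m): np.exp(v)
                                     for m, v in raw.items()}))
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_permutation_oracle_agrees_on_clear_cases(self):
        ms = _samples(**{"1": np.arange(8.0), "2": np.arange(8.0) + 0.5,
                         "3": np.arange(100.0, 108.0)})
        asym = steel_dwass(ms)
        perm = steel_dwass(ms, method="permutation", n_perm=999, seed=0)
        merged = asym.table.merge(perm.table, on=["month_a", "month_b"],
                                  suffixes=("_a", "_p"))
        # months 1 and 2 overlap heavily, month 3 is far away
        for _, row in merged.iterrows():
            assert row["significant_a"] == row["significant_p"]

    def test_single_observation_months_excluded_with_warning(self):
        ms = _samples(**{"1": [1, 2, 3], "2": [4, 5, 6], "3": [9]})
        with pytest.warns(UserWarning, match=r"\[3\]"):
            res = steel_dwass(ms)
        assert res.months == [1, 2]

    def test_too_few_usable_months_rejected(self):
        with pytest.raises(ValueError):
            steel_dwass(_samples(**{"1": [1, 2, 3]}))


class TestCompactLetters:
    def test_no_significant_pairs_single_letter(self):
        letters = compact_letters(_comp([1, 2, 3], set()))
        assert letters == {1: "a", 2: "a", 3: "a"}

    def test_all_pairs_significant_distinct_letters(self):
        months = [1, 2, 3]
        sig = {frozenset(p) for p in itertools.combinations(months, 2)}
        letters = compact_letters(_comp(months, sig))
        assert letters == {1: "a", 2: "b", 3: "c"}

    def test_chain_case_shares_middle(self):
        letters = compact_letters(_comp([1, 2, 3], {frozenset((1, 3))}))
        assert letters == {1: "a", 2: "ab", 3: "b"}

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(3, 8), st.data())
    def test_letter_axioms_on_random_significance_graphs(self, n, data):
        months = list(range(1, n + 1))
        pairs = list(itertools.combinations(months, 2))
        sig = {frozenset(p) for p in pairs
               if data.draw(st.booleans(), label=str(p))}
        letters = _insert_absorb(months, sig)
        for a, b in pairs:
            shared = set(letters[a]) & set(letters[b])
            if frozenset((a, b)) in sig:
                assert not shared, (a, b, letters)
            else:
                assert shared, (a, b, letters)


class TestKendallW:
    def test_identical_rankings_give_unity(self):
        ranks = np.tile(np.arange(1, 7), (4, 1))
        res = kendall_w(ranks)
        assert res.W == pytest.approx(1.0)
        assert res.df == 5
        assert res.p_chi2 < 0.05

    def test_reversed_pair_gives_zero(self):
        res = kendall_w([[1, 2, 3, 4], [4, 3, 2, 1]])
        assert res.W == pytest.approx(0.0)

    def test_hand_computed_three_by_three(self):
        res = kendall_w([[1, 2, 3], [1, 2, 3], [1, 3, 2]])
        # rank sums (3,7,8), S=14, W = 12*14 / (9*24)
        assert res.W == pytest.approx(14 / 18)
        assert res.chi2 == pytest.approx(3 * 2 * res.W)

    def test_judge_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        ranks = np.array([rng.permutation(5) + 1 for _ in range(4)])
        res = kendall_w(ranks)
        perm = kendall_w(ranks[[2, 0, 3, 1]])
        assert res.W == pytest.approx(perm.W)

    def test_exhaustive_untied_three_judges_matches_direct_sum(self):
        # every 3x3 rank matrix: W from the variance-of-rank-sums definition
        perms = list(itertools.permutations([1, 2, 3]))
        for rows in itertools.product(perms, repeat=3):
            ranks = np.asarray(rows, dtype=float)
            m, n = 3, 3
            s = np.sum((ranks.sum(0) - m * (n + 1) / 2) ** 2)
            expect = 12 * s / (m * m * (n ** 3 - n))
            assert kendall_w(ranks).W == pytest.approx(expect, abs=1e-12)

    def test_invalid_rank_row_rejected(self):
        with pytest.raises(ValueError):
            kendall_w([[1, 2, 2], [1, 2, 3]])  # not a midrank vector

    def test_midrank_ties_accepted_and_corrected(self):
        res = kendall_w([[1.5, 1.5, 3], [1, 2, 3]])
        assert 0 <= res.W <= 1 and res.tie_corrected

    def test_permutation_p_consistent_with_chi2_on_strong_signal(self):
        ranks = np.tile(np.arange(1, 8), (5, 1))
        res = kendall_w(ranks, n_perm=499, seed=3)
        assert res.p_perm < 0.01

    def test_permutation_p_uniform_under_null(self):
        # judges ranking at random: p < 0.05 should occur ~5% of the time
        rng = np.random.default_rng(12)
        hits = 0
        trials = 400
        for t in range(trials):
            ranks = np.array([rng.permutation(8) + 1 for _ in range(3)])
            res = kendall_w(ranks, n_perm=199, seed=t)
            hits += res.p_perm < 0.05
        assert 0.03 <= hits / trials <= 0.07


class TestRelativeRichness:
    def _yearly_matrix(self, monthly_means, years=2):
        counts = {dt.date(1990 + y, m, 15): monthly_means[m - 1]
                  for y in range(years) for m in range(1, 13)}
        return _matrix_from_counts(counts)

    def test_equal_means_give_zero_profile_with_warning(self):
        mat = self._yearly_matrix([5] * 12)
        with pytest.warns(UserWarning, match="equal"):
            prof = relative_richness(mat, "ECM")
        assert np.allclose(prof, 0.0)

    def test_linear_means_hand_zscore(self):
        mat = self._yearly_matrix(list(range(1, 13)))
        prof = relative_richness(mat, "ECM")
        # means 1..12: z for December is (12-6.5)/sqrt(13)
        assert prof[11] == pytest.approx(5.5 / np.sqrt(13.0))
        assert np.allclose(prof, -prof[::-1])

    def test_missing_month_marked_nan(self):
        counts = {dt.date(1990, m, 15): m for m in range(1, 12)}  # no Dec
        prof = relative_richness(_matrix_from_counts(counts), "ECM")
        assert np.isnan(prof[11]) and np.isfinite(prof[:11]).all()


class TestMonthlyRankMatrix:
    def test_ranks_follow_monthly_means(self):
        counts = {dt.date(1990, m, 15): m for m in range(1, 13)}
        ranks = monthly_rank_matrix(_matrix_from_counts(counts))
        assert ranks.tolist() == [list(range(1, 13))]

    def test_restricts_to_surveyed_months(self):
        counts = {dt.date(1990, m, 15): m for m in (3, 6, 9)}
        ranks = monthly_rank_matrix(_matrix_from_counts(counts))
        assert ranks.shape == (1, 3)
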