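import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fluvimyco as fm
from fluvimyco import diversity
from fluvimyco.containers import ValidationError

from _oracles import tukey_q_pvalue


class TestHellinger:
    @pytest.mark.parametrize("row,expected", [
        ([4, 0], [1.0, 0.0]),
        ([1, 1], [0.70711, 0.70711]),
        ([9, 16], [0.6, 0.8]),
    ])
    def test_known_rows(self, row, expected):
        table = pd.DataFrame([row], index=["s"], columns=list("ab")[:len(row)])
        out = diversity.hellinger(table)
        assert np.allclose(out.to_numpy()[0], expected, atol=1e-5)

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=10).filter(
        lambda r: sum(r) > 0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_rows_unit_norm(self, row):
        out = diversity.hellinger(pd.DataFrame(
            [row], columns=[f"o{i}" for i in range(len(row))]))
        assert np.sum(out.to_numpy() ** 2) == pytest.approx(1.0)

    def test_zero_row_rejected(self):
        with pytest.raises(ValidationError):
            diversity.hellinger(pd.DataFrame([[0, 0]], columns=["a", "b"]))


class TestZscore:
    def test_hand_computed(self):
        out = diversity.zscore(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert np.allclose(out["x"], [-1.0, 0.0, 1.0])  # n-1 denominator

    def test_idempotent_on_standardized(self):
        x = pd.DataFrame({"x": [-1.0, 0.0, 1.0]})
        out = diversity.zscore(x)
        pd.testing.assert_frame_equal(out, x, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValidationError, match="x"):
            diversity.zscore(pd.DataFrame({"x": [2.0, 2.0, 2.0]}))


class TestAlphaEstimators:
    @pytest.mark.parametrize("counts,expected", [
        ([1, 1, 2, 5, 10], 5.5),        # F1=2, F2=1
        ([3, 4, 5], 3.0),               # F1=F2=0 -> S_obs
        ([1, 1, 1, 1], 10.0),           # F2=0 branch
    ])
    def test_chao1(self, counts, expected):
        assert diversity.chao1(counts) == pytest.approx(expected)

    @pytest.mark.parametrize("counts,expected", [
        ([1, 1, 1, 1], np.log(4)),
        ([5, 0, 0], 0.0),
        ([1, 3], 0.5623351),
    ])
    def test_shannon(self, counts, expected):
        assert diversity.shannon(counts) == pytest.approx(expected, abs=1e-6)

    def test_shannon_ignores_zero_padding(self):
        assert diversity.shannon([2, 3, 5]) == pytest.approx(
            diversity.shannon([2, 3, 5, 0, 0, 0]))

    @pytest.mark.parametrize("counts,expected", [
        ([1, 1, 0], 3.0),   # {A,B}: two tip branches + shared stem
        ([1, 1, 1], 5.0),   # full community = total tree length
        ([1, 0, 0], 2.0),   # {A}: tip branch + stem to root
    ])
    def test_faith_pd(self, counts, expected, three_tip_tree):
        got = diversity.faith_pd(counts, ["A", "B", "C"], three_tip_tree)
        assert got == pytest.approx(expected)

    def test_faith_pd_monotone_in_taxa(self, three_tip_tree):
        a = diversity.faith_pd([1, 0, 0], ["A", "B", "C"], three_tip_tree)
        b = diversity.faith_pd([1, 1, 0], ["A", "B", "C"], three_tip_tree)
        c = diversity.faith_pd([1, 1, 1], ["A", "B", "C"], three_tip_tree)
        assert a <= b <= c

    def test_chao1_at_least_observed(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.integers(0, 6, size=30)
            if counts.sum() == 0:
                continue
            assert diversity.chao1(counts) >= (counts > 0).sum()


class TestRarefaction:
    def test_full_depth_gives_observed_richness(self):
        counts = [5, 3, 2, 1]
        curve = diversity.rarefaction_curve(counts, [11])
        assert curve.iloc[0] == pytest.approx(4.0)

    def test_depth_one_gives_one(self):
        curve = diversity.rarefaction_curve([5, 3, 2], [1])
        assert curve.iloc[0] == pytest.approx(1.0)

    def test_monotone_and_bounded(self):
        counts = [10, 6, 3, 1, 1]
        depths = np.arange(1, 22)
        curve = diversity.rarefaction_curve(counts, depths)
        assert (np.diff(curve.to_numpy()) >= -1e-12).all()
        assert curve.iloc[-1] <= 5.0

    def test_matches_monte_carlo(self):
        counts = np.array([12, 7, 4, 2, 1, 1])
        total = counts.sum()
        d = total // 2
        expected = diversity.rarefaction_curve(counts, [d]).iloc[0]
        rng = np.random.default_rng(0)
        pool = np.repeat(np.arange(len(counts)), counts)
        draws = [len(np.unique(rng.choice(pool, size=d, replace=False)))
                 for _ in range(10000)]
        mc = np.mean(draws)
        se = np.std(draws) / np.sqrt(len(draws))
        assert abs(expected - mc) < 2 * se + 1e-9


class TestAbundantOtus:
    def test_single_dominant(self):
        counts = pd.DataFrame([[95, 3, 2]], index=["s"], columns=list("abc"))
        out = diversity.abundant_otus(fm.OtuTable(counts), coverage=0.9)
        assert out.otu_ids == ["a"]

    def test_even_community_cumulative_walk(self):
        counts = pd.DataFrame([[10] * 10], index=["s"],
                              columns=[f"o{i}" for i in range(10)])
        out = diversity.abundant_otus(fm.OtuTable(counts), coverage=0.9)
        assert out.n_otus == 9

    def test_full_coverage_keeps_nonzero(self):
        counts = pd.DataFrame([[5, 0, 3]], index=["s"], columns=list("abc"))
        out = diversity.abundant_otus(fm.OtuTable(counts), coverage=1.0)
        assert out.otu_ids == ["a", "c"]


class TestWaterType:
    @pytest.mark.parametrize("psu,expected", [
        (0.3, "fresh"), (8.0, "brackish"), (31.0, "marine"),
        (0.5, "brackish"), (30.0, "brackish"),  # closed interval boundary
    ])
    def test_thresholds(self, psu, expected):
        assert diversity.water_type(psu) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            diversity.water_type(-1.0)


class TestTukeyHsd:
    def test_identical_groups_nonsignificant(self):
        vals = np.tile([1.0, 2.0, 3.0], 3)
        groups = np.repeat(["a", "b", "c"], 3)
        out = diversity.tukey_hsd(vals, groups)
        assert (out["p"] > 0.99).all()

    def test_separated_groups_power(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(200):
            vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(5, 1, 10)])
            groups = np.repeat(["a", "b"], 10)
            out = diversity.tukey_hsd(vals, groups)
            hits += (out["p"] < 0.001).all()
        assert hits >= 198

    def test_matches_studentized_range_formula(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0, 1, 8), rng.normal(1, 1, 8),
                               rng.normal(2, 1, 8)])
        groups = np.repeat(["a", "b", "c"], 8)
        out = diversity.tukey_hsd(vals, groups)
        means = [vals[groups == g].mean() for g in "abc"]
        sds = [vals[groups == g].std(ddof=1) for g in "abc"]
        row = out[(out.group_a == "a") & (out.group_b == "c")].iloc[0]
        expected = tukey_q_pvalue(means, sds, [8, 8, 8], 0, 2)
        assert row["p"] == pytest.approx(expected, abs=1e-8)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValidationError):
            diversity.tukey_hsd([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestGroupFrequency:
    def _table(self, counts, samples, otus, groups):
        t = fm.OtuTable(pd.DataFrame(counts, index=samples, columns=otus))
        t.taxon_group = pd.Series(groups, index=otus)
        return t

    def test_exclusive_lineage_frequencies(self):
        counts = [[5, 1], [3, 1], [0, 1], [0, 1], [0, 1], [0, 1]]
        table = self._table(counts, [f"s{i}" for i in range(6)],
                            ["basal1", "other"], ["basal", "other"])
        wt = pd.Series(["fresh"] * 2 + ["brackish"] * 2 + ["marine"] * 2,
                       index=table.sample_ids)
        res = diversity.group_frequency_test(table, wt)
        assert res.frequencies.loc["basal"].to_dict() == {
            "brackish": 0.0, "fresh": 1.0, "marine": 0.0}

    def test_identical_groups_all_nonsignificant(self):
        counts = [[2, 2]] * 6
        table = self._table(counts, [f"s{i}" for i in range(6)],
                            ["x", "y"], ["gx", "gy"])
        wt = pd.Series(["fresh", "fresh", "brackish", "brackish",
                        "marine", "marine"], index=table.sample_ids)
        res = diversity.group_frequency_test(table, wt)
        assert (res.tests["p"] > 0.99).all()

    def test_enriched_lineage_detected(self):
        # fresh-enriched clade: presence 0.9 in fresh vs 0.1 elsewhere
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            pres = np.concatenate([rng.random(8) < 0.9, rng.random(16) < 0.1])
            counts = np.column_stack([pres.astype(int) * 3,
                                      np.ones(24, dtype=int)])
            table = self._table(counts, [f"s{i}" for i in range(24)],
                                ["clade", "other"], ["clade", "other"])
            wt = pd.Series(np.repeat(["fresh", "brackish", "marine"], 8),
                           index=table.sample_ids)
            res = diversity.group_frequency_test(table, wt)
            row = res.tests[(res.tests.taxon_group == "clade")
                            & (res.tests.group_a == "fresh")
                            & (res.tests.group_b == "marine")]
            hits += (row["p"] < 0.05).all()
        assert hits >= 0.8 * n_rep
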