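"""Cross-area comparison: Jaccard arithmetic, top-k curves, group means and
ranked listings."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ethnosurvey import comparison, indices
from ethnosurvey.records import (
    CitationRecord,
    InterviewSet,
    UseCategory,
    filter_min_citations,
)
from ethnosurvey.simulate import SimConfig, generate

import _oracles as oracles


def _rec(iid, area, taxon, rank, cat):
    return CitationRecord(iid, area, taxon, rank, UseCategory(cat))


class TestJaccardTaxa:
    def test_published_style_cardinalities(self):
        """Two inventories of 147 and 119 taxa sharing 109 give JI 69.43%."""
        shared = {f"s{i}" for i in range(109)}
        set_a = shared | {f"a{i}" for i in range(38)}
        set_b = shared | {f"b{i}" for i in range(10)}
        result = comparison.jaccard_taxa(set_a, set_b)
        assert (result.a_count, result.b_count, result.shared) == (147, 119, 109)
        assert result.ji == pytest.approx(100 * 109 / 157)
        assert round(result.ji, 2) == 69.43

    def test_identical_sets(self):
        assert comparison.jaccard_taxa({"x", "y"}, {"x", "y"}).ji == 100.0

    def test_disjoint_sets(self):
        assert comparison.jaccard_taxa({"x"}, {"y"}).ji == 0.0

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            comparison.jaccard_taxa(set(), set())

    @given(
        a=st.sets(st.integers(0, 30)),
        b=st.sets(st.integers(0, 30)),
    )
    def test_symmetry_and_identity(self, a, b):
        if not (a or b):
            return
        ab = comparison.jaccard_taxa(a, b)
        ba = comparison.jaccard_taxa(b, a)
        assert ab.ji == pytest.approx(ba.ji)
        if a:
            assert comparison.jaccard_taxa(a, a).ji == 100.0

    @given(
        a=st.sets(st.integers(0, 30), min_size=1),
        b=st.sets(st.integers(0, 30), min_size=1),
    )
    def test_adding_a_shared_taxon_never_lowers_ji(self, a, b):
        base = comparison.jaccard_taxa(a, b).ji
        grown = comparison.jaccard_taxa(a | {99}, b | {99}).ji
        assert grown >= base - 1e-12


class TestJaccardTopk:
    def test_full_k_reduces_to_plain_jaccard(self, sim_data):
        filtered = filter_min_citations(sim_data, 2)
        full = comparison.jaccard_topk(filtered, k=len(filtered.taxa))
        sets = [
            set(indices.citation_frequency(filtered, a))
            for a in sorted(filtered.areas)
        ]
        assert full == comparison.jaccard_taxa(*sets)

    def test_top_taxon_in_both_areas_gives_100(self, fixture_data):
        filtered = filter_min_citations(fixture_data, 2)
        assert comparison.jaccard_topk(filtered, k=1).ji == 100.0

    def test_out_of_range_k_rejected(self, tiny_set):
        with pytest.raises(ValueError):
            comparison.jaccard_topk(tiny_set, k=0)
        with pytest.raises(ValueError):
            comparison.jaccard_topk(tiny_set, k=10_000)

    def test_matches_brute_force_recomputation(self):
        data = filter_min_citations(generate(SimConfig(seed=23)), 2)
        k = 40
        fc = oracles.oracle_fc(data, "all")
        top = set(sorted(fc, key=lambda t: (-fc[t], t))[:k])
        areas = sorted(data.areas)
        in_a = {r.taxon for r in data.records if r.area == areas[0]} & top
        in_b = {r.taxon for r in data.records if r.area == areas[1]} & top
        expected = 100 * len(in_a & in_b) / len(in_a | in_b)
        assert comparison.jaccard_topk(data, k).ji == pytest.approx(expected)

    def test_common_taxa_dominate_the_top_of_the_list(self, fixture_data):
        """Restricting to the most cited 20% cannot look less similar than
        the full inventory on overlap-heavy data."""
        filtered = filter_min_citations(fixture_data, 2)
        k = max(1, int(0.2 * len(filtered.taxa) + 0.5))
        top = comparison.jaccard_topk(filtered, k)
        overall = comparison.jaccard_topk(filtered, len(filtered.taxa))
        assert top.ji >= overall.ji


class TestJaccardByCategory:
    def test_identical_taxon_sets_give_100(self):
        records = [
            _rec("a0", "A", "Rosa canina", 1, "M"),
            _rec("b0", "B", "Rosa canina", 1, "M"),
        ]
        result = comparison.jaccard_by_use_category(
            InterviewSet(records), UseCategory.MEDICINE
        )
        assert result.ji == 100.0

    def test_category_in_one_area_only_gives_0(self):
        records = [
            _rec("a0", "A", "Rosa canina", 1, "C"),
            _rec("b0", "B", "Urtica dioica", 1, "E"),
            _rec("a0", "A", "Rosa canina", 1, "E"),
        ]
        result = comparison.jaccard_by_use_category(
            InterviewSet(records), UseCategory.CEREMONIAL
        )
        assert result.ji == 0.0

    def test_absent_category_rejected(self, tiny_set):
        with pytest.raises(ValueError):
            comparison.jaccard_by_use_category(tiny_set, UseCategory.CEREMONIAL)

    def test_matches_oracle_recomputation(self):
        data = filter_min_citations(generate(SimConfig(seed=23)), 2)
        areas = sorted(data.areas)
        in_a = {
            r.taxon
            for r in data.records
            if r.area == areas[0] and r.use_category == UseCategory.FOOD
        }
        in_b = {
            r.taxon
            for r in data.records
            if r.area == areas[1] and r.use_category == UseCategory.FOOD
        }
        expected = 100 * len(in_a & in_b) / len(in_a | in_b)
        result = comparison.jaccard_by_use_category(data, UseCategory.FOOD)
        assert result.ji == pytest.approx(expected)

    def test_frequency_mode_uses_report_counts(self):
        records = [
            _rec("a0", "A", "Rosa canina", 1, "E"),
            _rec("a1", "A", "Rosa canina", 1, "E"),
            _rec("a1", "A", "Urtica dioica", 2, "E"),
            _rec("b0", "B", "Rosa canina", 1, "E"),
        ]
        result = comparison.jaccard_by_use_category(
            InterviewSet(records), UseCategory.FOOD, mode="frequency"
        )
        # A=3 reports, B=1, shared = min(2,1) = 1 -> 100*1/3
        assert (result.a_count, result.b_count, result.shared) == (3, 1, 1)
        assert result.ji == pytest.approx(100 / 3)


class TestUnionCount:
    @pytest.mark.parametrize(
        "a, b, c, expected",
        [(147, 119, 109, 157), (5, 5, 5, 5), (3, 4, 0, 7)],
    )
    def test_examples(self, a, b, c, expected):
        assert comparison.union_count(a, b, c) == expected

    def test_invalid_shared_rejected(self):
        with pytest.raises(ValueError):
            comparison.union_count(3, 4, 4)

    @given(
        a=st.sets(st.integers(0, 50)),
        b=st.sets(st.integers(0, 50)),
    )
    def test_consistent_with_direct_set_union(self, a, b):
        assert comparison.union_count(len(a), len(b), len(a & b)) == len(a | b)


class TestMeanCitations:
    def test_constant_lists(self):
        records = [
            _rec(f"i{k}", "A", f"Taxon number{t:02d}", t + 1, "E")
            for k in range(3)
            for t in range(10)
        ]
        summary = comparison.mean_citations_per_interview(InterviewSet(records))
        assert summary.mean == 10.0
        assert summary.minimum == summary.maximum == 10

    def test_matches_oracle_mean(self, sim_data):
        summary = comparison.mean_citations_per_interview(sim_data)
        per_interview = [
            len({r.taxon for r in sim_data.records if r.interview_id == iid})
            for iid in sim_data.interview_ids()
        ]
        assert summary.mean == pytest.approx(float(np.mean(per_interview)))
        assert summary.minimum == min(per_interview)
        assert summary.maximum == max(per_interview)

    def test_balanced_pooled_mean_of_area_means(self):
        """Two equal-size areas with means 28.63 and 21.67 pool to 25.15."""
        assert comparison.pooled_mean([28.63, 21.67], [30, 30]) == pytest.approx(
            25.15
        )

    def test_pooled_mean_is_size_weighted(self):
        assert comparison.pooled_mean([10.0, 20.0], [1, 3]) == pytest.approx(17.5)


class TestCompareGroupMeans:
    def _balanced(self, values_a, values_b):
        records = []
        for g, (area, values) in enumerate([("A", values_a), ("B", values_b)]):
            for k, count in enumerate(values):
                for t in range(count):
                    records.append(
                        _rec(f"{area}{k}", area, f"Taxon number{t:02d}", t + 1, "E")
                    )
        return InterviewSet(records)

    def test_identical_groups(self):
        data = self._balanced([1, 2, 3], [1, 2, 3])
        result = comparison.compare_group_means(data, "A", "B")
        assert result.t == pytest.approx(0.0)
        assert result.p == pytest.approx(1.0)

    def test_clearly_separated_groups(self):
        data = self._balanced([1, 2, 3], [11, 12, 13])
        result = comparison.compare_group_means(data, "A", "B")
        assert abs(result.t) > 5
        assert result.p < 0.01
        assert result.difference == pytest.approx(-10.0)

    def test_uses_per_taxon_statistic(self):
        records = [
            _rec("a0", "A", "Rosa canina", 1, "E"),
            _rec("a0", "A", "Rosa canina", 1, "M"),
            _rec("a0", "A", "Urtica dioica", 2, "E"),
            _rec("b0", "B", "Rosa canina", 1, "E"),
            _rec("b0", "B", "Urtica dioica", 2, "E"),
        ]
        result = comparison.compare_group_means(
            InterviewSet(records), "A", "B", "uses-per-taxon"
        )
        assert result.mean_a == pytest.approx(1.5)
        assert result.mean_b == pytest.approx(1.0)

    def test_rejection_rate_matches_monte_carlo_power(self):
        """At the default design (n=30/area, list-length gap ~7, SD ~11)
        the t-test's rejection rate across simulated surveys agrees with an
        independent Monte-Carlo power estimate within 5 points."""
        config = SimConfig(seed=0)
        # oracle: direct sampling of clipped negative-binomial list lengths
        rng = np.random.default_rng(987654321)
        r = config.list_length_dispersion
        lo, hi = config.list_length_range
        n = config.n_interviews_per_area
        reps = 2000
        rejected = 0
        for _ in range(reps):
            groups = []
            for mean in config.list_length_means:
                draws = rng.negative_binomial(r, r / (r + mean), size=n)
                groups.append(np.clip(draws, lo, hi))
            _, p = stats.ttest_ind(groups[0], groups[1])
            rejected += p < 0.05
        oracle_power = rejected / reps

        hits = 0
        sim_reps = 300
        for seed in range(sim_reps):
            data = generate(SimConfig(seed=seed))
            areas = sorted(data.areas)
            result = comparison.compare_group_means(data, areas[1], areas[0])
            hits += result.p < 0.05
        assert abs(hits / sim_reps - oracle_power) < 0.05


class TestRankTable:
    def test_known_ordering(self, tiny_set):
        table = comparison.rank_table(tiny_set, "RFC", top_n=2)
        assert list(table["taxon_all"])[0].startswith("Taraxacum officinale")
        assert table["RFC_all"].iloc[0] == pytest.approx(1.0)

    def test_marker_set_is_top_list_intersection(self, fixture_data):
        filtered = filter_min_citations(fixture_data, 2)
        table = comparison.rank_table(filtered, "RFC", top_n=10)
        top_a = set(table["taxon_Izola"]) - {""}
        top_b = set(table["taxon_Komen"]) - {""}
        marked = {
            name[:-2] for name in table["taxon_all"] if name.endswith(" +")
        }
        assert marked == set(table.attrs["shared_top"]) & {
            n.rstrip(" +") for n in table["taxon_all"]
        }
        assert set(table.attrs["shared_top"]) == top_a & top_b

    def test_single_area_data(self):
        records = [_rec("a0", "A", "Rosa canina", 1, "E")]
        table = comparison.rank_table(InterviewSet(records), "RFC", top_n=1)
        assert "taxon_A" in table.columns
        assert "taxon_all" in table.columns

    def test_truncation_warns(self, tiny_set):
        with pytest.warns(UserWarning, match="truncat"):
            comparison.rank_table(tiny_set, "RFC", top_n=50)
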