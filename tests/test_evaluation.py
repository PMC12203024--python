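"""Grading, sampling, finite-population CIs, sample sizes, cross-tabulation."""

import math

import numpy as np
import pytest
from scipy import stats

from doseatc import (
    FinitePopulationFrame,
    GradingError,
    JoinError,
    LlmGrade,
    SamplingError,
    SearchGrade,
    cross_tabulate,
    finite_population_ci,
    fpc_half_width,
    grade_search_output,
    proportion_mostly_correct,
    proportion_perfect,
    required_sample_size,
    sample_without_replacement,
)
from doseatc.search_benchmark import SearchClassification


def _grades(ones, twos, threes):
    grades = []
    for grade, count in ((1, ones), (2, twos), (3, threes)):
        grades += [LlmGrade(item=f"g{grade}-{i}", grade=grade) for i in range(count)]
    return grades


class TestSampling:
    def test_excludes_pilot_and_returns_distinct(self):
        frame = FinitePopulationFrame.from_members([f"s{i}" for i in range(12294)])
        pilot = set(frame.members[:20])
        sample = sample_without_replacement(frame, 200, seed=5, exclude=pilot)
        assert len(sample) == 200
        assert len(set(sample)) == 200
        assert not pilot & set(sample)

    def test_census(self):
        frame = FinitePopulationFrame.from_members(list("abcde"))
        assert sorted(sample_without_replacement(frame, 5, seed=0)) == list("abcde")

    def test_same_seed_same_sample(self):
        frame = FinitePopulationFrame.from_members(range(1000))
        assert sample_without_replacement(frame, 50, seed=9) == sample_without_replacement(
            frame, 50, seed=9
        )

    def test_oversampling_rejected(self):
        frame = FinitePopulationFrame.from_members(range(10))
        with pytest.raises(SamplingError):
            sample_without_replacement(frame, 10, seed=0, exclude={0})


class TestProportions:
    def test_mostly_correct_from_mixed_grade_counts(self):
        grades = _grades(175, 10, 15)
        assert proportion_mostly_correct(grades) == pytest.approx(0.925)
        assert proportion_perfect(grades) == pytest.approx(0.875)

    def test_all_perfect(self):
        assert proportion_mostly_correct(_grades(5, 0, 0)) == 1.0

    def test_all_major_issue(self):
        assert proportion_mostly_correct(_grades(0, 0, 10)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(GradingError):
            proportion_mostly_correct([])

    def test_invalid_grade_rejected(self):
        with pytest.raises(GradingError):
            LlmGrade(item="x", grade=4)


class TestFinitePopulationCI:
    def test_interval_at_reference_inputs(self):
        estimate = finite_population_ci(185, 200, 12294, 0.80)
        assert estimate.p_hat == pytest.approx(0.925)
        assert estimate.as_percent() == (92.5, 90.1, 94.9)

    def test_census_half_width_is_zero(self):
        estimate = finite_population_ci(40, 50, 50, 0.95)
        assert estimate.ci_low == estimate.ci_high == estimate.p_hat

    def test_half_width_against_hand_evaluation(self):
        # z = Phi^-1(0.9), p = 0.5, n = 100, N = 10000
        estimate = finite_population_ci(50, 100, 10000, 0.80)
        half = (estimate.ci_high - estimate.ci_low) / 2
        assert half == pytest.approx(0.0638, abs=5e-5)

    def test_width_strictly_decreasing_in_n(self):
        widths = [fpc_half_width(0.9, n, 5000, 0.80) for n in range(10, 4999, 250)]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_matches_infinite_population_limit(self):
        n, p, conf = 200, 0.925, 0.80
        z = stats.norm.ppf(0.9)
        classic = z * math.sqrt(p * (1 - p) / n)
        finite = fpc_half_width(p, n, 1e12, conf)
        assert abs(finite - classic) / classic < 1e-6

    def test_bounds_clamped(self):
        estimate = finite_population_ci(1, 2, 1000, 0.999)
        assert 0.0 <= estimate.ci_low <= estimate.ci_high <= 1.0

    def test_precondition_violations(self):
        with pytest.raises(SamplingError):
            finite_population_ci(10, 5, 100, 0.8)
        with pytest.raises(SamplingError):
            finite_population_ci(5, 200, 100, 0.8)
        with pytest.raises(SamplingError):
            finite_population_ci(5, 10, 100, 1.5)


class TestRequiredSampleSize:
    def test_planning_at_reference_inputs(self):
        """Margin 0.02, planning p 0.95, 80% confidence, N 12294: direct
        inversion of the implemented half-width gives 192 (verified at the
        neighbouring integers below)."""
        n = required_sample_size(0.02, 0.95, 0.80, 12294)
        assert n == 192
        assert fpc_half_width(0.95, n, 12294, 0.80) <= 0.02
        assert fpc_half_width(0.95, n - 1, 12294, 0.80) > 0.02

    def test_huge_margin_needs_one(self):
        assert required_sample_size(0.9, 0.5, 0.80, 1000) == 1

    def test_tiny_margin_census_bound(self):
        assert required_sample_size(1e-9, 0.5, 0.80, 10) == 10

    @pytest.mark.parametrize("margin,p,conf,N", [
        (0.05, 0.5, 0.95, 500),
        (0.03, 0.9, 0.80, 2000),
        (0.01, 0.95, 0.90, 12294),
    ])
    def test_minimality(self, margin, p, conf, N):
        n = required_sample_size(margin, p, conf, N)
        assert fpc_half_width(p, n, N, conf) <= margin
        if n > 1:
            assert fpc_half_width(p, n - 1, N, conf) > margin


class TestGradeSearchOutput:
    def test_tie_of_two_acceptable_codes_is_acceptable(self):
        classification = SearchClassification(winners=frozenset({"C02", "G04"}), tally={"C02": 3, "G04": 3})
        assert grade_search_output(classification, {"C02": True, "G04": True}) is True

    def test_tie_with_one_inappropriate_code_is_rejected(self):
        classification = SearchClassification(winners=frozenset({"B01", "X99"}), tally={"B01": 2, "X99": 2})
        assert grade_search_output(classification, {"B01": True, "X99": False}) is False

    def test_empty_winners_not_acceptable(self):
        classification = SearchClassification(winners=frozenset(), tally={})
        assert grade_search_output(classification, {}) is False

    def test_missing_acceptability_entry(self):
        classification = SearchClassification(winners=frozenset({"B01"}), tally={"B01": 1})
        with pytest.raises(GradingError):
            grade_search_output(classification, {})


def _paired_grades(cells):
    """Build paired grade lists from 3x2 cell counts
    ((grade, acceptable) -> count)."""
    llm, search = [], []
    item = 0
    for (grade, acceptable), count in cells.items():
        for _ in range(count):
            name = f"item-{item}"
            llm.append(LlmGrade(item=name, grade=grade))
            search.append(SearchGrade(item=name, acceptable=acceptable))
            item += 1
    return llm, search


class TestCrossTab:
    def test_table_from_cell_counts(self):
        cells = {
            (1, True): 148, (1, False): 27,
            (2, True): 8, (2, False): 2,
            (3, True): 9, (3, False): 6,
        }
        llm, search = _paired_grades(cells)
        table = cross_tabulate(llm, search)
        assert table.row_margins == (175, 10, 15)
        assert table.col_margins == (165, 35)
        assert table.total == 200
        assert table.counts.loc[1, "acceptable"] == 148
        assert table.counts.loc[3, "not acceptable"] == 6

    def test_empty_input(self):
        table = cross_tabulate([], [])
        assert table.total == 0
        assert table.row_margins == (0, 0, 0)

    def test_single_item(self):
        table = cross_tabulate(
            [LlmGrade(item="x", grade=2)], [SearchGrade(item="x", acceptable=False)]
        )
        assert table.counts.loc[2, "not acceptable"] == 1
        assert table.total == 1

    def test_unmatched_items_rejected(self):
        with pytest.raises(JoinError):
            cross_tabulate(
                [LlmGrade(item="a", grade=1)], [SearchGrade(item="b", acceptable=True)]
            )

    def test_conservation_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            cells = {
                (g, a): int(rng.integers(0, 20))
                for g in (1, 2, 3)
                for a in (True, False)
            }
            table = cross_tabulate(*_paired_grades(cells))
            assert sum(table.row_margins) == table.total
            assert sum(table.col_margins) == table.total
            assert table.counts.to_numpy().sum() == table.total


def test_grade_csv_round_trip(tmp_path):
    llm_path = tmp_path / "llm.csv"
    llm_path.write_text("item,grade\na,1\nb,2\nc,3\n")
    search_path = tmp_path / "search.csv"
    search_path.write_text("item,acceptable\na,true\nb,false\nc,TRUE\n")
    from doseatc import read_llm_grades_csv, read_search_grades_csv

    llm = read_llm_grades_csv(llm_path)
    search = read_search_grades_csv(search_path)
    assert [g.grade for g in llm] == [1, 2, 3]
    assert [g.acceptable for g in search] == [True, False, True]
    table = cross_tabulate(llm, search)
    assert table.total == 3
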