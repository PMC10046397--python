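"""Validation statistics: hand oracles and boundary behaviour for the ISO
criteria, BHS grading, Bland–Altman limits, and Pearson correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgbp.protocol import ComparisonPair
from ppgbp.validation import (
    bhs_grade,
    bland_altman,
    cumulative_pct,
    diff_stats,
    iso_criterion1,
    iso_criterion2,
    pair_diffs,
    pearson_r,
    per_subject_sd,
    weekly_report,
)


def _pairs_from_diffs(diffs, subject="s", week=1, base=120.0):
    return [
        ComparisonPair(f"{subject}{i}", week, "BP3", base, 80.0, base + d, 80.0 + d)
        for i, d in enumerate(diffs)
    ]


class TestDiffStats:
    def test_hand_oracles(self):
        assert diff_stats(_pairs_from_diffs([0, 0, 0]), "SBP") == (0.0, 0.0)
        m, s = diff_stats(_pairs_from_diffs([-1, 0, 1]), "SBP")
        assert (m, s) == (0.0, pytest.approx(1.0))
        assert diff_stats(_pairs_from_diffs([5, 5, 5]), "DBP") == (5.0, 0.0)

    def test_matches_two_pass_streaming_oracle(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0, 4, 40)
        m, s = diff_stats(_pairs_from_diffs(d), "SBP")
        mean = sum(d) / len(d)  # explicit two-pass computation
        var = sum((x - mean) ** 2 for x in d) / (len(d) - 1)
        assert m == pytest.approx(mean, abs=1e-12)
        assert s == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            diff_stats(_pairs_from_diffs([1.0]), "SBP")

    def test_reorder_invariance(self):
        d = [3.0, -2.0, 7.0, 0.5, -4.0]
        a = diff_stats(_pairs_from_diffs(d), "SBP")
        b = diff_stats(list(reversed(_pairs_from_diffs(d))), "SBP")
        assert a == b


class TestIsoCriteria:
    @pytest.mark.parametrize(
        "mean,sd,expected",
        [(-1.86, 5.50, True), (-5.0, 8.0, True), (5.1, 7.0, False), (0.0, 8.01, False)],
    )
    def test_criterion1_boundaries(self, mean, sd, expected):
        assert iso_criterion1(mean, sd) is expected

    @pytest.mark.parametrize(
        "sd,target,expected",
        [(6.82, "SBP", True), (6.89, "SBP", True), (6.90, "SBP", False),
         (6.62, "DBP", True), (6.84, "DBP", True), (6.85, "DBP", False)],
    )
    def test_criterion2_boundaries(self, sd, target, expected):
        assert iso_criterion2(sd, target) is expected

    def test_criterion2_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            iso_criterion2(5.0, "MAP")

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            iso_criterion1(np.nan, 1.0)


class TestPerSubjectSd:
    @staticmethod
    def _subject_pairs(subject, diffs):
        return [
            ComparisonPair(subject, 1, "BP3", 120.0, 80.0, 120.0 + d, 80.0 + d) for d in diffs
        ]

    def test_two_subject_hand_value(self):
        pairs = self._subject_pairs("a", [-1, -1]) + self._subject_pairs("b", [1, 1])
        assert per_subject_sd(pairs, "SBP") == pytest.approx(np.sqrt(2.0))

    def test_identical_subject_means_give_zero(self):
        pairs = self._subject_pairs("a", [2, 2]) + self._subject_pairs("b", [2, 2])
        assert per_subject_sd(pairs, "SBP") == 0.0

    def test_one_pair_per_subject_equals_pooled_sd(self):
        d = [1.0, -3.0, 2.0, 0.0]
        pairs = [p for i, x in enumerate(d) for p in _pairs_from_diffs([x], subject=f"u{i}")]
        assert per_subject_sd(pairs, "SBP") == pytest.approx(diff_stats(pairs, "SBP")[1])

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            per_subject_sd(self._subject_pairs("only", [1, 2]), "SBP")


class TestCumulativePct:
    def test_hand_count(self):
        assert cumulative_pct([3, -7, 12]) == (
            pytest.approx(33.3333, abs=0.001),
            pytest.approx(66.6667, abs=0.001),
            pytest.approx(100.0),
        )

    def test_all_zero(self):
        assert cumulative_pct([0.0, 0.0]) == (100.0, 100.0, 100.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cumulative_pct([])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-40, 40), min_size=1, max_size=30))
    def test_monotone_nondecreasing(self, diffs):
        p5, p10, p15 = cumulative_pct(diffs)
        assert p5 <= p10 <= p15

    def test_thresholds_inclusive(self):
        assert cumulative_pct([5.0, 10.0, 15.0]) == (
            pytest.approx(100 / 3, abs=0.01),
            pytest.approx(200 / 3, abs=0.01),
            100.0,
        )


class TestBhsGrade:
    @pytest.mark.parametrize(
        "cum,grade",
        [
            ((60, 85, 95), "A"),
            ((59, 85, 95), "B"),
            ((57.29, 92.71, 98.96), "B"),  # whole-row rule on a mixed row
            ((40, 65, 85), "C"),
            ((39, 99, 99), "D"),
        ],
    )
    def test_grading(self, cum, grade):
        assert bhs_grade(cum) == grade

    @settings(max_examples=80, deadline=None)
    @given(
        st.tuples(st.floats(0, 100), st.floats(0, 100), st.floats(0, 100)),
        st.integers(0, 2),
        st.floats(0, 20),
    )
    def test_improving_any_percentage_never_worsens(self, cum, idx, bump):
        order = {"A": 0, "B": 1, "C": 2, "D": 3}
        better = list(cum)
        better[idx] = min(better[idx] + bump, 100.0)
        assert order[bhs_grade(tuple(better))] <= order[bhs_grade(cum)]


class TestBlandAltman:
    def test_hand_oracle(self):
        m, lo, hi = bland_altman(_pairs_from_diffs([-1, 0, 1]), "SBP")
        assert m == 0.0
        assert lo == pytest.approx(-1.96)
        assert hi == pytest.approx(1.96)

    def test_identical_devices(self):
        assert bland_altman(_pairs_from_diffs([0, 0, 0]), "DBP") == (0.0, 0.0, 0.0)

    def test_limits_bracket_mean(self):
        rng = np.random.default_rng(1)
        m, lo, hi = bland_altman(_pairs_from_diffs(rng.normal(2, 3, 20)), "SBP")
        assert lo <= m <= hi

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(_pairs_from_diffs([1, 2]), "SBP")


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r([2 * v for v in x], x)[0] == pytest.approx(1.0)
        assert pearson_r([-v for v in x], x)[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        t = np.array([118.0, 124.0, 111.0, 130.0, 120.0])
        r_ = np.array([120.0, 122.0, 113.0, 128.0, 119.0])
        num = np.sum((t - t.mean()) * (r_ - r_.mean()))
        den = np.sqrt(np.sum((t - t.mean()) ** 2) * np.sum((r_ - r_.mean()) ** 2))
        assert pearson_r(t, r_)[0] == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def cohort_pairs():
    rng = np.random.default_rng(7)
    pairs = []
    for week in range(1, 6):
        for i in range(30):
            base_s, base_d = rng.normal(115, 10), rng.normal(72, 8)
            for slot in ("BP3", "BP5", "BP7"):
                ref_s = base_s + rng.normal(0, 1)
                ref_d = base_d + rng.normal(0, 1)
                pairs.append(
                    ComparisonPair(
                        f"S{i}", week, slot, ref_s, ref_d,
                        ref_s + rng.normal(-1, 3), ref_d + rng.normal(-1, 3),
                    )
                )
    return pairs


class TestWeeklyReport:
    def test_five_weeks_two_targets_gives_ten_reports(self, cohort_pairs):
        reports = weekly_report(cohort_pairs)
        assert len(reports) == 10
        assert {(r.week, r.target) for r in reports} == {
            (w, t) for w in range(1, 6) for t in ("SBP", "DBP")
        }

    def test_cumulative_percentages_nondecreasing(self, cohort_pairs):
        for r in weekly_report(cohort_pairs):
            assert r.cum_pct[0] <= r.cum_pct[1] <= r.cum_pct[2]

    def test_statistics_consistent_with_components(self, cohort_pairs):
        rep = weekly_report(cohort_pairs)[0]
        wk = [p for p in cohort_pairs if p.week == rep.week]
        m, s = diff_stats(wk, rep.target)
        assert rep.mean_diff == pytest.approx(m)
        assert rep.sd_diff == pytest.approx(s)
        assert rep.iso1_pass == iso_criterion1(m, s)
        assert rep.bland_altman[0] == pytest.approx(np.mean(pair_diffs(wk, rep.target)))

    def test_reorder_invariance(self, cohort_pairs):
        rng = np.random.default_rng(0)
        shuffled = list(cohort_pairs)
        rng.shuffle(shuffled)
        a = weekly_report(cohort_pairs)[0]
        b = next(r for r in weekly_report(shuffled) if (r.week, r.target) == (a.week, a.target))
        assert a.mean_diff == pytest.approx(b.mean_diff, abs=1e-12)
        assert a.per_subject_sd == pytest.approx(b.per_subject_sd, abs=1e-12)
        assert a.cum_pct == b.cum_pct
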