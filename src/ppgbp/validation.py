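"""Accuracy statistics for BP-monitor validation: ISO 81060-2 criteria 1 and
2, BHS cumulative-percentage grading, Bland–Altman agreement, and Pearson
correlation.

All statistics operate on test-minus-reference differences from comparison
pairs.  Criterion 1 bounds the pooled mean and SD of the differences
(|mean| ≤ 5 mmHg, SD ≤ 8.0 mmHg); criterion 2 bounds the SD of per-subject
mean differences (≤ 6.89 mmHg for SBP, ≤ 6.84 mmHg for DBP).  BHS grades A–D
come from the cumulative percentage of absolute differences within 5/10/15
mmHg; a grade is awarded only if all three thresholds are met.  All
threshold comparisons are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .protocol import ComparisonPair

__all__ = [
    "ISO_CRITERION1_MEAN",
    "ISO_CRITERION1_SD",
    "ISO_CRITERION2_SD",
    "BHS_THRESHOLDS",
    "ValidationReport",
    "pair_diffs",
    "diff_stats",
    "iso_criterion1",
    "per_subject_sd",
    "iso_criterion2",
    "cumulative_pct",
    "bhs_grade",
    "bland_altman",
    "pearson_r",
    "weekly_report",
    "report_table",
]

ISO_CRITERION1_MEAN = 5.0
ISO_CRITERION1_SD = 8.0
ISO_CRITERION2_SD = {"SBP": 6.89, "DBP": 6.84}

#: BHS cumulative-percentage thresholds (grade -> required % within 5/10/15 mmHg).
BHS_THRESHOLDS = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}


@dataclass
class ValidationReport:
    """Every accuracy statistic for one week × target."""

    target: str
    week: int
    n_pairs: int
    mean_diff: float
    sd_diff: float
    per_subject_sd: float
    cum_pct: tuple[float, float, float]
    iso1_pass: bool
    iso2_pass: bool
    bhs_grade: str
    bland_altman: tuple[float, float, float]
    pearson_r: float
    pearson_p: float


def pair_diffs(pairs: list[ComparisonPair], target: str) -> np.ndarray:
    """Test − reference differences (mmHg) for the chosen target."""
    if target == "SBP":
        return np.array([p.test_sbp - p.reference_sbp for p in pairs])
    if target == "DBP":
        return np.array([p.test_dbp - p.reference_dbp for p in pairs])
    raise ValueError(f"unknown target {target!r}")


def diff_stats(pairs: list[ComparisonPair], target: str) -> tuple[float, float]:
    """Pooled mean and sample SD (N−1) of the test−reference differences."""
    d = pair_diffs(pairs, target)
    if len(d) < 2:
        raise ValueError("need at least 2 pairs")
    return float(np.mean(d)), float(np.std(d, ddof=1))


def iso_criterion1(mean_diff: float, sd_diff: float) -> bool:
    """Criterion 1: |mean| ≤ 5 mmHg and SD ≤ 8.0 mmHg (inclusive)."""
    if not (np.isfinite(mean_diff) and np.isfinite(sd_diff)):
        raise ValueError("non-finite inputs")
    return abs(mean_diff) <= ISO_CRITERION1_MEAN and sd_diff <= ISO_CRITERION1_SD


def per_subject_sd(pairs: list[ComparisonPair], target: str) -> float:
    """SD (N−1) across per-subject mean differences (the criterion-2 statistic)."""
    by_subject: dict[str, list[float]] = {}
    for p, d in zip(pairs, pair_diffs(pairs, target)):
        by_subject.setdefault(p.subject_id, []).append(float(d))
    if len(by_subject) < 2:
        raise ValueError("criterion 2 needs at least 2 subjects")
    means = [float(np.mean(v)) for v in by_subject.values()]
    return float(np.std(means, ddof=1))


def iso_criterion2(sd: float, target: str) -> bool:
    """Criterion 2: per-subject SD ≤ 6.89 (SBP) / 6.84 (DBP) mmHg, inclusive."""
    if target not in ISO_CRITERION2_SD:
        raise ValueError(f"unknown target {target!r}")
    if not np.isfinite(sd):
        raise ValueError("non-finite input")
    return sd <= ISO_CRITERION2_SD[target]


def cumulative_pct(diffs: np.ndarray | list[float]) -> tuple[float, float, float]:
    """Percentage of |difference| within 5, 10 and 15 mmHg (inclusive)."""
    d = np.abs(np.asarray(diffs, dtype=float))
    if d.size == 0:
        raise ValueError("empty difference list")
    return tuple(float(100.0 * np.mean(d <= t)) for t in (5.0, 10.0, 15.0))


def bhs_grade(cum_pct: tuple[float, float, float]) -> str:
    """Best BHS grade whose thresholds are all met; D otherwise."""
    for grade in ("A", "B", "C"):
        if all(p >= t for p, t in zip(cum_pct, BHS_THRESHOLDS[grade])):
            return grade
    return "D"


def bland_altman(pairs: list[ComparisonPair], target: str) -> tuple[float, float, float]:
    """Mean difference and 95% limits of agreement (mean ± 1.96 SD)."""
    d = pair_diffs(pairs, target)
    if len(d) < 3:
        raise ValueError("Bland–Altman needs at least 3 pairs")
    m = float(np.mean(d))
    s = float(np.std(d, ddof=1))
    return m, m - 1.96 * s, m + 1.96 * s


def pearson_r(test: np.ndarray | list[float], reference: np.ndarray | list[float]) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-distribution p-value."""
    t = np.asarray(test, dtype=float)
    r = np.asarray(reference, dtype=float)
    if len(t) < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if np.std(t) == 0 or np.std(r) == 0:
        raise ValueError("zero variance on one side")
    res = stats.pearsonr(t, r)
    return float(res.statistic), float(res.pvalue)


def weekly_report(pairs: list[ComparisonPair], targets: tuple[str, ...] = ("SBP", "DBP")) -> list[ValidationReport]:
    """Assemble one ValidationReport per week × target present in the pairs."""
    weeks = sorted({p.week for p in pairs})
    reports: list[ValidationReport] = []
    for week in weeks:
        wk = [p for p in pairs if p.week == week]
        for target in targets:
            d = pair_diffs(wk, target)
            mean_d, sd_d = diff_stats(wk, target)
            try:
                ps_sd = per_subject_sd(wk, target)
            except ValueError:  # single-subject cohort: criterion 2 undefined
                ps_sd = float("nan")
            cum = cumulative_pct(d)
            tst = [p.test_sbp if target == "SBP" else p.test_dbp for p in wk]
            ref = [p.reference_sbp if target == "SBP" else p.reference_dbp for p in wk]
            r, pval = pearson_r(tst, ref)
            reports.append(
                ValidationReport(
                    target=target,
                    week=week,
                    n_pairs=len(wk),
                    mean_diff=mean_d,
                    sd_diff=sd_d,
                    per_subject_sd=ps_sd,
                    cum_pct=cum,
                    iso1_pass=iso_criterion1(mean_d, sd_d),
                    iso2_pass=bool(np.isfinite(ps_sd)) and iso_criterion2(ps_sd, target),
                    bhs_grade=bhs_grade(cum),
                    bland_altman=bland_altman(wk, target),
                    pearson_r=r,
                    pearson_p=pval,
                )
            )
    return reports


def report_table(reports: list[ValidationReport]):
    """Render reports as a pandas DataFrame mirroring the weekly summary table."""
    import pandas as pd

    return pd.DataFrame(
        {
            "week": r.week,
            "target": r.target,
            "n_pairs": r.n_pairs,
            "pct_le5": r.cum_pct[0],
            "pct_le10": r.cum_pct[1],
            "pct_le15": r.cum_pct[2],
            "mean_diff": r.mean_diff,
            "sd_diff": r.sd_diff,
            "per_subject_sd": r.per_subject_sd,
            "bhs_grade": r.bhs_grade,
            "iso1_pass": r.iso1_pass,
            "iso2_pass": r.iso2_pass,
            "pearson_r": r.pearson_r,
        }
        for r in reports
    )
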