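"""End-to-end simulated validation study.

Wires every stage together: synthesize a cohort of subjects → pretrain the
exponential-kernel GP on one synthetic PPG database → fine-tune it on a
second (kernel hyperparameters frozen) → calibrate each subject once against
a cuff reading in week 1 → run the same-arm sequential protocol for five
weeks with uncalibrated follow-ups → pair test and reference readings →
compute the full validation report.  A single seed governs the whole run
through a ``numpy`` SeedSequence tree, so identical configurations produce
identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .calibration import CalibratedEstimator, calibrate, estimate_bp
from .config import RunConfig
from .features import FeatureMatrix, FeatureVector, build_feature_matrix
from .gpr import GPRModel, KernelParams, finetune, fit
from .protocol import BPReading, ComparisonPair, build_pairs, schedule
from .synth import PPGRecord, SubjectProfile, synth_recording
from .validation import ValidationReport, weekly_report

__all__ = ["StudyResult", "make_cohort", "make_training_data", "train_models",
           "features_for_recording", "simulate_study", "run_pipeline"]

log = logging.getLogger(__name__)

_MIN_PULSE_PRESSURE = 25.0


@dataclass
class StudyResult:
    """Everything the simulated study produces."""

    readings: list[BPReading]
    pairs: list[ComparisonPair]
    reports: list[ValidationReport]
    truth_errors: dict[tuple[int, str], np.ndarray]   # (week, target) -> est − truth
    anchor_errors: list[tuple[float, float]]          # per-subject (SBP, DBP) anchoring residual
    sbp_model: GPRModel
    dbp_model: GPRModel


def _clip_bp(sbp: float, dbp: float) -> tuple[float, float]:
    sbp = float(np.clip(sbp, 80.0, 180.0))
    dbp = float(np.clip(dbp, 45.0, 110.0))
    if sbp - dbp < _MIN_PULSE_PRESSURE:
        dbp = sbp - _MIN_PULSE_PRESSURE
    return sbp, dbp


def make_cohort(n: int, rng: np.random.Generator, prefix: str = "S") -> list[SubjectProfile]:
    """Draw a study cohort spanning hypo-, normo- and hypertensive pressures.

    Pressures follow the weekly cohort statistics of a typical validation
    study (SBP ≈ 111 ± 12, DBP ≈ 67 ± 10 mmHg) with a physiological pulse
    pressure of at least 25 mmHg.
    """
    profiles = []
    for i in range(n):
        sbp, dbp = _clip_bp(rng.normal(111.0, 12.0), rng.normal(67.0, 10.0))
        profiles.append(
            SubjectProfile(
                subject_id=f"{prefix}{i + 1:03d}",
                sbp_true=sbp,
                dbp_true=dbp,
                heart_rate=float(rng.uniform(55.0, 90.0)),
                resp_rate=float(rng.uniform(12.0, 18.0)),
                skin_tier="II" if rng.random() < 0.53 else "III",
            )
        )
    return profiles


def make_training_data(
    n_profiles: int, seed_seq: np.random.SeedSequence, quality: str = "excellent", duration: float = 31.0
) -> FeatureMatrix:
    """Synthesize a training database: one recording (two 15-s windows) per
    drawn BP point, features extracted per window with ground truth attached.

    Profile diversity matters more than windows per profile: each profile
    contributes fresh nuisance covariates (heart rate, respiration, skin
    tier), which is what the regressor must learn to ignore."""
    rng = np.random.default_rng(seed_seq)
    records: list[PPGRecord] = []
    for i in range(n_profiles):
        sbp, dbp = _clip_bp(rng.normal(111.0, 14.0), rng.normal(67.0, 12.0))
        profile = SubjectProfile(
            subject_id=f"T{i + 1:03d}",
            sbp_true=sbp,
            dbp_true=dbp,
            heart_rate=float(rng.uniform(55.0, 80.0)),
            resp_rate=float(rng.uniform(12.0, 18.0)),
            skin_tier="II" if rng.random() < 0.5 else "III",
        )
        records.append(
            synth_recording(profile, duration, quality, rng_seed=int(rng.integers(2**31)))
        )
    return build_feature_matrix(records)


def train_models(config: RunConfig, seed_seq: np.random.SeedSequence) -> tuple[GPRModel, GPRModel]:
    """Pretrain on one synthetic database, then fine-tune on a second with the
    kernel scale and signal SD frozen at the shipped constants."""
    ss_pre, ss_fine = seed_seq.spawn(2)
    fixed = KernelParams(config.kernel_scale, config.signal_std, noise_std=1.0)
    pre = make_training_data(config.n_pretrain_profiles, ss_pre, config.quality)
    sbp_model = fit(pre, pre.sbp, init=fixed, fix_kernel=True, target="SBP")
    dbp_model = fit(pre, pre.dbp, init=fixed, fix_kernel=True, target="DBP")
    fine = make_training_data(config.n_finetune_profiles, ss_fine, config.quality)
    return (
        finetune(sbp_model, fine, fine.sbp),
        finetune(dbp_model, fine, fine.dbp),
    )


def features_for_recording(record: PPGRecord) -> FeatureVector:
    """Feature vector of the first 15-s window of a recording."""
    fm = build_feature_matrix([record])
    row = fm.X[0]
    return FeatureVector(*row, window_start=0.0, n_pulses=0)


def _measure_features(
    profile: SubjectProfile, sbp: float, dbp: float, quality: str, rng: np.random.Generator
) -> FeatureVector | None:
    """One test-device acquisition: a 16-s recording at the given true BP."""
    p = dc_replace(profile, sbp_true=sbp, dbp_true=dbp)
    for _ in range(3):  # rare segmentation failures get a fresh acquisition
        rec = synth_recording(p, 16.0, quality, rng_seed=int(rng.integers(2**31)))
        try:
            return features_for_recording(rec)
        except ValueError:
            continue
    return None


def simulate_study(config: RunConfig) -> StudyResult:
    """Run the full one-time-calibration validation study on synthetic subjects."""
    root = np.random.SeedSequence(config.seed)
    ss_cohort, ss_train, ss_study = root.spawn(3)
    cohort = make_cohort(config.n_subjects, np.random.default_rng(ss_cohort))
    sbp_model, dbp_model = train_models(config, ss_train)

    rng = np.random.default_rng(ss_study)
    readings: list[BPReading] = []
    truth_errors: dict[tuple[int, str], list[float]] = {}
    anchor_errors: list[tuple[float, float]] = []
    estimators: dict[str, CalibratedEstimator] = {}

    for profile in cohort:
        week_sbp, week_dbp = profile.sbp_true, profile.dbp_true
        for week in range(1, config.n_weeks + 1):
            if week > 1:  # slow physiological drift between weekly sessions
                week_sbp, week_dbp = _clip_bp(
                    week_sbp + rng.normal(0.0, config.weekly_drift_mmhg),
                    week_dbp + rng.normal(0.0, config.weekly_drift_mmhg),
                )
            for k, slot in enumerate(schedule(week)):
                t = k * 60.0
                slot_sbp, slot_dbp = _clip_bp(
                    week_sbp + rng.normal(0.0, config.slot_bp_jitter_mmhg),
                    week_dbp + rng.normal(0.0, config.slot_bp_jitter_mmhg),
                )
                if slot.device == "reference":
                    for obs in ("obs1", "obs2"):
                        readings.append(
                            BPReading(
                                subject_id=profile.subject_id, week=week, slot=slot.label,
                                device="reference", observer=obs,
                                sbp=slot_sbp + rng.normal(0.0, config.observer_noise_mmhg),
                                dbp=slot_dbp + rng.normal(0.0, config.observer_noise_mmhg),
                                time=t,
                            )
                        )
                    if slot.label == "BP1":
                        cuff = (
                            (readings[-2].sbp + readings[-1].sbp) / 2.0,
                            (readings[-2].dbp + readings[-1].dbp) / 2.0,
                        )
                    continue

                fv = _measure_features(profile, slot_sbp, slot_dbp, config.quality, rng)
                if fv is None:
                    log.warning("subject %s week %d %s: no usable signal", profile.subject_id, week, slot.label)
                    continue
                if slot.label == "BP2":
                    est = calibrate(sbp_model, dbp_model, cuff, fv, timestamp=t)
                    estimators[profile.subject_id] = est
                    bp = estimate_bp(est, fv)
                    anchor_errors.append((bp.sbp - cuff[0], bp.dbp - cuff[1]))
                else:
                    bp = estimate_bp(estimators[profile.subject_id], fv)
                    truth_errors.setdefault((week, "SBP"), []).append(bp.sbp - slot_sbp)
                    truth_errors.setdefault((week, "DBP"), []).append(bp.dbp - slot_dbp)
                readings.append(
                    BPReading(
                        subject_id=profile.subject_id, week=week, slot=slot.label,
                        device="test", observer="obs1", sbp=bp.sbp, dbp=bp.dbp, time=t,
                    )
                )

    pairs = build_pairs(readings)
    reports = weekly_report(pairs)
    return StudyResult(
        readings=readings,
        pairs=pairs,
        reports=reports,
        truth_errors={k: np.array(v) for k, v in truth_errors.items()},
        anchor_errors=anchor_errors,
        sbp_model=sbp_model,
        dbp_model=dbp_model,
    )


def run_pipeline(config: RunConfig) -> StudyResult:
    """Run the study and, if configured, write all artifacts to ``out_dir``."""
    result = simulate_study(config)
    if config.out_dir:
        from pathlib import Path

        from .recordio import write_pairs, write_readings
        from .validation import report_table

        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_readings(result.readings, out / "readings.csv")
        write_pairs(result.pairs, out / "pairs.csv")
        report_table(result.reports).to_csv(out / "report.csv", index=False)
    return result
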