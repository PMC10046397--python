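"""Plain-text file formats for PPG records, feature matrices and pairs.

A record is a two-column CSV (``t_seconds, amplitude``) with an optional JSON
sidecar (same stem, ``.json``) carrying the sampling rate, subject profile,
per-window ground truth and quality tier.  Without a sidecar the sampling
rate is inferred from the timestamps, which must be uniform to within 0.1%.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureMatrix
from .protocol import BPReading, ComparisonPair
from .synth import PPGRecord, SubjectProfile

__all__ = [
    "write_record",
    "read_record",
    "write_features",
    "read_features",
    "write_readings",
    "read_readings",
    "write_pairs",
    "read_pairs",
]

FS_TOLERANCE = 0.001  # relative jitter allowed in timestamps


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_record(record: PPGRecord, path: str | Path) -> None:
    path = Path(path)
    t = np.arange(len(record.samples)) / record.fs
    pd.DataFrame({"t_seconds": t, "amplitude": record.samples}).to_csv(path, index=False, float_format="%.17g")
    meta = {
        "fs": record.fs,
        "quality_tier": record.quality_tier,
        "truth": record.truth,
        "profile": asdict(record.profile) if record.profile else None,
        "beat_onsets": record.beat_onsets.tolist() if record.beat_onsets is not None else None,
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_record(path: str | Path) -> PPGRecord:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"t_seconds", "amplitude"} <= set(df.columns):
        raise ValueError("record CSV must have columns t_seconds, amplitude")
    t = df["t_seconds"].to_numpy(dtype=float)
    samples = df["amplitude"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) == 0:
        raise ValueError("record too short")
    mean_dt = float(np.mean(dt))
    if mean_dt <= 0 or np.max(np.abs(dt - mean_dt)) > FS_TOLERANCE * mean_dt:
        raise ValueError("non-uniform sampling beyond 0.1% tolerance")
    fs_inferred = 1.0 / mean_dt

    meta: dict = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
        fs = float(meta["fs"])
        if abs(fs - fs_inferred) > FS_TOLERANCE * fs:
            raise ValueError(f"declared fs {fs} inconsistent with timestamps ({fs_inferred:.3f})")
    else:
        fs = float(round(fs_inferred, 6))

    profile = SubjectProfile(**meta["profile"]) if meta.get("profile") else None
    truth = [tuple(w) for w in meta["truth"]] if meta.get("truth") else None
    onsets = np.array(meta["beat_onsets"], dtype=int) if meta.get("beat_onsets") else None
    return PPGRecord(
        samples=samples, fs=fs, truth=truth,
        quality_tier=meta.get("quality_tier"), beat_onsets=onsets, profile=profile,
    )


def write_features(fm: FeatureMatrix, path: str | Path) -> None:
    df = pd.DataFrame(fm.X, columns=fm.feature_names)
    if fm.sbp is not None:
        df["sbp_true"] = fm.sbp
    if fm.dbp is not None:
        df["dbp_true"] = fm.dbp
    df.to_csv(path, index=False, float_format="%.17g")


def read_features(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"feature CSV missing columns {missing}")
    return FeatureMatrix(
        X=df[FEATURE_NAMES].to_numpy(dtype=float),
        sbp=df["sbp_true"].to_numpy(dtype=float) if "sbp_true" in df else None,
        dbp=df["dbp_true"].to_numpy(dtype=float) if "dbp_true" in df else None,
    )


_READING_COLS = ["subject_id", "week", "slot", "device", "observer", "sbp", "dbp", "time"]


def write_readings(readings: list[BPReading], path: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in readings])[_READING_COLS].to_csv(path, index=False, float_format="%.17g")


def read_readings(path: str | Path) -> list[BPReading]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        BPReading(
            subject_id=str(row.subject_id), week=int(row.week), slot=row.slot,
            device=row.device, observer=row.observer,
            sbp=float(row.sbp), dbp=float(row.dbp), time=float(row.time),
        )
        for row in df.itertuples()
    ]


def write_pairs(pairs: list[ComparisonPair], path: str | Path) -> None:
    pd.DataFrame([asdict(p) for p in pairs]).to_csv(path, index=False, float_format="%.17g")


def read_pairs(path: str | Path) -> list[ComparisonPair]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        ComparisonPair(
            subject_id=str(row.subject_id), week=int(row.week),
            reference_slot=row.reference_slot,
            reference_sbp=float(row.reference_sbp), reference_dbp=float(row.reference_dbp),
            test_sbp=float(row.test_sbp), test_dbp=float(row.test_dbp),
        )
        for row in df.itertuples()
    ]
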