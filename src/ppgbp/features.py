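"""Ten-dimensional PPG waveform feature vector per 15-s window.

Eight features are classical pulse-contour descriptors: systolic and
diastolic areas (normalised by total area and by pulse amplitude), maximal
amplitude over time (an upstroke-slope proxy), systolic and diastolic times,
and the mean peak-to-peak interval.  Two further standard contour features —
pulse amplitude and pulse width at half amplitude — complete the
10-dimensional vector.

Per-pulse quantities are computed on the baseline-subtracted beat (foot
amplitude removed), the systolic region running foot → systolic peak and the
diastolic region systolic peak → beat end, areas by trapezoidal integration.
The window value of each feature is the median across the window's pulses,
which is robust to the occasional residual artifact beat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .signal import Pulse, acdc_split, detect_peaks, segment_pulses
from .synth import PPGRecord

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "FeatureMatrix",
    "extract_features",
    "window_pulses",
    "build_feature_matrix",
]

log = logging.getLogger(__name__)

WINDOW_S = 15.0

#: Fixed column order of the feature matrix.
FEATURE_NAMES = [
    "sys_area_over_total",
    "dia_area_over_total",
    "sys_area_over_amp",
    "dia_area_over_amp",
    "max_amp_over_time",
    "systolic_time",
    "diastolic_time",
    "mean_pp_interval",
    "pulse_amplitude",
    "pulse_width_half_amp",
]


@dataclass
class FeatureVector:
    """The 10 per-window features plus bookkeeping fields."""

    sys_area_over_total: float
    dia_area_over_total: float
    sys_area_over_amp: float
    dia_area_over_amp: float
    max_amp_over_time: float
    systolic_time: float
    diastolic_time: float
    mean_pp_interval: float
    pulse_amplitude: float
    pulse_width_half_amp: float
    window_start: float = 0.0
    n_pulses: int = 0

    @property
    def values(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


@dataclass
class FeatureMatrix:
    """N windows × 10 features, with optional per-window ground-truth BP."""

    X: np.ndarray
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    sbp: np.ndarray | None = None
    dbp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("column count does not match feature names")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        if self.X.shape[0] < 1:
            raise ValueError("feature matrix must have at least one row")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def nbits(self, bits_per_value: int = 32) -> int:
        """In-memory size of the matrix at the given float precision, in bits."""
        return self.n * self.X.shape[1] * bits_per_value


def _half_amp_width(x: np.ndarray, sys_idx: int, amp: float, fs: float) -> float:
    """Width at half amplitude with linear interpolation at the crossings."""
    half = 0.5 * amp
    # upstroke crossing: last sample below half before the peak
    left = sys_idx
    while left > 0 and x[left - 1] >= half:
        left -= 1
    if left == 0 or x[left] <= x[left - 1]:
        t_left = float(left)
    else:
        t_left = (left - 1) + (half - x[left - 1]) / (x[left] - x[left - 1])
    # downstroke crossing: first sample below half after the peak
    right = sys_idx
    while right < len(x) - 1 and x[right + 1] >= half:
        right += 1
    if right == len(x) - 1 or x[right + 1] >= x[right]:
        t_right = float(right)
    else:
        t_right = right + (x[right] - half) / (x[right] - x[right + 1])
    return max(t_right - t_left, 1.0) / fs


def extract_features(pulses: list[Pulse], fs: float, window_start: float = 0.0) -> FeatureVector:
    """Compute the 10-feature vector for the pulses of one 15-s window.

    Requires at least two usable pulses (the peak-to-peak interval needs a
    pair).  Raises ``ValueError`` for windows that cannot be characterised.
    """
    usable = [p if p.systolic_peak_index is not None else detect_peaks(p) for p in pulses]
    usable = [p for p in usable if p.valid and p.systolic_peak_index is not None]
    if len(usable) < 2:
        raise ValueError(f"window at {window_start:.0f}s rejected: fewer than 2 usable pulses")

    dt = 1.0 / fs
    per_pulse: list[np.ndarray] = []
    peak_times: list[float] = []
    for p in usable:
        # remove per-beat baseline drift: subtract the foot-to-end chord so
        # both ends of the beat sit at zero (standard pulse-contour practice)
        raw = p.samples
        n = len(raw)
        chord = raw[p.foot_index] + (raw[-1] - raw[p.foot_index]) * (
            np.arange(n) - p.foot_index
        ) / max(n - 1 - p.foot_index, 1)
        x = raw - chord
        sys_idx = p.systolic_peak_index
        amp = x[sys_idx]
        if amp <= 0:
            continue
        sys_area = float(np.trapezoid(x[p.foot_index : sys_idx + 1], dx=dt))
        dia_area = float(np.trapezoid(x[sys_idx:], dx=dt))
        total = sys_area + dia_area
        if total <= 0:
            continue
        t_sys = (sys_idx - p.foot_index) * dt
        t_dia = (len(x) - 1 - sys_idx) * dt
        if t_sys <= 0 or t_dia <= 0:
            continue
        per_pulse.append(
            np.array(
                [
                    sys_area / total,
                    dia_area / total,
                    sys_area / amp,
                    dia_area / amp,
                    amp / t_sys,
                    t_sys,
                    t_dia,
                    np.nan,  # interval filled from peak-time differences below
                    amp,
                    _half_amp_width(x, sys_idx, amp, fs),
                ]
            )
        )
        peak_times.append((p.start_index + sys_idx) * dt)

    if len(per_pulse) < 2:
        raise ValueError(f"window at {window_start:.0f}s rejected: fewer than 2 usable pulses")
    med = np.median(np.vstack(per_pulse), axis=0)
    med[7] = float(np.mean(np.diff(sorted(peak_times))))
    return FeatureVector(*med, window_start=window_start, n_pulses=len(per_pulse))


def window_pulses(pulses: list[Pulse], fs: float, duration: float, window_s: float = WINDOW_S) -> list[list[Pulse]]:
    """Assign pulses (by foot time) to non-overlapping windows aligned to t=0."""
    n_windows = int(duration // window_s)
    out: list[list[Pulse]] = [[] for _ in range(n_windows)]
    for p in pulses:
        w = int((p.start_index / fs) // window_s)
        if 0 <= w < n_windows:
            out[w].append(p)
    return out


def build_feature_matrix(records: list[PPGRecord], window_s: float = WINDOW_S) -> FeatureMatrix:
    """Run the signal pipeline over records and assemble the N×10 matrix.

    One row per accepted 15-s window; windows with fewer than two usable
    pulses are logged and skipped.  Ground-truth BP, where the records carry
    it, is aligned row-wise in ``sbp``/``dbp``.
    """
    rows: list[np.ndarray] = []
    sbp: list[float] = []
    dbp: list[float] = []
    have_truth = all(r.truth is not None for r in records)
    for rec in records:
        ac, _ = acdc_split(rec)
        pulses = [detect_peaks(p) for p in segment_pulses(ac, rec.fs)]
        for w, wp in enumerate(window_pulses(pulses, rec.fs, rec.duration, window_s)):
            try:
                fv = extract_features(wp, rec.fs, window_start=w * window_s)
            except ValueError as exc:
                log.info("skipping window: %s", exc)
                continue
            rows.append(fv.values)
            if have_truth and rec.truth is not None and w < len(rec.truth):
                sbp.append(rec.truth[w][0])
                dbp.append(rec.truth[w][1])
    if not rows:
        raise ValueError("no window yielded a usable feature vector")
    X = np.vstack(rows)
    return FeatureMatrix(
        X=X,
        sbp=np.array(sbp) if have_truth and len(sbp) == len(rows) else None,
        dbp=np.array(dbp) if have_truth and len(dbp) == len(rows) else None,
    )
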