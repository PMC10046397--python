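"""PPG signal conditioning: AC/DC decomposition, beat segmentation, landmark
detection, and per-pulse quality grading.

The DC component (tissue absorption, venous pooling, respiration) is removed
with a zero-phase low-pass filter whose cutoff sits below the cardiac band;
the AC residual carries the pulsatile waveform.  Beats are delimited
foot-to-foot, the systolic peak is the post-foot global maximum, and the
diastolic peak is the most prominent later local maximum.  Quality grades
mirror the perceptual fair/good/excellent scale: excellent pulses show both
peaks clearly above the noise floor, good pulses only the systolic peak,
fair pulses neither reliably.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .synth import PPGRecord

__all__ = [
    "Pulse",
    "acdc_split",
    "segment_pulses",
    "detect_peaks",
    "grade_quality",
    "pulse_snr_db",
]

DC_CUTOFF_HZ = 0.5           # separates respiration (<0.4 Hz) from cardiac (>0.7 Hz)
MIN_BEAT_S = 60.0 / 180.0    # physiological beat-duration window, 180 bpm cap
MAX_BEAT_S = 60.0 / 40.0     # 40 bpm floor
DIASTOLIC_PROMINENCE_FRAC = 0.05   # of pulse amplitude
EXCELLENT_SNR_DB = 12.0
GOOD_SNR_DB = 6.0
_SMOOTH_CUTOFF_HZ = 10.0     # cardiac morphology lives below ~10 Hz


@dataclass
class Pulse:
    """One segmented heartbeat of AC signal with waveform landmarks.

    Indices are 0-based into ``samples``; the beat interval is
    foot-inclusive, next-foot-exclusive.  ``start_index`` locates the foot in
    the parent recording so that inter-beat intervals can be computed.
    """

    samples: np.ndarray
    fs: float
    foot_index: int = 0
    systolic_peak_index: int | None = None
    diastolic_peak_index: int | None = None
    quality: str | None = None
    start_index: int = 0
    valid: bool = True

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


def acdc_split(record: PPGRecord, cutoff_hz: float = DC_CUTOFF_HZ) -> tuple[np.ndarray, np.ndarray]:
    """Split a record into (AC, DC) with ``AC + DC == samples`` exactly.

    DC is a zero-phase (forward-backward) second-order Butterworth low-pass of
    the input; AC is defined as the residual, so reconstruction is exact by
    construction.
    """
    x = record.samples
    if len(x) < 2.0 * record.fs:
        raise ValueError("record shorter than 2 s: too short for DC filter warm-up")
    sos = sps.butter(4, cutoff_hz, btype="low", fs=record.fs, output="sos")
    dc = sps.sosfiltfilt(sos, x)
    return x - dc, dc


def segment_pulses(ac: np.ndarray, fs: float) -> list[Pulse]:
    """Delimit beats foot-to-foot in an AC trace.

    Feet are the local minima immediately preceding upstrokes whose slope
    exceeds an adaptive threshold (40% of the 95th percentile of positive
    slopes).  Candidate beats with duration outside the physiological
    [60/180, 60/40] s window are discarded; a trailing partial beat (no
    closing foot) is excluded.
    """
    ac = np.asarray(ac, dtype=float)
    if len(ac) < 3:
        return []
    # foot detection runs on a lightly smoothed copy: differentiation amplifies
    # wideband noise by fs, so raw slopes would trigger spurious upstrokes
    if len(ac) > 15:
        sos = sps.butter(2, _SMOOTH_CUTOFF_HZ, btype="low", fs=fs, output="sos")
        smooth = sps.sosfiltfilt(sos, ac)
    else:
        smooth = ac
    slope = np.diff(smooth) * fs
    pos = slope[slope > 0]
    if pos.size == 0:
        return []
    thresh = 0.4 * np.percentile(pos, 95)
    if thresh <= 0:
        return []
    # rising edges of the above-threshold slope mask mark upstroke starts
    above = slope > thresh
    edges = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        edges = np.insert(edges, 0, 0)

    # prominent waveform minima are the foot candidates; the prominence gate
    # rejects noise ripples along the diastolic run-off
    minima, _ = sps.find_peaks(-smooth, prominence=0.05 * np.ptp(smooth))

    min_gap = int(MIN_BEAT_S * fs)
    feet: list[int] = []
    for e in edges:
        prior = minima[minima <= e]
        if prior.size and e - prior[-1] <= int(MAX_BEAT_S * fs):
            i = int(prior[-1])
        else:
            # no prominent minimum (e.g. record starts mid-foot): walk back
            i = e
            while i > 0 and smooth[i - 1] <= smooth[i]:
                i -= 1
        # smoothing smears the sharp onset; refine on the raw trace, then walk
        # forward down any near-flat diastolic tail to the true bottom of the V
        lo = max(i - 5, 0)
        hi = min(i + int(0.12 * fs) + 1, len(ac))
        win = ac[lo:hi]
        i = lo + int(np.argmin(win))
        tol = 0.01 * float(np.ptp(win)) if win.size else 0.0
        while i + 1 < hi and ac[i + 1] <= ac[i] + tol:
            i += 1
        if not feet or i - feet[-1] >= min_gap:
            feet.append(i)

    pulses: list[Pulse] = []
    for a, b in zip(feet[:-1], feet[1:]):
        dur = (b - a) / fs
        if MIN_BEAT_S <= dur <= MAX_BEAT_S:
            pulses.append(Pulse(samples=ac[a:b].copy(), fs=fs, foot_index=0, start_index=a))
    return pulses


def detect_peaks(pulse: Pulse) -> Pulse:
    """Fill systolic and diastolic peak indices on a segmented pulse.

    The systolic peak is the global maximum after the foot.  The diastolic
    peak is the most prominent local maximum after the systolic peak whose
    prominence exceeds 5% of the pulse amplitude; absent such a maximum the
    field stays ``None``.  A pulse whose global maximum is not the earliest
    major peak (diastolic lobe taller than systolic) is flagged invalid.
    """
    x = pulse.samples
    if len(x) < 3:
        return replace(pulse, valid=False)
    sys_idx = int(np.argmax(x[pulse.foot_index:])) + pulse.foot_index
    amplitude = x[sys_idx] - x[pulse.foot_index]
    dia_idx: int | None = None
    if sys_idx + 2 < len(x) and amplitude > 0:
        tail = x[sys_idx:]
        peaks, props = sps.find_peaks(tail, prominence=DIASTOLIC_PROMINENCE_FRAC * amplitude)
        if peaks.size:
            dia_idx = sys_idx + int(peaks[np.argmax(props["prominences"])])

    valid = True
    if dia_idx is not None and x[dia_idx] >= x[sys_idx]:
        valid = False  # diastolic lobe dominating the systolic one
    # a "systolic" peak in the latter half with no earlier major peak suggests
    # the true systolic lobe was swamped — flag rather than silently swap
    if sys_idx - pulse.foot_index > 0.6 * len(x):
        valid = False
    return replace(pulse, systolic_peak_index=sys_idx, diastolic_peak_index=dia_idx, valid=valid)


def pulse_snr_db(pulse: Pulse) -> float:
    """Estimate per-pulse SNR: smoothed-waveform power over high-frequency residual.

    The waveform estimate is a zero-phase low-pass at 10 Hz (cardiac
    morphology band); the residual is everything above it.
    """
    x = pulse.samples - np.mean(pulse.samples)
    if len(x) < 15 or not np.any(x):
        return -np.inf
    sos = sps.butter(2, _SMOOTH_CUTOFF_HZ, btype="low", fs=pulse.fs, output="sos")
    smooth = sps.sosfiltfilt(sos, x, padlen=min(len(x) - 1, 12))
    resid = x - smooth
    p_sig = float(np.mean(np.square(smooth)))
    p_res = float(np.mean(np.square(resid)))
    if p_res == 0.0:
        return np.inf
    return 10.0 * np.log10(p_sig / p_res) if p_sig > 0 else -np.inf


def grade_quality(
    pulse: Pulse,
    excellent_snr_db: float = EXCELLENT_SNR_DB,
    good_snr_db: float = GOOD_SNR_DB,
) -> str:
    """Grade a pulse fair / good / excellent.

    Excellent: systolic and diastolic peaks both detected and SNR at or above
    the excellent threshold.  Good: systolic peak detected with moderate SNR
    but no distinguishable diastolic peak (or SNR below the excellent bar).
    Fair: peaks not reliably distinguishable from noise.
    """
    if pulse.systolic_peak_index is None:
        pulse = detect_peaks(pulse)
    snr = pulse_snr_db(pulse)
    both = pulse.valid and pulse.systolic_peak_index is not None and pulse.diastolic_peak_index is not None
    sys_only = pulse.valid and pulse.systolic_peak_index is not None
    if both and snr >= excellent_snr_db:
        return "excellent"
    if sys_only and snr >= good_snr_db:
        return "good"
    return "fair"
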