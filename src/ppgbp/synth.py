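"""Synthetic reflective-PPG generator with known ground-truth blood pressure.

Produces 256 Hz single-channel PPG traces built from a two-Gaussian beat
phantom (systolic lobe plus a smaller, later diastolic lobe) riding on a slow
DC baseline (constant tissue offset plus a respiration sinusoid).  A
deterministic, injective map from (SBP, DBP) to beat morphology gives every
downstream stage — segmentation, feature extraction, regression, calibration,
validation — an exact ground truth to recover.

Quality tiers are operationalised as additive white-noise SNR levels
(excellent 30 dB, good 15 dB, fair 5 dB); the fair tier additionally suffers
random baseline jumps emulating micromotion artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_FS",
    "QUALITY_SNR_DB",
    "SubjectProfile",
    "PPGRecord",
    "MorphologyParams",
    "bp_to_morphology",
    "synth_pulse",
    "synth_recording",
]

DEFAULT_FS = 256.0
WINDOW_S = 15.0

#: White-noise SNR (dB, relative to AC rms) assigned to each signal-quality tier.
#: "noiseless" is a synthetic-only tier used as a ground-truth oracle in tests.
QUALITY_SNR_DB = {"excellent": 30.0, "good": 15.0, "fair": 5.0, "noiseless": np.inf}

#: Relative AC amplitude per skin phototype (darker skin absorbs more green light).
SKIN_TIER_AMPLITUDE = {"II": 1.0, "III": 0.85}

# Morphology constants (seconds / dimensionless), nominal at a 60 bpm beat.
# The systolic lobe center sits 1/_SIGMA_SYS_FRAC ≈ 2.5 lobe widths after the
# beat onset, so the upstroke begins immediately at the foot and the onset is
# a sharp waveform minimum that segmentation can localise unambiguously.
_T_SYS_REF = 0.17        # foot-to-systolic-peak time at SBP 120 mmHg
_T_SYS_SLOPE = -0.0008   # s per mmHg of SBP (faster ejection at higher SBP)
_SIGMA_SYS_FRAC = 0.40   # systolic lobe width as a fraction of t_sys
_AMP_RATIO_REF = 0.25    # diastolic/systolic lobe amplitude at DBP 80 mmHg
_AMP_RATIO_LOGSLOPE = 0.03  # per mmHg of DBP (exponential, stays in (0, 1))
_DIA_DELAY_REF = 0.26    # systolic-peak to diastolic-peak delay at DBP 80, s
_DIA_DELAY_SLOPE = 0.0005  # s per mmHg of DBP (later reflected wave)
_SIGMA_DIA_REF = 0.070   # diastolic lobe width at DBP 80, s
_SIGMA_DIA_SLOPE = 0.0005  # s per mmHg of DBP
_NOMINAL_BEAT_S = 0.80   # beats shorter than this have morphology compressed
_DC_OFFSET_RATIO = 10.0  # DC offset : AC amplitude, typical reflective PPG
_RESP_AMP_RATIO = 0.5    # respiration sinusoid amplitude : AC amplitude
_SAWTOOTH_FRAC = 0.12    # late-diastolic run-off amplitude as a fraction of
                         # systolic amplitude; decays with a fixed time
                         # constant, making the beat onset a sharp waveform
                         # minimum while keeping its area beat-length-invariant
_RUNOFF_TAU_S = 0.22     # run-off decay time constant, s


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth physiology for one synthetic subject."""

    subject_id: str
    sbp_true: float
    dbp_true: float
    heart_rate: float = 70.0
    resp_rate: float = 15.0
    skin_tier: str = "II"

    def __post_init__(self) -> None:
        if not (60.0 <= self.sbp_true <= 200.0):
            raise ValueError(f"SBP {self.sbp_true} outside supported range [60, 200] mmHg")
        if not (40.0 <= self.dbp_true <= 120.0):
            raise ValueError(f"DBP {self.dbp_true} outside supported range [40, 120] mmHg")
        if self.sbp_true <= self.dbp_true:
            raise ValueError("SBP must exceed DBP")
        if not (40.0 <= self.heart_rate <= 180.0):
            raise ValueError(f"heart rate {self.heart_rate} outside [40, 180] bpm")
        if self.skin_tier not in SKIN_TIER_AMPLITUDE:
            raise ValueError(f"unknown skin tier {self.skin_tier!r}")


@dataclass
class PPGRecord:
    """A uniformly sampled PPG trace, optionally with ground truth attached.

    ``truth`` holds one (SBP, DBP) pair per non-overlapping 15-s window;
    ``beat_onsets`` is the generator's own log of beat-start sample indices
    and serves as the oracle for segmentation tests.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    truth: list[tuple[float, float]] | None = None
    quality_tier: str | None = None
    beat_onsets: np.ndarray | None = None
    profile: SubjectProfile | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class MorphologyParams:
    """Two-Gaussian beat-phantom parameters (times in s from the beat foot)."""

    amp_sys: float
    amp_dia: float
    t_sys: float
    t_dia: float
    sigma_sys: float
    sigma_dia: float

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Closed-form beat waveform on a zero baseline."""
        return self.amp_sys * np.exp(-0.5 * ((t - self.t_sys) / self.sigma_sys) ** 2) + (
            self.amp_dia * np.exp(-0.5 * ((t - self.t_dia) / self.sigma_dia) ** 2)
        )

    def compressed(self, beat_s: float) -> "MorphologyParams":
        """Time-compress the template for beats shorter than the nominal period."""
        c = min(1.0, beat_s / _NOMINAL_BEAT_S)
        return MorphologyParams(
            amp_sys=self.amp_sys,
            amp_dia=self.amp_dia,
            t_sys=self.t_sys * c,
            t_dia=self.t_dia * c,
            sigma_sys=self.sigma_sys * c,
            sigma_dia=self.sigma_dia * c,
        )


def bp_to_morphology(sbp: float, dbp: float, amp_scale: float = 1.0) -> MorphologyParams:
    """Map (SBP, DBP) to beat morphology, deterministically and injectively.

    Monotonicities (documented contract):

    * systolic time ``t_sys`` and systolic lobe width strictly *decrease* with
      SBP — a stiffer, faster ejection at higher systolic pressure;
    * diastolic/systolic amplitude ratio (hence diastolic-to-systolic area
      ratio) and the diastolic-peak delay strictly *increase* with DBP — a
      stronger, later reflected wave at higher diastolic pressure.

    SBP is read back from ``t_sys`` (or the lobe width) and DBP from the
    amplitude ratio, so the map is injective over the supported range
    (SBP 60–200, DBP 40–120 mmHg).
    """
    if not (60.0 <= sbp <= 200.0) or not (40.0 <= dbp <= 120.0):
        raise ValueError(f"BP ({sbp}, {dbp}) outside supported range")
    if sbp <= dbp:
        raise ValueError("SBP must exceed DBP")
    t_sys = _T_SYS_REF + _T_SYS_SLOPE * (sbp - 120.0)
    amp_ratio = _AMP_RATIO_REF * np.exp(_AMP_RATIO_LOGSLOPE * (dbp - 80.0))
    return MorphologyParams(
        amp_sys=amp_scale,
        amp_dia=amp_scale * amp_ratio,
        t_sys=t_sys,
        t_dia=t_sys + _DIA_DELAY_REF + _DIA_DELAY_SLOPE * (dbp - 80.0),
        sigma_sys=_SIGMA_SYS_FRAC * t_sys,
        sigma_dia=_SIGMA_DIA_REF + _SIGMA_DIA_SLOPE * (dbp - 80.0),
    )


def _render_beat(morph: MorphologyParams, beat_s: float, fs: float) -> np.ndarray:
    """Two-Gaussian beat plus the exponential late-diastolic run-off."""
    n = int(round(beat_s * fs))
    t = np.arange(n) / fs
    return morph.evaluate(t) + _SAWTOOTH_FRAC * morph.amp_sys * np.exp(-t / _RUNOFF_TAU_S)


def _beat_template(profile: SubjectProfile, fs: float) -> tuple[np.ndarray, MorphologyParams]:
    beat_s = 60.0 / profile.heart_rate
    morph = bp_to_morphology(
        profile.sbp_true, profile.dbp_true, amp_scale=SKIN_TIER_AMPLITUDE[profile.skin_tier]
    ).compressed(beat_s)
    return _render_beat(morph, beat_s, fs), morph


def _noise_std(clean_ac: np.ndarray, quality: str) -> float:
    if quality not in QUALITY_SNR_DB:
        raise ValueError(f"invalid quality tier {quality!r}; expected one of {sorted(QUALITY_SNR_DB)}")
    rms = float(np.sqrt(np.mean(np.square(clean_ac))))
    return rms / (10.0 ** (QUALITY_SNR_DB[quality] / 20.0))


def synth_pulse(
    profile: SubjectProfile,
    quality: str = "excellent",
    rng_seed: int = 0,
    fs: float = DEFAULT_FS,
    amp_scale: float | None = None,
) -> np.ndarray:
    """One beat of AC signal on a zero baseline, with tier-level white noise.

    ``amp_scale`` overrides the skin-tier amplitude (0 yields a flat beat,
    since the noise floor is defined relative to the AC signal power).
    """
    if amp_scale is None:
        beat, _ = _beat_template(profile, fs)
    else:
        beat_s = 60.0 / profile.heart_rate
        morph = bp_to_morphology(profile.sbp_true, profile.dbp_true, amp_scale=amp_scale).compressed(beat_s)
        beat = _render_beat(morph, beat_s, fs)
    sigma = _noise_std(beat, quality) if np.any(beat) else 0.0
    rng = np.random.default_rng(rng_seed)
    return beat + rng.normal(0.0, sigma, size=beat.shape) if sigma > 0 else beat.copy()


def synth_recording(
    profile: SubjectProfile,
    duration: float,
    quality: str = "excellent",
    rng_seed: int = 0,
    fs: float = DEFAULT_FS,
) -> PPGRecord:
    """Synthesize a full recording: concatenated beats plus a DC baseline.

    The AC component is a train of identical two-lobe beats; the DC component
    is a constant offset plus a respiration sinusoid at ``profile.resp_rate``,
    with a DC:AC amplitude ratio of about 10:1.  All randomness (white noise,
    fair-tier baseline jumps) flows from ``rng_seed``.
    """
    if quality not in QUALITY_SNR_DB:
        raise ValueError(f"invalid quality tier {quality!r}; expected one of {sorted(QUALITY_SNR_DB)}")
    beat_s = 60.0 / profile.heart_rate
    if duration < beat_s:
        raise ValueError("duration must cover at least one beat")
    n_total = int(round(duration * fs))
    beat, _ = _beat_template(profile, fs)
    n_beat = len(beat)
    n_beats = math.ceil(n_total / n_beat)
    ac = np.tile(beat, n_beats)[:n_total]
    onsets = np.arange(0, n_total - n_beat + 1, n_beat)

    amp = SKIN_TIER_AMPLITUDE[profile.skin_tier]
    t = np.arange(n_total) / fs
    dc = _DC_OFFSET_RATIO * amp + _RESP_AMP_RATIO * amp * np.sin(
        2.0 * np.pi * (profile.resp_rate / 60.0) * t
    )

    rng = np.random.default_rng(rng_seed)
    sigma = _noise_std(beat, quality)
    noise = rng.normal(0.0, sigma, size=n_total) if sigma > 0 else 0.0

    samples = ac + dc + noise
    if quality == "fair":
        # micromotion artifact: step discontinuities in the baseline, ~1 per 10 s
        n_jumps = rng.poisson(0.1 * duration)
        for _ in range(n_jumps):
            at = rng.integers(0, n_total)
            samples[at:] += rng.uniform(0.5, 2.0) * amp * rng.choice([-1.0, 1.0])

    n_windows = int(duration // WINDOW_S)
    truth = [(profile.sbp_true, profile.dbp_true) for _ in range(n_windows)] or None
    return PPGRecord(
        samples=samples,
        fs=fs,
        truth=truth,
        quality_tier=quality,
        beat_onsets=onsets,
        profile=profile,
    )
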