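"""Cuff-reference calibration: anchoring relative PPG-based BP estimates to
absolute pressure.

PPG waveform features track *changes* in blood pressure, not its absolute
level, so a one-time reading from a cuffed reference monitor is used to
anchor the regressor: the offset between the cuff reading and the model's
prediction at the calibration operating point is stored per target and added
to every subsequent estimate.  Immediately after calibration the estimate at
the calibration features therefore equals the cuff reading exactly.

An eight-step deterministic session state machine mirrors the device's
auto-calibration workflow (cuff measurement → wireless transfer → model
update → acknowledgement), rejecting out-of-order events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureVector
from .gpr import GPRModel, predict_one

__all__ = [
    "CalibrationRecord",
    "CalibratedEstimator",
    "BPEstimate",
    "calibrate",
    "estimate_bp",
    "CalibrationSession",
    "SESSION_STATES",
    "SESSION_EVENTS",
]


@dataclass(frozen=True)
class CalibrationRecord:
    """One cuff reading and the PPG features observed at calibration time."""

    cuff_sbp: float
    cuff_dbp: float
    features_at_cal: FeatureVector
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if self.cuff_sbp <= self.cuff_dbp:
            raise ValueError("cuff SBP must exceed cuff DBP (possible data-entry error)")
        if not np.all(np.isfinite(self.features_at_cal.values)):
            raise ValueError("calibration features must be finite")


@dataclass(frozen=True)
class BPEstimate:
    """An absolute BP estimate with posterior uncertainty and a validity flag."""

    sbp: float
    dbp: float
    sbp_std: float
    dbp_std: float
    valid: bool = True


@dataclass
class CalibratedEstimator:
    """A pair of GP models anchored to a cuff reading by additive offsets."""

    sbp_model: GPRModel
    dbp_model: GPRModel
    cal: CalibrationRecord | None = None
    offsets: tuple[float, float] | None = None

    @property
    def is_calibrated(self) -> bool:
        return self.cal is not None and self.offsets is not None


def calibrate(
    sbp_model: GPRModel,
    dbp_model: GPRModel,
    cuff: tuple[float, float],
    features: FeatureVector,
    timestamp: float = 0.0,
) -> CalibratedEstimator:
    """Anchor the models: offset = cuff reading − model prediction at the
    calibration features, per target.  The most recent calibration wins."""
    cal = CalibrationRecord(cuff_sbp=cuff[0], cuff_dbp=cuff[1], features_at_cal=features, timestamp=timestamp)
    x = features.values
    pred_sbp, _ = predict_one(sbp_model, x)
    pred_dbp, _ = predict_one(dbp_model, x)
    return CalibratedEstimator(
        sbp_model=sbp_model,
        dbp_model=dbp_model,
        cal=cal,
        offsets=(cal.cuff_sbp - pred_sbp, cal.cuff_dbp - pred_dbp),
    )


def estimate_bp(est: CalibratedEstimator, features: FeatureVector) -> BPEstimate:
    """Absolute BP estimate: posterior mean plus the stored calibration offset.

    The posterior standard deviation passes through unchanged (a constant
    shift has no uncertainty of its own).  A physiologically impossible
    result (SBP ≤ DBP) is flagged invalid rather than silently corrected.
    """
    if not est.is_calibrated:
        raise ValueError("estimator is uncalibrated: absolute BP requires a cuff calibration")
    x = features.values
    m_s, s_s = predict_one(est.sbp_model, x)
    m_d, s_d = predict_one(est.dbp_model, x)
    sbp = m_s + est.offsets[0]
    dbp = m_d + est.offsets[1]
    return BPEstimate(sbp=sbp, dbp=dbp, sbp_std=s_s, dbp_std=s_d, valid=sbp > dbp)


# ---------------------------------------------------------------------------
# Calibration-session workflow
# ---------------------------------------------------------------------------

#: The eight workflow states, in happy-path order (plus the aborted sink).
SESSION_STATES = (
    "default",        # estimator in default mode, no calibration in progress
    "ready",          # calibration mode activated
    "measured",       # cuff reading taken
    "transferred",    # reading transferred to the wearable
    "calibrating",    # model offset being computed (auto-step)
    "awaiting_ack",   # waiting for user confirmation (auto-step)
    "calibrated",     # terminal: calibration complete
    "aborted",        # terminal sink for out-of-order events
)

SESSION_EVENTS = ("start", "cuff_reading", "transfer", "ack")

# external-event transitions; "transfer" auto-advances through the two
# internal steps (calibrating, awaiting_ack), which are recorded in the log
_TRANSITIONS: dict[tuple[str, str], str] = {
    ("default", "start"): "ready",
    ("ready", "cuff_reading"): "measured",
    ("measured", "transfer"): "awaiting_ack",
    ("awaiting_ack", "ack"): "calibrated",
    ("calibrated", "ack"): "calibrated",  # duplicate ack is idempotent
}


class CalibrationSession:
    """Deterministic eight-state calibration workflow.

    Events must arrive in order (start → cuff_reading → transfer → ack); any
    out-of-order event aborts the session with a diagnostic.  A duplicate
    acknowledgement in the terminal state is idempotent.  The step ``log``
    records every state entered, including the two automatic internal steps
    between transfer and acknowledgement.
    """

    def __init__(self) -> None:
        self.state = "default"
        self.log: list[str] = ["default"]
        self.diagnostic: str | None = None

    def dispatch(self, event: str) -> str:
        if event not in SESSION_EVENTS:
            raise ValueError(f"unknown event {event!r}")
        if self.state == "aborted":
            return self.state
        nxt = _TRANSITIONS.get((self.state, event))
        if nxt is None:
            self.diagnostic = f"event {event!r} not permitted in state {self.state!r}"
            self.state = "aborted"
            self.log.append("aborted")
            return self.state
        if nxt == self.state:  # idempotent replay: no state change, no log entry
            return self.state
        if (self.state, event) == ("measured", "transfer"):
            self.log.extend(["transferred", "calibrating", "awaiting_ack"])
        else:
            self.log.append(nxt)
        self.state = nxt
        return self.state

    @property
    def is_calibrated(self) -> bool:
        return self.state == "calibrated"
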