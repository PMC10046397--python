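"""Same-arm sequential measurement schedule and test/reference pairing.

The validation protocol alternates readings between the reference
sphygmomanometer (odd slots BP1, BP3, BP5, BP7) and the cuffless test device
(even slots BP2, BP4, BP6, BP8), with at least 60 s between readings.  BP1
and BP2 are the calibration pair, taken in week 1 only; weeks 2–5 run BP3
through BP8.  For analysis, the average of the two blinded observers'
reference readings at BP3/BP5/BP7 is paired with the test reading that
immediately follows (BP4/BP6/BP8), giving three comparison pairs per subject
per week — 90 pairs per week for a complete 30-subject cohort.  Calibration
slots never form a pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

__all__ = ["Slot", "BPReading", "ComparisonPair", "schedule", "build_pairs", "ALL_SLOTS"]

log = logging.getLogger(__name__)

ALL_SLOTS = tuple(f"BP{i}" for i in range(1, 9))
_REFERENCE_SLOTS = ("BP1", "BP3", "BP5", "BP7")
_CALIBRATION_SLOTS = ("BP1", "BP2")
_PAIRED_REFERENCE_SLOTS = ("BP3", "BP5", "BP7")
MIN_INTERVAL_S = 60.0
BLINDED_OBSERVERS = ("obs1", "obs2")


@dataclass(frozen=True)
class Slot:
    """One position in the measurement sequence."""

    label: str
    device: str           # "reference" or "test"
    calibration: bool

    def __post_init__(self) -> None:
        if self.label not in ALL_SLOTS:
            raise ValueError(f"unknown slot {self.label!r}")


@dataclass(frozen=True)
class BPReading:
    """One BP reading in a protocol slot."""

    subject_id: str
    week: int
    slot: str
    device: str           # "reference" or "test"
    observer: str         # obs1 / obs2 / supervisor
    sbp: float
    dbp: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.week <= 5):
            raise ValueError(f"week {self.week} outside 1..5")
        if self.slot not in ALL_SLOTS:
            raise ValueError(f"unknown slot {self.slot!r}")
        expected = "reference" if self.slot in _REFERENCE_SLOTS else "test"
        if self.device != expected:
            raise ValueError(f"slot {self.slot} must be a {expected} reading")
        if self.week >= 2 and self.slot in _CALIBRATION_SLOTS:
            raise ValueError("calibration slots BP1/BP2 only occur in week 1")


@dataclass(frozen=True)
class ComparisonPair:
    """One reference-vs-test comparison (observer-averaged reference)."""

    subject_id: str
    week: int
    reference_slot: str
    reference_sbp: float
    reference_dbp: float
    test_sbp: float
    test_dbp: float

    def __post_init__(self) -> None:
        if self.reference_slot in _CALIBRATION_SLOTS:
            raise ValueError("calibration slots never form a comparison pair")


def schedule(week: int) -> list[Slot]:
    """Ordered slot list for the given week.

    Week 1 runs the full BP1..BP8 sequence, alternating reference and test
    and starting with the reference device, with BP1/BP2 tagged as the
    calibration pair.  Weeks 2–5 skip calibration and run BP3..BP8.
    """
    if not (1 <= week <= 5):
        raise ValueError(f"week {week} outside the 5-week protocol")
    first = 1 if week == 1 else 3
    return [
        Slot(
            label=f"BP{i}",
            device="reference" if i % 2 == 1 else "test",
            calibration=f"BP{i}" in _CALIBRATION_SLOTS,
        )
        for i in range(first, 9)
    ]


def build_pairs(readings: list[BPReading]) -> list[ComparisonPair]:
    """Pair each observer-averaged reference slot with the following test slot.

    For every subject-week, the mean of the two blinded observers' readings
    at BP3/BP5/BP7 is compared with the test reading at BP4/BP6/BP8.  A pair
    with a missing observer or test reading is dropped and logged; supervisor
    readings never enter the pairing.
    """
    by_key: dict[tuple[str, int], list[BPReading]] = {}
    for r in readings:
        by_key.setdefault((r.subject_id, r.week), []).append(r)

    pairs: list[ComparisonPair] = []
    for (subject, week), group in sorted(by_key.items()):
        for ref_slot in _PAIRED_REFERENCE_SLOTS:
            test_slot = f"BP{int(ref_slot[2]) + 1}"
            obs = {
                r.observer: r
                for r in group
                if r.slot == ref_slot and r.observer in BLINDED_OBSERVERS
            }
            tests = [r for r in group if r.slot == test_slot and r.observer != "supervisor"]
            if len(obs) < 2 or not tests:
                log.info("dropping pair %s week %s %s: missing reading", subject, week, ref_slot)
                continue
            t = tests[0]
            pairs.append(
                ComparisonPair(
                    subject_id=subject,
                    week=week,
                    reference_slot=ref_slot,
                    reference_sbp=(obs["obs1"].sbp + obs["obs2"].sbp) / 2.0,
                    reference_dbp=(obs["obs1"].dbp + obs["obs2"].dbp) / 2.0,
                    test_sbp=t.sbp,
                    test_dbp=t.dbp,
                )
            )
    return pairs
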