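"""Run configuration for the end-to-end pipeline, with lossless JSON round-trip."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a full simulated validation study needs.

    Physical parameters carry units in their names where ambiguous; the
    kernel constants are the shipped pretrained-configuration values.
    """

    fs: float = 256.0
    window_s: float = 15.0
    dc_cutoff_hz: float = 0.5
    excellent_snr_db: float = 12.0
    good_snr_db: float = 6.0
    kernel_scale: float = 11.9
    signal_std: float = 9.6
    seed: int = 0
    n_subjects: int = 30
    n_weeks: int = 5
    n_pretrain_profiles: int = 100  # 31-s recordings -> 2 windows each
    n_finetune_profiles: int = 30
    quality: str = "excellent"
    observer_noise_mmhg: float = 2.0
    slot_bp_jitter_mmhg: float = 1.5
    weekly_drift_mmhg: float = 2.0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("fs", "window_s", "dc_cutoff_hz", "kernel_scale", "signal_std"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_subjects < 1 or not (1 <= self.n_weeks <= 5):
            raise ValueError("need at least 1 subject and 1–5 weeks")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
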