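"""Core in-memory containers for a recording session.

A session bundles the synchronized signal streams of one participant
(16 EEG + 6 EOG + 2 earlobe channels and a 3-axis gyroscope at the EEG
rate, plus body/ankle speed traces at the motion-capture rate) together
with the event table that describes the experimental schedule (block
starts, 35-s contrast periods, target onsets and button presses).

Time convention: seconds from recording start; sample indices are
0-based; windows are half-open ``[t0, t1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EEG_LABELS = [
    "Fp1", "Fp2", "F3", "Fz", "F4", "C3", "Cz", "C4",
    "P3", "Pz", "P4", "PO7", "PO8", "O1", "Oz", "O2",
]

EOG_LABELS = ["EOGLU", "EOGLD", "EOGLC", "EOGRU", "EOGRD", "EOGRC"]
EARLOBE_LABELS = ["A1", "A2"]
GYRO_LABELS = ["GyroX", "GyroY", "GyroZ"]
MOTION_LABELS = ["SpeedBack", "SpeedAnkleL", "SpeedAnkleR"]

OCCIPITAL_POOL = ["PO7", "PO8", "O1", "Oz", "O2"]

EVENT_KINDS = {"block_start", "contrast_onset", "target_onset", "button_press"}
EVENT_COLUMNS = ["time", "kind", "condition", "contrast", "block", "target_location"]

PERIOD_DURATION_S = 35.0
TARGETS_PER_PERIOD = 6


class SessionError(ValueError):
    """Raised when a session violates its structural invariants."""


def empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=EVENT_COLUMNS)


def validate_events(events: pd.DataFrame, duration_s: float | None = None) -> None:
    """Check event-table invariants; raise :class:`SessionError` on violation."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise SessionError(f"event table missing columns: {missing}")
    t = events["time"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise SessionError("event times must be non-decreasing")
    bad = set(events["kind"]) - EVENT_KINDS
    if bad:
        raise SessionError(f"unknown event kinds: {sorted(bad)}")
    if duration_s is not None and t.size and (t.min() < 0 or t.max() > duration_s):
        raise SessionError(
            f"event at t={t.max():.2f}s outside recording of {duration_s:.2f}s"
        )


@dataclass
class Session:
    """One participant's synchronized multi-stream recording.

    ``eeg``/``eog``/``earlobe``/``gyro`` share the EEG sample clock
    (``fs_eeg``); ``motion`` runs on its own clock (``fs_motion``).
    All electrophysiology is in microvolts, the gyroscope in deg/s and
    the speed traces in m/s.
    """

    eeg: np.ndarray           # (16, n) μV
    eog: np.ndarray           # (6, n) μV
    earlobe: np.ndarray       # (2, n) μV
    gyro: np.ndarray          # (3, n) deg/s
    motion: np.ndarray        # (3, m) m/s
    events: pd.DataFrame
    fs_eeg: float = 500.0
    fs_motion: float = 120.0
    eeg_labels: list[str] = field(default_factory=lambda: list(EEG_LABELS))
    eog_labels: list[str] = field(default_factory=lambda: list(EOG_LABELS))
    earlobe_labels: list[str] = field(default_factory=lambda: list(EARLOBE_LABELS))
    gyro_labels: list[str] = field(default_factory=lambda: list(GYRO_LABELS))
    motion_labels: list[str] = field(default_factory=lambda: list(MOTION_LABELS))
    ground_truth: dict = field(default_factory=dict)
    participant: int = 0

    @property
    def n_samples(self) -> int:
        return int(self.eeg.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_eeg

    def channel(self, label: str) -> np.ndarray:
        """Return one electrophysiology channel by label."""
        for arr, labels in (
            (self.eeg, self.eeg_labels),
            (self.eog, self.eog_labels),
            (self.earlobe, self.earlobe_labels),
        ):
            if label in labels:
                return arr[labels.index(label)]
        raise KeyError(f"no channel named {label!r}")

    def validate(self) -> None:
        if self.eeg.shape[0] != 16:
            raise SessionError(f"expected 16 EEG channels, got {self.eeg.shape[0]}")
        if self.eog.shape[0] != 6:
            raise SessionError(f"expected 6 EOG channels, got {self.eog.shape[0]}")
        if self.earlobe.shape[0] != 2:
            raise SessionError(
                f"expected 2 earlobe channels, got {self.earlobe.shape[0]}"
            )
        n = self.n_samples
        for name, arr in (("eog", self.eog), ("earlobe", self.earlobe),
                          ("gyro", self.gyro)):
            if arr.shape[1] != n:
                raise SessionError(f"{name} not on the EEG sample clock")
        validate_events(self.events, self.duration_s)

    def sample_index(self, t: float) -> int:
        return int(round(t * self.fs_eeg))
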