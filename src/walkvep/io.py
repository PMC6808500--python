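"""On-disk formats: EDF signals, TSV event tables, JSON metadata.

A session directory contains

* ``signals.edf`` — the 24 electrophysiology channels plus the 3-axis
  gyroscope on the EEG clock (500 Hz);
* ``motion.edf``  — the 3 body/ankle speed traces (120 Hz);
* ``events.tsv``  — the event table;
* ``meta.json``   — sampling rates, channel labels, participant id;
* optional ``truth_*.tsv`` — ground-truth artifact/component lists of
  the synthetic generator, and ``simconfig.json`` echoing its settings.

EDF files are written by this package's minimal 16-bit writer and read
back through MNE's EDF reader, so a round trip crosses two independent
codecs.  All electrophysiology is stored as μV (recovered exactly up
to 16-bit quantization of each channel's range).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._edf import write_edf
from .config import PipelineConfig, load_config  # noqa: F401  (re-export)
from .session import (
    EARLOBE_LABELS,
    EEG_LABELS,
    EOG_LABELS,
    EVENT_COLUMNS,
    GYRO_LABELS,
    MOTION_LABELS,
    Session,
    SessionError,
    validate_events,
)

_TRUTH_KEYS = ("periods", "blinks", "saccades", "head_moves", "targets")


class FormatError(ValueError):
    """Raised when an on-disk session is malformed or inconsistent."""


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t",
                         dtype={"kind": str, "condition": str},
                         keep_default_na=False,
                         na_values={"contrast": [""], "time": [""]})
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise FormatError(f"events.tsv missing columns: {missing}")
    return events


def write_session(session: Session, out_dir: str | Path,
                  sim_config=None) -> Path:
    """Serialize a session to ``out_dir`` (created if needed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    electro = np.vstack([session.eeg, session.eog, session.earlobe,
                         session.gyro])
    labels = (session.eeg_labels + session.eog_labels
              + session.earlobe_labels + session.gyro_labels)
    dims = ["uV"] * 24 + ["deg/s"] * 3
    write_edf(out / "signals.edf", list(electro), labels, session.fs_eeg,
              phys_dims=dims)
    write_edf(out / "motion.edf", list(session.motion),
              session.motion_labels, session.fs_motion,
              phys_dims=["m/s"] * 3)
    write_events_tsv(session.events, out / "events.tsv")
    meta = dict(fs_eeg=session.fs_eeg, fs_motion=session.fs_motion,
                eeg_labels=session.eeg_labels,
                eog_labels=session.eog_labels,
                earlobe_labels=session.earlobe_labels,
                gyro_labels=session.gyro_labels,
                motion_labels=session.motion_labels,
                participant=session.participant,
                n_samples=session.n_samples)
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    for key in _TRUTH_KEYS:
        if key in session.ground_truth:
            session.ground_truth[key].to_csv(out / f"truth_{key}.tsv",
                                             sep="\t", index=False)
    if sim_config is not None:
        cfg = {k: (list(v.items()) if isinstance(v, dict) else v)
               for k, v in dataclasses.asdict(sim_config).items()}
        (out / "simconfig.json").write_text(json.dumps(cfg, indent=1))
    return out


def _read_edf(path: Path, uv_labels: set[str]) -> tuple[np.ndarray,
                                                        list[str], float]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    # MNE scales μV channels to volts but leaves deg/s and m/s channels
    # in their physical units; undo only the μV scaling
    for i, lab in enumerate(raw.ch_names):
        if lab in uv_labels:
            data[i] = data[i] * 1e6
    return data, list(raw.ch_names), float(raw.info["sfreq"])


def read_session(in_dir: str | Path) -> Session:
    """Load and validate a session directory written by
    :func:`write_session`."""
    src = Path(in_dir)
    for fname in ("signals.edf", "motion.edf", "events.tsv", "meta.json"):
        if not (src / fname).exists():
            raise FormatError(f"missing file: {fname}")
    meta = json.loads((src / "meta.json").read_text())
    uv = set(meta["eeg_labels"] + meta["eog_labels"]
             + meta["earlobe_labels"])
    data, labels, fs = _read_edf(src / "signals.edf", uv)
    expected = (meta["eeg_labels"] + meta["eog_labels"]
                + meta["earlobe_labels"] + meta["gyro_labels"])
    missing = [lab for lab in expected if lab not in labels]
    if missing:
        raise FormatError(f"signals.edf missing channels: {missing}")
    order = [labels.index(lab) for lab in expected]
    data = data[order]
    motion, mlabels, fs_motion = _read_edf(src / "motion.edf", set())
    miss_m = [lab for lab in meta["motion_labels"] if lab not in mlabels]
    if miss_m:
        raise FormatError(f"motion.edf missing channels: {miss_m}")
    motion = motion[[mlabels.index(lab) for lab in meta["motion_labels"]]]

    events = read_events_tsv(src / "events.tsv")
    try:
        validate_events(events, data.shape[1] / fs + 1.0 / fs)
    except SessionError as err:
        raise FormatError(f"inconsistent events: {err}") from err

    truth = {}
    for key in _TRUTH_KEYS:
        p = src / f"truth_{key}.tsv"
        if p.exists():
            truth[key] = pd.read_csv(p, sep="\t")

    session = Session(
        eeg=data[:16], eog=data[16:22], earlobe=data[22:24],
        gyro=data[24:27] if data.shape[0] >= 27 else np.zeros((3,
                                                               data.shape[1])),
        motion=motion, events=events, fs_eeg=fs, fs_motion=fs_motion,
        eeg_labels=meta["eeg_labels"], eog_labels=meta["eog_labels"],
        earlobe_labels=meta["earlobe_labels"],
        gyro_labels=meta["gyro_labels"],
        motion_labels=meta["motion_labels"],
        participant=int(meta.get("participant", 0)),
        ground_truth=truth,
    )
    try:
        session.validate()
    except SessionError as err:
        raise FormatError(str(err)) from err
    return session
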