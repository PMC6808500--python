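"""Minimal EDF writer (16-bit, fixed 1-s records).

Writes plain EDF with one data record per second and integer samples
per record, which covers this package's 500 Hz electrophysiology and
120 Hz motion streams.  Reading is delegated to MNE's EDF reader, so
the writer doubles as an independent codec in round-trip tests.
Signals are quantized to 16 bits over their physical range — the usual
EDF precision loss.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} > {width}")
    return b.ljust(width)


def _num(value, width: int) -> bytes:
    text = f"{value:.10g}"[:width]
    return _field(text, width)


def write_edf(path: str | Path, signals: list[np.ndarray],
              labels: list[str], sfreq: float,
              phys_dims: list[str] | None = None,
              patient: str = "X", recording: str = "synthetic") -> None:
    """Write equally sampled signals to an EDF file.

    ``signals`` are 1-D arrays of equal length in physical units;
    ``sfreq`` must be a whole number of samples per 1-s record.  The
    final partial record is zero-padded.
    """
    if len(signals) != len(labels):
        raise ValueError("one label per signal required")
    spr = int(round(sfreq))
    if abs(sfreq - spr) > 1e-9:
        raise ValueError("sampling rate must be an integer for 1-s records")
    n = signals[0].shape[0]
    if any(s.shape[0] != n for s in signals):
        raise ValueError("all signals must share one length")
    phys_dims = phys_dims or ["uV"] * len(signals)
    n_records = int(np.ceil(n / spr))
    ns = len(signals)

    phys_min, phys_max, digital = [], [], []
    for sig in signals:
        lo, hi = float(np.min(sig)), float(np.max(sig))
        if hi - lo < 1e-9:
            lo, hi = lo - 1.0, hi + 1.0
        scale = (_DIG_MAX - _DIG_MIN) / (hi - lo)
        d = np.round((sig - lo) * scale + _DIG_MIN).astype("<i2")
        padded = np.zeros(n_records * spr, dtype="<i2")
        padded[:n] = d
        phys_min.append(lo)
        phys_max.append(hi)
        digital.append(padded.reshape(n_records, spr))

    now = datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field(patient, 80),
        _field(recording, 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _num(256 * (1 + ns), 8),
        _field("", 44),
        _num(n_records, 8),
        _num(1, 8),
        _num(ns, 4),
    ])
    per_signal = b"".join([
        b"".join(_field(lab, 16) for lab in labels),
        b"".join(_field("", 80) for _ in labels),
        b"".join(_field(dim, 8) for dim in phys_dims),
        b"".join(_num(v, 8) for v in phys_min),
        b"".join(_num(v, 8) for v in phys_max),
        b"".join(_num(_DIG_MIN, 8) for _ in labels),
        b"".join(_num(_DIG_MAX, 8) for _ in labels),
        b"".join(_field("", 80) for _ in labels),
        b"".join(_num(spr, 8) for _ in labels),
        b"".join(_field("", 32) for _ in labels),
    ])
    with open(path, "wb") as fh:
        fh.write(header + per_signal)
        for rec in range(n_records):
            for sig in digital:
                fh.write(sig[rec].tobytes())


def quantization_step(signal: np.ndarray) -> float:
    """Worst-case physical resolution of the 16-bit encoding."""
    lo, hi = float(np.min(signal)), float(np.max(signal))
    if hi - lo < 1e-9:
        return 2.0 / (_DIG_MAX - _DIG_MIN)
    return (hi - lo) / (_DIG_MAX - _DIG_MIN)
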