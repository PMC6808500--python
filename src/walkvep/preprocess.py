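"""Filtering, epoching, trial extraction and trial-exclusion rules.

The pipeline cuts continuous data into 35-s contrast-period epochs,
band-filters them (1–100 Hz windowed-sinc FIR, Kaiser window), then
segments 2-s pre-target trials ending at each target onset.  Trials are
excluded when a button press falls in the 2.5 s before the target, and
per walking condition when their 20–99 Hz power is an outlier under the
MAD–median rule: a trial with high-frequency power ``p`` is rejected
when ``|p − median(P)| × 0.6745 > 2.24 × MAD`` with
``MAD = median(|P − median(P)|)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import PipelineConfig
from .session import PERIOD_DURATION_S, Session


class FilterError(ValueError):
    pass


class RepairError(ValueError):
    pass


# ---------------------------------------------------------------------------
# zero-phase FIR filtering
# ---------------------------------------------------------------------------

def design_fir(low: float | None, high: float | None, fs: float,
               cfg: PipelineConfig | None = None,
               window: str = "kaiser") -> np.ndarray:
    """Windowed-sinc FIR taps for a band-pass / high-pass / low-pass.

    The transition width is a fraction of the low edge (with a floor in
    Hz) and the stopband attenuation is taken from the filter spec.
    ``window`` may be ``"kaiser"`` (default) or ``"hamming"``.
    """
    cfg = cfg or PipelineConfig()
    spec = cfg.filter
    nyq = fs / 2.0
    if low is not None and not (0 < low < nyq):
        raise FilterError(f"low edge {low} Hz outside (0, {nyq}) Hz")
    if high is not None and not (0 < high < nyq):
        raise FilterError(f"high edge {high} Hz outside (0, {nyq}) Hz")
    if low is not None and high is not None and low >= high:
        raise FilterError("low edge must be below high edge")

    edge = low if low is not None else high
    width = max(spec.transition_frac * edge, spec.min_transition_hz)
    if window == "kaiser":
        numtaps, beta = sps.kaiserord(spec.stopband_db, width / nyq)
        win: str | tuple = ("kaiser", beta)
    else:
        numtaps = int(np.ceil(3.3 * fs / width))
        win = window
    numtaps |= 1  # odd length -> integer group delay, type-I response
    if low is not None and high is not None:
        cutoff, pass_zero = [low, high], False
    elif low is not None:
        cutoff, pass_zero = [low], False
    else:
        cutoff, pass_zero = [high], True
    return sps.firwin(numtaps, cutoff, window=win, pass_zero=pass_zero, fs=fs)


def bandpass_fir(x: np.ndarray, low: float | None, high: float | None,
                 fs: float, cfg: PipelineConfig | None = None,
                 window: str = "kaiser") -> np.ndarray:
    """Zero-phase FIR filtering along the last axis.

    A linear-phase (symmetric, odd-length) kernel is applied once with
    its group delay compensated, so the output is exactly zero-phase.
    """
    taps = design_fir(low, high, fs, cfg, window=window)
    if x.shape[-1] < len(taps) // 4:
        warnings.warn("signal much shorter than filter kernel; edge effects "
                      "will dominate", stacklevel=2)
    return sps.fftconvolve(x, taps[(None,) * (x.ndim - 1)], mode="same",
                           axes=-1)


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

@dataclass
class TrialSet:
    """Labelled windows into a session's sample clock.

    ``table`` has one row per trial with half-open sample bounds
    ``[i0, i1)``, factor labels, and exclusion flags.  ``kind`` is
    ``"period_35s"`` or ``"pretarget_2s"``.
    """

    session: Session
    table: pd.DataFrame
    kind: str

    def __len__(self) -> int:
        return len(self.table)

    @property
    def included(self) -> pd.DataFrame:
        flags = [c for c in self.table.columns if c.startswith("excluded")]
        mask = ~self.table[flags].any(axis=1) if flags else np.ones(
            len(self.table), bool)
        if "short_trial" in self.table.columns:
            mask &= ~self.table["short_trial"]
        return self.table[mask]

    def get_data(self, channels: list[str] | None = None,
                 rows: pd.DataFrame | None = None) -> np.ndarray:
        """Stack trial windows to (n_trials, n_channels, n_samples)."""
        rows = self.table if rows is None else rows
        labels = self.session.eeg_labels if channels is None else channels
        chans = [self.session.channel(c) for c in labels]
        n = int((rows.i1 - rows.i0).min())
        out = np.empty((len(rows), len(chans), n))
        for k, (_, r) in enumerate(rows.iterrows()):
            for j, ch in enumerate(chans):
                out[k, j] = ch[int(r.i0): int(r.i0) + n]
        return out


def epoch_periods(session: Session) -> TrialSet:
    """One 35-s epoch per contrast period.

    A period extending past the end of the recording is kept but
    flagged ``truncated`` rather than silently dropped.
    """
    fs = session.fs_eeg
    onsets = session.events[session.events.kind == "contrast_onset"]
    if onsets.empty:
        raise ValueError("no contrast_onset events in session")
    rows = []
    n = session.n_samples
    for _, ev in onsets.iterrows():
        i0 = int(round(ev.time * fs))
        i1 = int(round((ev.time + PERIOD_DURATION_S) * fs))
        rows.append(dict(t0=ev.time, i0=i0, i1=min(i1, n),
                         condition=ev.condition, contrast=ev.contrast,
                         block=int(ev.block), truncated=i1 > n))
    return TrialSet(session, pd.DataFrame(rows), kind="period_35s")


def extract_pretarget_trials(periods: TrialSet,
                             cfg: PipelineConfig | None = None) -> TrialSet:
    """2-s windows ``[t_target − 2, t_target)`` with press-based exclusion.

    Trials with a button press anywhere in the 2.5 s before the target
    onset are flagged ``excluded_press``; trials whose window would
    start before the enclosing period are flagged ``short_trial``.
    """
    cfg = cfg or PipelineConfig()
    session = periods.session
    fs = session.fs_eeg
    events = session.events
    presses = events.loc[events.kind == "button_press", "time"].to_numpy()
    targets = events[events.kind == "target_onset"]
    win = cfg.behavior.pre_press_exclusion_s
    rows = []
    for _, ev in targets.iterrows():
        t0 = ev.time - 2.0
        i0, i1 = int(round(t0 * fs)), int(round(ev.time * fs))
        per = periods.table[(periods.table.t0 <= ev.time)
                            & (ev.time < periods.table.t0 + PERIOD_DURATION_S)]
        period_start = float(per.t0.iloc[0]) if len(per) else np.nan
        has_press = bool(np.any((presses >= ev.time - win)
                                & (presses < ev.time)))
        rows.append(dict(t_target=ev.time, i0=i0, i1=i1,
                         condition=ev.condition, contrast=ev.contrast,
                         block=int(ev.block),
                         target_location=ev.target_location,
                         excluded_press=has_press,
                         short_trial=(not len(per)) or t0 < period_start))
    return TrialSet(session, pd.DataFrame(rows), kind="pretarget_2s")


# ---------------------------------------------------------------------------
# MAD–median exclusion
# ---------------------------------------------------------------------------

def mad_median_outliers(p: np.ndarray, scale: float = 0.6745,
                        cutoff: float = 2.24) -> np.ndarray:
    """Boolean outlier mask under the MAD–median rule.

    A point is an outlier when ``|p − median(P)| × scale > cutoff × MAD``.
    Scale-invariant: ``p`` and ``10·p`` yield identical masks.
    """
    p = np.asarray(p, dtype=float)
    med = np.median(p)
    mad = np.median(np.abs(p - med))
    return np.abs(p - med) * scale > cutoff * mad


def mad_exclude_hf(trials: TrialSet, hf_power: np.ndarray,
                   cfg: PipelineConfig | None = None) -> TrialSet:
    """Flag high-frequency-power outliers within each walking condition.

    ``hf_power`` is the per-trial sum of 20–99 Hz Welch power (one value
    per row of ``trials.table``).  Groups with fewer than 3 trials are
    left untouched with a warning.
    """
    cfg = cfg or PipelineConfig()
    if len(hf_power) != len(trials.table):
        raise ValueError("hf_power length must match number of trials")
    table = trials.table.copy()
    flags = np.zeros(len(table), dtype=bool)
    for cond, idx in table.groupby("condition").groups.items():
        pos = table.index.get_indexer(idx)
        if len(pos) < 3:
            warnings.warn(f"condition {cond!r} has {len(pos)} trials; "
                          "MAD exclusion skipped", stacklevel=2)
            continue
        flags[pos] = mad_median_outliers(hf_power[pos], cfg.mad.scale,
                                         cfg.mad.cutoff)
    table["excluded_mad"] = flags
    return TrialSet(trials.session, table, kind=trials.kind)


# ---------------------------------------------------------------------------
# epoch repair
# ---------------------------------------------------------------------------

def repair_epochs(data: np.ndarray, channel_labels: list[str],
                  mask: list[tuple[int, str]],
                  neighbours: dict[str, list[str]],
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Replace masked (epoch, channel) entries by their neighbour average.

    ``data`` is (n_epochs, n_channels, n_samples); ``mask`` lists
    (epoch index, channel label) pairs to repair; ``neighbours`` maps a
    channel label to the labels averaged as its replacement.  Returns
    the repaired copy and a per-epoch ``repaired`` flag vector.
    """
    out = data.copy()
    repaired = np.zeros(data.shape[0], dtype=bool)
    index = {lab: i for i, lab in enumerate(channel_labels)}
    by_epoch: dict[int, list[str]] = {}
    for ep, ch in mask:
        by_epoch.setdefault(ep, []).append(ch)
    for ep, chans in by_epoch.items():
        if set(chans) >= set(channel_labels):
            raise RepairError(f"epoch {ep}: all channels masked")
        for ch in chans:
            nbrs = [c for c in neighbours.get(ch, []) if c not in chans]
            if not nbrs:
                raise RepairError(f"epoch {ep}: no usable neighbours "
                                  f"for {ch!r}")
            out[ep, index[ch]] = data[ep, [index[c] for c in nbrs]].mean(axis=0)
        repaired[ep] = True
    return out, repaired
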