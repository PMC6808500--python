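"""Blink, saccade and head-movement detection from EOG and gyroscope.

Blinks are threshold crossings of the band-passed (0.2–20 Hz) vertical
EOG difference (above-eye minus below-eye, left eye), with minimum-peak
and local-SD criteria and a 100 ms merge rule.  Saccades are detected
without an eye tracker from the radial EOG (REOG: mean of the six EOG
channels minus Pz): the 20–90 Hz sixth-order-Butterworth band-passed
REOG carries the biphasic saccadic spike potential, whose Hilbert
envelope is thresholded at mean + 2.5 SD per recording block.  The
spike-potential amplitude grows with saccade size; a second-order
polynomial fitted to calibration saccades of known size turns the mean
spike amplitude into a saccade-size estimate.  Strong head movements
are supra-threshold excursions of gyroscope rotational velocity merged
over a 2-s window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import PipelineConfig
from .preprocess import bandpass_fir
from .session import Session


def merge_points(times: np.ndarray, gap: float) -> list[np.ndarray]:
    """Group sorted time points closer than ``gap`` into runs."""
    times = np.sort(np.asarray(times, dtype=float))
    if times.size == 0:
        return []
    splits = np.where(np.diff(times) >= gap)[0] + 1
    return np.split(times, splits)


def block_bounds(session: Session) -> list[tuple[float, float]]:
    """(start, end) of every recording block, from block_start events."""
    starts = session.events.loc[session.events.kind == "block_start",
                                "time"].to_numpy(dtype=float)
    ends = np.append(starts[1:], session.duration_s)
    return list(zip(starts, ends))


# ---------------------------------------------------------------------------
# blinks
# ---------------------------------------------------------------------------

def detect_blinks(above: np.ndarray, below: np.ndarray, fs: float,
                  cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Blink events from one eye's vertical EOG pair.

    Returns a frame with ``t_peak`` (s) and ``peak_amp`` (μV) per blink.
    """
    cfg = cfg or PipelineConfig()
    b = cfg.blink
    if above.shape != below.shape:
        raise ValueError("above/below channels must have equal length")
    v = bandpass_fir(above - below, b.hp_hz, b.lp_hz, fs, cfg)

    crossings = np.where((v[:-1] < b.cross_uv) & (v[1:] >= b.cross_uv))[0] + 1
    if crossings.size == 0:
        return pd.DataFrame(columns=["t_peak", "peak_amp"])

    half_peak = int(round(0.3 * fs))            # peak search range
    half_sd = int(round(b.sd_window_ms / 2000.0 * fs))
    rows = []
    for grp in merge_points(crossings / fs, b.merge_ms / 1000.0):
        i = int(round(grp[0] * fs))
        seg = v[i: i + half_peak]
        if seg.size == 0:
            continue
        ip = i + int(np.argmax(seg))
        peak = float(v[ip])
        if peak < b.min_peak_uv:
            continue
        local = v[max(ip - half_sd, 0): ip + half_sd]
        if float(np.std(local)) < b.min_sd_uv:
            continue
        rows.append(dict(t_peak=ip / fs, peak_amp=peak))
    out = pd.DataFrame(rows, columns=["t_peak", "peak_amp"])
    # candidates that survived but refer to the same peak
    if len(out) > 1:
        keep = np.append(True, np.diff(out.t_peak.to_numpy())
                         >= b.merge_ms / 1000.0)
        out = out[keep].reset_index(drop=True)
    return out


def detect_blinks_session(session: Session,
                          cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Blinks from the left-eye channels of a session."""
    return detect_blinks(session.channel("EOGLU"), session.channel("EOGLD"),
                         session.fs_eeg, cfg)


# ---------------------------------------------------------------------------
# saccades via the radial EOG
# ---------------------------------------------------------------------------

def compute_reog(session: Session) -> np.ndarray:
    """Radial EOG: mean of all six EOG channels minus Pz."""
    return session.eog.mean(axis=0) - session.channel("Pz")


def _reog_bandpass(x: np.ndarray, fs: float, cfg: PipelineConfig) -> np.ndarray:
    lo, hi = cfg.saccade.band_hz
    sos = sps.butter(cfg.saccade.order, [lo, hi], btype="bandpass",
                     output="sos", fs=fs)
    return sps.sosfiltfilt(sos, x)


def detect_saccades(reog: np.ndarray, fs: float,
                    bounds: list[tuple[float, float]],
                    cfg: PipelineConfig | None = None,
                    ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Saccade events from the REOG signal, thresholded per block.

    Returns ``(saccades, reog_filtered, envelope)``.  ``saccades`` has
    ``t`` (envelope peak), ``t_start``/``t_end`` of the supra-threshold
    group, the peak envelope value and the block index.  Per block the
    threshold is mean + ``sd_mult`` · SD of the Hilbert envelope of the
    20–90 Hz filtered REOG; supra-threshold points less than
    ``group_ms`` apart form one saccade.  Detections inside the filter
    warm-up zone at block edges are dropped.
    """
    cfg = cfg or PipelineConfig()
    s = cfg.saccade
    filtered = np.zeros_like(reog)
    envelope = np.zeros_like(reog)
    rows = []
    warm = s.warmup_ms / 1000.0
    min_len = int(round(10 * s.order))  # sosfiltfilt padding requirement
    for bi, (t0, t1) in enumerate(bounds):
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        seg = reog[i0:i1]
        if seg.size <= min_len:
            warnings.warn(f"block {bi} shorter than filter warm-up; skipped",
                          stacklevel=2)
            continue
        f = _reog_bandpass(seg, fs, cfg)
        env = np.abs(sps.hilbert(f))
        filtered[i0:i1] = f
        envelope[i0:i1] = env
        thr = env.mean() + s.sd_mult * env.std()
        supra = np.where(env > thr)[0]
        for grp in merge_points(supra / fs, s.group_ms / 1000.0):
            ia = int(round(grp[0] * fs))
            ib = int(round(grp[-1] * fs)) + 1
            ip = ia + int(np.argmax(env[ia:ib]))
            t = t0 + ip / fs
            if t - t0 < warm or t1 - t < warm:
                continue
            rows.append(dict(t=t, t_start=t0 + ia / fs, t_end=t0 + ib / fs,
                             peak_env=float(env[ip]), block=bi))
    return (pd.DataFrame(rows, columns=["t", "t_start", "t_end", "peak_env",
                                        "block"]),
            filtered, envelope)


def extract_spike_potential(reog_filtered: np.ndarray, fs: float,
                            saccades: pd.DataFrame,
                            normalizer: float | np.ndarray,
                            window_ms: float = 80.0,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Mean normalized spike-potential waveform over detected saccades.

    For each saccade an ``window_ms`` window of the filtered REOG is
    extracted centred at the signal's lowest point inside the saccade's
    supra-threshold interval, divided by ``normalizer`` (the block- or
    session-mean Hilbert amplitude; scalar or one value per saccade),
    and averaged.  Returns ``(mean_waveform, amps_at_zero)`` where the
    amplitude is read at the window centre (t = 0).  Saccades whose
    window exceeds the recording are skipped.
    """
    if len(saccades) == 0:
        raise ValueError("no saccades to extract from")
    half = int(round(window_ms / 2000.0 * fs))
    norm = np.broadcast_to(np.asarray(normalizer, dtype=float),
                           (len(saccades),))
    segs, amps = [], []
    for k, (_, row) in enumerate(saccades.iterrows()):
        ia = int(round(row.t_start * fs))
        ib = max(int(round(row.t_end * fs)), ia + 1)
        ic = ia + int(np.argmin(reog_filtered[ia:ib]))
        if ic - half < 0 or ic + half + 1 > reog_filtered.size:
            continue
        seg = reog_filtered[ic - half: ic + half + 1] / norm[k]
        segs.append(seg)
        amps.append(seg[half])
    if not segs:
        raise ValueError("no saccade window fits inside the recording")
    return np.mean(segs, axis=0), np.asarray(amps)


# ---------------------------------------------------------------------------
# spike-amplitude → saccade-size calibration
# ---------------------------------------------------------------------------

@dataclass
class SizeCalibration:
    """Second-order polynomial mapping spike amplitude to saccade size.

    Fitted on calibration saccades of known sizes; estimates outside
    the calibrated amplitude range are clamped and flagged.
    """

    coeffs: np.ndarray            # highest order first (np.polyval order)
    amp_range: tuple[float, float]
    sizes: np.ndarray
    amplitudes: np.ndarray
    residuals: np.ndarray
    monotone: bool

    def estimate(self, amplitude: float | np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
        """Estimated size (deg) and an out-of-range flag per amplitude."""
        a = np.asarray(amplitude, dtype=float)
        clamped = np.clip(a, *self.amp_range)
        return np.polyval(self.coeffs, clamped), (a < self.amp_range[0]) | (
            a > self.amp_range[1])


def fit_size_calibration(sizes: np.ndarray,
                         amplitudes: np.ndarray) -> SizeCalibration:
    """Least-squares degree-2 fit of saccade size against spike amplitude."""
    sizes = np.asarray(sizes, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if len(np.unique(sizes)) < 3:
        raise ValueError("need at least 3 distinct calibration sizes")
    coeffs = np.polyfit(amplitudes, sizes, deg=2)
    fitted = np.polyval(coeffs, amplitudes)
    amp_range = (float(amplitudes.min()), float(amplitudes.max()))
    grid = np.linspace(*amp_range, 200)
    monotone = bool(np.all(np.diff(np.polyval(coeffs, grid)) >= 0)
                    or np.all(np.diff(np.polyval(coeffs, grid)) <= 0))
    if not monotone:
        warnings.warn("size calibration is non-monotone inside the "
                      "calibrated range", stacklevel=2)
    return SizeCalibration(coeffs=coeffs, amp_range=amp_range, sizes=sizes,
                           amplitudes=amplitudes, residuals=sizes - fitted,
                           monotone=monotone)


# ---------------------------------------------------------------------------
# head movements
# ---------------------------------------------------------------------------

def detect_head_movements(gyro: np.ndarray, fs: float,
                          bounds: list[tuple[float, float]],
                          cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Strong head-movement events from 3-axis rotational velocity.

    Per block, the deviation magnitude of the mean-subtracted gyro
    vector is thresholded at mean + ``sd_mult`` · SD; supra-threshold
    points within ``merge_s`` form one event with ``t_start``/``t_end``.
    """
    cfg = cfg or PipelineConfig()
    h = cfg.head
    rows = []
    for bi, (t0, t1) in enumerate(bounds):
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        seg = gyro[:, i0:i1]
        if seg.shape[1] < 2:
            continue
        dev = np.linalg.norm(seg - seg.mean(axis=1, keepdims=True), axis=0)
        thr = dev.mean() + h.sd_mult * dev.std()
        supra = np.where(dev > thr)[0]
        for grp in merge_points(supra / fs, h.merge_s):
            rows.append(dict(t_start=t0 + grp[0], t_end=t0 + grp[-1],
                             block=bi))
    return pd.DataFrame(rows, columns=["t_start", "t_end", "block"])


def count_events_per_trial(event_times: np.ndarray,
                           trials: pd.DataFrame, fs: float) -> np.ndarray:
    """Events falling in each trial's half-open window ``[i0/fs, i1/fs)``."""
    event_times = np.asarray(event_times, dtype=float)
    counts = np.empty(len(trials), dtype=int)
    for k, (_, row) in enumerate(trials.iterrows()):
        t0, t1 = row.i0 / fs, row.i1 / fs
        counts[k] = int(np.sum((event_times >= t0) & (event_times < t1)))
    return counts
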