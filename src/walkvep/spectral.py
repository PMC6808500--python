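"""Welch spectra and the SSVEP / alpha statistics derived from them.

Power spectra use Welch's method with 1-s Hamming windows and 50%
overlap, giving a 1 Hz frequency grid.  The SSVEP statistic is the
power at the stimulation frequency (15 Hz) referenced by subtraction to
the mean power at 13/14/16/17 Hz, which removes broadband shifts (e.g.
the walking-induced spectral upshift); alpha power is referenced
analogously.  Target-evoked SSVEP dynamics come from the Hilbert
envelope of the 14.5–15.5 Hz band-passed signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import PipelineConfig
from .preprocess import bandpass_fir


class GridError(ValueError):
    """A requested frequency does not lie on the spectrum's grid."""


def welch_psd(x: np.ndarray, fs: float,
              cfg: PipelineConfig | None = None,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD along the last axis; returns ``(freqs, power)``.

    With the default 1-s window the grid is 0, 1, …, Nyquist Hz.  Power
    is a one-sided density on the 1 Hz grid, so summed power over a
    band equals the variance contributed by that band (Parseval).
    """
    cfg = cfg or PipelineConfig()
    nperseg = int(round(cfg.welch.window_s * fs))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"trial of {x.shape[-1]} samples shorter than the "
            f"{nperseg}-sample Welch window")
    noverlap = int(round(cfg.welch.overlap * nperseg))
    freqs, power = sps.welch(x, fs=fs, window=cfg.welch.taper,
                             nperseg=nperseg, noverlap=noverlap,
                             detrend=False, scaling="density", axis=-1)
    return freqs, power


def _grid_index(freqs: np.ndarray, f: float) -> int:
    idx = np.argmin(np.abs(freqs - f))
    if abs(freqs[idx] - f) > 1e-9:
        raise GridError(f"{f} Hz not on the spectral grid")
    return int(idx)


def referenced_power(power: np.ndarray, freqs: np.ndarray, target: float,
                     refs: tuple[float, ...] | list[float]) -> np.ndarray:
    """Power at ``target`` minus the mean power at the reference
    frequencies, along the last axis.  May be negative."""
    it = _grid_index(freqs, target)
    ir = [_grid_index(freqs, f) for f in refs]
    return power[..., it] - power[..., ir].mean(axis=-1)


def band_power(power: np.ndarray, freqs: np.ndarray,
               band: tuple[float, float]) -> np.ndarray:
    """Sum of power over grid bins in ``band`` (inclusive bounds)."""
    mask = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    return power[..., mask].sum(axis=-1)


def select_channels(power: np.ndarray, freqs: np.ndarray,
                    labels: list[str], pool: list[str],
                    n: int = 3, target: float = 15.0) -> list[str]:
    """The ``n`` pool channels with highest mean power at ``target`` Hz.

    ``power`` is (n_trials, n_channels, n_freqs); the mean is over all
    trials.  Ties break deterministically by pool order.
    """
    if not pool:
        raise ValueError("channel pool is empty")
    if n > len(pool):
        raise ValueError(f"cannot select {n} channels from a pool of "
                         f"{len(pool)}")
    it = _grid_index(freqs, target)
    mean_p = power[..., it].mean(axis=0)
    scores = {lab: mean_p[labels.index(lab)] for lab in pool}
    order = sorted(range(len(pool)),
                   key=lambda i: (-scores[pool[i]], i))
    return [pool[i] for i in order[:n]]


def peak_alpha(power: np.ndarray, freqs: np.ndarray,
               band: tuple[float, float] = (8.0, 12.0)) -> float:
    """Grid frequency in ``band`` maximizing mean power over trials and
    channels; ties resolve to the lower frequency."""
    mask = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    if not mask.any():
        raise ValueError(f"no grid frequencies in band {band}")
    mean_p = power.reshape(-1, power.shape[-1]).mean(axis=0)
    in_band = np.where(mask)[0]
    return float(freqs[in_band[np.argmax(mean_p[in_band])]])


def hilbert_envelope(x: np.ndarray, fs: float,
                     band: tuple[float, float] | None = None,
                     cfg: PipelineConfig | None = None) -> np.ndarray:
    """Instantaneous amplitude of the band-passed signal (last axis).

    The band-pass is a Hamming-window FIR (the narrowband counterpart
    of the broadband Kaiser filters); the envelope is the magnitude of
    the analytic signal.  The first/last ``envelope_edge_s`` seconds
    carry filter edge effects and should be excluded from statistics.
    """
    cfg = cfg or PipelineConfig()
    band = band or cfg.envelope_band
    nyq = fs / 2
    if not (0 < band[0] < band[1] < nyq):
        raise ValueError(f"band {band} outside (0, {nyq}) Hz")
    filtered = bandpass_fir(x, band[0], band[1], fs, cfg, window="hamming")
    return np.abs(sps.hilbert(filtered, axis=-1))


def evoked_perturbation(envelopes: np.ndarray, fs: float,
                        target_times: list[np.ndarray],
                        mode: str = "mean_200_600",
                        pre_s: float = 1.0, post_s: float = 1.2,
                        ) -> dict:
    """Target-locked SSVEP envelope average and its dip statistic.

    ``envelopes`` is (n_epochs, n_samples); ``target_times[k]`` holds
    the within-epoch target onsets (s) of epoch ``k``.  Targets whose
    ``[−pre, +post]`` window does not fit inside the epoch are skipped.
    ``mode`` selects the summary of the post-target window:
    ``"mean_200_600"`` (mean amplitude 200–600 ms after onset) or
    ``"min_200_1000"`` (lowest amplitude point in 200–1000 ms).
    Baseline is the mean envelope in [−1, 0) s before onset.
    """
    if mode not in ("mean_200_600", "min_200_1000"):
        raise ValueError(f"unknown mode {mode!r}")
    n_pre, n_post = int(round(pre_s * fs)), int(round(post_s * fs))
    segments = []
    for k, times in enumerate(target_times):
        env = envelopes[k]
        for t in np.atleast_1d(times):
            i = int(round(t * fs))
            if i - n_pre < 0 or i + n_post > env.shape[-1]:
                continue
            segments.append(env[i - n_pre: i + n_post])
    if not segments:
        raise ValueError("no target with a full peri-target window")
    locked = np.mean(segments, axis=0)
    t_axis = (np.arange(locked.size) - n_pre) / fs
    baseline = float(locked[(t_axis >= -1.0) & (t_axis < 0.0)].mean())
    if mode == "mean_200_600":
        stat = float(locked[(t_axis >= 0.2) & (t_axis <= 0.6)].mean())
    else:
        stat = float(locked[(t_axis >= 0.2) & (t_axis <= 1.0)].min())
    return dict(time=t_axis, locked=locked, baseline=baseline,
                statistic=stat, n_targets=len(segments), mode=mode)


def spectrum_table(power: np.ndarray, freqs: np.ndarray,
                   trial_labels: pd.DataFrame,
                   cfg: PipelineConfig | None = None,
                   alpha_peak_hz: float | None = None) -> pd.DataFrame:
    """Per-trial derived spectral statistics.

    ``power`` is (n_trials, n_channels, n_freqs) for the selected SSVEP
    channels; the channel dimension is averaged.  Adds raw/referenced
    SSVEP power, raw/referenced alpha power (at the participant's peak
    alpha frequency when given, else the band maximum) and the 20–99 Hz
    high-frequency power sum to a copy of ``trial_labels``.
    """
    cfg = cfg or PipelineConfig()
    mean_p = power.mean(axis=1)
    out = trial_labels.reset_index(drop=True).copy()
    it = _grid_index(freqs, cfg.ssvep_freq)
    out["raw_ssvep"] = mean_p[:, it]
    out["ref_ssvep"] = referenced_power(mean_p, freqs, cfg.ssvep_freq,
                                        cfg.ssvep_reference_freqs)
    if alpha_peak_hz is None:
        alpha_peak_hz = peak_alpha(power, freqs, cfg.alpha_band)
    ia = _grid_index(freqs, alpha_peak_hz)
    out["peak_alpha_freq"] = alpha_peak_hz
    out["raw_alpha"] = mean_p[:, ia]
    out["ref_alpha"] = referenced_power(mean_p, freqs, alpha_peak_hz,
                                        cfg.alpha_reference_freqs)
    out["hf_power"] = band_power(mean_p, freqs, cfg.hf_band)
    for name, band in (("delta_power", (2.0, 3.0)),
                       ("theta_power", (4.0, 7.0)),
                       ("alpha_power", cfg.alpha_band)):
        out[name] = band_power(mean_p, freqs, band)
    return out
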