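"""Synthetic free-walking SSVEP sessions with known ground truth.

The generator emulates the statistical structure the downstream
analysis assumes, so every stage of the pipeline can be exercised
against a known answer:

* a 15 Hz SSVEP whose amplitude depends on walking condition × surround
  contrast (surround suppression grows with walking speed);
* an occipital alpha oscillation (participant-specific peak in 8–12 Hz)
  whose amplitude drops with walking speed;
* coloured 1/f background noise plus band-limited 20–99 Hz noise whose
  RMS grows with walking speed (the broadband "upshift" of mobile EEG);
* gait-frequency components near 1 Hz (slow) and 1.75 Hz (normal
  walking) in EEG and in the ankle speed traces;
* blink templates on the vertical EOG channels, biphasic saccadic spike
  potentials on all EOG channels with amplitude a quadratic function of
  saccade size, and head-movement velocity bursts on the gyroscope;
* a simulated observer with a cumulative-Gaussian psychometric function
  whose detection threshold depends on walking condition × contrast.

Every random draw flows from one seeded generator; per-participant
substreams are derived deterministically, so a configuration (including
its seed) fully determines the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .session import (
    EEG_LABELS,
    EVENT_COLUMNS,
    PERIOD_DURATION_S,
    TARGETS_PER_PERIOD,
    Session,
    validate_events,
)

CONDITIONS = ("still", "slow", "normal")
CONTRAST_LEVELS = (0.0, 0.33, 0.67, 1.0)


class ScheduleError(ValueError):
    """Raised when the event-schedule constraints cannot be satisfied."""


def _default_ssvep_map() -> dict:
    # Surround suppression of the SSVEP grows with walking speed: flat
    # across contrast when standing still, graded suppression when walking.
    return {
        ("still", 0.0): 1.00, ("still", 0.33): 0.97,
        ("still", 0.67): 0.94, ("still", 1.0): 0.90,
        ("slow", 0.0): 1.00, ("slow", 0.33): 0.82,
        ("slow", 0.67): 0.62, ("slow", 1.0): 0.45,
        ("normal", 0.0): 1.00, ("normal", 0.33): 0.70,
        ("normal", 0.67): 0.45, ("normal", 1.0): 0.30,
    }


def _default_alpha_map() -> dict:
    return {"still": 4.0, "slow": 3.0, "normal": 2.0}


def _default_hf_map() -> dict:
    return {"still": 1.0, "slow": 1.5, "normal": 2.0}


def _default_threshold_map() -> dict:
    # Detection threshold (contrast units) rises with surround contrast,
    # more steeply when walking.
    out = {}
    walk_penalty = {"still": 0.0, "slow": 0.015, "normal": 0.03}
    contrast_slope = {"still": 0.02, "slow": 0.03, "normal": 0.045}
    for cond in CONDITIONS:
        for c in CONTRAST_LEVELS:
            out[(cond, c)] = 0.06 + walk_penalty[cond] + contrast_slope[cond] * c
    return out


def _default_ssvep_topography() -> dict:
    return {"Oz": 1.0, "O1": 0.85, "O2": 0.85, "PO7": 0.5, "PO8": 0.5,
            "Pz": 0.25, "P3": 0.15, "P4": 0.15}


def _default_alpha_topography() -> dict:
    return {"Oz": 1.0, "O1": 0.9, "O2": 0.9, "PO7": 0.7, "PO8": 0.7,
            "Pz": 0.5, "P3": 0.4, "P4": 0.4, "Cz": 0.2}


@dataclass
class SimConfig:
    """All knobs of the synthetic experiment.

    Amplitudes are in μV; rates in events/min; contrast in [0, 1].
    The defaults encode the study design this generator emulates:
    3 walking conditions × 7 blocks × 4 surround-contrast periods of
    35 s, 6 targets per period.
    """

    seed: int = 0
    n_participants: int = 25
    walking_conditions: tuple[str, ...] = CONDITIONS
    contrast_levels: tuple[float, ...] = CONTRAST_LEVELS
    n_blocks_per_condition: int = 7
    fs_eeg: float = 500.0
    fs_motion: float = 120.0
    block_gap_s: float = 4.0
    # --- oscillatory components ---
    ssvep_freq: float = 15.0
    ssvep_amplitude_map: dict = field(default_factory=_default_ssvep_map)
    ssvep_base_amplitude: float = 1.2
    ssvep_topography: dict = field(default_factory=_default_ssvep_topography)
    # integer peaks 8-11 Hz: keeps the sinusoidal alpha line's window
    # leakage out of the 13/14 Hz SSVEP reference bins
    alpha_peak_range: tuple[float, float] = (8.0, 11.0)
    alpha_amplitude_map: dict = field(default_factory=_default_alpha_map)
    alpha_topography: dict = field(default_factory=_default_alpha_topography)
    amplitude_jitter_sd: float = 0.2       # log-normal per-period jitter
    alpha_ssvep_coupling: float = 0.0      # correlation of per-period jitters
    # --- noise ---
    noise_exponent: float = 1.0
    noise_rms: float = 4.0                 # broadband 1/f RMS per channel
    hf_noise_map: dict = field(default_factory=_default_hf_map)
    # --- gait ---
    gait_freq_map: dict = field(default_factory=lambda: {"slow": 1.0,
                                                         "normal": 1.75})
    gait_eeg_amplitude: float = 2.0
    walking_speed_map: dict = field(default_factory=lambda: {"still": 0.0,
                                                             "slow": 0.8,
                                                             "normal": 1.5})
    # --- ocular / head artifacts ---
    blink_rate: float = 6.0
    blink_amplitude: float = 150.0         # peak of the vertical EOG difference
    blink_duration_s: float = 0.4
    saccade_rate: float = 40.0
    saccade_size_lognorm: tuple[float, float] = (-0.7, 0.6)  # (mu, sigma) deg
    saccade_size_range: tuple[float, float] = (0.1, 5.0)
    spike_quadratic: tuple[float, float, float] = (35.0, 15.0, 1.6)
    spike_sigma_ms: float = 2.2
    head_move_rate: float = 2.0
    head_move_amplitude: float = 120.0     # deg/s burst peak
    head_move_duration_s: float = 0.7
    gyro_noise_rms: float = 5.0
    # --- simulated observer ---
    observer_threshold_map: dict = field(default_factory=_default_threshold_map)
    observer_slope: float = 0.04           # cumulative-Gaussian SD, contrast units
    lapse_rate: float = 0.02
    false_alarm_rate: float = 0.6          # spontaneous presses / min
    rt_shift_s: float = 0.2
    rt_lognorm: tuple[float, float] = (math.log(0.25), 0.35)

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_blocks_per_condition < 1:
            raise ValueError("counts must be positive")
        if any(not (0 <= c <= 1) for c in self.contrast_levels):
            raise ValueError("contrast levels must lie in [0, 1]")
        for amp in self.ssvep_amplitude_map.values():
            if amp < 0:
                raise ValueError("SSVEP amplitudes must be >= 0")
        for amp in self.alpha_amplitude_map.values():
            if amp < 0:
                raise ValueError("alpha amplitudes must be >= 0")
        if not (0 <= self.lapse_rate <= 1):
            raise ValueError("lapse_rate must lie in [0, 1]")
        if not (-1 <= self.alpha_ssvep_coupling <= 1):
            raise ValueError("alpha_ssvep_coupling must lie in [-1, 1]")

    # deterministic per-participant / per-purpose substreams
    def rng(self, participant: int, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(participant, stream))
        )

    def alpha_peak(self, participant: int) -> float:
        lo, hi = self.alpha_peak_range
        # integer peaks so the 1 Hz analysis grid can recover them exactly
        choices = np.arange(math.ceil(lo), math.floor(hi) + 1)
        return float(self.rng(participant, 9).choice(choices))


# ---------------------------------------------------------------------------
# event schedule
# ---------------------------------------------------------------------------

TARGET_LOCATIONS = ("up", "down", "left", "right")

_TARGET_FIRST_S = 5.0
_TARGET_LAST_S = 31.5
_SOA_RANGE = (3.5, 6.5)


def _draw_target_times(rng: np.random.Generator) -> np.ndarray:
    """Six target onsets in [5, 31.5] s with SOA ~ U[3.5, 6.5] s."""
    lo, hi = _SOA_RANGE
    span_max = _TARGET_LAST_S - _TARGET_FIRST_S
    if (TARGETS_PER_PERIOD - 1) * lo > span_max:
        raise ScheduleError("SOA range cannot fit the required targets")
    for _ in range(1000):
        soas = rng.uniform(lo, hi, size=TARGETS_PER_PERIOD - 1)
        span = soas.sum()
        if span <= span_max:
            start = _TARGET_FIRST_S + rng.uniform(0.0, span_max - span)
            return start + np.concatenate(([0.0], np.cumsum(soas)))
    raise ScheduleError("could not satisfy target timing constraints")


def make_event_schedule(cfg: SimConfig, participant: int = 0) -> pd.DataFrame:
    """Deterministic experiment schedule for one participant.

    Blocks (``n_blocks_per_condition`` per walking condition, shuffled)
    each contain the four surround-contrast periods of 35 s in random
    order, with six targets per period.
    """
    cfg.validate()
    rng = cfg.rng(participant, 1)
    conditions = [c for c in cfg.walking_conditions
                  for _ in range(cfg.n_blocks_per_condition)]
    rng.shuffle(conditions)

    rows: list[dict] = []
    t = 0.0
    for block, cond in enumerate(conditions):
        rows.append(dict(time=t, kind="block_start", condition=cond,
                         contrast=np.nan, block=block, target_location=""))
        contrasts = list(cfg.contrast_levels)
        rng.shuffle(contrasts)
        for contrast in contrasts:
            rows.append(dict(time=t, kind="contrast_onset", condition=cond,
                             contrast=contrast, block=block,
                             target_location=""))
            for rel in _draw_target_times(rng):
                rows.append(dict(time=t + rel, kind="target_onset",
                                 condition=cond, contrast=contrast,
                                 block=block,
                                 target_location=rng.choice(TARGET_LOCATIONS)))
            t += PERIOD_DURATION_S
        t += cfg.block_gap_s
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    events = events.sort_values("time", kind="stable").reset_index(drop=True)
    validate_events(events)
    return events


def schedule_duration_s(cfg: SimConfig, events: pd.DataFrame) -> float:
    """Recording length implied by a schedule (plus a 2 s tail)."""
    last_onset = events.loc[events.kind == "contrast_onset", "time"].max()
    return float(last_onset + PERIOD_DURATION_S + 2.0)


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def colored_noise(rng: np.random.Generator, shape: tuple[int, ...],
                  fs: float, exponent: float, rms: float,
                  band: tuple[float, float] | None = None) -> np.ndarray:
    """Gaussian noise with power ∝ 1/f^exponent via spectral shaping.

    ``shape`` is (..., n_samples).  With ``band`` set, the spectrum is
    restricted to that band (used for the high-frequency noise floor).
    """
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.ones_like(freqs)
    if exponent != 0:
        with np.errstate(divide="ignore"):
            gain = freqs ** (-exponent / 2.0)
        gain[0] = 0.0
    if band is not None:
        gain = gain * ((freqs >= band[0]) & (freqs <= band[1]))
    else:
        gain[0] = 0.0
    out = np.fft.irfft(spec * gain, n=n, axis=-1)
    cur = np.sqrt(np.mean(out ** 2, axis=-1, keepdims=True))
    cur[cur == 0] = 1.0
    return out * (rms / cur)


def _raised_cosine(n: int) -> np.ndarray:
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / (n - 1)))


def spike_potential_template(cfg: SimConfig, fs: float) -> np.ndarray:
    """Biphasic saccadic spike potential: derivative-of-Gaussian, unit peak."""
    sigma = cfg.spike_sigma_ms / 1000.0
    half = int(round(4 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    w = -t * np.exp(-t ** 2 / (2 * sigma ** 2))
    return w / np.abs(w).max()


def spike_amplitude(cfg: SimConfig, size_deg: np.ndarray | float) -> np.ndarray:
    """Spike-potential peak (μV) as a quadratic in saccade size (deg)."""
    c0, c1, c2 = cfg.spike_quadratic
    s = np.asarray(size_deg, dtype=float)
    return c0 + c1 * s + c2 * s ** 2


def _period_table(events: pd.DataFrame) -> pd.DataFrame:
    per = events[events.kind == "contrast_onset"].reset_index(drop=True)
    return per[["time", "condition", "contrast", "block"]]


def _event_times_in(rng: np.random.Generator, t0: float, t1: float,
                    n: int, min_sep: float, margin: float) -> np.ndarray:
    """n event times in [t0+margin, t1-margin) with minimal separation."""
    lo, hi = t0 + margin, t1 - margin
    if n <= 0 or hi <= lo:
        return np.empty(0)
    for _ in range(200):
        t = np.sort(rng.uniform(lo, hi, size=n))
        if n == 1 or np.all(np.diff(t) >= min_sep):
            return t
    return np.linspace(lo, hi, n)  # fall back to a regular grid


def _per_period_count(rate_per_min: float, duration: float) -> int:
    return int(round(rate_per_min * duration / 60.0))


def synthesize_signals(cfg: SimConfig, events: pd.DataFrame,
                       participant: int = 0,
                       eeg_channels: list[str] | None = None,
                       include_artifacts: bool = True) -> Session:
    """Render a full multi-stream :class:`Session` for one schedule.

    ``eeg_channels`` restricts synthesis to a subset of EEG channels
    (the remaining rows are zero) for cheap fixtures; artifact streams
    can be switched off entirely with ``include_artifacts=False``.
    Ground-truth component and artifact lists are attached to
    ``session.ground_truth``.
    """
    cfg.validate()
    fs = cfg.fs_eeg
    duration = schedule_duration_s(cfg, events)
    n = int(round(duration * fs))
    t_axis = np.arange(n) / fs

    labels = list(EEG_LABELS)
    active = labels if eeg_channels is None else list(eeg_channels)
    unknown = set(active) - set(labels)
    if unknown:
        raise ValueError(f"unknown EEG channels: {sorted(unknown)}")
    active_idx = [labels.index(ch) for ch in active]

    rng_noise = cfg.rng(participant, 2)
    eeg = np.zeros((16, n))
    eeg[active_idx] = colored_noise(rng_noise, (len(active_idx), n), fs,
                                    cfg.noise_exponent, cfg.noise_rms)

    periods = _period_table(events)
    alpha_f = cfg.alpha_peak(participant)
    rng_amp = cfg.rng(participant, 3)

    ssvep_gain = np.array([cfg.ssvep_topography.get(ch, 0.0) for ch in labels])
    alpha_gain = np.array([cfg.alpha_topography.get(ch, 0.0) for ch in labels])
    mask = np.zeros(16, dtype=bool)
    mask[active_idx] = True
    ssvep_gain[~mask] = 0.0
    alpha_gain[~mask] = 0.0

    rho = cfg.alpha_ssvep_coupling
    truth_periods = []
    for _, per in periods.iterrows():
        i0 = int(round(per.time * fs))
        i1 = min(int(round((per.time + PERIOD_DURATION_S) * fs)), n)
        tt = t_axis[i0:i1]
        z = rng_amp.multivariate_normal(
            [0.0, 0.0], [[1.0, rho], [rho, 1.0]])
        jit_s, jit_a = np.exp(cfg.amplitude_jitter_sd * z)
        amp_s = (cfg.ssvep_base_amplitude
                 * cfg.ssvep_amplitude_map[(per.condition, per.contrast)]
                 * jit_s)
        amp_a = cfg.alpha_amplitude_map[per.condition] * jit_a
        phase_s, phase_a, phase_m = rng_amp.uniform(0, 2 * np.pi, 3)
        ssvep = amp_s * np.sin(2 * np.pi * cfg.ssvep_freq * tt + phase_s)
        # slow amplitude modulation keeps alpha realistic but narrowband
        alpha_env = 1.0 + 0.3 * np.sin(2 * np.pi * 0.1 * tt + phase_m)
        alpha = amp_a * alpha_env * np.sin(2 * np.pi * alpha_f * tt + phase_a)
        eeg[:, i0:i1] += ssvep_gain[:, None] * ssvep
        eeg[:, i0:i1] += alpha_gain[:, None] * alpha
        hf = colored_noise(rng_noise, (len(active_idx), i1 - i0), fs, 0.0,
                           cfg.hf_noise_map[per.condition], band=(20.0, 99.0))
        eeg[active_idx, i0:i1] += hf
        if per.condition in cfg.gait_freq_map:
            fg = cfg.gait_freq_map[per.condition]
            gait = cfg.gait_eeg_amplitude * (
                np.sin(2 * np.pi * fg * tt + phase_m)
                + 0.4 * np.sin(2 * np.pi * 2 * fg * tt + phase_m))
            eeg[active_idx, i0:i1] += gait
        truth_periods.append(dict(time=per.time, condition=per.condition,
                                  contrast=per.contrast, block=per.block,
                                  ssvep_amplitude=amp_s,
                                  alpha_amplitude=amp_a,
                                  alpha_freq=alpha_f))

    # ----- EOG / earlobe -----
    rng_art = cfg.rng(participant, 4)
    eog = colored_noise(rng_art, (6, n), fs, cfg.noise_exponent,
                        0.75 * cfg.noise_rms)
    eog += colored_noise(rng_art, (6, n), fs, 0.0, 1.0, band=(20.0, 99.0))
    earlobe = colored_noise(rng_art, (2, n), fs, cfg.noise_exponent,
                            0.5 * cfg.noise_rms)
    gyro = colored_noise(rng_art, (3, n), fs, 0.0, cfg.gyro_noise_rms)

    blink_rows: list[dict] = []
    sacc_rows: list[dict] = []
    head_rows: list[dict] = []
    if include_artifacts:
        blink_len = int(round(cfg.blink_duration_s * fs))
        blink_tmpl = _raised_cosine(blink_len)
        spike_tmpl = spike_potential_template(cfg, fs)
        spike_half = len(spike_tmpl) // 2
        head_len = int(round(cfg.head_move_duration_s * fs))
        head_tmpl = _raised_cosine(head_len)
        for _, per in periods.iterrows():
            t0, t1 = per.time, per.time + PERIOD_DURATION_S
            n_blinks = _per_period_count(cfg.blink_rate, PERIOD_DURATION_S)
            for tb in _event_times_in(rng_art, t0, t1, n_blinks, 0.8, 0.5):
                i0 = int(round(tb * fs)) - blink_len // 2
                sl = slice(max(i0, 0), min(i0 + blink_len, n))
                seg = blink_tmpl[sl.start - i0: sl.stop - i0]
                half = cfg.blink_amplitude / 2.0
                for ch, sign in (("EOGLU", +1), ("EOGRU", +1),
                                 ("EOGLD", -1), ("EOGRD", -1)):
                    eog[EOG_INDEX[ch], sl] += sign * half * seg
                blink_rows.append(dict(time=tb, peak_amp=cfg.blink_amplitude,
                                       block=per.block))
            n_sacc = _per_period_count(cfg.saccade_rate, PERIOD_DURATION_S)
            for ts in _event_times_in(rng_art, t0, t1, n_sacc, 0.15, 0.2):
                mu, sd = cfg.saccade_size_lognorm
                size = float(np.clip(rng_art.lognormal(mu, sd),
                                     *cfg.saccade_size_range))
                amp = float(spike_amplitude(cfg, size))
                i0 = int(round(ts * fs)) - spike_half
                sl = slice(max(i0, 0), min(i0 + len(spike_tmpl), n))
                seg = spike_tmpl[sl.start - i0: sl.stop - i0]
                eog[:, sl] += amp * seg
                sacc_rows.append(dict(time=ts, size=size, amp=amp,
                                      block=per.block))
            n_head = (_per_period_count(cfg.head_move_rate, PERIOD_DURATION_S)
                      if per.condition != "still" else 0)
            for th in _event_times_in(rng_art, t0, t1, n_head, 3.0, 1.0):
                i0 = int(round(th * fs)) - head_len // 2
                sl = slice(max(i0, 0), min(i0 + head_len, n))
                seg = head_tmpl[sl.start - i0: sl.stop - i0]
                axis_w = rng_art.dirichlet(np.ones(3))
                gyro[:, sl] += (cfg.head_move_amplitude
                                * axis_w[:, None] * seg)
                head_rows.append(dict(t_start=max(th - cfg.head_move_duration_s / 2, 0.0),
                                      t_end=th + cfg.head_move_duration_s / 2,
                                      block=per.block))

    # ----- motion speed traces -----
    m = int(round(duration * cfg.fs_motion))
    tm = np.arange(m) / cfg.fs_motion
    rng_mot = cfg.rng(participant, 5)
    motion = 0.02 * rng_mot.standard_normal((3, m))
    for _, per in periods.iterrows():
        j0 = int(round(per.time * cfg.fs_motion))
        j1 = min(int(round((per.time + PERIOD_DURATION_S) * cfg.fs_motion)), m)
        seg_t = tm[j0:j1]
        base = cfg.walking_speed_map.get(per.condition, 0.0)
        motion[0, j0:j1] += base
        if per.condition in cfg.gait_freq_map:
            fg = cfg.gait_freq_map[per.condition]
            ph = rng_mot.uniform(0, 2 * np.pi)
            motion[0, j0:j1] += 0.1 * base * np.sin(2 * np.pi * fg * seg_t + ph)
            for leg, leg_ph in ((1, 0.0), (2, np.pi)):
                motion[leg, j0:j1] += base * (
                    0.8 + 0.5 * np.sin(2 * np.pi * fg * seg_t + ph + leg_ph))

    session = Session(
        eeg=eeg, eog=eog, earlobe=earlobe, gyro=gyro, motion=motion,
        events=events.copy(), fs_eeg=fs, fs_motion=cfg.fs_motion,
        participant=participant,
        ground_truth=dict(
            periods=pd.DataFrame(truth_periods),
            blinks=pd.DataFrame(blink_rows, columns=["time", "peak_amp",
                                                     "block"]),
            saccades=pd.DataFrame(sacc_rows, columns=["time", "size", "amp",
                                                      "block"]),
            head_moves=pd.DataFrame(head_rows, columns=["t_start", "t_end",
                                                        "block"]),
            alpha_freq=alpha_f,
        ),
    )
    session.validate()
    return session


EOG_INDEX = {lab: i for i, lab in enumerate(
    ["EOGLU", "EOGLD", "EOGLC", "EOGRU", "EOGRD", "EOGRC"])}


# ---------------------------------------------------------------------------
# simulated observer
# ---------------------------------------------------------------------------

def psychometric(level: np.ndarray | float, threshold: float,
                 slope: float, lapse: float = 0.0) -> np.ndarray | float:
    """Detection probability: (1 − lapse) · Φ((level − threshold) / slope).

    ``threshold`` is the 50% point of the lapse-free curve; ``slope``
    the cumulative-Gaussian SD in contrast units.
    """
    return (1.0 - lapse) * ndtr((np.asarray(level, float) - threshold) / slope)


def level_for_performance(threshold: float, slope: float, p: float,
                          lapse: float = 0.0) -> float:
    """Stimulus level at which the psychometric function equals ``p``."""
    if not (0 < p < 1 - lapse):
        raise ValueError("requested performance not attainable")
    return threshold + slope * float(ndtri(p / (1.0 - lapse)))


def default_target_level(cfg: SimConfig, p: float = 0.84) -> float:
    """Target contrast as set by the screening staircase: the level at
    which the still / 0%-surround observer detects with probability p."""
    thr = cfg.observer_threshold_map[("still", 0.0)]
    return level_for_performance(thr, cfg.observer_slope, p, cfg.lapse_rate)


def simulate_observer(cfg: SimConfig, events: pd.DataFrame,
                      stimulus_level: float | None = None,
                      participant: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate button presses for every target in a schedule.

    Returns ``(events_with_presses, truth)`` where ``truth`` has one row
    per target (hit flag and reaction time) and the event table gains
    ``button_press`` rows (hits plus spontaneous false-alarm presses).
    """
    cfg.validate()
    if stimulus_level is None:
        stimulus_level = default_target_level(cfg)
    if stimulus_level < 0:
        raise ValueError("stimulus level must be >= 0")
    rng = cfg.rng(participant, 6)
    targets = events[events.kind == "target_onset"]
    press_rows: list[dict] = []
    truth_rows: list[dict] = []
    mu, sd = cfg.rt_lognorm
    for _, row in targets.iterrows():
        thr = cfg.observer_threshold_map[(row.condition, row.contrast)]
        p_hit = psychometric(stimulus_level, thr, cfg.observer_slope,
                             cfg.lapse_rate)
        hit = bool(rng.uniform() < p_hit)
        rt = np.nan
        if hit:
            rt = cfg.rt_shift_s + float(rng.lognormal(mu, sd))
            press_rows.append(dict(time=row.time + rt, kind="button_press",
                                   condition=row.condition,
                                   contrast=row.contrast, block=row.block,
                                   target_location=""))
        truth_rows.append(dict(time=row.time, condition=row.condition,
                               contrast=row.contrast, block=row.block,
                               target_location=row.target_location,
                               hit=hit, rt=rt))
    # spontaneous false alarms, uniform within each contrast period
    for _, per in _period_table(events).iterrows():
        n_fa = rng.poisson(cfg.false_alarm_rate * PERIOD_DURATION_S / 60.0)
        for tf in rng.uniform(per.time, per.time + PERIOD_DURATION_S, n_fa):
            press_rows.append(dict(time=tf, kind="button_press",
                                   condition=per.condition,
                                   contrast=per.contrast, block=per.block,
                                   target_location=""))
    out = pd.concat([events, pd.DataFrame(press_rows, columns=EVENT_COLUMNS)],
                    ignore_index=True)
    out = out.sort_values("time", kind="stable").reset_index(drop=True)
    return out, pd.DataFrame(truth_rows)


def simulate_session(cfg: SimConfig, participant: int = 0,
                     stimulus_level: float | None = None,
                     eeg_channels: list[str] | None = None) -> Session:
    """Schedule + observer + signals for one participant."""
    schedule = make_event_schedule(cfg, participant)
    events, truth = simulate_observer(cfg, schedule, stimulus_level,
                                      participant)
    session = synthesize_signals(cfg, events, participant,
                                 eeg_channels=eeg_channels)
    session.ground_truth["targets"] = truth
    return session


# ---------------------------------------------------------------------------
# trial-level generator (scaled-down studies)
# ---------------------------------------------------------------------------

def synthesize_trial_array(cfg: SimConfig, participant: int,
                           trials_per_cell: int,
                           trial_s: float = 2.0,
                           channels: tuple[str, ...] = ("O1", "Oz", "O2"),
                           ) -> tuple[np.ndarray, pd.DataFrame]:
    """Stand-alone 2-s pre-target trials, bypassing full-session rendering.

    Returns ``(data, labels)`` with ``data`` of shape
    ``(n_trials, n_channels, n_samples)`` and one label row per trial
    (condition, contrast, ground-truth SSVEP/alpha amplitudes).  Used for
    simulation studies that need many participants, where rendering full
    35-s sessions would be wasteful; the per-trial signal model is the
    same as :func:`synthesize_signals` restricted to occipital channels.
    """
    cfg.validate()
    fs = cfg.fs_eeg
    n_samp = int(round(trial_s * fs))
    cells = [(cond, c) for cond in cfg.walking_conditions
             for c in cfg.contrast_levels]
    n_trials = len(cells) * trials_per_cell
    rng = cfg.rng(participant, 7)
    t = np.arange(n_samp) / fs
    alpha_f = cfg.alpha_peak(participant)
    gains_s = np.array([cfg.ssvep_topography.get(ch, 0.0) for ch in channels])
    gains_a = np.array([cfg.alpha_topography.get(ch, 0.0) for ch in channels])

    data = colored_noise(rng, (n_trials, len(channels), n_samp), fs,
                         cfg.noise_exponent, cfg.noise_rms)
    rho = cfg.alpha_ssvep_coupling
    rows = []
    i = 0
    for cond, contrast in cells:
        hf = colored_noise(rng, (trials_per_cell, len(channels), n_samp),
                           fs, 0.0, cfg.hf_noise_map[cond], band=(20.0, 99.0))
        data[i:i + trials_per_cell] += hf
        for k in range(trials_per_cell):
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]])
            jit_s, jit_a = np.exp(cfg.amplitude_jitter_sd * z)
            amp_s = (cfg.ssvep_base_amplitude
                     * cfg.ssvep_amplitude_map[(cond, contrast)] * jit_s)
            amp_a = cfg.alpha_amplitude_map[cond] * jit_a
            ph_s, ph_a = rng.uniform(0, 2 * np.pi, 2)
            data[i] += gains_s[:, None] * amp_s * np.sin(
                2 * np.pi * cfg.ssvep_freq * t + ph_s)
            data[i] += gains_a[:, None] * amp_a * np.sin(
                2 * np.pi * alpha_f * t + ph_a)
            rows.append(dict(trial=i, condition=cond, contrast=contrast,
                             block=cells.index((cond, contrast)),
                             ssvep_amplitude=amp_s, alpha_amplitude=amp_a,
                             alpha_freq=alpha_f))
            i += 1
    return data, pd.DataFrame(rows)
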