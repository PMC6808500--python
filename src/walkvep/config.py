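"""Pipeline configuration: every numeric constant of the analysis in one place.

Defaults reproduce the analysis constants of the free-walking SSVEP
protocol this package implements: Welch spectra from 1-s windows with
50% overlap, SSVEP power at 15 Hz referenced to 13/14/16/17 Hz,
high-frequency band 20–99 Hz, the MAD–median outlier rule with scale
0.6745 and cutoff 2.24, and the blink / saccade / head-movement
detector thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, is_dataclass, replace
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is out of range or unknown."""


@dataclass(frozen=True)
class FilterSpec:
    """Kaiser-window FIR design rules used for all band filtering."""

    transition_frac: float = 0.25   # transition width as fraction of low edge
    min_transition_hz: float = 1.0
    stopband_db: float = 60.0

    def validate(self) -> None:
        if not (0 < self.transition_frac <= 1):
            raise ConfigError("filter.transition_frac must be in (0, 1]")
        if self.min_transition_hz <= 0 or self.stopband_db <= 0:
            raise ConfigError("filter widths/attenuation must be positive")


@dataclass(frozen=True)
class WelchSpec:
    window_s: float = 1.0
    overlap: float = 0.5
    taper: str = "hamming"

    def validate(self) -> None:
        if self.window_s <= 0:
            raise ConfigError("welch.window_s must be positive")
        if not (0 <= self.overlap < 1):
            raise ConfigError("welch.overlap must be in [0, 1)")


@dataclass(frozen=True)
class MadSpec:
    scale: float = 0.6745
    cutoff: float = 2.24

    def validate(self) -> None:
        if self.scale <= 0 or self.cutoff <= 0:
            raise ConfigError("mad constants must be positive")


@dataclass(frozen=True)
class BlinkSpec:
    hp_hz: float = 0.2
    lp_hz: float = 20.0
    cross_uv: float = 20.0
    min_peak_uv: float = 40.0
    min_sd_uv: float = 15.0
    merge_ms: float = 100.0
    sd_window_ms: float = 400.0   # window for the local-amplitude-SD criterion

    def validate(self) -> None:
        if not (0 < self.hp_hz < self.lp_hz):
            raise ConfigError("blink band edges must satisfy 0 < hp < lp")
        for name in ("cross_uv", "min_peak_uv", "min_sd_uv", "merge_ms",
                     "sd_window_ms"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"blink.{name} must be positive")


@dataclass(frozen=True)
class SaccadeSpec:
    band_hz: tuple[float, float] = (20.0, 90.0)
    order: int = 6
    sd_mult: float = 2.5
    group_ms: float = 20.0
    window_ms: float = 80.0
    warmup_ms: float = 100.0

    def validate(self) -> None:
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise ConfigError("saccade.band_hz must be increasing and positive")
        if self.order < 1:
            raise ConfigError("saccade.order must be >= 1")
        for name in ("sd_mult", "group_ms", "window_ms", "warmup_ms"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"saccade.{name} must be positive")


@dataclass(frozen=True)
class HeadSpec:
    sd_mult: float = 2.5
    merge_s: float = 2.0

    def validate(self) -> None:
        if self.sd_mult <= 0 or self.merge_s <= 0:
            raise ConfigError("head constants must be positive")


@dataclass(frozen=True)
class BehaviorSpec:
    hit_window_s: float = 1.0
    pre_press_exclusion_s: float = 2.5

    def validate(self) -> None:
        if self.hit_window_s <= 0 or self.pre_press_exclusion_s <= 0:
            raise ConfigError("behavior windows must be positive")


@dataclass(frozen=True)
class StaircaseSpec:
    """Transformed up/down staircase rules.

    The screening staircase is 1-up-4-down with a fixed step; the
    follow-up threshold staircase is 1-up-3-down with a 6% step before
    the fourth reversal and 3% after, stopping at 13 reversals, the
    threshold being the mean of the last 10 reversal levels.
    """

    step_1u4d: float = 0.02
    step_initial_1u3d: float = 0.06
    step_late_1u3d: float = 0.03
    step_switch_reversal: int = 4
    n_reversals_1u3d: int = 13
    n_reversals_averaged: int = 10

    def validate(self) -> None:
        for name in ("step_1u4d", "step_initial_1u3d", "step_late_1u3d"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"staircase.{name} must be positive")
        if self.n_reversals_averaged > self.n_reversals_1u3d:
            raise ConfigError("cannot average more reversals than collected")


@dataclass(frozen=True)
class PipelineConfig:
    filter: FilterSpec = field(default_factory=FilterSpec)
    welch: WelchSpec = field(default_factory=WelchSpec)
    ssvep_freq: float = 15.0
    ssvep_reference_freqs: tuple[float, ...] = (13.0, 14.0, 16.0, 17.0)
    alpha_band: tuple[float, float] = (8.0, 12.0)
    alpha_reference_freqs: tuple[float, ...] = (10.0, 11.0, 12.0)
    hf_band: tuple[float, float] = (20.0, 99.0)
    envelope_band: tuple[float, float] = (14.5, 15.5)
    envelope_edge_s: float = 0.5
    broadband: tuple[float, float] = (1.0, 100.0)
    mad: MadSpec = field(default_factory=MadSpec)
    blink: BlinkSpec = field(default_factory=BlinkSpec)
    saccade: SaccadeSpec = field(default_factory=SaccadeSpec)
    head: HeadSpec = field(default_factory=HeadSpec)
    behavior: BehaviorSpec = field(default_factory=BehaviorSpec)
    staircase: StaircaseSpec = field(default_factory=StaircaseSpec)
    n_ssvep_channels: int = 3

    def validate(self) -> None:
        for sub in (self.filter, self.welch, self.mad, self.blink,
                    self.saccade, self.head, self.behavior, self.staircase):
            sub.validate()
        for name in ("alpha_band", "hf_band", "envelope_band", "broadband"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ConfigError(f"{name} must be increasing and positive, "
                                  f"got ({lo}, {hi})")
        if self.ssvep_freq <= 0:
            raise ConfigError("ssvep_freq must be positive")
        if self.n_ssvep_channels < 1:
            raise ConfigError("n_ssvep_channels must be >= 1")


def _coerce(value: Any, template: Any) -> Any:
    if isinstance(template, tuple) and isinstance(value, (list, tuple)):
        return tuple(value)
    return value


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a (possibly partial) mapping."""
    cfg = PipelineConfig()
    updates: dict[str, Any] = {}
    for key, value in data.items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown config field: {key!r}")
        current = getattr(cfg, key)
        if is_dataclass(current) and isinstance(value, dict):
            sub_updates = {}
            for k, v in value.items():
                if not hasattr(current, k):
                    raise ConfigError(f"unknown config field: {key}.{k}")
                sub_updates[k] = _coerce(v, getattr(current, k))
            updates[key] = replace(current, **sub_updates)
        else:
            updates[key] = _coerce(value, current)
    cfg = replace(cfg, **updates)
    cfg.validate()
    return cfg


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML/JSON pipeline configuration; an empty file yields defaults."""
    if path is None:
        cfg = PipelineConfig()
        cfg.validate()
        return cfg
    raw = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(raw)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(data)
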