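"""Adaptive staircases, response scoring and the target-preference index.

Transformed up/down staircases: one miss raises the stimulus level by
one step, ``k`` consecutive hits lower it; the procedure converges to
the level where the hit probability is ``0.5**(1/k)`` — 84.1% for
1-up-4-down (used to set the target contrast before the main task) and
79.4% for 1-up-3-down (the follow-up threshold procedure, step 6%
before the fourth reversal and 3% after, stopping at 13 reversals with
the threshold taken as the mean of the last 10 reversal levels).

The target preference index summarizes how unevenly detections spread
over the four target locations:  ``Σ_i |T − t_i| / (6T)`` with ``t_i``
the per-location detection rates and ``T`` their mean — 0 for uniform
responding, 1 when only one location is ever detected.  Because the
index is biased upward when few targets are detected, its significance
is assessed against a simulation null that scatters the detected
targets uniformly over locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import PipelineConfig, StaircaseSpec


# ---------------------------------------------------------------------------
# staircases
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StaircaseState:
    """Immutable state of a transformed up/down staircase."""

    rule: str                      # "1up4down" | "1up3down"
    level: float
    spec: StaircaseSpec = field(default_factory=StaircaseSpec)
    consecutive_correct: int = 0
    n_trials: int = 0
    reversals: tuple[tuple[int, float], ...] = ()   # (trial index, level)
    last_direction: int = 0        # +1 up, -1 down, 0 none yet
    clamped: bool = False
    history: tuple[float, ...] = ()

    @property
    def k_down(self) -> int:
        return {"1up4down": 4, "1up3down": 3}[self.rule]

    @property
    def step(self) -> float:
        if self.rule == "1up4down":
            return self.spec.step_1u4d
        # steps taken before the fourth reversal has occurred use the
        # large step; from the fourth reversal on, the small one
        if len(self.reversals) < self.spec.step_switch_reversal:
            return self.spec.step_initial_1u3d
        return self.spec.step_late_1u3d

    @property
    def finished(self) -> bool:
        return (self.rule == "1up3down"
                and len(self.reversals) >= self.spec.n_reversals_1u3d)


def staircase_step(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the staircase by one trial outcome.

    Any miss moves the level up by one step immediately; ``k``
    consecutive hits move it down and reset the counter.  A direction
    change is logged as a reversal at the level where it occurred.
    Levels are clamped at 0 (with a flag) rather than going negative.
    """
    trial = state.n_trials
    level, direction = state.level, 0
    consec = state.consecutive_correct
    if correct:
        consec += 1
        if consec >= state.k_down:
            level -= state.step
            consec = 0
            direction = -1
    else:
        level += state.step
        consec = 0
        direction = +1
    reversals = state.reversals
    last_dir = state.last_direction
    if direction != 0:
        if last_dir != 0 and direction != last_dir:
            reversals = reversals + ((trial, state.level),)
        last_dir = direction
    clamped = state.clamped
    if level < 0:
        level, clamped = 0.0, True
    return replace(state, level=level, consecutive_correct=consec,
                   n_trials=trial + 1, reversals=reversals,
                   last_direction=last_dir, clamped=clamped,
                   history=state.history + (state.level,))


def run_staircase(rule: str, observer, start_level: float,
                  n_trials: int | None = None,
                  rng: np.random.Generator | None = None,
                  spec: StaircaseSpec | None = None) -> StaircaseState:
    """Run a staircase against ``observer(level) -> P(correct)``.

    For ``1up4down`` give ``n_trials``; ``1up3down`` stops at the
    configured reversal count (with ``n_trials`` as a safety bound).
    """
    rng = rng or np.random.default_rng()
    state = StaircaseState(rule=rule, level=start_level,
                           spec=spec or StaircaseSpec())
    limit = n_trials if n_trials is not None else 10_000
    for _ in range(limit):
        if state.finished:
            break
        correct = bool(rng.uniform() < observer(state.level))
        state = staircase_step(state, correct)
    return state


def staircase_threshold(state: StaircaseState,
                        n_reversals: int | None = None) -> float:
    """Mean level over the last ``n_reversals`` reversal points."""
    n = n_reversals if n_reversals is not None else state.spec.n_reversals_averaged
    if len(state.reversals) < n:
        raise ValueError(f"only {len(state.reversals)} reversals recorded, "
                         f"need {n}")
    return float(np.mean([lvl for _, lvl in state.reversals[-n:]]))


# ---------------------------------------------------------------------------
# response scoring
# ---------------------------------------------------------------------------

def score_responses(events: pd.DataFrame,
                    cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-target outcomes from an event stream.

    A press within ``(t_target, t_target + hit_window]`` makes the
    earliest unassigned target a hit with RT = press − target; every
    press is used at most once and presses matching no target are false
    alarms.  Returns one row per target (hit, rt) plus one row per
    false alarm (``kind == "fa"``), each labelled with its condition
    cell.
    """
    cfg = cfg or PipelineConfig()
    win = cfg.behavior.hit_window_s
    targets = events[events.kind == "target_onset"].sort_values("time")
    presses = events[events.kind == "button_press"].sort_values("time")
    press_times = presses["time"].to_numpy(dtype=float)
    assigned = np.zeros(len(press_times), dtype=bool)
    rows = []
    for _, tg in targets.iterrows():
        cand = np.where((press_times > tg.time)
                        & (press_times <= tg.time + win) & ~assigned)[0]
        hit, rt = False, np.nan
        if cand.size:
            assigned[cand[0]] = True
            hit, rt = True, float(press_times[cand[0]] - tg.time)
        rows.append(dict(kind="target", time=tg.time, condition=tg.condition,
                         contrast=tg.contrast, block=tg.block,
                         target_location=tg.target_location,
                         hit=hit, rt=rt))
    for k, (_, pr) in enumerate(presses.iterrows()):
        if not assigned[k]:
            rows.append(dict(kind="fa", time=pr.time, condition=pr.condition,
                             contrast=pr.contrast, block=pr.block,
                             target_location="", hit=False, rt=np.nan))
    return pd.DataFrame(rows)


def detection_rate_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Per (condition, contrast) cell: detection rate, FA count, mean RT."""
    targets = scored[scored.kind == "target"]
    fas = scored[scored.kind == "fa"]
    rows = []
    for (cond, contrast), grp in targets.groupby(["condition", "contrast"]):
        n_fa = len(fas[(fas.condition == cond) & (fas.contrast == contrast)])
        hits = grp[grp.hit]
        rows.append(dict(condition=cond, contrast=contrast,
                         n_targets=len(grp), n_hits=len(hits),
                         detection_rate=len(hits) / len(grp),
                         false_alarms=n_fa,
                         mean_rt=hits.rt.mean() if len(hits) else np.nan))
    return pd.DataFrame(rows)


def location_rates(scored: pd.DataFrame,
                   locations: tuple[str, ...] = ("up", "down", "left",
                                                 "right")) -> pd.DataFrame:
    """Per (condition, contrast, location) detection rate table."""
    targets = scored[scored.kind == "target"]
    rows = []
    for (cond, contrast), grp in targets.groupby(["condition", "contrast"]):
        for loc in locations:
            sub = grp[grp.target_location == loc]
            rows.append(dict(condition=cond, contrast=contrast, location=loc,
                             n_targets=len(sub),
                             n_hits=int(sub.hit.sum()),
                             rate=sub.hit.mean() if len(sub) else np.nan))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# target preference index
# ---------------------------------------------------------------------------

def preference_index(rates) -> float:
    """Unevenness of detection over locations: ``Σ_i |T − t_i| / (6T)``.

    ``T`` is the mean of the four per-location rates ``t_i``.  0 when
    all rates are equal, 1 when only one location is detected;
    invariant to a common rescaling of the rates.  Undefined (raises)
    when no target was detected at all (``T = 0``).
    """
    t = np.asarray(rates, dtype=float)
    if t.ndim != 1 or t.size != 4:
        raise ValueError("expected four per-location rates")
    if np.any(t < 0):
        raise ValueError("rates must be non-negative")
    big_t = t.mean()
    if big_t == 0:
        raise ZeroDivisionError("preference index undefined when nothing "
                                "was detected (T = 0)")
    return float(np.abs(big_t - t).sum() / (6.0 * big_t))


def simulate_null_indices(n_detected: int, n_sims: int = 1000,
                          rng: np.random.Generator | None = None,
                          n_locations: int = 4) -> np.ndarray:
    """Preference indices when detections fall uniformly over locations."""
    if n_detected <= 0:
        raise ValueError("need at least one detected target")
    rng = rng or np.random.default_rng()
    locs = rng.integers(0, n_locations, size=(n_sims, n_detected))
    counts = np.stack([(locs == j).sum(axis=1) for j in range(n_locations)],
                      axis=1).astype(float)
    big_t = counts.mean(axis=1)
    return np.abs(counts - big_t[:, None]).sum(axis=1) / (6.0 * big_t)


def preference_null(observed: float, n_detected: int, n_sims: int = 1000,
                    rng: np.random.Generator | None = None) -> float:
    """p-value: fraction of null indices at or above the observed index.

    The null scatters the same number of detected targets independently
    and uniformly over the four locations; because the per-location
    target counts cancel from the index, only ``n_detected`` matters.
    """
    sims = simulate_null_indices(n_detected, n_sims, rng)
    return float(np.mean(sims >= observed))


# ---------------------------------------------------------------------------
# follow-up threshold analyses
# ---------------------------------------------------------------------------

def relative_threshold_diff(walk: float, still: float) -> float:
    """Normalized walking–still threshold difference
    ``(walk − still) / (walk + still)`` ∈ [−1, 1]."""
    if walk < 0 or still < 0:
        raise ValueError("thresholds must be non-negative")
    if walk + still == 0:
        raise ZeroDivisionError("both thresholds are zero")
    return (walk - still) / (walk + still)


def baseline_matched_subset(table: pd.DataFrame, rank_key: str,
                            n_exclude: int) -> pd.DataFrame:
    """Drop the ``n_exclude`` participants ranking highest on ``rank_key``.

    ``table`` has one row per participant.  Sorting is descending by
    key with ties broken by participant id (stable), emulating the
    exclusion of participants with the largest baseline detection-rate
    difference so the remaining sample is baseline-matched.
    """
    if n_exclude >= len(table):
        raise ValueError("cannot exclude every participant")
    if n_exclude < 0:
        raise ValueError("n_exclude must be >= 0")
    ordered = table.sort_values([rank_key, "participant"],
                                ascending=[False, True], kind="stable")
    return ordered.iloc[n_exclude:].sort_values("participant").reset_index(
        drop=True)
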