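"""End-to-end orchestration: session → trial spectra → condition cells.

``analyze_session`` runs the full single-participant chain (epoching,
filtering, pre-target trial extraction with press exclusion, Welch
spectra, occipital channel selection, MAD–median HF exclusion and the
referenced SSVEP/alpha statistics) and aggregates per condition cell.
``simulate_experiment`` repeats a scaled-down version of the chain over
many simulated participants using the trial-level generator, returning
the cell table a group-level within-subjects ANOVA consumes — the
harness for power/recovery simulation studies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .preprocess import (TrialSet, bandpass_fir, epoch_periods,
                         extract_pretarget_trials, mad_exclude_hf)
from .session import OCCIPITAL_POOL, Session
from .spectral import select_channels, spectrum_table, welch_psd
from .synth import SimConfig, synthesize_trial_array


def analyze_session(session: Session,
                    cfg: PipelineConfig | None = None,
                    filter_data: bool = True) -> dict:
    """Single-participant spectral pipeline.

    Returns a dict with the period and pre-target trial sets, the
    selected SSVEP channels, the per-trial spectrum table (exclusion
    flags merged in) and the per-cell means over retained trials.
    """
    cfg = cfg or PipelineConfig()
    periods = epoch_periods(session)
    trials = extract_pretarget_trials(periods, cfg)
    usable = trials.table[~(trials.table.excluded_press
                            | trials.table.short_trial)]

    data = trials.get_data(channels=session.eeg_labels, rows=usable)
    if filter_data:
        lo, hi = cfg.broadband
        data = bandpass_fir(data, lo, hi, session.fs_eeg, cfg)
    freqs, power = welch_psd(data, session.fs_eeg, cfg)
    pool = [ch for ch in OCCIPITAL_POOL if ch in session.eeg_labels]
    picks = select_channels(power, freqs, session.eeg_labels, pool,
                            n=cfg.n_ssvep_channels, target=cfg.ssvep_freq)
    pick_idx = [session.eeg_labels.index(ch) for ch in picks]
    spectra = spectrum_table(power[:, pick_idx], freqs,
                             usable.reset_index(drop=True), cfg)

    flagged = mad_exclude_hf(
        TrialSet(session, spectra, kind="pretarget_2s"),
        spectra["hf_power"].to_numpy(), cfg)
    spectra = flagged.table
    retained = spectra[~spectra.excluded_mad]
    cells = (retained.groupby(["condition", "contrast"])
             [["raw_ssvep", "ref_ssvep", "raw_alpha", "ref_alpha",
               "hf_power"]].mean().reset_index())
    return dict(periods=periods, trials=trials, channels=picks,
                spectra=spectra, cells=cells, freqs=freqs)


def _trial_cells(cfg: SimConfig, participant: int, trials_per_cell: int,
                 pipe: PipelineConfig) -> pd.DataFrame:
    data, labels = synthesize_trial_array(cfg, participant, trials_per_cell)
    freqs, power = welch_psd(data, cfg.fs_eeg, pipe)
    spectra = spectrum_table(power, freqs, labels, pipe)
    mask = np.zeros(len(spectra), dtype=bool)
    from .preprocess import mad_median_outliers
    for cond, idx in spectra.groupby("condition").groups.items():
        pos = spectra.index.get_indexer(idx)
        mask[pos] = mad_median_outliers(
            spectra["hf_power"].to_numpy()[pos],
            pipe.mad.scale, pipe.mad.cutoff)
    retained = spectra[~mask]
    cells = (retained.groupby(["condition", "contrast"])
             [["raw_ssvep", "ref_ssvep", "raw_alpha", "ref_alpha"]]
             .mean().reset_index())
    cells.insert(0, "participant", participant)
    return cells


def simulate_experiment(cfg: SimConfig, n_subjects: int = 25,
                        trials_per_cell: int = 6,
                        pipe: PipelineConfig | None = None) -> pd.DataFrame:
    """Cell table (participant × condition × contrast) for one simulated
    experiment, via the trial-level generator and the spectral pipeline."""
    pipe = pipe or PipelineConfig()
    return pd.concat(
        [_trial_cells(cfg, p, trials_per_cell, pipe)
         for p in range(n_subjects)], ignore_index=True)


def cells_to_array(cells: pd.DataFrame, measure: str,
                   conditions: tuple[str, ...],
                   contrasts: tuple[float, ...]) -> np.ndarray:
    """Pivot a cell table to the (n, a, b) array ``rm_anova`` expects."""
    participants = sorted(cells.participant.unique())
    out = np.full((len(participants), len(conditions), len(contrasts)),
                  np.nan)
    for k, p in enumerate(participants):
        sub = cells[cells.participant == p]
        for i, cond in enumerate(conditions):
            for j, c in enumerate(contrasts):
                cell = sub[(sub.condition == cond)
                           & (np.isclose(sub.contrast, c))]
                if len(cell):
                    out[k, i, j] = cell[measure].iloc[0]
    if np.isnan(out).any():
        raise ValueError("incomplete cell table")
    return out
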