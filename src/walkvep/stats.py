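"""Inferential layer: within-subjects ANOVA, t tests, FDR, and the
trial-level association analyses.

The two-way within-subjects ANOVA is computed directly from sums of
squares (each effect tested against its effect-by-subject interaction)
with Greenhouse–Geisser correction of the degrees of freedom when
Mauchly's test rejects sphericity.  The SSVEP–alpha association is
probed two ways: a median split of trials by raw SSVEP power (with
high-frequency-power matching between the weak/strong groups) and a
two-level regression — per-participant OLS of single-trial SSVEP power
on alpha power and blink/saccade counts (power z-scored within each
testing block), followed by a group-level one-sample t on the slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaEffect:
    name: str
    F: float
    df1: float
    df2: float
    p: float
    eta_p2: float
    epsilon: float            # Greenhouse–Geisser estimate
    sphericity_p: float       # Mauchly p (nan when untestable)
    corrected: bool           # GG applied to the reported p
    p_uncorrected: float
    df1_gg: float
    df2_gg: float
    p_gg: float


def _helmert(k: int) -> np.ndarray:
    """Orthonormal (k × k−1) contrast basis of the k-level factor."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.linalg.norm(h[:, j - 1])
    return h


def _gg_and_mauchly(cells: np.ndarray, contrast: np.ndarray
                    ) -> tuple[float, float]:
    """Greenhouse–Geisser ε and Mauchly p for one within effect.

    ``cells`` is (n, p) subject-by-cell data; ``contrast`` (p × df)
    orthonormal columns spanning the effect.
    """
    n, df = cells.shape[0], contrast.shape[1]
    d = cells @ contrast
    sigma = np.cov(d, rowvar=False)
    sigma = np.atleast_2d(sigma)
    tr = np.trace(sigma)
    eps = (tr ** 2) / (df * np.trace(sigma @ sigma)) if tr > 0 else 1.0
    eps = float(min(max(eps, 1.0 / df), 1.0))
    if df < 2:
        return 1.0, np.nan
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0 or n - 1 <= df:
        return eps, 0.0   # singular covariance: sphericity untenable
    log_w = logdet - df * np.log(tr / df)
    f = 1.0 - (2 * df ** 2 + df + 2) / (6.0 * df * (n - 1))
    chi2 = -(n - 1) * f * log_w
    df_chi = df * (df + 1) // 2 - 1
    return eps, float(sst.chi2.sf(chi2, df_chi))


def rm_anova(data: np.ndarray, alpha: float = 0.05,
             factor_names: tuple[str, str] = ("A", "B")) -> dict:
    """Two-way fully within-subjects ANOVA on ``data`` (n, a, b).

    Returns a dict of :class:`AnovaEffect` for the two main effects and
    the interaction.  Greenhouse–Geisser-corrected p-values replace the
    uncorrected ones when Mauchly's test rejects sphericity at
    ``alpha`` (the GG quantities are reported either way).  Partial
    eta-squared is SS_effect / (SS_effect + SS_error).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be (n_subjects, a, b)")
    if np.isnan(data).any():
        raise ValueError("missing cells are not allowed")
    n, a, b = data.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = data.mean()
    m_s = data.mean(axis=(1, 2))
    m_a = data.mean(axis=(0, 2))
    m_b = data.mean(axis=(0, 1))
    m_ab = data.mean(axis=0)
    m_sa = data.mean(axis=2)
    m_sb = data.mean(axis=1)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - grand) ** 2) - ss_a - ss_b
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_subj = a * b * np.sum((m_s - grand) ** 2)
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs

    cells = data.reshape(n, a * b)
    h_a, h_b = _helmert(a), _helmert(b)
    ones_a = np.full((a, 1), 1 / np.sqrt(a))
    ones_b = np.full((b, 1), 1 / np.sqrt(b))
    contrasts = {
        factor_names[0]: np.kron(h_a, ones_b),
        factor_names[1]: np.kron(ones_a, h_b),
        f"{factor_names[0]}x{factor_names[1]}": np.kron(h_a, h_b),
    }
    effects = {
        factor_names[0]: (ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        factor_names[1]: (ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        f"{factor_names[0]}x{factor_names[1]}":
            (ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    }
    out: dict[str, AnovaEffect] = {}
    for name, (ss_eff, df1, ss_err, df2) in effects.items():
        ms_eff, ms_err = ss_eff / df1, ss_err / df2
        f_val = ms_eff / ms_err if ms_err > 0 else 0.0
        p_unc = float(sst.f.sf(f_val, df1, df2)) if ms_err > 0 else 1.0
        eps, mauchly_p = _gg_and_mauchly(cells, contrasts[name])
        df1_gg, df2_gg = eps * df1, eps * df2
        p_gg = float(sst.f.sf(f_val, df1_gg, df2_gg)) if ms_err > 0 else 1.0
        corrected = bool(not np.isnan(mauchly_p) and mauchly_p < alpha)
        out[name] = AnovaEffect(
            name=name, F=float(f_val),
            df1=df1_gg if corrected else df1,
            df2=df2_gg if corrected else df2,
            p=p_gg if corrected else p_unc,
            eta_p2=float(ss_eff / (ss_eff + ss_err)) if ss_eff + ss_err > 0
            else 0.0,
            epsilon=eps, sphericity_p=mauchly_p, corrected=corrected,
            p_uncorrected=p_unc, df1_gg=df1_gg, df2_gg=df2_gg, p_gg=p_gg)
    return out


# ---------------------------------------------------------------------------
# t tests and FDR
# ---------------------------------------------------------------------------

def paired_t(x: np.ndarray, y: np.ndarray) -> dict:
    """Two-tailed paired t test with the within-subject effect size
    ``d_z = mean(diff) / sd(diff)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("zero-variance difference: t undefined")
    n = diff.size
    t = diff.mean() / (sd / np.sqrt(n))
    return dict(t=float(t), df=n - 1,
                p=float(2 * sst.t.sf(abs(t), n - 1)),
                d_z=float(diff.mean() / sd))


def one_sample_t(x: np.ndarray, popmean: float = 0.0) -> dict:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("zero variance: t undefined")
    t = (x.mean() - popmean) / (sd / np.sqrt(x.size))
    return dict(t=float(t), df=x.size - 1,
                p=float(2 * sst.t.sf(abs(t), x.size - 1)),
                d=float((x.mean() - popmean) / sd))


def fdr_bh(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (adjusted p, rejection mask at q)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    adjusted = np.empty_like(adj)
    adjusted[order] = adj
    return adjusted, adjusted <= q


# ---------------------------------------------------------------------------
# SSVEP–alpha association
# ---------------------------------------------------------------------------

def median_split_matched(spectra: pd.DataFrame,
                         walking_conditions: tuple[str, ...] = ("slow",
                                                                "normal"),
                         n_trim: int = 5,
                         min_group: int = 5) -> pd.DataFrame:
    """Median split of trials by raw SSVEP power, HF-matched.

    Within each walking condition, trials at or below the condition
    median of ``raw_ssvep`` form the weak group (the median trial joins
    the weak group on odd counts), the rest the strong group.  For the
    conditions in ``walking_conditions``, the ``n_trim`` lowest-HF
    trials leave the weak group and the ``n_trim`` highest-HF trials
    leave the strong group, removing the groups' HF-power confound;
    trimming is skipped when a group would drop below ``min_group``
    trials.  Returns per-condition per-group mean band powers.
    """
    required = {"condition", "raw_ssvep", "hf_power"}
    if not required <= set(spectra.columns):
        raise ValueError(f"spectra table needs columns {sorted(required)}")
    rows = []
    for cond, grp in spectra.groupby("condition"):
        if len(grp) < 12:
            raise ValueError(f"condition {cond!r}: need >= 12 trials for a "
                             "median split, got {len(grp)}")
        med = grp.raw_ssvep.median()
        weak = grp[grp.raw_ssvep <= med]
        strong = grp[grp.raw_ssvep > med]
        if cond in walking_conditions:
            if (len(weak) - n_trim >= min_group
                    and len(strong) - n_trim >= min_group):
                weak = weak.sort_values("hf_power").iloc[n_trim:]
                strong = strong.sort_values("hf_power").iloc[:len(strong)
                                                             - n_trim]
            else:
                warnings.warn(f"condition {cond!r}: too few trials to trim "
                              "HF extremes", stacklevel=2)
        for label, g in (("weak", weak), ("strong", strong)):
            row = dict(condition=cond, group=label, n_trials=len(g))
            for col in ("raw_ssvep", "hf_power", "delta_power",
                        "theta_power", "alpha_power", "raw_alpha",
                        "ref_alpha"):
                if col in g.columns:
                    row[col] = float(g[col].mean())
            rows.append(row)
    return pd.DataFrame(rows)


def count_matched_average(values: np.ndarray, counts: np.ndarray) -> float:
    """Mean of ``values`` stratified by ``counts``: average within each
    count stratum first, then unweighted across strata — removing the
    confound of unequal count distributions."""
    values = np.asarray(values, dtype=float)
    counts = np.asarray(counts)
    if values.shape != counts.shape:
        raise ValueError("values and counts must align")
    strata = [values[counts == c].mean() for c in np.unique(counts)]
    return float(np.mean(strata))


def _zscore_within(values: pd.Series, groups: pd.Series) -> np.ndarray:
    out = np.empty(len(values))
    for g, idx in values.groupby(groups).groups.items():
        v = values.loc[idx].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        out[values.index.get_indexer(idx)] = (
            (v - v.mean()) / sd if sd > 0 else 0.0)
    return out


def two_level_regression(trials: pd.DataFrame,
                         response: str = "raw_ssvep",
                         predictors: tuple[str, ...] = ("raw_alpha",
                                                        "n_blinks",
                                                        "n_saccades"),
                         normalize: tuple[str, ...] = ("raw_ssvep",
                                                       "raw_alpha"),
                         ) -> tuple[pd.DataFrame, dict]:
    """Per-participant OLS of single-trial SSVEP power, then group t.

    ``trials`` needs columns ``participant``, ``block``, the response
    and the predictors.  Columns named in ``normalize`` are z-scored
    within each (participant, block) before fitting.  Participants
    with a rank-deficient design (e.g. a constant predictor) are
    skipped with a warning.  Returns (per-participant slopes, group
    one-sample t of each slope against 0).
    """
    needed = {"participant", "block", response, *predictors}
    if not needed <= set(trials.columns):
        raise ValueError(f"trials table needs columns {sorted(needed)}")
    slopes = []
    for pid, grp in trials.groupby("participant"):
        grp = grp.reset_index(drop=True)
        if len(grp) < len(predictors) + 2:
            warnings.warn(f"participant {pid}: too few trials; skipped",
                          stacklevel=2)
            continue
        cols = {}
        for name in (response, *predictors):
            v = grp[name].astype(float)
            cols[name] = (_zscore_within(v, grp["block"])
                          if name in normalize else v.to_numpy())
        x = np.column_stack([np.ones(len(grp))]
                            + [cols[p] for p in predictors])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            warnings.warn(f"participant {pid}: rank-deficient design; "
                          "skipped", stacklevel=2)
            continue
        beta, *_ = np.linalg.lstsq(x, cols[response], rcond=None)
        slopes.append(dict(participant=pid,
                           **{p: beta[j + 1] for j, p in
                              enumerate(predictors)}))
    slope_df = pd.DataFrame(slopes)
    if len(slope_df) < 2:
        raise ValueError("fewer than 2 participants with estimable slopes")
    group = {p: one_sample_t(slope_df[p].to_numpy()) for p in predictors}
    return slope_df, group
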