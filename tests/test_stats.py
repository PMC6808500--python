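"""ANOVA, t tests, FDR, median split, count matching, two-level regression."""

import numpy as np
import pandas as pd
import pytest

from walkvep.stats import (
    count_matched_average,
    fdr_bh,
    median_split_matched,
    one_sample_t,
    paired_t,
    rm_anova,
    two_level_regression,
)


def bruteforce_rm_anova(data):
    """Loop-based sums-of-squares oracle for the two-way within design."""
    n, a, b = data.shape
    grand = data.mean()
    ss = dict(A=0.0, B=0.0, AB=0.0, AS=0.0, BS=0.0, ABS=0.0)
    for i in range(a):
        ss["A"] += n * b * (data[:, i, :].mean() - grand) ** 2
    for j in range(b):
        ss["B"] += n * a * (data[:, :, j].mean() - grand) ** 2
    for i in range(a):
        for j in range(b):
            ss["AB"] += n * (data[:, i, j].mean() - data[:, i, :].mean()
                             - data[:, :, j].mean() + grand) ** 2
    for s in range(n):
        for i in range(a):
            ss["AS"] += b * (data[s, i, :].mean() - data[s].mean()
                             - data[:, i, :].mean() + grand) ** 2
        for j in range(b):
            ss["BS"] += a * (data[s, :, j].mean() - data[s].mean()
                             - data[:, :, j].mean() + grand) ** 2
        for i in range(a):
            for j in range(b):
                ss["ABS"] += (data[s, i, j] - data[s, i, :].mean()
                              - data[s, :, j].mean()
                              - data[:, i, j].mean()
                              + data[s].mean() + data[:, i, :].mean()
                              + data[:, :, j].mean() - grand) ** 2
    f_a = (ss["A"] / (a - 1)) / (ss["AS"] / ((a - 1) * (n - 1)))
    f_b = (ss["B"] / (b - 1)) / (ss["BS"] / ((b - 1) * (n - 1)))
    f_ab = (ss["AB"] / ((a - 1) * (b - 1))) / (
        ss["ABS"] / ((a - 1) * (b - 1) * (n - 1)))
    return f_a, f_b, f_ab, ss


class TestRmAnova:
    def test_constant_responses_give_zero_f(self):
        res = rm_anova(np.full((5, 3, 4), 2.0))
        assert all(eff.F == 0.0 for eff in res.values())

    def test_two_level_factor_has_epsilon_one(self):
        rng = np.random.default_rng(0)
        res = rm_anova(rng.normal(size=(8, 2, 4)))
        assert res["A"].epsilon == 1.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            data = rng.normal(size=(7, 3, 4)) + rng.normal(size=(7, 1, 1))
            res = rm_anova(data)
            f_a, f_b, f_ab, _ = bruteforce_rm_anova(data)
            assert res["A"].F == pytest.approx(f_a, abs=1e-10)
            assert res["B"].F == pytest.approx(f_b, abs=1e-10)
            assert res["AxB"].F == pytest.approx(f_ab, abs=1e-10)

    def test_matches_pingouin(self):
        """Independent cross-check of F, uncorrected p and main-effect
        Greenhouse-Geisser epsilon."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        data = rng.normal(size=(10, 3, 4))
        res = rm_anova(data, factor_names=("cond", "contrast"))
        rows = [dict(subj=s, cond=f"c{i}", contrast=f"k{j}", y=data[s, i, j])
                for s in range(10) for i in range(3) for j in range(4)]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = pg.rm_anova(data=pd.DataFrame(rows), dv="y",
                              within=["cond", "contrast"], subject="subj",
                              detailed=True).set_index("Source")
        for name, src in (("cond", "cond"), ("contrast", "contrast"),
                          ("condxcontrast", "cond * contrast")):
            assert res[name].F == pytest.approx(aov.loc[src, "F"], abs=1e-8)
            assert res[name].p_uncorrected == pytest.approx(
                aov.loc[src, "p_unc"], abs=1e-8)
        for name in ("cond", "contrast"):
            assert res[name].epsilon == pytest.approx(
                aov.loc[name if name == "cond" else "contrast", "eps"],
                abs=1e-6)

    def test_eta_p2_definition(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(6, 3, 4))
        res = rm_anova(data)
        _, _, _, ss = bruteforce_rm_anova(data)
        assert res["A"].eta_p2 == pytest.approx(
            ss["A"] / (ss["A"] + ss["AS"]), abs=1e-10)

    def test_missing_cells_rejected(self):
        data = np.zeros((4, 3, 4))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova(data)


class TestTTests:
    def test_identical_samples_undefined(self):
        x = np.arange(5.0)
        with pytest.raises(ZeroDivisionError):
            paired_t(x, x)

    def test_matches_formula_oracle(self):
        x = np.array([10.2, 9.8, 11.5, 12.0, 8.9, 10.7])
        y = np.array([9.5, 9.9, 10.8, 11.1, 8.2, 10.0])
        res = paired_t(x, y)
        d = x - y
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert res["t"] == pytest.approx(t_oracle, abs=1e-12)
        assert res["d_z"] == pytest.approx(d.mean() / d.std(ddof=1),
                                           abs=1e-12)
        from scipy.stats import ttest_rel
        sp = ttest_rel(x, y)
        assert res["t"] == pytest.approx(sp.statistic, abs=1e-12)
        assert res["p"] == pytest.approx(sp.pvalue, abs=1e-12)

    def test_dz_estimates_standardized_effect(self):
        rng = np.random.default_rng(4)
        diff = 0.5 + rng.normal(0, 1.0, 5000)
        res = paired_t(diff, np.zeros_like(diff))
        assert res["d_z"] == pytest.approx(0.5, abs=0.05)

    def test_one_sample_t(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = one_sample_t(x, popmean=2.0)
        from scipy.stats import ttest_1samp
        sp = ttest_1samp(x, 2.0)
        assert res["t"] == pytest.approx(sp.statistic, abs=1e-12)


class TestFdr:
    def test_stepup_hand_case(self):
        # sorted p: 0.01<=0.0125, 0.02<=0.025, 0.03<=0.0375, 0.04<=0.05
        _, reject = fdr_bh([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_all_ones_none_rejected(self):
        adj, reject = fdr_bh(np.ones(10))
        assert not reject.any()
        assert np.all(adj == 1.0)

    def test_adjusted_monotone_in_sorted_order(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        adj, _ = fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(6)
        p = rng.uniform(size=40)
        adj, reject = fdr_bh(p, q=0.05)
        sm_reject, sm_adj, *_ = sm.multipletests(p, alpha=0.05,
                                                 method="fdr_bh")
        assert np.allclose(adj, sm_adj, atol=1e-12)
        assert np.array_equal(reject, sm_reject)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])


def _spectra_frame(rng, n_per_cond=30, coupling=0.0):
    rows = []
    for cond in ("still", "slow", "normal"):
        base = dict(still=0, slow=1, normal=2)[cond]
        z = rng.normal(size=n_per_cond)
        ssvep = np.exp(0.5 * z)
        alpha = np.exp(0.5 * (coupling * z
                              + np.sqrt(max(1 - coupling ** 2, 0))
                              * rng.normal(size=n_per_cond)))
        hf = np.exp(rng.normal(base, 0.3, n_per_cond))
        for k in range(n_per_cond):
            rows.append(dict(condition=cond, raw_ssvep=ssvep[k],
                             alpha_power=alpha[k], hf_power=hf[k]))
    return pd.DataFrame(rows)


class TestMedianSplit:
    def test_median_trial_joins_weak_group_on_odd_counts(self):
        rng = np.random.default_rng(7)
        df = _spectra_frame(rng, n_per_cond=13)
        out = median_split_matched(df, walking_conditions=())
        still = out[out.condition == "still"]
        weak = still[still.group == "weak"].n_trials.iloc[0]
        strong = still[still.group == "strong"].n_trials.iloc[0]
        assert (weak, strong) == (7, 6)

    def test_hf_trimming_reduces_group_difference(self):
        rng = np.random.default_rng(8)
        df = _spectra_frame(rng, n_per_cond=40)
        # couple hf to ssvep so the split produces an HF confound
        df["hf_power"] = df.hf_power * (1 + df.raw_ssvep)
        untrimmed = median_split_matched(df, walking_conditions=())
        trimmed = median_split_matched(df, walking_conditions=("slow",
                                                               "normal"))
        def gap(tab, cond):
            t = tab[tab.condition == cond].set_index("group")
            return t.loc["strong", "hf_power"] - t.loc["weak", "hf_power"]
        for cond in ("slow", "normal"):
            assert abs(gap(trimmed, cond)) < abs(gap(untrimmed, cond))

    def test_coupled_generator_shows_alpha_difference(self):
        """With alpha-SSVEP coupling, the strong-SSVEP trial group has
        reliably higher alpha power across simulated participants."""
        rng = np.random.default_rng(9)
        diffs = []
        for _ in range(20):   # simulated participants
            df = _spectra_frame(rng, n_per_cond=40, coupling=0.7)
            out = median_split_matched(df)
            t = out.groupby("group").alpha_power.mean()
            diffs.append(t["strong"] - t["weak"])
        res = one_sample_t(np.array(diffs))
        assert res["t"] > 0 and res["p"] < 0.05

    def test_no_coupling_difference_centred_on_zero(self):
        rng = np.random.default_rng(10)
        diffs = []
        for _ in range(25):
            df = _spectra_frame(rng, n_per_cond=40, coupling=0.0)
            out = median_split_matched(df)
            t = out.groupby("group").alpha_power.mean()
            diffs.append(t["strong"] - t["weak"])
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs))

    def test_too_few_trials_rejected(self):
        df = _spectra_frame(np.random.default_rng(11), n_per_cond=5)
        with pytest.raises(ValueError):
            median_split_matched(df)


class TestCountMatchedAverage:
    def test_uniform_counts_equal_plain_mean(self):
        v = np.array([1.0, 2.0, 3.0])
        assert count_matched_average(v, np.zeros(3)) == pytest.approx(2.0)

    def test_strata_weighted_equally(self):
        v = np.array([1.0, 1.0, 1.0, 3.0])   # strata means 1 and 3
        c = np.array([0, 0, 0, 1])
        assert count_matched_average(v, c) == pytest.approx(2.0)

    def test_removes_count_confound(self):
        """When the measure depends only on the count, count-matched
        means are equal across conditions with different count mixes."""
        rng = np.random.default_rng(12)
        effect = {0: 1.0, 1: 2.0, 2: 4.0}
        means = []
        for weights in ((0.7, 0.2, 0.1), (0.1, 0.2, 0.7)):
            counts = rng.choice([0, 1, 2], size=600, p=weights)
            values = np.array([effect[c] for c in counts])
            means.append(count_matched_average(values, counts))
        assert means[0] == pytest.approx(means[1], abs=1e-12)


class TestTwoLevelRegression:
    def _trials(self, rng, n_subj=25, n_trials=96, b_alpha=0.5,
                b_blink=-0.2):
        rows = []
        for pid in range(n_subj):
            blocks = np.repeat(np.arange(8), n_trials // 8)
            alpha = rng.normal(size=n_trials) + rng.normal() * 0.5
            blinks = rng.poisson(1.0, n_trials)
            sacc = rng.poisson(2.0, n_trials)
            ssvep = (b_alpha * alpha + b_blink * blinks
                     + rng.normal(0, 1.0, n_trials))
            for k in range(n_trials):
                rows.append(dict(participant=pid, block=blocks[k],
                                 raw_ssvep=ssvep[k], raw_alpha=alpha[k],
                                 n_blinks=blinks[k], n_saccades=sacc[k]))
        return pd.DataFrame(rows)

    def test_slope_signs_recovered(self):
        rng = np.random.default_rng(13)
        slopes, group = two_level_regression(self._trials(rng))
        assert group["raw_alpha"]["t"] > 0 and group["raw_alpha"]["p"] < 0.05
        assert group["n_blinks"]["t"] < 0 and group["n_blinks"]["p"] < 0.05
        assert group["n_saccades"]["p"] > 0.05

    def test_null_coupling_type_one_error(self):
        rng = np.random.default_rng(14)
        hits = 0
        n_sims = 60
        for _ in range(n_sims):
            trials = self._trials(rng, n_subj=10, n_trials=48,
                                  b_alpha=0.0, b_blink=0.0)
            _, group = two_level_regression(trials)
            hits += group["raw_alpha"]["p"] < 0.05
        assert hits / n_sims < 0.15

    def test_constant_predictor_participant_skipped(self):
        rng = np.random.default_rng(15)
        trials = self._trials(rng, n_subj=3)
        trials.loc[trials.participant == 1, "n_blinks"] = 2
        with pytest.warns(UserWarning, match="rank-deficient"):
            slopes, _ = two_level_regression(trials)
        assert set(slopes.participant) == {0, 2}
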