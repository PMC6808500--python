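"""Blink / saccade / head-movement detection against ground truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import match_events
from walkvep import oculomotor as oc
from walkvep.synth import (
    SimConfig,
    simulate_session,
    spike_amplitude,
    spike_potential_template,
)

FS = 500.0


class TestMergePoints:
    def test_empty(self):
        assert oc.merge_points(np.array([]), 0.1) == []

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=30),
           st.floats(0.01, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_matches_interval_union_oracle(self, times, gap):
        """Grouping equals a brute-force union of ``[t, t+gap)``
        intervals over the sorted points."""
        groups = oc.merge_points(np.array(times), gap)
        # oracle: walk the sorted list, split where the gap is reached
        ts = sorted(times)
        oracle = [[ts[0]]]
        for prev, cur in zip(ts, ts[1:]):
            if cur - prev >= gap:
                oracle.append([cur])
            else:
                oracle[-1].append(cur)
        assert [list(g) for g in groups] == oracle


class TestBlinks:
    def test_injected_blinks_recovered(self, small_session, pc):
        det = oc.detect_blinks_session(small_session, pc)
        truth = small_session.ground_truth["blinks"]
        recall, precision = match_events(det.t_peak.to_numpy(),
                                         truth.time.to_numpy(), tol_s=0.05)
        assert recall >= 0.9 and precision >= 0.9

    def test_peak_time_accuracy(self, small_session, pc):
        det = oc.detect_blinks_session(small_session, pc)
        truth = np.sort(small_session.ground_truth["blinks"].time.to_numpy())
        err = [np.min(np.abs(truth - t)) for t in det.t_peak]
        assert np.median(err) < 0.02

    def test_flat_signal_no_blinks(self, pc):
        zero = np.zeros(int(60 * FS))
        det = oc.detect_blinks(zero, zero, FS, pc)
        assert len(det) == 0

    def test_nearby_crossings_merge_to_one(self, pc):
        """Two threshold crossings 50 ms apart are one blink."""
        t = np.arange(int(20 * FS)) / FS
        v = np.zeros_like(t)
        # double-humped blink: two crossings of the 20 uV threshold
        for t0 in (10.0, 10.05):
            idx = (t >= t0) & (t < t0 + 0.15)
            v[idx] += 100 * np.sin(np.pi * (t[idx] - t0) / 0.15) ** 2
        det = oc.detect_blinks(v, np.zeros_like(v), FS, pc)
        assert len(det) == 1

    def test_small_peak_rejected(self, pc):
        t = np.arange(int(20 * FS)) / FS
        v = np.zeros_like(t)
        idx = (t >= 10.0) & (t < 10.4)
        v[idx] = 30 * np.sin(np.pi * (t[idx] - 10.0) / 0.4) ** 2
        det = oc.detect_blinks(v, np.zeros_like(v), FS, pc)  # peak < 40 uV
        assert len(det) == 0


class TestReog:
    def test_eog_equal_pz_gives_zero(self, small_session):
        import copy
        sess = copy.copy(small_session)
        pz = sess.channel("Pz")
        sess.eog = np.tile(pz, (6, 1))
        assert np.allclose(oc.compute_reog(sess), 0.0)

    def test_constant_offset_passes_through(self, small_session):
        import copy
        sess = copy.copy(small_session)
        pz = sess.channel("Pz")
        sess.eog = np.tile(pz + 3.5, (6, 1))
        assert np.allclose(oc.compute_reog(sess), 3.5)

    def test_single_channel_spike_diluted_sixfold(self, small_session):
        import copy
        sess = copy.copy(small_session)
        pz = sess.channel("Pz")
        sess.eog = np.tile(pz, (6, 1)).copy()
        sess.eog[2, 1000] += 60.0
        assert oc.compute_reog(sess)[1000] == pytest.approx(10.0)


class TestSaccades:
    def test_recall_precision_at_default_snr(self, small_session, pc):
        reog = oc.compute_reog(small_session)
        det, _, _ = oc.detect_saccades(reog, small_session.fs_eeg,
                                       oc.block_bounds(small_session), pc)
        truth = small_session.ground_truth["saccades"]
        recall, precision = match_events(det.t.to_numpy(),
                                         truth.time.to_numpy(), tol_s=0.05)
        assert recall >= 0.9 and precision >= 0.9

    def test_pure_low_frequency_signal_no_detections(self, pc):
        t = np.arange(int(120 * FS)) / FS
        x = 50 * np.sin(2 * np.pi * 10.0 * t)   # far below the 20-90 band
        det, _, _ = oc.detect_saccades(x, FS, [(0.0, 120.0)], pc)
        assert len(det) == 0

    def test_close_supra_threshold_points_group(self, small_cfg, pc):
        """Spike lobes 10 ms apart form a single saccade."""
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1.0, int(120 * FS))
        tmpl = spike_potential_template(small_cfg, FS)
        for t0 in (30.0, 60.0, 90.0):
            i = int(t0 * FS)
            x[i:i + tmpl.size] += 80 * tmpl
        det, _, _ = oc.detect_saccades(x, FS, [(0.0, 120.0)], pc)
        assert len(det) == 3


class TestSpikeExtraction:
    def test_identical_templates_average_to_template(self, small_cfg, pc):
        tmpl = spike_potential_template(small_cfg, FS)
        x = np.zeros(int(60 * FS))
        times = [10.0, 25.0, 40.0]
        for t0 in times:
            i = int(t0 * FS)
            x[i:i + tmpl.size] += 50 * tmpl
        centre = int(np.argmin(tmpl))
        sacc = pd.DataFrame(dict(
            t=[t + centre / FS for t in times],
            t_start=[t for t in times],
            t_end=[t + tmpl.size / FS for t in times],
            peak_env=50.0, block=0))
        wave, amps = oc.extract_spike_potential(x, FS, sacc, normalizer=2.0)
        half = wave.size // 2
        assert wave[half] == pytest.approx(50 * tmpl.min() / 2.0)
        assert np.allclose(amps, amps[0])

    def test_noise_averages_out(self, small_cfg):
        rng = np.random.default_rng(1)
        tmpl = spike_potential_template(small_cfg, FS)
        errs = []
        for n_spikes in (10, 160):
            x = rng.normal(0, 2.0, int(400 * FS))
            times = np.arange(n_spikes) * 2.0 + 5.0
            for t0 in times:
                i = int(t0 * FS)
                x[i:i + tmpl.size] += 50 * tmpl
            sacc = pd.DataFrame(dict(
                t=times, t_start=times, t_end=times + tmpl.size / FS,
                peak_env=50.0, block=0))
            wave, _ = oc.extract_spike_potential(x, FS, sacc, normalizer=1.0)
            half = wave.size // 2
            target = np.zeros_like(wave)
            c = int(np.argmin(tmpl))
            lo = half - c
            target[lo:lo + tmpl.size] = 50 * tmpl
            errs.append(np.sqrt(np.mean((wave - target) ** 2)))
        # RMS error shrinks roughly as 1/sqrt(n): 16x spikes -> ~4x less
        assert errs[1] < errs[0] / 2.5

    def test_window_outside_recording_skipped(self, pc):
        x = np.zeros(1000)
        sacc = pd.DataFrame(dict(t=[0.01], t_start=[0.0], t_end=[0.02],
                                 peak_env=1.0, block=0))
        with pytest.raises(ValueError):
            oc.extract_spike_potential(x, FS, sacc, normalizer=1.0)


class TestSizeCalibration:
    def test_exact_quadratic_recovered(self):
        amps = np.array([10.0, 20, 30, 50, 80])
        sizes = 0.001 * amps ** 2 + 0.01 * amps - 0.05
        cal = oc.fit_size_calibration(sizes, amps)
        assert np.allclose(cal.coeffs, [0.001, 0.01, -0.05], atol=1e-10)
        assert np.allclose(cal.residuals, 0.0, atol=1e-10)

    def test_generator_round_trip_within_10pc(self, small_cfg):
        """size -> spike amplitude -> estimated size, with calibration
        noise, recovers sizes in [0.2, 5] deg to < 10% relative error."""
        rng = np.random.default_rng(4)
        sizes = np.array([0.1, 0.2, 0.5, 1.0, 5.0])
        cal_sizes = np.repeat(sizes, 20)
        cal_amps = spike_amplitude(small_cfg, cal_sizes) \
            + rng.normal(0, 1.0, cal_sizes.size)
        cal = oc.fit_size_calibration(cal_sizes, cal_amps)
        probe = np.array([0.2, 0.5, 1.0, 2.0, 5.0])
        est, flag = cal.estimate(spike_amplitude(small_cfg, probe))
        assert not flag.any()
        assert np.all(np.abs(est - probe) / probe < 0.10)

    def test_out_of_range_clamped_and_flagged(self):
        cal = oc.fit_size_calibration(np.array([0.1, 1.0, 5.0]),
                                      np.array([10.0, 30.0, 100.0]))
        est, flag = cal.estimate(500.0)
        assert flag.all()
        inside, _ = cal.estimate(100.0)
        assert est == pytest.approx(inside)

    def test_too_few_sizes_rejected(self):
        with pytest.raises(ValueError):
            oc.fit_size_calibration(np.array([1.0, 1.0]),
                                    np.array([10.0, 11.0]))


class TestHeadMovements:
    def test_constant_velocity_no_events(self, pc):
        gyro = np.full((3, int(60 * FS)), 5.0)
        det = oc.detect_head_movements(gyro, FS, [(0.0, 60.0)], pc)
        assert len(det) == 0

    def test_single_burst_detected(self, pc):
        rng = np.random.default_rng(5)
        gyro = rng.normal(0, 3.0, (3, int(60 * FS)))
        i = int(30 * FS)
        gyro[0, i:i + 250] += 150.0 * np.hanning(250)
        det = oc.detect_head_movements(gyro, FS, [(0.0, 60.0)], pc)
        assert len(det) == 1
        assert det.t_start.iloc[0] == pytest.approx(30.0, abs=0.3)

    def test_bursts_within_two_seconds_merge(self, pc):
        rng = np.random.default_rng(6)
        gyro = rng.normal(0, 3.0, (3, int(60 * FS)))
        for t0 in (30.0, 31.0):    # 1 s apart -> one event
            i = int(t0 * FS)
            gyro[1, i:i + 100] += 200.0
        det = oc.detect_head_movements(gyro, FS, [(0.0, 60.0)], pc)
        assert len(det) == 1

    def test_session_bursts_recovered(self, small_session, pc):
        det = oc.detect_head_movements(small_session.gyro,
                                       small_session.fs_eeg,
                                       oc.block_bounds(small_session), pc)
        truth = small_session.ground_truth["head_moves"]
        centre_det = (det.t_start + det.t_end) / 2
        centre_tru = (truth.t_start + truth.t_end) / 2
        recall, _ = match_events(centre_det.to_numpy(),
                                 centre_tru.to_numpy(), tol_s=1.0)
        assert recall >= 0.8


class TestEventCounts:
    def test_half_open_boundary_convention(self):
        trials = pd.DataFrame(dict(i0=[0, 500], i1=[500, 1000]))
        counts = oc.count_events_per_trial(np.array([0.0, 1.0, 1.999]),
                                           trials, FS)
        # t=1.0 belongs to the second trial's [1, 2) window
        assert list(counts) == [1, 2]

    def test_no_events_all_zero(self):
        trials = pd.DataFrame(dict(i0=[0, 500], i1=[500, 1000]))
        assert list(oc.count_events_per_trial(np.array([]), trials,
                                              FS)) == [0, 0]

    def test_conservation(self, small_session, pc):
        from walkvep.preprocess import epoch_periods
        periods = epoch_periods(small_session)
        truth = small_session.ground_truth["blinks"].time.to_numpy()
        counts = oc.count_events_per_trial(truth, periods.table,
                                           small_session.fs_eeg)
        assert counts.sum() <= truth.size
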