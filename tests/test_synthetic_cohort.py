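"""Synthetic cohort generator: couplings, determinism, PAC emulation,
artifact injection."""

import numpy as np
import pytest

from cardiofuse.anthropometrics import bsa_mosteller
from cardiofuse.preprocess import detect_beats, ppg_quality, zscore_gate
from cardiofuse.records import ECG_FS, PPG_FS
from cardiofuse.synthetic_cohort import (
    CI_MAX, CI_MIN, CouplingParams, PatientMeta, TrajectoryParams,
    emulate_pac_stream, inject_artifacts, sample_patient, simulate_cohort,
    simulate_ci_trajectory, synthesize_waveforms,
)


class TestSamplePatient:
    def test_forced_anthropometrics_give_expected_bsa(self):
        pm = PatientMeta("x", 167, 63)
        assert pm.bsa == pytest.approx(np.sqrt(167 * 63 / 3600), abs=1e-9)
        assert PatientMeta("y", 180, 20).bsa == pytest.approx(1.0, abs=1e-12)

    def test_cohort_medians_are_calibrated(self):
        draws = [sample_patient(seed) for seed in range(1000)]
        heights = np.array([p.height_cm for p in draws])
        weights = np.array([p.weight_kg for p in draws])
        assert 160 <= np.median(heights) <= 174
        assert 55 <= np.median(weights) <= 71
        bsa = np.median([p.bsa for p in draws])
        assert 1.5 <= bsa <= 1.9

    def test_determinism(self):
        a, b = sample_patient(123), sample_patient(123)
        assert (a.height_cm, a.weight_kg) == (b.height_cm, b.weight_kg)


class TestCiTrajectory:
    def test_zero_drift_is_constant_baseline(self):
        tr = simulate_ci_trajectory(
            700, TrajectoryParams(baseline=2.4, drift_amplitude=0.0,
                                  walk_sd=0.0), rng_seed=5)
        assert np.allclose(tr.ci_values, 2.4)

    def test_same_seed_bitwise_identical(self):
        a = simulate_ci_trajectory(900, rng_seed=7)
        b = simulate_ci_trajectory(900, rng_seed=7)
        assert np.array_equal(a.ci_values, b.ci_values)
        assert np.array_equal(a.times, b.times)

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_bounds_clipped(self, seed):
        tr = simulate_ci_trajectory(
            1200, TrajectoryParams(drift_amplitude=3.0), rng_seed=seed)
        assert tr.ci_values.min() >= CI_MIN
        assert tr.ci_values.max() <= CI_MAX

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate_ci_trajectory(0.0)


class TestWaveformSynthesis:
    def test_constant_ci_gives_expected_rr_interval(
            self, constant_waveforms):
        ecg, _ = constant_waveforms
        peaks = detect_beats(ecg.samples, ecg.fs)
        rr = np.diff(peaks) / ecg.fs
        expected = 60.0 / (55 + 8 * 2.0)  # CI = 2 -> HR = 71 bpm
        # R-R equals 60/HR to within one ECG sample
        assert np.all(np.abs(rr - expected) <= 1.0 / ecg.fs)

    def test_sampling_rates_and_lengths(self, clean_waveforms):
        ecg, ppg = clean_waveforms
        assert ecg.fs == ECG_FS and ppg.fs == PPG_FS
        assert ecg.n == 600 * 250 and ppg.n == 600 * 75

    def test_higher_ci_shortens_ecg_to_ppg_delay(self, patient,
                                                 clean_coupling):
        delays = []
        for ci in (1.8, 3.2):
            tr = simulate_ci_trajectory(
                120, TrajectoryParams(baseline=ci, drift_amplitude=0,
                                      walk_sd=0), rng_seed=0)
            ecg, ppg = synthesize_waveforms(patient, tr, clean_coupling)
            r = detect_beats(ecg.samples, ecg.fs)[:40] / ecg.fs
            p = detect_beats(ppg.samples, ppg.fs)[:40] / ppg.fs
            # mean R-to-following-pulse-peak delay
            d = [p[np.searchsorted(p, t)] - t for t in r
                 if np.searchsorted(p, t) < len(p)]
            delays.append(np.mean(d))
        assert delays[1] < delays[0]  # ptt_per_ci < 0

    def test_pulse_amplitude_tracks_stroke_volume(self, patient,
                                                  clean_coupling):
        amps, svs = [], []
        for ci in (2.0, 3.0):
            tr = simulate_ci_trajectory(
                120, TrajectoryParams(baseline=ci, drift_amplitude=0,
                                      walk_sd=0), rng_seed=0)
            _, ppg = synthesize_waveforms(patient, tr, clean_coupling)
            amps.append(ppg.samples.max())
            hr = 55 + 8 * ci
            svs.append(ci * patient.bsa / hr)
        assert amps[1] / amps[0] == pytest.approx(svs[1] / svs[0], rel=0.01)

    def test_coupling_out_of_range_rejected(self, patient, drift_trajectory):
        bad = CouplingParams(hr_base=170.0, hr_per_ci=20.0)
        with pytest.raises(ValueError):
            synthesize_waveforms(patient, drift_trajectory, bad)
        bad_ptt = CouplingParams(ptt_base=50.0, ptt_per_ci=-25.0)
        with pytest.raises(ValueError):
            synthesize_waveforms(patient, drift_trajectory, bad_ptt)

    def test_determinism(self, patient, drift_trajectory, clean_coupling):
        e1, p1 = synthesize_waveforms(patient, drift_trajectory,
                                      clean_coupling)
        e2, p2 = synthesize_waveforms(patient, drift_trajectory,
                                      clean_coupling)
        assert np.array_equal(e1.samples, e2.samples)
        assert np.array_equal(p1.samples, p2.samples)


class TestPacEmulator:
    def test_constant_ci_streams_constant_co(self, patient):
        tr = simulate_ci_trajectory(
            600, TrajectoryParams(baseline=2.0, drift_amplitude=0,
                                  walk_sd=0), rng_seed=0)
        pac = emulate_pac_stream(patient, tr)
        assert np.allclose(pac.co, 2.0 * patient.bsa, atol=1e-12)
        assert np.allclose(pac.ci, 2.0, atol=1e-12)

    def test_streaming_grid_and_cycle_count(self, patient, drift_trajectory):
        pac = emulate_pac_stream(patient, drift_trajectory)
        assert np.allclose(np.diff(pac.times), 2.0)
        # 600 s of recording -> at most 10 distinct 1-min computation epochs
        assert len(np.unique(pac.co)) <= 10

    def test_streamed_value_is_trailing_mean(self, patient, drift_trajectory):
        """Label consistency: streamed CO / BSA reproduces the trailing 60 s
        ground-truth mean exactly (beyond the first cycle)."""
        pac = emulate_pac_stream(patient, drift_trajectory)
        tr = drift_trajectory
        for t, co in zip(pac.times[::30], pac.co[::30]):
            if t - tr.t0 < 60:
                continue
            cycle_end = tr.t0 + 60.0 * np.floor((t - tr.t0) / 60.0)
            assert co / patient.bsa == pytest.approx(
                tr.trailing_mean(cycle_end), abs=1e-9)

    def test_step_fully_reflected_after_one_window(self, patient):
        # CI steps 2 -> 3 at t = 120 s
        t = np.arange(0, 601.0)
        ci = np.where(t < 120, 2.0, 3.0)
        from cardiofuse.synthetic_cohort import CiTrajectory
        tr = CiTrajectory(times=t, ci_values=ci)
        pac = emulate_pac_stream(patient, tr)
        val_at = lambda tt: pac.co[np.searchsorted(pac.times, tt)]
        # before the step reaches any completed cycle: pure pre-step value
        assert val_at(118.0) == pytest.approx(2.0 * patient.bsa, rel=1e-9)
        # cycle ending at 180 covers (120, 180]: only then fully post-step
        mid = val_at(150.0) / patient.bsa
        assert 2.0 < mid < 3.0
        assert val_at(182.0) == pytest.approx(3.0 * patient.bsa, rel=1e-9)

    def test_too_short_trajectory_rejected(self, patient):
        tr = simulate_ci_trajectory(30.0, rng_seed=0)
        with pytest.raises(ValueError):
            emulate_pac_stream(patient, tr)


class TestArtifacts:
    def test_empty_span_list_is_identity(self, clean_waveforms):
        _, ppg = clean_waveforms
        out = inject_artifacts(ppg, "flatline", [])
        assert np.array_equal(out.samples, ppg.samples)

    def test_flatline_kills_peak_to_peak(self, clean_waveforms):
        _, ppg = clean_waveforms
        out = inject_artifacts(ppg, "flatline", [(100.0, 160.0)])
        span = out.samples[int(100 * ppg.fs): int(160 * ppg.fs)]
        assert span.max() - span.min() < 1e-9

    def test_noise_burst_drops_quality_z(self, clean_waveforms):
        _, ppg = clean_waveforms
        bad = inject_artifacts(ppg, "noise_burst", [(120.0, 180.0)],
                               rng_seed=1)
        scores = []
        for k in range(9):
            seg = bad.samples[int(60 * k * ppg.fs): int(60 * (k + 1) * ppg.fs)]
            scores.append(ppg_quality(seg, fs=ppg.fs, segment_id=str(k)))
        kept, excluded = zscore_gate(scores)
        assert any(s.segment_id == "2" for s in excluded)
        assert [s for s in excluded if s.segment_id == "2"][0].z_score < -2.0

    def test_unknown_kind_rejected(self, clean_waveforms):
        ecg, _ = clean_waveforms
        with pytest.raises(ValueError):
            inject_artifacts(ecg, "dropout", [(0.0, 1.0)])

    def test_span_outside_duration_rejected(self, clean_waveforms):
        ecg, _ = clean_waveforms
        with pytest.raises(ValueError):
            inject_artifacts(ecg, "flatline", [(590.0, 700.0)])


class TestCohort:
    def test_physiologic_couplings_monotone(self):
        """Across a cohort, HR rises and PTT falls with CI as configured."""
        cohort = simulate_cohort(6, duration_s=600, seed=11)
        cis, hrs, ptts = [], [], []
        cp = CouplingParams()
        for rec in cohort:
            ci = rec.trajectory.ci_values.mean()
            cis.append(ci)
            hrs.append(float(cp.hr(ci)))
            ptts.append(float(cp.ptt_s(ci)))
        assert np.corrcoef(cis, hrs)[0, 1] > 0
        assert np.corrcoef(cis, ptts)[0, 1] < 0

    def test_cohort_deterministic(self):
        a = simulate_cohort(2, duration_s=600, seed=3)
        b = simulate_cohort(2, duration_s=600, seed=3)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.ecg.samples, rb.ecg.samples)
            assert np.array_equal(ra.pac.co, rb.pac.co)

    def test_csv_writer_roundtrip(self, tmp_path):
        import pandas as pd
        from cardiofuse.synthetic_cohort import write_cohort_csv
        cohort = simulate_cohort(2, duration_s=600, seed=3)
        write_cohort_csv(cohort, str(tmp_path))
        meta = pd.read_csv(tmp_path / "patients.csv")
        assert len(meta) == 2
        wf = pd.read_csv(tmp_path / "P000_ppg.csv")
        assert list(wf.columns) == ["unix_time_s", "value"]
        assert len(wf) == cohort[0].ppg.n
        pac = pd.read_csv(tmp_path / "P000_pac.csv")
        assert np.allclose(pac["co_lpm"], cohort[0].pac.co)
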