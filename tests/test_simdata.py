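"""Simulator checks: beat/breath/pulse rate fidelity against signal-processing
oracles, schema invariants, episode injection, and cohort-level imbalance."""

import numpy as np
import pytest
from scipy.signal import find_peaks, periodogram

from dsfnet import simdata, windows
from dsfnet.errors import ConfigurationError
from dsfnet.net import FRAME_DIM
from dsfnet.simdata import (COL, EcgPhase, inject_end_episode, simulate_cohort,
                            simulate_patient, synthesize_ecg_frame,
                            synthesize_pleth_frame, synthesize_resp_frame)


def _run_ecg(hr, seconds, anomalies=None, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    phase = EcgPhase()
    sig = []
    for t in range(seconds):
        frame, phase = synthesize_ecg_frame(hr, phase, (anomalies or {}).get(t, []),
                                            noise_sd, rng)
        sig.append(frame)
    return np.concatenate(sig)


def _count_r_peaks(sig):
    peaks, _ = find_peaks(sig, height=0.6, distance=64)
    return peaks


class TestEcg:
    def test_beat_rate_matches_hr_peak_count_oracle(self):
        """hr=60 -> one R peak per second, mean R-R = 1.0 s over a minute."""
        sig = _run_ecg(60, 60)
        peaks = _count_r_peaks(sig)
        assert abs(len(peaks) - 60) <= 2
        rr = np.diff(peaks) / 256.0
        assert abs(rr.mean() - 1.0) < 0.05

    def test_doubling_hr_doubles_beat_count(self):
        n60 = len(_count_r_peaks(_run_ecg(60, 60)))
        n120 = len(_count_r_peaks(_run_ecg(120, 60)))
        assert abs(n120 / n60 - 2.0) < 0.05

    def test_rate_fidelity_within_five_percent(self):
        for hr in (48, 75, 110):
            n = len(_count_r_peaks(_run_ecg(hr, 120)))
            assert abs(n - 2 * hr) / (2 * hr) < 0.05

    def test_deterministic_for_same_phase_and_seed(self):
        phase = EcgPhase(t_next=0.4)
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        f1, p1 = synthesize_ecg_frame(72, phase, [], 0.05, rng1)
        f2, p2 = synthesize_ecg_frame(72, phase, [], 0.05, rng2)
        np.testing.assert_array_equal(f1, f2)
        assert p1.t_next == p2.t_next

    def test_pvc_produces_large_negative_deflection(self):
        clean = _run_ecg(60, 4)
        with_pvc = _run_ecg(60, 4, anomalies={2: ["pvc"]})
        assert with_pvc.min() < -1.0 < clean.min() + 0.9
        # outside the affected beats the signal is unchanged
        np.testing.assert_array_equal(clean[:256], with_pvc[:256])

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValueError, match="hr"):
            synthesize_ecg_frame(0.0)


class TestRespAndPleth:
    @pytest.mark.parametrize("rr,expected_hz", [(12, 0.2), (24, 0.4)])
    def test_dominant_frequency_periodogram_oracle(self, rr, expected_hz):
        phase, sig = 0.0, []
        for _ in range(60):
            frame, phase = synthesize_resp_frame(rr, phase)
            sig.append(frame)
        f, pxx = periodogram(np.concatenate(sig), fs=256)
        assert abs(f[np.argmax(pxx)] - expected_hz) < 0.02

    def test_resp_reproducible_and_validates_rate(self):
        f1, p1 = synthesize_resp_frame(12, 0.25)
        f2, p2 = synthesize_resp_frame(12, 0.25)
        np.testing.assert_array_equal(f1, f2)
        assert p1 == p2
        with pytest.raises(ValueError):
            synthesize_resp_frame(-3)

    def test_pleth_zero_perfusion_is_flat(self):
        sig, _ = synthesize_pleth_frame(70, 0.1, perfusion_index=0.0)
        np.testing.assert_array_equal(sig, 0.0)

    def test_pleth_one_pulse_per_second_at_hr60(self):
        phase, sig = 0.0, []
        for _ in range(30):
            frame, phase = synthesize_pleth_frame(60, phase, 2.0)
            sig.append(frame)
        sig = np.concatenate(sig)
        peaks, _ = find_peaks(sig, prominence=1.0, distance=30)
        assert abs(len(peaks) - 30) <= 1

    def test_pleth_amplitude_scales_with_perfusion_index(self):
        s1, _ = synthesize_pleth_frame(60, 0.0, 1.0)
        s2, _ = synthesize_pleth_frame(60, 0.0, 2.0)
        r = (s2.max() - s2.min()) / (s1.max() - s1.min())
        assert abs(r - 2.0) < 1e-9


@pytest.fixture(scope="module")
def record():
    profile = simdata.PatientProfile(patient_id="X", precursor_intensity=2.0)
    return simulate_patient(profile, 120, np.random.default_rng(3))


class TestPatientAndInjection:
    def test_frames_pass_schema_invariants(self, record):
        assert record.frames.shape == (120, FRAME_DIM)
        record.validate()
        for i in (0, 60, 119):
            record.frame(i).validate()

    def test_vitals_relations(self, record):
        f = record.frames
        s, d, m = f[:, COL["NIBP_S"]], f[:, COL["NIBP_D"]], f[:, COL["NIBP_M"]]
        assert np.all(s > d)
        np.testing.assert_allclose(m, d + (s - d) / 3.0, atol=1e-3)
        assert np.all(f[:, COL["SpO2"]] <= 100.0)
        np.testing.assert_allclose(f[:, COL["HR"]], f[:, COL["PR"]], atol=5.0)

    def test_zero_intensity_injection_only_annotates(self, record):
        out = inject_end_episode(record, 100, 60, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out.frames, record.frames)
        assert out.end_onsets == [100.0]

    def test_injection_raises_pvc_counter_during_ramp(self, record):
        out = inject_end_episode(record, 100, 60, 3.0, np.random.default_rng(1))
        ramp = slice(40, 100)
        pre = slice(0, 40)
        assert out.frames[ramp, COL["PVCs"]].mean() > out.frames[pre, COL["PVCs"]].mean()
        assert out.frames[ramp, COL["SpO2"]].mean() < record.frames[ramp, COL["SpO2"]].mean()
        # frames before the ramp untouched
        np.testing.assert_array_equal(out.frames[pre], record.frames[pre])

    def test_injection_deterministic_for_same_seed(self, record):
        a = inject_end_episode(record, 100, 60, 2.0, np.random.default_rng(9))
        b = inject_end_episode(record, 100, 60, 2.0, np.random.default_rng(9))
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_injection_range_errors(self, record):
        with pytest.raises(ValueError, match="beyond"):
            inject_end_episode(record, 500, 60, 1.0, np.random.default_rng(0))
        with pytest.raises(ValueError, match="precedes"):
            inject_end_episode(record, 30, 60, 1.0, np.random.default_rng(0))


class TestCohort:
    def test_same_seed_gives_byte_identical_cohorts(self):
        a = simulate_cohort(n_patients=4, duration_s=60, end_prevalence=0.5,
                            imbalance_target=2.0, seed=42, intensity=2.0)
        b = simulate_cohort(n_patients=4, duration_s=60, end_prevalence=0.5,
                            imbalance_target=2.0, seed=42, intensity=2.0)
        for pa, pb in zip(a.patients, b.patients):
            np.testing.assert_array_equal(pa.frames, pb.frames)
            assert pa.end_onsets == pb.end_onsets

    def test_zero_prevalence_yields_no_positive_windows(self):
        cohort = simulate_cohort(n_patients=3, duration_s=60, end_prevalence=0.0,
                                 seed=1)
        store_labels = []
        cfg = windows.WindowConfig()
        for rec in cohort.patients:
            _, labels, keep = windows.window_index(rec, cfg)
            store_labels.append(labels[keep])
        assert np.concatenate(store_labels).sum() == 0

    def test_clinical_imbalance_regime_realized(self, tmp_path):
        """30 patients at target 1:160 -> realised ratio within [1:128, 1:200]."""
        cohort = simulate_cohort(n_patients=30, duration_s=1200, end_prevalence=0.2,
                                 imbalance_target=160.0, seed=5, intensity=1.0)
        store = windows.materialize_windows(cohort, None, windows.WindowConfig(),
                                            tmp_path / "store")
        ratio = windows.realized_imbalance(store)
        assert 128.0 <= ratio <= 200.0

    def test_infeasible_imbalance_raises(self):
        with pytest.raises(ConfigurationError):
            simulate_cohort(n_patients=3, duration_s=40, end_prevalence=1.0,
                            imbalance_target=500.0, seed=0)

    def test_cohort_csv_round_trip(self, tmp_path):
        cohort = simulate_cohort(n_patients=3, duration_s=60, end_prevalence=1 / 3,
                                 imbalance_target=2.0, seed=8, intensity=2.0)
        simdata.write_cohort(cohort, tmp_path / "cohort")
        back = simdata.read_cohort(tmp_path / "cohort")
        assert back.patient_ids == cohort.patient_ids
        for pa, pb in zip(cohort.patients, back.patients):
            assert pa.end_onsets == pb.end_onsets
            np.testing.assert_allclose(pa.frames, pb.frames, rtol=1e-4, atol=1e-4)

    def test_precursor_signal_separable_by_spo2(self, easy_cohort, easy_store):
        """Sanity floor: logistic model on window-mean SpO2 beats chance AUC."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import roc_auc_score
        means = []
        for i in range(easy_store.n_windows):
            pid = easy_store.window_pids[i]
            e = easy_store.window_ends[i]
            frames = easy_store.window(pid, e)
            means.append(frames[:, COL["SpO2"]].mean())
        X = np.asarray(means)[:, None]
        y = np.asarray(easy_store.labels)
        clf = LogisticRegression().fit(X, y)
        auc = roc_auc_score(y, clf.predict_proba(X)[:, 1])
        assert auc > 0.5
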