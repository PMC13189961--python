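"""Windowing, labelling, patient-level split and window-store checks."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsfnet import simdata, windows
from dsfnet.errors import ConfigurationError
from dsfnet.net import FRAME_DIM
from dsfnet.windows import (SplitSpec, WindowConfig, build_windows,
                            kfold_by_patient, label_window, materialize_windows,
                            split_by_patient, window_index, window_overlap_ratio)


def _record(n_frames, onsets=(), pid="P0"):
    frames = np.zeros((n_frames, FRAME_DIM), dtype=np.float32)
    frames[:, 0] = np.arange(n_frames)
    frames[:, 3] = 97.0  # plausible SpO2 so validate() passes
    prof = simdata.PatientProfile(patient_id=pid)
    return simdata.PatientRecord(profile=prof, frames=frames,
                                 end_onsets=list(onsets))


class TestWindowing:
    @pytest.mark.parametrize("n,L,S,expected", [
        (100, 15, 1, 86), (15, 15, 1, 1), (14, 15, 1, 0), (100, 15, 15, 6),
    ])
    def test_window_count_formula(self, n, L, S, expected):
        ws = build_windows(_record(n), WindowConfig(L=L, S=S))
        assert len(ws) == expected
        if ws:
            assert all(w.frames.shape == (L, FRAME_DIM) for w in ws)

    @given(n=st.integers(15, 300), L=st.integers(2, 30), S=st.integers(1, 30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_window_count_matches_offset_enumeration(self, n, L, S):
        S = min(S, L)
        cfg = WindowConfig(L=L, S=S, horizon=max(1800, L))
        ws = build_windows(_record(max(n, L)), cfg)
        n_frames = max(n, L)
        enumerated = len(range(L - 1, n_frames, S))
        assert len(ws) == enumerated == (n_frames - L) // S + 1

    def test_windows_are_views_not_copies(self):
        rec = _record(30)
        ws = build_windows(rec, WindowConfig())
        assert ws[0].frames.base is rec.frames

    @pytest.mark.parametrize("L,S,expected", [(15, 1, 14 / 15), (15, 15, 0.0),
                                              (10, 5, 0.5)])
    def test_overlap_ratio(self, L, S, expected):
        assert window_overlap_ratio(WindowConfig(L=L, S=S)) == pytest.approx(expected)
        if (L, S) == (15, 1):
            assert round(100 * window_overlap_ratio(WindowConfig(L=L, S=S))) == 93


class TestLabelling:
    def test_thirty_minute_positive_band(self):
        cfg = WindowConfig()
        assert label_window(2400 - 600, [2400], cfg) == 1   # 600 s before onset
        assert label_window(2400 - 1800, [2400], cfg) == 1  # band edge included
        assert label_window(2400 - 1801, [2400], cfg) == 0  # just outside
        assert label_window(100, [], cfg) == 0

    def test_post_onset_boundary_excluded_from_positives(self):
        cfg = WindowConfig()
        assert label_window(2400, [2400], cfg) == 0  # t = onset -> not positive
        assert windows.window_excluded(2400, [2400], cfg)
        assert not windows.window_excluded(2400 + cfg.guard, [2400], cfg)

    def test_guard_band_windows_dropped_from_index(self):
        rec = _record(200, onsets=[100])
        ends, labels, keep = window_index(rec, WindowConfig(guard=50))
        times = rec.frames[ends, 0]
        assert np.all(labels[(times >= 0) & (times < 100)][keep[(times >= 0) & (times < 100)]])
        dropped = times[~keep]
        assert dropped.min() >= 100 and dropped.max() < 150

    def test_labels_causal_under_truncation(self):
        """Truncating frames after the last onset never relabels earlier windows."""
        rec = _record(400, onsets=[120])
        cfg = WindowConfig(guard=100)
        ends, labels, keep = window_index(rec, cfg)
        cut = 300
        short = _record(cut, onsets=[120])
        ends_s, labels_s, keep_s = window_index(short, cfg)
        k = len(ends_s)
        np.testing.assert_array_equal(labels[:k], labels_s)
        np.testing.assert_array_equal(keep[:k], keep_s)


@pytest.fixture(scope="module")
def cohort30():
    return simdata.simulate_cohort(n_patients=30, duration_s=60,
                                   end_prevalence=0.2, imbalance_target=6.0,
                                   seed=3, intensity=1.0)


class TestSplits:
    def test_30_patients_allocate_24_3_3(self, cohort30):
        split = split_by_patient(cohort30, (8, 1, 1), seed=0)
        assert (len(split.train_ids), len(split.val_ids), len(split.test_ids)) == (24, 3, 3)

    def test_split_deterministic_and_disjoint(self, cohort30):
        a = split_by_patient(cohort30, seed=5)
        b = split_by_patient(cohort30, seed=5)
        assert a.train_ids == b.train_ids and a.val_ids == b.val_ids
        all_ids = a.all_ids
        assert sorted(all_ids) == sorted(cohort30.patient_ids)
        assert len(set(all_ids)) == len(all_ids)

    def test_every_patient_maps_to_exactly_one_set(self, cohort30):
        split = split_by_patient(cohort30, seed=1)
        for pid in cohort30.patient_ids:
            assert split.set_of(pid) in ("train", "val", "test")

    def test_overlapping_split_spec_rejected(self):
        with pytest.raises(ConfigurationError, match="leakage"):
            SplitSpec(train_ids=["a", "b"], val_ids=["b"], test_ids=["c"])

    def test_too_few_patients_rejected(self):
        tiny = simdata.Cohort(
            patients=[_record(20, pid=f"Q{i}") for i in range(2)],
            seed=0, imbalance_target=1.0)
        with pytest.raises(ConfigurationError):
            split_by_patient(tiny)

    def test_kfold_allocation_and_disjointness(self, cohort30):
        folds, holdout = kfold_by_patient(cohort30, k=5, holdout_fraction=0.1, seed=2)
        assert len(holdout) == 3
        sizes = [len(f) for f in folds]
        assert all(abs(s - 27 / 5) <= 1 for s in sizes)
        everything = [pid for f in folds for pid in f] + holdout
        assert sorted(everything) == sorted(cohort30.patient_ids)
        f2, h2 = kfold_by_patient(cohort30, k=5, holdout_fraction=0.1, seed=2)
        assert f2 == folds and h2 == holdout

    def test_kfold_infeasible_k_rejected(self, cohort30):
        with pytest.raises(ConfigurationError):
            kfold_by_patient(cohort30, k=40)


@pytest.fixture(scope="module")
def cohort():
    return simdata.simulate_cohort(n_patients=4, duration_s=80,
                                   end_prevalence=0.5, imbalance_target=2.0,
                                   seed=6, intensity=2.0)


class TestWindowStore:
    def test_round_trip_is_bit_exact(self, cohort, tmp_path):
        cfg = WindowConfig()
        store = materialize_windows(cohort, None, cfg, tmp_path / "s")
        for rec in cohort.patients:
            for w in build_windows(rec, cfg):
                if windows.window_excluded(w.frames[-1, 0], rec.end_onsets, cfg):
                    continue
                got = store.window(rec.patient_id, w.end_index)
                np.testing.assert_array_equal(got, w.frames)

    def test_disk_size_linear_in_frames_not_windows(self, cohort, tmp_path):
        s1 = materialize_windows(cohort, None, WindowConfig(S=1), tmp_path / "s1")
        s15 = materialize_windows(cohort, None, WindowConfig(S=15), tmp_path / "s15")
        for rec in cohort.patients:
            a = (tmp_path / "s1" / f"{rec.patient_id}.bin").stat().st_size
            b = (tmp_path / "s15" / f"{rec.patient_id}.bin").stat().st_size
            assert a == b == rec.duration * FRAME_DIM * 4
        assert s1.n_windows > s15.n_windows

    def test_sidecar_label_counts_match_recount(self, cohort, tmp_path):
        cfg = WindowConfig()
        store = materialize_windows(cohort, None, cfg, tmp_path / "s")
        manifest = json.loads((tmp_path / "s" / "manifest.json").read_text())
        assert manifest["label_counts"]["positive"] == int((store.labels == 1).sum())
        assert manifest["label_counts"]["negative"] == int((store.labels == 0).sum())
        direct_pos = sum(int(window_index(rec, cfg)[1][window_index(rec, cfg)[2]].sum())
                         for rec in cohort.patients)
        assert manifest["label_counts"]["positive"] == direct_pos

    def test_gather_matches_single_window_access(self, cohort, tmp_path):
        store = materialize_windows(cohort, None, WindowConfig(), tmp_path / "s")
        idx = np.asarray([0, 5, store.n_windows - 1])
        batch = store.gather(idx)
        for row, i in enumerate(idx):
            np.testing.assert_array_equal(
                batch[row], store.window(store.window_pids[i], store.window_ends[i]))

    def test_split_membership_no_leakage(self, cohort, tmp_path):
        split = split_by_patient(cohort, (2, 1, 1), seed=0)
        store = materialize_windows(cohort, split, WindowConfig(), tmp_path / "s")
        got = store.split_ids()
        for name in ("train", "val", "test"):
            ids = set(getattr(got, f"{name}_ids"))
            other = set(got.all_ids) - ids
            w_ids = set(store.window_pids[store.indices_for(ids)])
            assert w_ids <= ids and not (w_ids & other)
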