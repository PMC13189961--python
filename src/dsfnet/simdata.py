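"""Synthetic bedside-monitor cohorts with labelled deterioration episodes.

Emulates the per-second multimodal frame schema of a neurocritical-care
monitor: a timestamp, 8 vital signs (HR, PR, SpO2, PI, NIBP systolic /
diastolic / mean, RR), 6 per-minute cardiac-event counters (PVCs, VPBs,
pauses, missed beats, couplets, R-on-T), and three waveforms — ECG and
respiration at 256 samples per second-frame, plethysmogram at 60 — for 587
scalars per frame in total.

ECG beats are sums of five Gaussians (P, Q, R, S, T sub-waves) on a per-beat
time axis; premature ventricular contractions are rendered as premature,
wide, negatively-skewed complexes followed by a compensatory pause, and
R-on-T events as narrow ectopics landing on the preceding T wave.  All
amplitudes are dimensionless normalised units.

Deterioration ("END") episodes are injected as a monotone precursor ramp
ending at the annotated onset: ectopic-beat rates rise, SpO2 declines, blood
pressure drifts, and heart-rate variability increases, each scaled by an
intensity gain.  Cohort generation places onsets so that the *window-level*
positive:negative ratio downstream of the default sliding-window labelling
matches a configurable imbalance target (the clinical regime is ~1:160).
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ConfigurationError
from .net import FRAME_COLUMNS, FRAME_DIM, NUMERIC_FEATURES

GENERATOR_VERSION = "1.0"

# column index of each numeric feature inside a 587-scalar frame row
COL = {name: 1 + i for i, name in enumerate(NUMERIC_FEATURES)}
ECG_COLS = slice(15, 271)
RESP_COLS = slice(271, 527)
PLETH_COLS = slice(527, 587)

ECG_FS = 256
RESP_FS = 256
PLETH_FS = 60

# ECG beat template: (amplitude, offset as fraction of the beat period, width in s)
_NORMAL_BEAT = (
    (0.15, -0.20, 0.040),   # P
    (-0.10, -0.040, 0.015),  # Q
    (1.00, 0.0, 0.022),      # R
    (-0.25, 0.040, 0.018),   # S
    (0.35, 0.30, 0.070),     # T
)
# PVC: wide (1.6x), 1.5x-amplitude negative-skew complex + discordant T wave
_PVC_BEAT = (
    (-1.50, 0.0, 0.035),
    (0.70, 0.09, 0.060),
)
# R-on-T: narrow premature spike overlapping the previous T wave
_RONT_BEAT = (
    (0.90, 0.0, 0.015),
    (-0.30, 0.05, 0.030),
)
_BEAT_TEMPLATES = {"normal": _NORMAL_BEAT, "pvc": _PVC_BEAT, "r_on_t": _RONT_BEAT}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class PatientProfile:
    patient_id: str
    base_hr: float = 75.0          # beats/min
    base_rr: float = 15.0          # breaths/min
    base_spo2: float = 97.0        # %
    base_nibp: tuple = (120.0, 75.0)  # (systolic, diastolic) mmHg
    noise_sd: float = 1.0          # per-channel additive-noise scale
    precursor_intensity: float = 1.0  # dimensionless ramp gain >= 0

    def __post_init__(self):
        if not 40 <= self.base_hr <= 180:
            raise ConfigurationError(f"base_hr {self.base_hr} outside [40, 180]")
        if not 70 <= self.base_spo2 <= 100:
            raise ConfigurationError(f"base_spo2 {self.base_spo2} outside [70, 100]")
        if self.base_nibp[0] <= self.base_nibp[1]:
            raise ConfigurationError(f"systolic must exceed diastolic: {self.base_nibp}")
        if self.precursor_intensity < 0:
            raise ConfigurationError("precursor_intensity must be >= 0")


@dataclass
class FrameRecord:
    """One per-second multimodal observation (view into a patient's frame matrix)."""

    timestamp: float
    vitals: np.ndarray          # (8,)
    cardiac_events: np.ndarray  # (6,)
    ecg: np.ndarray             # (256,)
    resp: np.ndarray            # (256,)
    pleth: np.ndarray           # (60,)

    @classmethod
    def from_row(cls, row: np.ndarray) -> "FrameRecord":
        return cls(timestamp=float(row[0]), vitals=row[1:9], cardiac_events=row[9:15],
                   ecg=row[ECG_COLS], resp=row[RESP_COLS], pleth=row[PLETH_COLS])

    def validate(self) -> None:
        total = 1 + self.vitals.size + self.cardiac_events.size + \
            self.ecg.size + self.resp.size + self.pleth.size
        if total != FRAME_DIM:
            raise ValueError(f"frame carries {total} scalars, expected {FRAME_DIM}")
        if np.any(self.cardiac_events < 0):
            raise ValueError("cardiac event counters must be nonnegative")
        if self.vitals[2] > 100:
            raise ValueError("SpO2 cannot exceed 100%")
        for w in (self.ecg, self.resp, self.pleth):
            if not np.all(np.isfinite(w)):
                raise ValueError("waveform contains non-finite values")


@dataclass
class PatientRecord:
    profile: PatientProfile
    frames: np.ndarray                  # (duration, 587) float32, 1 Hz
    end_onsets: list = field(default_factory=list)

    @property
    def patient_id(self) -> str:
        return self.profile.patient_id

    @property
    def duration(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> FrameRecord:
        return FrameRecord.from_row(self.frames[i])

    def validate(self) -> None:
        if self.frames.shape[1] != FRAME_DIM:
            raise ValueError(f"frames must have {FRAME_DIM} columns")
        ts = self.frames[:, 0]
        if not np.allclose(np.diff(ts), 1.0):
            raise ValueError("frames must be strictly increasing by 1 s")
        for o in self.end_onsets:
            if not 0 <= o <= self.duration:
                raise ValueError(f"onset {o} outside [0, {self.duration}]")


@dataclass
class Cohort:
    patients: list
    seed: int
    imbalance_target: float

    def __post_init__(self):
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("patient ids must be unique")

    def patient(self, pid: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == pid:
                return p
        raise KeyError(pid)

    @property
    def patient_ids(self) -> list:
        return [p.patient_id for p in self.patients]


# ---------------------------------------------------------------------------
# Waveform synthesis (frame-by-frame, phase-continuous)
# ---------------------------------------------------------------------------


@dataclass
class EcgPhase:
    """Continuity state of the ECG generator: absolute clock + beat schedule."""

    t: float = 0.0                 # start time of the next frame
    t_next: float = 0.3            # scheduled time of the next beat
    beats: list = field(default_factory=list)   # (t_R, kind, period)

    def copy(self) -> "EcgPhase":
        return EcgPhase(self.t, self.t_next, list(self.beats))


def _beat_waveform(t: np.ndarray, t_r: float, kind: str, period: float) -> np.ndarray:
    out = np.zeros_like(t)
    for amp, off_frac, width in _BEAT_TEMPLATES[kind]:
        center = t_r + off_frac * period
        out += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return out


def synthesize_ecg_frame(hr: float, phase: EcgPhase | None = None,
                         anomalies: list | tuple = (), noise_sd: float = 0.0,
                         rng: np.random.Generator | None = None):
    """One second of ECG at 256 samples/s.

    Beats carry P-QRS-T morphology; ``anomalies`` is a queue of beat-level
    tags ("pvc", "r_on_t") consumed by the beats scheduled during this frame.
    Returns ``(samples, updated_phase)``; the passed phase is not mutated.
    """
    if hr <= 0:
        raise ValueError(f"hr must be positive, got {hr}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    phase = EcgPhase() if phase is None else phase.copy()
    period = 60.0 / hr
    frame_end = phase.t + 1.0
    pending = list(anomalies)
    while phase.t_next < frame_end + 0.5:
        kind = pending.pop(0) if pending else "normal"
        if kind == "normal":
            phase.beats.append((phase.t_next, "normal", period))
            phase.t_next += period
        elif kind == "pvc":
            # premature wide complex + compensatory pause (next beat keeps schedule)
            phase.beats.append((phase.t_next - 0.35 * period, "pvc", period))
            phase.t_next += period
        elif kind == "r_on_t":
            # ectopic landing on the previous beat's T wave, then a pause
            phase.beats.append((phase.t_next - 0.65 * period, "r_on_t", period))
            phase.t_next += 0.5 * period
        else:
            raise ValueError(f"unknown anomaly tag: {kind!r}")
    t = phase.t + np.arange(ECG_FS) / ECG_FS
    sig = np.zeros(ECG_FS)
    for t_r, kind, p in phase.beats:
        if t_r > frame_end + 0.6 or t_r < phase.t - 0.8:
            continue
        sig += _beat_waveform(t, t_r, kind, p)
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, ECG_FS)
    phase.beats = [b for b in phase.beats if b[0] > frame_end - 0.8]
    phase.t = frame_end
    return sig, phase


def synthesize_resp_frame(rr: float, phase: float = 0.0, noise_sd: float = 0.0,
                          rng: np.random.Generator | None = None):
    """One second of quasi-sinusoidal respiration at 256 samples/s (rr/60 Hz)."""
    if rr <= 0:
        raise ValueError(f"rr must be positive, got {rr}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    f = rr / 60.0
    p = phase + f * np.arange(RESP_FS) / RESP_FS
    sig = np.sin(2 * np.pi * p) + 0.15 * np.sin(4 * np.pi * p + 0.8)
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, RESP_FS)
    return sig, (phase + f) % 1.0


def _pleth_template(p: np.ndarray) -> np.ndarray:
    # systolic upstroke with a small dicrotic bump; one pulse per cycle, range [0, ~1]
    return np.sin(np.pi * p) ** 3 + 0.18 * np.exp(-0.5 * ((p - 0.72) / 0.06) ** 2)


def synthesize_pleth_frame(hr: float, phase: float = 0.0, perfusion_index: float = 2.0,
                           noise_sd: float = 0.0,
                           rng: np.random.Generator | None = None):
    """One second of pulse-oximetry volume waveform at 60 samples/s.

    Pulse rate follows ``hr``; amplitude scales linearly with the perfusion
    index (pulsatile/non-pulsatile flow ratio).
    """
    if hr <= 0:
        raise ValueError(f"hr must be positive, got {hr}")
    if perfusion_index < 0:
        raise ValueError("perfusion_index must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    f = hr / 60.0
    p = (phase + f * np.arange(PLETH_FS) / PLETH_FS) % 1.0
    sig = perfusion_index * _pleth_template(p)
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, PLETH_FS)
    return sig, (phase + f) % 1.0


# ---------------------------------------------------------------------------
# Patient-level simulation
# ---------------------------------------------------------------------------


def _ar1(n: int, rho: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary-ish AR(1) track used for slow vital-sign wander."""
    return lfilter([1.0], [1.0, -rho], rng.normal(0.0, sd, n))


def _rolling_minute_counts(event_times: np.ndarray, duration: int) -> np.ndarray:
    """Per-second rolling count of events in the trailing 60 s window."""
    per_sec = np.zeros(duration + 1)
    idx = np.floor(event_times).astype(int)
    idx = idx[(idx >= 0) & (idx < duration)]
    np.add.at(per_sec, idx, 1.0)
    csum = np.cumsum(per_sec)[:duration]
    out = csum.copy()
    out[60:] -= csum[:-60]
    return out


def simulate_patient(profile: PatientProfile, duration_s: int,
                     rng: np.random.Generator) -> PatientRecord:
    """Generate a stable (episode-free) patient record at 1 Hz."""
    n = int(duration_s)
    nz = profile.noise_sd
    hr = np.clip(profile.base_hr + _ar1(n, 0.995, 0.08 * nz, rng), 40, 180)
    pr = hr + rng.normal(0.0, 0.3 * nz, n)
    spo2 = np.clip(profile.base_spo2 + _ar1(n, 0.99, 0.03 * nz, rng), 70, 100)
    pi = np.clip(2.0 + _ar1(n, 0.99, 0.02 * nz, rng), 0.2, 10.0)
    nibp_s = profile.base_nibp[0] + _ar1(n, 0.998, 0.05 * nz, rng)
    nibp_d = profile.base_nibp[1] + _ar1(n, 0.998, 0.03 * nz, rng)
    nibp_m = nibp_d + (nibp_s - nibp_d) / 3.0
    rr = np.clip(profile.base_rr + _ar1(n, 0.995, 0.03 * nz, rng), 6, 40)

    # sparse baseline ectopy (events/minute rates are deliberately low)
    pvc_times = np.flatnonzero(rng.random(n) < 0.2 / 60.0).astype(float)
    ront_times = np.flatnonzero(rng.random(n) < 0.02 / 60.0).astype(float)
    pause_times = np.flatnonzero(rng.random(n) < 0.05 / 60.0).astype(float)
    missed_times = np.flatnonzero(rng.random(n) < 0.05 / 60.0).astype(float)
    anomalies: dict = {}
    for t in pvc_times:
        anomalies.setdefault(int(t), []).append("pvc")
    for t in ront_times:
        anomalies.setdefault(int(t), []).append("r_on_t")

    frames = np.zeros((n, FRAME_DIM), dtype=np.float32)
    frames[:, 0] = np.arange(n)
    for name, track in (("HR", hr), ("PR", pr), ("SpO2", spo2), ("PI", pi),
                        ("NIBP_S", nibp_s), ("NIBP_D", nibp_d), ("NIBP_M", nibp_m),
                        ("RR", rr)):
        frames[:, COL[name]] = track
    frames[:, COL["PVCs"]] = _rolling_minute_counts(pvc_times, n)
    frames[:, COL["VPBs"]] = frames[:, COL["PVCs"]]
    frames[:, COL["Pauses"]] = _rolling_minute_counts(pause_times, n)
    frames[:, COL["Missed"]] = _rolling_minute_counts(missed_times, n)
    frames[:, COL["Couplets"]] = _rolling_minute_counts(
        _couplet_times(np.sort(pvc_times)), n)
    frames[:, COL["RonT"]] = _rolling_minute_counts(ront_times, n)

    wf_noise = 0.02 * nz
    ecg_phase = EcgPhase(t_next=0.3 + 0.4 * rng.random())
    resp_phase = rng.random()
    pleth_phase = rng.random()
    for t in range(n):
        ecg, ecg_phase = synthesize_ecg_frame(
            hr[t], ecg_phase, anomalies.get(t, []), wf_noise, rng)
        resp, resp_phase = synthesize_resp_frame(rr[t], resp_phase, wf_noise, rng)
        pleth, pleth_phase = synthesize_pleth_frame(
            hr[t], pleth_phase, pi[t], wf_noise, rng)
        frames[t, ECG_COLS] = ecg
        frames[t, RESP_COLS] = resp
        frames[t, PLETH_COLS] = pleth
    return PatientRecord(profile=profile, frames=frames, end_onsets=[])


def _couplet_times(sorted_times: np.ndarray) -> np.ndarray:
    if sorted_times.size < 2:
        return np.zeros(0)
    gaps = np.diff(sorted_times)
    return sorted_times[1:][gaps <= 2.0]


# ---------------------------------------------------------------------------
# Episode injection
# ---------------------------------------------------------------------------


def inject_end_episode(record: PatientRecord, onset: float, ramp_duration: float,
                       intensity: float, rng: np.random.Generator) -> PatientRecord:
    """Inject a deterioration episode with a monotone precursor ramp.

    During ``[onset - ramp_duration, onset)`` the PVC / R-on-T rates, SpO2
    decline, NIBP drift and HR variability all scale with ``intensity`` times
    a linear ramp reaching 1 at onset; frames outside the ramp are untouched
    and the onset time is appended to the record's annotations.
    """
    if ramp_duration > 1800:
        raise ValueError(f"ramp_duration {ramp_duration} exceeds 1800 s")
    if onset < ramp_duration:
        raise ValueError(f"onset {onset} precedes its ramp ({ramp_duration} s)")
    if onset > record.duration:
        raise ValueError(f"onset {onset} beyond record duration {record.duration}")
    out = PatientRecord(profile=record.profile, frames=record.frames.copy(),
                        end_onsets=sorted(record.end_onsets + [float(onset)]))
    if intensity == 0 or ramp_duration == 0:
        return out
    start = int(math.ceil(onset - ramp_duration))
    stop = int(math.ceil(onset))          # ramp seconds: start .. stop-1
    secs = np.arange(start, stop)
    r = (secs - (onset - ramp_duration) + 1.0) / ramp_duration  # -> 1 at onset
    f = out.frames

    spo2 = f[secs, COL["SpO2"]] - 5.0 * intensity * r
    f[secs, COL["SpO2"]] = np.clip(spo2, 40.0, 100.0)
    f[secs, COL["NIBP_S"]] += (12.0 * intensity * r).astype(np.float32)
    f[secs, COL["NIBP_D"]] += (5.0 * intensity * r).astype(np.float32)
    f[secs, COL["NIBP_M"]] = f[secs, COL["NIBP_D"]] + (
        f[secs, COL["NIBP_S"]] - f[secs, COL["NIBP_D"]]) / 3.0
    hrv = 6.0 * intensity * r * np.sin(2 * np.pi * secs / 20.0)
    f[secs, COL["HR"]] = np.clip(f[secs, COL["HR"]] + hrv, 40, 200)
    f[secs, COL["PR"]] = np.clip(f[secs, COL["PR"]] + hrv, 40, 200)
    f[secs, COL["RR"]] += (2.0 * intensity * r).astype(np.float32)

    # ramped ectopic bursts superposed on the existing ECG
    lam = np.minimum(1.5, 0.35 * intensity * r)
    pvc_times, ront_times = [], []
    ts_local = np.arange(ECG_FS) / ECG_FS
    for s, lam_s in zip(secs, lam):
        for _ in range(int(rng.poisson(lam_s))):
            u = 0.15 + 0.7 * rng.random()
            kind = "r_on_t" if rng.random() < 0.25 else "pvc"
            (ront_times if kind == "r_on_t" else pvc_times).append(s + u)
            f[s, ECG_COLS] += _beat_waveform(
                ts_local, u, kind, 60.0 / max(f[s, COL["HR"]], 40.0)).astype(np.float32)
    pvc_counts = _rolling_minute_counts(np.asarray(pvc_times), out.duration)
    ront_counts = _rolling_minute_counts(np.asarray(ront_times), out.duration)
    coup_counts = _rolling_minute_counts(
        _couplet_times(np.sort(np.asarray(pvc_times))), out.duration)
    f[:, COL["PVCs"]] += pvc_counts
    f[:, COL["VPBs"]] += pvc_counts
    f[:, COL["RonT"]] += ront_counts
    f[:, COL["Couplets"]] += coup_counts
    return out


# ---------------------------------------------------------------------------
# Cohort-level planning and generation
# ---------------------------------------------------------------------------


def window_label_counts(duration: int, onsets: list, L: int = 15, S: int = 1,
                        horizon: int = 1800, guard: int = 1800):
    """(positive, negative, excluded) window counts for one record.

    Mirrors the downstream labelling semantics: a window is identified by its
    last-frame time ``e``; positive iff ``onset - horizon <= e < onset`` for
    some onset, excluded (neither class) iff ``onset <= e < onset + guard``.
    """
    ends = np.arange(L - 1, duration, S)
    pos = np.zeros(ends.shape, dtype=bool)
    exc = np.zeros(ends.shape, dtype=bool)
    for o in onsets:
        pos |= (ends >= o - horizon) & (ends < o)
        exc |= (ends >= o) & (ends < o + guard)
    pos &= ~exc
    n_pos = int(pos.sum())
    n_exc = int(exc.sum())
    return n_pos, int(ends.size - n_pos - n_exc), n_exc


def _solve_onset(n_patients: int, n_ep: int, duration: int, target: float,
                 L: int = 15, horizon: int = 1800, guard: int = 1800) -> int:
    """Pick a common onset time so that neg/pos across the cohort ~= target."""
    best, best_err = None, np.inf
    for o in range(L + 5, duration):
        p, neg_ep, _ = window_label_counts(duration, [o], L, 1, horizon, guard)
        if p == 0:
            continue
        pos = n_ep * p
        neg = n_ep * neg_ep + (n_patients - n_ep) * (duration - L + 1)
        err = abs(neg / pos - target) / target
        if err < best_err:
            best, best_err = o, err
    if best is None or best_err > 0.25:
        raise ConfigurationError(
            f"imbalance target 1:{target} infeasible for duration {duration} s "
            f"with {n_ep}/{n_patients} episode patients (best rel. error {best_err:.2f})")
    return best


def simulate_cohort(n_patients: int = 30, duration_s: int = 1800,
                    end_prevalence: float = 0.2, imbalance_target: float = 160.0,
                    seed: int = 0, intensity: float = 1.0,
                    noise_sd: float = 1.0) -> Cohort:
    """Generate a cohort whose window-level class ratio matches the target.

    ``imbalance_target`` is the negative:positive ratio R in "1:R".  Onset
    times are placed (identically across episode patients) so that, after
    default sliding-window labelling (L=15, S=1, 30-min horizon and post-onset
    guard), the realised ratio lands within 25% of the target.  Fully
    deterministic for a given seed.
    """
    if n_patients < 3:
        raise ConfigurationError("need at least 3 patients for patient-level splits")
    if duration_s < 15:
        raise ConfigurationError("duration shorter than one window")
    n_ep = int(round(end_prevalence * n_patients))
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.spawn(n_patients)

    onset = _solve_onset(n_patients, n_ep, duration_s, imbalance_target) \
        if n_ep > 0 else None
    ep_idx = set(master.choice(n_patients, size=n_ep, replace=False).tolist())

    patients = []
    for i in range(n_patients):
        rng = np.random.default_rng(child_seeds[i])
        profile = PatientProfile(
            patient_id=f"P{i:03d}",
            base_hr=float(rng.uniform(60, 100)),
            base_rr=float(rng.uniform(12, 20)),
            base_spo2=float(rng.uniform(95, 99)),
            base_nibp=(float(rng.uniform(110, 150)), float(rng.uniform(60, 90))),
            noise_sd=noise_sd,
            precursor_intensity=intensity,
        )
        rec = simulate_patient(profile, duration_s, rng)
        if i in ep_idx:
            ramp = min(float(onset), 1500.0)
            rec = inject_end_episode(rec, float(onset), ramp, intensity, rng)
        patients.append(rec)
    return Cohort(patients=patients, seed=seed, imbalance_target=imbalance_target)


# ---------------------------------------------------------------------------
# Cohort I/O (one CSV per patient + JSON manifest)
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "generator_version": GENERATOR_VERSION,
        "seed": cohort.seed,
        "imbalance_target": cohort.imbalance_target,
        "patients": {},
    }
    for rec in cohort.patients:
        pid = rec.patient_id
        pd.DataFrame(rec.frames, columns=FRAME_COLUMNS).to_csv(
            out / f"{pid}.csv", index=False, float_format="%.6g")
        prof = rec.profile
        manifest["patients"][pid] = {
            "end_onsets": list(map(float, rec.end_onsets)),
            "profile": {
                "patient_id": prof.patient_id, "base_hr": prof.base_hr,
                "base_rr": prof.base_rr, "base_spo2": prof.base_spo2,
                "base_nibp": list(prof.base_nibp), "noise_sd": prof.noise_sd,
                "precursor_intensity": prof.precursor_intensity,
            },
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_cohort(in_dir) -> Cohort:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    patients = []
    for pid, meta in manifest["patients"].items():
        prof_d = dict(meta["profile"])
        prof_d["base_nibp"] = tuple(prof_d["base_nibp"])
        frames = pd.read_csv(src / f"{pid}.csv").to_numpy(dtype=np.float32)
        patients.append(PatientRecord(
            profile=PatientProfile(**prof_d), frames=frames,
            end_onsets=list(meta["end_onsets"])))
    return Cohort(patients=patients, seed=manifest["seed"],
                  imbalance_target=manifest["imbalance_target"])
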