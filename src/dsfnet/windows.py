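"""Sliding-window segmentation, causal labelling, patient-level splits and
memory-mapped window storage.

Windows are L=15-frame views advanced with stride S=1 (≈93% overlap).  A
window is labelled by its *last* frame's timestamp ``e``: positive iff
``onset - horizon <= e < onset`` for some annotated deterioration onset
(horizon 1800 s, i.e. the 30-minute pre-onset observation band), negative
otherwise.  Frames inside a post-onset guard band of the same length are
excluded from training entirely (neither class) so that "stable" negatives
are not contaminated by the deterioration itself.

Splits and cross-validation folds are patient-level: no patient's windows
ever appear in more than one of train/val/test (or in two folds), which is
the leakage guard the evaluation protocol depends on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .net import FRAME_DIM, state_hash
from .simdata import Cohort, PatientRecord

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"


@dataclass
class WindowConfig:
    L: int = 15          # window length, frames
    S: int = 1           # stride, frames
    horizon: int = 1800  # positive-label lookahead, s
    guard: int = 1800    # post-onset exclusion band, s

    def __post_init__(self):
        if not 1 <= self.S <= self.L:
            raise ConfigurationError(f"stride must satisfy 1 <= S <= L, got S={self.S}, L={self.L}")
        if self.horizon < self.L:
            raise ConfigurationError(f"horizon {self.horizon} shorter than window L={self.L}")

    def to_dict(self) -> dict:
        return {"L": self.L, "S": self.S, "horizon": self.horizon, "guard": self.guard}


@dataclass
class WindowSample:
    patient_id: str
    end_index: int
    frames: np.ndarray   # (L, 587) view into the patient's frame matrix
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label}")


@dataclass
class SplitSpec:
    train_ids: list
    val_ids: list
    test_ids: list
    ratios: tuple = (8, 1, 1)
    seed: int = 0

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ConfigurationError(
                        f"patient-level leakage: {sorted(sets[i] & sets[j])} "
                        "appear in two split sets")

    @property
    def all_ids(self) -> list:
        return list(self.train_ids) + list(self.val_ids) + list(self.test_ids)

    def set_of(self, pid: str) -> str:
        for name in ("train", "val", "test"):
            if pid in getattr(self, f"{name}_ids"):
                return name
        raise KeyError(pid)


# ---------------------------------------------------------------------------
# Windowing and labelling
# ---------------------------------------------------------------------------


def window_overlap_ratio(cfg: WindowConfig) -> float:
    """Fraction of shared frames between consecutive windows: (L - S) / L."""
    return (cfg.L - cfg.S) / cfg.L


def label_window(end_time: float, end_onsets, cfg: WindowConfig) -> int:
    """1 iff the window's last-frame time lies in [onset - horizon, onset)."""
    for o in end_onsets:
        if o - cfg.horizon <= end_time < o:
            return 1
    return 0


def window_excluded(end_time: float, end_onsets, cfg: WindowConfig) -> bool:
    """True iff the last frame falls in a post-onset guard band [onset, onset+guard)."""
    return any(o <= end_time < o + cfg.guard for o in end_onsets)


def build_windows(record: PatientRecord, cfg: WindowConfig) -> list:
    """All windows of a record, in time order, as zero-copy views.

    Count = floor((n_frames - L)/S) + 1; a record shorter than L yields an
    empty list (logged, not an error).
    """
    n = record.duration
    if n < cfg.L:
        log.info("record %s shorter than one window (%d < %d frames)",
                 record.patient_id, n, cfg.L)
        return []
    out = []
    for end in range(cfg.L - 1, n, cfg.S):
        frames = record.frames[end - cfg.L + 1:end + 1]
        t = float(record.frames[end, 0])
        out.append(WindowSample(record.patient_id, end, frames,
                                label_window(t, record.end_onsets, cfg)))
    return out


def window_index(record: PatientRecord, cfg: WindowConfig):
    """(end_indices, labels, keep_mask) for one record, vectorised.

    ``keep_mask`` is False for windows in the post-onset guard band; those are
    dropped from training/evaluation indices.
    """
    n = record.duration
    ends = np.arange(cfg.L - 1, n, cfg.S)
    times = record.frames[ends, 0]
    pos = np.zeros(ends.shape, dtype=bool)
    exc = np.zeros(ends.shape, dtype=bool)
    for o in record.end_onsets:
        pos |= (times >= o - cfg.horizon) & (times < o)
        exc |= (times >= o) & (times < o + cfg.guard)
    pos &= ~exc
    return ends, pos.astype(np.int8), ~exc


# ---------------------------------------------------------------------------
# Patient-level splits
# ---------------------------------------------------------------------------


def _allocate(n: int, ratios) -> list:
    """Floor allocation of n items to ratio buckets; remainder goes to the first
    (train) bucket."""
    total = sum(ratios)
    sizes = [n * r // total for r in ratios]
    sizes[0] += n - sum(sizes)
    return sizes


def _episode_ids(cohort: Cohort) -> set:
    return {p.patient_id for p in cohort.patients if p.end_onsets}


def split_by_patient(cohort: Cohort, ratios=(8, 1, 1), seed: int = 0,
                     stratify: bool = True) -> SplitSpec:
    """Deterministic patient-level split with floor+remainder-to-train sizes.

    With ``stratify`` (default), one episode-bearing patient and one
    episode-free patient are planted in each non-empty set (capacity
    permitting) before the remaining patients are shuffled in, so that
    desk-scale validation/test sets contain windows of both classes whenever
    possible.
    """
    ids = cohort.patient_ids
    n_buckets = sum(1 for r in ratios if r > 0)
    if len(ids) < n_buckets:
        raise ConfigurationError(
            f"{len(ids)} patients cannot fill {n_buckets} split sets")
    sizes = _allocate(len(ids), ratios)
    rng = np.random.default_rng(seed)
    ep = [i for i in ids if i in _episode_ids(cohort)]
    non = [i for i in ids if i not in _episode_ids(cohort)]
    rng.shuffle(ep)
    rng.shuffle(non)
    sets: dict = {"train": [], "val": [], "test": []}
    order = ["val", "test", "train"]   # fill the small sets' guaranteed slots first
    if stratify:
        for name, size in zip(order, (sizes[1], sizes[2], sizes[0])):
            if size > 0 and ep:
                sets[name].append(ep.pop())
            if len(sets[name]) < size and non:
                sets[name].append(non.pop())
    pool = ep + non
    rng.shuffle(pool)
    for name, size in zip(("train", "val", "test"), sizes):
        while len(sets[name]) < size:
            sets[name].append(pool.pop())
    return SplitSpec(train_ids=sets["train"], val_ids=sets["val"],
                     test_ids=sets["test"], ratios=tuple(ratios), seed=seed)


def kfold_by_patient(cohort: Cohort, k: int, holdout_fraction: float = 0.1,
                     seed: int = 0, stratify: bool = True):
    """Patient-level k folds after removing a fixed holdout set.

    Returns ``(folds, holdout_ids)`` where ``folds`` is a list of k disjoint
    patient-id lists; union of folds + holdout covers the cohort exactly.
    """
    ids = cohort.patient_ids
    n_hold = max(1, int(round(holdout_fraction * len(ids))))
    if k > len(ids) - n_hold:
        raise ConfigurationError(
            f"k={k} folds infeasible with {len(ids) - n_hold} non-holdout patients")
    rng = np.random.default_rng(seed)
    ep = [i for i in ids if i in _episode_ids(cohort)]
    non = [i for i in ids if i not in _episode_ids(cohort)]
    rng.shuffle(ep)
    rng.shuffle(non)
    units = [[] for _ in range(k + 1)]            # folds 0..k-1, holdout = k
    base = (len(ids) - n_hold) // k
    rem = (len(ids) - n_hold) - base * k
    capacities = [base + (1 if i < rem else 0) for i in range(k)] + [n_hold]
    if stratify:
        # deal episode patients round-robin across folds then holdout
        j = 0
        while ep:
            placed = False
            for _ in range(k + 1):
                u = j % (k + 1)
                j += 1
                if len(units[u]) < capacities[u]:
                    units[u].append(ep.pop())
                    placed = True
                    break
            if not placed:
                break
    pool = ep + non
    rng.shuffle(pool)
    for i, cap in enumerate(capacities):
        while len(units[i]) < cap:
            units[i].append(pool.pop())
    folds, holdout = units[:k], units[k]
    seen: set = set()
    for part in folds + [holdout]:
        if seen & set(part):
            raise ConfigurationError("patient-level leakage across folds")
        seen |= set(part)
    return folds, holdout


# ---------------------------------------------------------------------------
# Memory-mapped window store
# ---------------------------------------------------------------------------


class WindowStore:
    """Per-patient float32 frame matrices on disk + window index tables.

    Frames are stored once per patient (``<pid>.bin``, row-major n×587); a
    window is addressed as ``(patient, end_index)`` and gathered as a view
    slice, so on-disk size grows with frames, never with window count.
    """

    def __init__(self, path):
        self.path = Path(path)
        self.manifest = json.loads((self.path / "manifest.json").read_text())
        self.cfg = WindowConfig(**self.manifest["window_config"])
        self._mm: dict = {}
        pids, ends, labels = [], [], []
        for pid, meta in self.manifest["patients"].items():
            self._mm[pid] = np.memmap(self.path / f"{pid}.bin", dtype=np.float32,
                                      mode="r", shape=(meta["n_frames"], FRAME_DIM))
            pids.extend([pid] * len(meta["ends"]))
            ends.extend(meta["ends"])
            labels.extend(meta["labels"])
        self.window_pids = np.asarray(pids, dtype=object)
        self.window_ends = np.asarray(ends, dtype=np.int64)
        self.labels = np.asarray(labels, dtype=np.int8)

    # -- access -------------------------------------------------------------
    @property
    def n_windows(self) -> int:
        return self.window_ends.size

    @property
    def config_hash(self) -> str:
        return self.manifest["config_hash"]

    def patient_frames(self, pid: str) -> np.ndarray:
        return self._mm[pid]

    def indices_for(self, patient_ids) -> np.ndarray:
        wanted = set(patient_ids)
        return np.flatnonzero([p in wanted for p in self.window_pids])

    def gather(self, indices) -> np.ndarray:
        """Assemble (B, L, 587) window frames for the given window indices."""
        L = self.cfg.L
        out = np.empty((len(indices), L, FRAME_DIM), dtype=np.float32)
        for row, i in enumerate(indices):
            mm = self._mm[self.window_pids[i]]
            e = self.window_ends[i]
            out[row] = mm[e - L + 1:e + 1]
        return out

    def window(self, pid: str, end_index: int) -> np.ndarray:
        L = self.cfg.L
        return np.asarray(self._mm[pid][end_index - L + 1:end_index + 1])

    def split_ids(self) -> SplitSpec | None:
        s = self.manifest.get("split")
        if s is None:
            return None
        return SplitSpec(train_ids=s["train"], val_ids=s["val"], test_ids=s["test"],
                         ratios=tuple(s["ratios"]), seed=s["seed"])


def materialize_windows(cohort: Cohort, split: SplitSpec | None, cfg: WindowConfig,
                        out_path, config_hash: str | None = None) -> WindowStore:
    """Write per-patient frame binaries + a JSON sidecar and open the store."""
    out = Path(out_path)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create window store at {out}: {exc}") from exc
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "dtype": "float32",
        "frame_dim": FRAME_DIM,
        "window_config": cfg.to_dict(),
        "patients": {},
        "label_counts": {"positive": 0, "negative": 0, "excluded": 0},
    }
    for rec in cohort.patients:
        ends, labels, keep = window_index(rec, cfg)
        kept_ends = ends[keep]
        kept_labels = labels[keep]
        rec.frames.astype(np.float32).tofile(out / f"{rec.patient_id}.bin")
        manifest["patients"][rec.patient_id] = {
            "n_frames": int(rec.duration),
            "end_onsets": list(map(float, rec.end_onsets)),
            "ends": kept_ends.tolist(),
            "labels": kept_labels.tolist(),
        }
        manifest["label_counts"]["positive"] += int(kept_labels.sum())
        manifest["label_counts"]["negative"] += int((kept_labels == 0).sum())
        manifest["label_counts"]["excluded"] += int((~keep).sum())
    if split is not None:
        manifest["split"] = {"train": list(split.train_ids), "val": list(split.val_ids),
                             "test": list(split.test_ids), "ratios": list(split.ratios),
                             "seed": split.seed}
    manifest["config_hash"] = config_hash or state_hash(
        {"window_config": cfg.to_dict(), "patients": sorted(cohort.patient_ids)})
    (out / "manifest.json").write_text(json.dumps(manifest))
    return WindowStore(out)


def realized_imbalance(store: WindowStore) -> float:
    """Realised negative:positive window ratio of a store."""
    pos = int((store.labels == 1).sum())
    neg = int((store.labels == 0).sum())
    if pos == 0:
        raise ConfigurationError("store contains no positive windows")
    return neg / pos
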