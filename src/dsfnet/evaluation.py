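"""Evaluation: recall / precision / F1, rank-based AUC, F1-optimal decision
threshold, and score-distribution diagnostics.

AUC uses the rank formulation

    AUC = ( Σ_{i∈pos} rank_i − M(M+1)/2 ) / (M·N)

with ascending midranks for ties, which makes it identical to the
Mann–Whitney pair statistic: the fraction of (positive, negative) pairs the
positive outranks, ties counted half.

The operating threshold τ* = argmax_{τ∈(0,1)} F1(τ) is found exactly: F1 is
piecewise constant between adjacent distinct scores, so scanning the distinct
scores plus their midpoints attains the global maximum.  Ties break toward
the smallest τ (favouring recall).  τ* is selected on validation scores and
then frozen for the test set; recalibration under drift is a re-run of the
scan on new data, not an automatic mechanism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import UndefinedMetricError

log = logging.getLogger(__name__)


@dataclass
class PredictionSet:
    scores: np.ndarray
    labels: np.ndarray
    patient_ids: list | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.scores.shape != self.labels.shape:
            raise ValueError(f"scores {self.scores.shape} and labels "
                             f"{self.labels.shape} differ in length")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")

    @property
    def n_pos(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.labels == 0).sum())


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    recall: float
    precision: float
    f1: float
    auc: float
    threshold: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("tp", "fp", "fn", "tn", "recall", "precision", "f1", "auc", "threshold")}


@dataclass
class ThresholdResult:
    tau_star: float
    f1_at_tau: float
    scanned_candidates: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Confusion counts and ratio metrics
# ---------------------------------------------------------------------------


def confusion_at_threshold(preds: PredictionSet, tau: float):
    """(tp, fp, fn, tn) with the decision rule: positive iff score >= tau."""
    if not 0.0 < tau < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {tau}")
    pred = preds.scores >= tau
    pos = preds.labels == 1
    tp = int((pred & pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    return tp, fp, fn, tn


def recall_score(tp: int, fn: int) -> float:
    """TP / (TP + FN); 0 by convention when no positives exist."""
    if tp + fn == 0:
        log.debug("recall undefined (no positives); returning 0")
        return 0.0
    return tp / (tp + fn)


def precision_score(tp: int, fp: int) -> float:
    if tp + fp == 0:
        log.debug("precision undefined (no predicted positives); returning 0")
        return 0.0
    return tp / (tp + fp)


def f1_score(tp: int, fp: int, fn: int) -> float:
    """2·TP / (2·TP + FP + FN); 0 by convention in the degenerate case."""
    denom = 2 * tp + fp + fn
    if denom == 0:
        log.debug("F1 undefined (tp=fp=fn=0); returning 0")
        return 0.0
    return 2 * tp / denom


# ---------------------------------------------------------------------------
# Rank AUC
# ---------------------------------------------------------------------------


def auc_rank(preds: PredictionSet) -> float:
    """Rank-formula AUC with midranks for ties (= Mann–Whitney statistic)."""
    m, n = preds.n_pos, preds.n_neg
    if m == 0 or n == 0:
        raise UndefinedMetricError(
            f"AUC undefined with {m} positives and {n} negatives")
    ranks = rankdata(preds.scores, method="average")
    pos_rank_sum = ranks[preds.labels == 1].sum()
    return float((pos_rank_sum - m * (m + 1) / 2.0) / (m * n))


# ---------------------------------------------------------------------------
# F1-optimal threshold
# ---------------------------------------------------------------------------


def optimize_threshold(preds: PredictionSet) -> ThresholdResult:
    """Exact argmax of F1(τ) over (0, 1) on the given (validation) scores."""
    if preds.n_pos == 0 or preds.n_neg == 0:
        raise UndefinedMetricError("threshold optimisation needs both classes")
    u = np.unique(preds.scores)
    cands = [u]
    if u.size > 1:
        cands.append((u[:-1] + u[1:]) / 2.0)
    cands.append(np.atleast_1d(u[0] / 2.0))             # admit "everything positive"
    cands.append(np.atleast_1d((u[-1] + 1.0) / 2.0))    # admit "everything negative"
    tau_grid = np.unique(np.concatenate(cands))
    tau_grid = tau_grid[(tau_grid > 0.0) & (tau_grid < 1.0)]
    if tau_grid.size == 0:
        tau_grid = np.asarray([0.5])
    # vectorised confusion via sorted scores
    order = np.argsort(preds.scores, kind="mergesort")
    s_sorted = preds.scores[order]
    pos_sorted = (preds.labels[order] == 1).astype(np.int64)
    pos_above = preds.n_pos - np.concatenate([[0], np.cumsum(pos_sorted)])
    all_above = len(s_sorted) - np.arange(len(s_sorted) + 1)
    first_ge = np.searchsorted(s_sorted, tau_grid, side="left")
    tp = pos_above[first_ge]
    fp = all_above[first_ge] - tp
    fn = preds.n_pos - tp
    f1 = np.where(2 * tp + fp + fn > 0, 2 * tp / np.maximum(2 * tp + fp + fn, 1), 0.0)
    best = int(np.argmax(f1))            # first max -> smallest τ (favours recall)
    return ThresholdResult(tau_star=float(tau_grid[best]), f1_at_tau=float(f1[best]),
                           scanned_candidates=tau_grid)


def evaluate_predictions(preds: PredictionSet, tau: float = 0.5) -> MetricsReport:
    tp, fp, fn, tn = confusion_at_threshold(preds, tau)
    try:
        auc = auc_rank(preds)
    except UndefinedMetricError:
        auc = float("nan")
    return MetricsReport(tp=tp, fp=fp, fn=fn, tn=tn,
                         recall=recall_score(tp, fn),
                         precision=precision_score(tp, fp),
                         f1=f1_score(tp, fp, fn),
                         auc=auc, threshold=tau)


# ---------------------------------------------------------------------------
# Score-distribution diagnostics
# ---------------------------------------------------------------------------


@dataclass
class ScoreDistribution:
    bin_edges: np.ndarray       # 101 edges on [0, 1]
    hist_pos: np.ndarray        # normalised to sum 1 (zeros if class empty)
    hist_neg: np.ndarray
    overlap: float              # Σ_bins min(h_pos, h_neg)


def score_distribution(preds: PredictionSet, bins: int = 100) -> ScoreDistribution:
    """Fixed-bin per-class score histograms + overlap coefficient.

    Overlap near 0 is the signature of a decisive decision boundary (the
    bimodal near-0 / near-1 split a well-separated classifier produces);
    overlap 1 means the classes are indistinguishable in score space.
    """
    if preds.scores.size == 0:
        raise ValueError("empty prediction set")
    edges = np.linspace(0.0, 1.0, bins + 1)
    hists = []
    for cls in (1, 0):
        s = preds.scores[preds.labels == cls]
        h, _ = np.histogram(s, bins=edges)
        h = h.astype(np.float64)
        if h.sum() > 0:
            h /= h.sum()
        hists.append(h)
    overlap = float(np.minimum(hists[0], hists[1]).sum())
    return ScoreDistribution(bin_edges=edges, hist_pos=hists[0], hist_neg=hists[1],
                             overlap=overlap)
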