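"""Evaluation protocol: TPR at fixed FPR, success rate, detection accuracy, F1.

Detection performance is measured the way neutrality-test scans are
benchmarked: a detection threshold is set at a percentile of the
per-replicate scores of neutral simulations (the 95th percentile for a
5% false positive rate), and the true positive rate is the fraction of
sweep replicates whose score strictly exceeds it.  Localization quality
is summarized by the success rate (fraction of replicates whose reported
sweep location is within ``e`` bp of the true target, boundary
inclusive; ``e`` defaults to 1% of the region length) and the detection
accuracy (mean distance from the true target as a percentage of the
region length — lower is better).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "threshold_at_fpr",
    "tpr",
    "fpr",
    "success_rate",
    "detection_accuracy",
    "f1",
    "EvalReport",
]


def threshold_at_fpr(neutral_scores, fpr_level: float = 0.05) -> float:
    """Detection threshold from neutral calibration scores.

    Nearest-rank ``(1 - fpr_level)`` percentile of the neutral
    per-replicate scores; a replicate is called positive iff its score is
    strictly greater than the threshold.
    """
    scores = np.asarray(neutral_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no neutral calibration scores")
    if not (0 < fpr_level < 1):
        raise ValueError("fpr_level must be in (0, 1)")
    # unscannable replicates (NaN) rank below every real score
    scores = np.where(np.isnan(scores), -np.inf, scores)
    q = 1.0 - fpr_level
    rank = int(np.ceil(q * scores.size))  # nearest-rank, 1-based
    rank = min(max(rank, 1), scores.size)
    return float(np.sort(scores)[rank - 1])


def tpr(selection_scores, threshold: float) -> float:
    """Fraction of selection replicates scoring strictly above threshold.

    NaN scores (unscannable replicates) count as negatives."""
    scores = np.asarray(selection_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no selection scores")
    return float((scores > threshold).mean())


def fpr(neutral_scores, threshold: float) -> float:
    """Fraction of neutral replicates scoring strictly above threshold."""
    scores = np.asarray(neutral_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no neutral scores")
    return float((scores > threshold).mean())


def success_rate(reported_locs, true_target: float, e_bp: float) -> float:
    """Fraction of replicates localized within ``e_bp`` of the target
    (inclusive boundary).  NaN locations (no call) count as misses."""
    if e_bp <= 0:
        raise ValueError("e_bp must be > 0")
    locs = np.asarray(reported_locs, dtype=float)
    if locs.size == 0:
        raise ValueError("no reported locations")
    return float((np.abs(locs - true_target) <= e_bp).mean())


def detection_accuracy(reported_locs, true_target: float, region_len: float) -> float:
    """Mean |reported - true| distance as a percentage of region length."""
    if region_len <= 0:
        raise ValueError("region_len must be > 0")
    locs = np.asarray(reported_locs, dtype=float)
    if locs.size == 0:
        raise ValueError("no reported locations")
    # replicates without a location call (NaN) are excluded from the mean
    return float(np.nanmean(np.abs(locs - true_target)) / region_len * 100.0)


def f1(true_labels, predicted_labels, positive=1) -> float:
    """F1 score 2PR/(P+R); 0 when precision + recall is 0."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    tp = int(np.sum((t == positive) & (p == positive)))
    fp_ = int(np.sum((t != positive) & (p == positive)))
    fn = int(np.sum((t == positive) & (p != positive)))
    denom = 2 * tp + fp_ + fn
    return 0.0 if denom == 0 else 2 * tp / denom


@dataclass
class EvalReport:
    """Summary of one evaluation run."""

    n_neutral: int
    n_selection: int
    fpr_level: float
    threshold: float
    tpr: float
    e_bp: float
    success_rate: float
    detection_accuracy_pct: float
    f1: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_neutral": self.n_neutral,
            "n_selection": self.n_selection,
            "fpr_level": self.fpr_level,
            "threshold": self.threshold,
            "tpr": self.tpr,
            "e_bp": self.e_bp,
            "success_rate": self.success_rate,
            "detection_accuracy_pct": self.detection_accuracy_pct,
            "f1": self.f1,
        }


def evaluate_scores(
    neutral_scores,
    selection_scores,
    reported_locs,
    true_target: float,
    region_len: float,
    fpr_level: float = 0.05,
    e_fraction: float = 0.01,
) -> EvalReport:
    """Assemble the standard report from per-replicate scores and
    reported sweep locations (``e = e_fraction * region_len``)."""
    thr = threshold_at_fpr(neutral_scores, fpr_level)
    e_bp = e_fraction * region_len
    return EvalReport(
        n_neutral=len(np.asarray(neutral_scores)),
        n_selection=len(np.asarray(selection_scores)),
        fpr_level=fpr_level,
        threshold=thr,
        tpr=tpr(selection_scores, thr),
        e_bp=e_bp,
        success_rate=success_rate(reported_locs, true_target, e_bp),
        detection_accuracy_pct=detection_accuracy(
            reported_locs, true_target, region_len
        ),
    )
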