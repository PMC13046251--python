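"""Evaluation protocol: stratified episode-level splits, alarm
aggregation, detection/prediction metrics, bootstrap confidence
intervals and Cohen's kappa.

Alarm policy: an alarm fires at the k-th consecutive supra-threshold
window (default k = 2) and further alarms are suppressed for a
refractory period (default 30 minutes, uncompressed).  False positives
are alarms falling outside every pre-ictal and ictal interval;
``fp_per_hour`` divides them by the non-pre-ictal, non-ictal recording
hours.  Horizon sensitivity counts a seizure as predicted at horizon H
when any alarm falls within ``[onset - H, onset)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "AlarmPolicy",
    "EvalReport",
    "split_episodes",
    "alarms_from_windows",
    "prediction_metrics",
    "classification_metrics",
    "bootstrap_ci",
    "cohens_kappa",
]

logger = logging.getLogger(__name__)

HORIZONS_MIN = (30.0, 60.0, 90.0)


@dataclass
class AlarmPolicy:
    """Window-to-alarm aggregation."""

    consecutive_windows: int = 2
    refractory_minutes: float = 30.0
    probability_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.consecutive_windows < 1:
            raise ValueError("consecutive_windows must be >= 1")
        if self.refractory_minutes < 0:
            raise ValueError("refractory must be >= 0")


@dataclass
class EvalReport:
    """Metric container; fractions in [0, 1], times in minutes."""

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    f1: float | None = None
    auc_roc: float | None = None
    auc_pr: float | None = None
    fp_per_hour: float | None = None
    horizon_sensitivity: dict[float, float] = field(default_factory=dict)
    time_mae: float | None = None
    kappa: float | None = None
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    confusion: dict[str, int] = field(default_factory=dict)


def split_episodes(
    episodes: list,
    n_folds: int = 4,
    seizure_counts: list[int] | None = None,
    seed: int = 0,
) -> list[int]:
    """Stratified episode-level cross-validation assignment.

    Returns one fold id per episode.  Folds are disjoint by construction;
    a greedy longest-processing-time assignment on seizure counts keeps
    per-fold seizure totals balanced (max - min <= 1 whenever sizes
    allow).  Fold sizes differ by at most one.
    """
    n = len(episodes)
    if n < n_folds:
        raise ValueError(f"cannot split {n} episodes into {n_folds} folds")
    counts = np.asarray(
        seizure_counts if seizure_counts is not None else [1] * n, dtype=float
    )
    rng = np.random.default_rng(seed)
    # shuffle for tie-breaking determinism, then sort by count descending
    order = rng.permutation(n)
    order = order[np.argsort(-counts[order], kind="stable")]
    max_size = int(np.ceil(n / n_folds))
    fold_totals = np.zeros(n_folds)
    fold_sizes = np.zeros(n_folds, dtype=int)
    assignment = np.empty(n, dtype=int)
    for idx in order:
        open_folds = np.where(fold_sizes < max_size)[0]
        # among open folds prefer the lightest seizure total, then smallest
        best = open_folds[np.lexsort((fold_sizes[open_folds], fold_totals[open_folds]))][0]
        assignment[idx] = best
        fold_totals[best] += counts[idx]
        fold_sizes[best] += 1
    # deterministic pairwise-swap refinement: LPT alone can miss the <= 1
    # spread even when it is achievable
    for _ in range(200):
        spread = fold_totals.max() - fold_totals.min()
        if spread <= 1:
            break
        best_gain, best_pair = 0.0, None
        for i in range(n):
            for j in range(i + 1, n):
                fi, fj = assignment[i], assignment[j]
                if fi == fj:
                    continue
                delta = counts[i] - counts[j]
                trial = fold_totals.copy()
                trial[fi] -= delta
                trial[fj] += delta
                gain = spread - (trial.max() - trial.min())
                if gain > best_gain:
                    best_gain, best_pair = gain, (i, j)
        if best_pair is None:
            break
        i, j = best_pair
        fi, fj = assignment[i], assignment[j]
        delta = counts[i] - counts[j]
        fold_totals[fi] -= delta
        fold_totals[fj] += delta
        assignment[i], assignment[j] = fj, fi
    return assignment.tolist()


def alarms_from_windows(
    probabilities: np.ndarray,
    window_times: np.ndarray,
    policy: AlarmPolicy | None = None,
) -> list[float]:
    """Alarm times from a time-ordered per-window probability sequence.

    ``window_times`` are the (uncompressed) minute timestamps of the
    windows.  The alarm fires at the k-th consecutive supra-threshold
    window; the refractory period then suppresses subsequent alarms.
    """
    policy = policy or AlarmPolicy()
    p = np.asarray(probabilities, dtype=float)
    t = np.asarray(window_times, dtype=float)
    if p.shape != t.shape:
        raise ValueError("probabilities and window_times must align")
    alarms: list[float] = []
    run = 0
    blocked_until = -np.inf
    for prob, time in zip(p, t):
        if prob > policy.probability_threshold:
            run += 1
        else:
            run = 0
        if run >= policy.consecutive_windows and time >= blocked_until:
            alarms.append(float(time))
            blocked_until = time + policy.refractory_minutes
            run = 0
    return alarms


@dataclass
class EpisodeTimeline:
    """Episode timing (uncompressed minutes) for prediction metrics."""

    duration: float
    onset: float | None  # seizure onset; None for seizure-free recordings
    ictal_end: float | None = None


def prediction_metrics(
    alarms_per_episode: list[list[float]],
    episodes: list[EpisodeTimeline],
    horizons: tuple[float, ...] = HORIZONS_MIN,
) -> EvalReport:
    """Horizon sensitivity and false positives per hour.

    A seizure is predicted at horizon H when any alarm lies in
    ``[onset - H, onset)``.  Alarms during the ictal interval are neither
    true nor false positives; other alarms outside the 90-minute
    pre-ictal window count as false positives.  Eligible time excludes
    pre-ictal and ictal intervals.
    """
    if len(alarms_per_episode) != len(episodes):
        raise ValueError("one alarm list per episode required")
    horizon_hits = {h: 0 for h in horizons}
    n_seizures = 0
    fp = 0
    eligible_minutes = 0.0
    max_h = max(horizons)
    for alarms, ep in zip(alarms_per_episode, episodes):
        if ep.onset is not None:
            n_seizures += 1
            ictal_end = ep.ictal_end if ep.ictal_end is not None else ep.onset
            pre_start = max(ep.onset - max_h, 0.0)
            eligible_minutes += pre_start + max(ep.duration - ictal_end, 0.0)
            for h in horizons:
                if any(ep.onset - h <= a < ep.onset for a in alarms):
                    horizon_hits[h] += 1
            for a in alarms:
                in_preictal = pre_start <= a < ep.onset
                in_ictal = ep.onset <= a < ictal_end
                if not in_preictal and not in_ictal:
                    fp += 1
        else:
            eligible_minutes += ep.duration
            fp += len(alarms)
    if eligible_minutes <= 0:
        raise ValueError("no eligible recording time for the FP/hr denominator")
    report = EvalReport()
    report.horizon_sensitivity = {
        h: (horizon_hits[h] / n_seizures if n_seizures else float("nan"))
        for h in horizons
    }
    report.fp_per_hour = fp / (eligible_minutes / 60.0)
    return report


def classification_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
) -> EvalReport:
    """Confusion-matrix metrics plus rank-based AUCs for binary labels.

    ``scores`` may be probabilities (thresholded at ``threshold``) or
    already-binary predictions.  AUCs are reported as None with a log
    note when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0 or scores.shape != labels.shape:
        raise ValueError("scores and labels must be non-empty and aligned")
    pred = (scores > threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    n = labels.size
    report = EvalReport(confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn})
    report.accuracy = (tp + tn) / n
    report.sensitivity = tp / (tp + fn) if tp + fn else None
    report.specificity = tn / (tn + fp) if tn + fp else None
    report.precision = tp / (tp + fp) if tp + fp else None
    if report.precision is not None and report.sensitivity is not None \
            and (report.precision + report.sensitivity) > 0:
        report.f1 = 2 * report.precision * report.sensitivity / (
            report.precision + report.sensitivity)
    if len(np.unique(labels)) < 2:
        logger.info("single-class labels: AUC undefined, reported as None")
    else:
        report.auc_roc = float(roc_auc_score(labels, scores))
        report.auc_pr = float(average_precision_score(labels, scores))
    return report


def bootstrap_ci(
    values: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI over per-unit (per-episode) metric values."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("bootstrap needs at least 2 units")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def cohens_kappa(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Chance-corrected agreement ``(po - pe) / (1 - pe)``.

    Returns NaN (with a log note) when expected agreement is 1, where
    kappa is undefined.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("label sequences must align and have >= 2 items")
    po = float(np.mean(a == b))
    classes = np.union1d(a, b)
    pe = float(sum(np.mean(a == c) * np.mean(b == c) for c in classes))
    if pe >= 1.0:
        logger.info("expected agreement is 1; kappa undefined")
        return float("nan")
    return (po - pe) / (1.0 - pe)
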