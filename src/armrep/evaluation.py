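"""Criterion-standard comparison against annotated intervals.

Scoring is sample-wise on the elevation-trace time grid: every sample is
labelled active or resting by the detector and by the annotations, and the
three scores are time ratios over the covered samples.  The active class of
the annotations is propulsion together with non-propulsion activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .arm_core import BoutSet, CycleSet, FourStats, detect_cycles, segment_bouts
from .errors import DataError, ParameterError
from .io_model import AnnotationTrack, ElevationTrace

logger = logging.getLogger(__name__)

ACTIVE_LABELS = ("propulsion", "non_propulsion")


@dataclass
class ValidationScores:
    """Time-ratio agreement between detected and annotated activity.

    accuracy = (true active + true resting) / total covered time;
    sensitivity = true active / annotated active time;
    specificity = true resting / annotated resting time.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    true_active_s: float
    true_resting_s: float
    total_s: float

    def __post_init__(self) -> None:
        for name in ("accuracy", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 1 + 1e-9):
                raise DataError(f"{name} out of [0, 1]: {v}")
        if self.total_s > 0:
            expected = (self.true_active_s + self.true_resting_s) / self.total_s
            if abs(self.accuracy - expected) > 1e-9:
                raise DataError("accuracy inconsistent with true active/resting times")

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "true_active_s": self.true_active_s,
            "true_resting_s": self.true_resting_s,
            "total_s": self.total_s,
        }


@dataclass
class StrokeCountResult:
    """Estimated vs actual cycle count inside selected intervals.

    ``error_fraction`` is (estimated - actual) / actual: negative means
    underestimation, positive overestimation; None when actual is zero.
    """

    estimated: int
    actual: int
    error_fraction: float | None

    def to_dict(self) -> dict:
        return {
            "estimated": self.estimated,
            "actual": self.actual,
            "error_fraction": self.error_fraction,
        }


def classify_samples(bouts: BoutSet, t: np.ndarray) -> np.ndarray:
    """Boolean per-sample activity labels: True = active, False = resting.

    A sample is active when it falls inside any active bout (inclusive
    bounds); resting bouts and edge slack are both resting.
    """
    t = np.asarray(t, dtype=float)
    active = np.zeros(t.shape, dtype=bool)
    for b in bouts.active:
        active |= (t >= b.start_s) & (t <= b.end_s)
    return active


def _truth_labels(truth: AnnotationTrack, t: np.ndarray) -> np.ndarray:
    """Per-sample annotation state: 1 active, 0 resting, -1 uncovered.

    Interval membership is half-open: start_s <= t < end_s.
    """
    t = np.asarray(t, dtype=float)
    lab = np.full(t.shape, -1, dtype=int)
    for start, end, label in truth.intervals:
        mask = (t >= start) & (t < end)
        lab[mask] = 1 if label in ACTIVE_LABELS else 0
    return lab


def score_against_annotations(
    pred_active: np.ndarray, truth: AnnotationTrack, t: np.ndarray
) -> ValidationScores:
    """Sample-wise scores of predicted activity against annotations.

    Samples not covered by any annotation interval are excluded from every
    numerator and denominator (and logged).
    """
    t = np.asarray(t, dtype=float)
    pred_active = np.asarray(pred_active, dtype=bool)
    if pred_active.shape != t.shape:
        raise DataError("pred and t must have the same length")
    lab = _truth_labels(truth, t)
    covered = lab >= 0
    n_uncovered = int((~covered).sum())
    if n_uncovered:
        logger.info("%d samples not covered by annotations; excluded", n_uncovered)
    if not covered.any():
        raise DataError("annotations cover no samples of the time grid")
    dt = float(np.median(np.diff(t))) if t.size >= 2 else 1.0
    truth_active = lab == 1
    tp = int((pred_active & truth_active & covered).sum())
    tn = int((~pred_active & ~truth_active & covered).sum())
    n_active = int((truth_active & covered).sum())
    n_rest = int((~truth_active & covered).sum())
    n_total = int(covered.sum())
    return ValidationScores(
        accuracy=(tp + tn) / n_total,
        sensitivity=tp / n_active if n_active else 0.0,
        specificity=tn / n_rest if n_rest else 0.0,
        true_active_s=tp * dt,
        true_resting_s=tn * dt,
        total_s=n_total * dt,
    )


def count_cycles_in_intervals(
    cycles: CycleSet,
    truth: AnnotationTrack,
    label_filter: tuple[str, ...] = ("propulsion",),
    actual: int | None = None,
) -> StrokeCountResult:
    """Count detected cycles whose peak lies inside selected intervals.

    A cycle belongs to an interval when its peak time is inside
    [start_s, end_s).  When ``actual`` (the criterion count) is given the
    signed error fraction is reported; it is None (undefined) if actual is 0.
    """
    selected = truth.select(label_filter)
    estimated = 0
    for c in cycles.cycles:
        if any(start <= c.peak_s < end for start, end, _ in selected):
            estimated += 1
    if actual is None:
        return StrokeCountResult(estimated=estimated, actual=0, error_fraction=None)
    error = (estimated - actual) / actual if actual > 0 else None
    return StrokeCountResult(estimated=estimated, actual=actual, error_fraction=error)


@dataclass
class SweepRow:
    threshold_deg: float
    n_cycles: int
    n_active_bouts: int
    n_resting_bouts: int
    scores: ValidationScores | None = None

    def to_dict(self) -> dict:
        row = {
            "threshold_deg": self.threshold_deg,
            "n_cycles": self.n_cycles,
            "n_active_bouts": self.n_active_bouts,
            "n_resting_bouts": self.n_resting_bouts,
        }
        if self.scores is not None:
            row.update(
                {
                    "accuracy": self.scores.accuracy,
                    "sensitivity": self.scores.sensitivity,
                    "specificity": self.scores.specificity,
                }
            )
        return row


def threshold_sweep(
    trace: ElevationTrace,
    thresholds=(5.0, 10.0, 15.0, 20.0),
    truth: AnnotationTrack | None = None,
    rest_gap_s: float = 7.0,
    idle_band_deg: float = 2.0,
) -> list[SweepRow]:
    """Cycle/bout statistics (and scores, when truth is given) per threshold."""
    thresholds = [float(x) for x in thresholds]
    if len(set(thresholds)) != len(thresholds) or any(x <= 0 for x in thresholds):
        raise ParameterError("thresholds must be positive and distinct")
    rows = []
    span = (float(trace.t[0]), float(trace.t[-1])) if len(trace) else (0.0, 0.0)
    for thr in thresholds:
        band = min(idle_band_deg, thr / 2)
        cycles = detect_cycles(trace, thr, band)
        bouts = segment_bouts(cycles, rest_gap_s, span)
        scores = None
        if truth is not None and len(truth):
            pred = classify_samples(bouts, trace.t)
            scores = score_against_annotations(pred, truth, trace.t)
        rows.append(
            SweepRow(
                threshold_deg=thr,
                n_cycles=len(cycles),
                n_active_bouts=len(bouts.active),
                n_resting_bouts=len(bouts.resting),
                scores=scores,
            )
        )
    return rows


@dataclass
class IntervalSummary:
    """Per-annotation-label cycle summary (one row of the per-activity table)."""

    label: str
    duration_s: float
    n_cycles: int
    median_elevation: FourStats
    peak_elevation: FourStats

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "duration_s": self.duration_s,
            "n_cycles": self.n_cycles,
            **self.median_elevation.to_dict("median_elevation_deg_per_cycle"),
            **self.peak_elevation.to_dict("peak_elevation_deg_per_cycle"),
        }


def per_interval_metrics(
    cycles: CycleSet, trace: ElevationTrace, truth: AnnotationTrack
) -> list[IntervalSummary]:
    """Per-label duration, cycle count and per-cycle elevation statistics.

    Cycles are assigned to intervals by peak-time membership; labels with no
    cycles report count 0 and null angle statistics.  Returns one row per
    label present in the annotations, in first-appearance order.
    """
    labels: list[str] = []
    for _, _, lab in truth.intervals:
        if lab not in labels:
            labels.append(lab)
    rows = []
    for lab in labels:
        ivs = truth.select([lab])
        selected = [
            c
            for c in cycles.cycles
            if any(start <= c.peak_s < end for start, end, _ in ivs)
        ]
        rows.append(
            IntervalSummary(
                label=lab,
                duration_s=float(sum(end - start for start, end, _ in ivs)),
                n_cycles=len(selected),
                median_elevation=FourStats.of(c.median_elev_deg for c in selected),
                peak_elevation=FourStats.of(c.peak_elev_deg for c in selected),
            )
        )
    return rows
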