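"""Detection of repetitive arm-movement structure in an elevation trace.

The pipeline is: optional zero-phase smoothing, alternating turning-point
extraction, small-range pruning of the extrema series at the movement
threshold, cycle anchoring around each surviving maximum, bout segmentation
with the rest-gap rule, and the summary metric set.

A movement cycle is one arm elevation whose range exceeds the movement
threshold followed by one lowering exceeding the threshold; sub-threshold
motion between the two events is idle time that belongs to the cycle.
Consecutive cycles separated by no-activity intervals of at most
``rest_gap_s`` (default 7 s) share an active bout; a strictly longer
no-activity interval ends the bout and is itself a resting bout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import signal

from .errors import DataError, ParameterError
from .io_model import ElevationTrace


# ---------------------------------------------------------------------------
# domain types


@dataclass
class MovementCycle:
    start_s: float
    peak_s: float
    end_s: float
    rise_deg: float
    fall_deg: float
    peak_elev_deg: float
    median_elev_deg: float

    def __post_init__(self) -> None:
        if not (self.start_s < self.peak_s < self.end_s):
            raise DataError(
                f"cycle ordering violated: start={self.start_s}, "
                f"peak={self.peak_s}, end={self.end_s}"
            )
        if self.peak_elev_deg < self.median_elev_deg - 1e-9:
            raise DataError("peak_elev_deg must be >= median_elev_deg")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class CycleSet:
    cycles: list[MovementCycle]
    threshold_deg: float
    idle_band_deg: float = 2.0

    def __post_init__(self) -> None:
        for a, b in zip(self.cycles, self.cycles[1:]):
            if a.end_s > b.start_s + 1e-9:
                raise DataError(f"cycles overlap: {a.end_s} > {b.start_s}")

    def __len__(self) -> int:
        return len(self.cycles)


@dataclass
class Bout:
    kind: Literal["active", "resting"]
    start_s: float
    end_s: float
    n_cycles: int | None = None
    median_elev_deg: float | None = None
    peak_elev_deg: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("active", "resting"):
            raise DataError(f"unknown bout kind {self.kind!r}")
        if not self.end_s > self.start_s:
            raise DataError("bout must have positive duration")
        if self.kind == "active" and not (self.n_cycles or 0) >= 1:
            raise DataError("active bout must contain at least one cycle")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class BoutSet:
    bouts: list[Bout]
    recording_span_s: float
    lead_slack_s: float = 0.0
    trail_slack_s: float = 0.0

    def __post_init__(self) -> None:
        for a, b in zip(self.bouts, self.bouts[1:]):
            if a.kind == b.kind:
                raise DataError("active and resting bouts must alternate")
            if a.end_s > b.start_s + 1e-9:
                raise DataError("bouts overlap")
        n_active = sum(1 for b in self.bouts if b.kind == "active")
        n_rest = len(self.bouts) - n_active
        if abs(n_rest - n_active) > 1:
            raise DataError("|#resting - #active| must be <= 1")

    @property
    def active(self) -> list[Bout]:
        return [b for b in self.bouts if b.kind == "active"]

    @property
    def resting(self) -> list[Bout]:
        return [b for b in self.bouts if b.kind == "resting"]


@dataclass
class FourStats:
    """mean / sample SD / median / IQR of one per-bout quantity.

    Quartiles use linear interpolation between order statistics (numpy
    default); SD uses ddof=1 and is None for fewer than two values; all four
    are None for an empty sample.
    """

    mean: float | None = None
    sd: float | None = None
    median: float | None = None
    iqr: float | None = None

    @classmethod
    def of(cls, values) -> "FourStats":
        x = np.asarray(list(values), dtype=float)
        if x.size == 0:
            return cls()
        q1, q3 = np.percentile(x, [25, 75])
        return cls(
            mean=float(np.mean(x)),
            sd=float(np.std(x, ddof=1)) if x.size >= 2 else None,
            median=float(np.median(x)),
            iqr=float(q3 - q1),
        )

    def to_dict(self, prefix: str, suffix: str = "") -> dict:
        return {
            f"{prefix}_mean{suffix}": self.mean,
            f"{prefix}_sd{suffix}": self.sd,
            f"{prefix}_median{suffix}": self.median,
            f"{prefix}_iqr{suffix}": self.iqr,
        }

    @classmethod
    def from_dict(cls, d: dict, prefix: str, suffix: str = "") -> "FourStats":
        return cls(
            mean=d[f"{prefix}_mean{suffix}"],
            sd=d[f"{prefix}_sd{suffix}"],
            median=d[f"{prefix}_median{suffix}"],
            iqr=d[f"{prefix}_iqr{suffix}"],
        )


@dataclass
class ActiveBoutFamily:
    """Per-active-bout summary over one bout selection (all, or > long cut)."""

    n_bouts: int = 0
    total_active_s: float = 0.0
    duration: FourStats = field(default_factory=FourStats)
    cycles_per_bout: FourStats = field(default_factory=FourStats)
    median_elevation: FourStats = field(default_factory=FourStats)
    peak_elevation: FourStats = field(default_factory=FourStats)

    @classmethod
    def of(cls, bouts: list[Bout]) -> "ActiveBoutFamily":
        return cls(
            n_bouts=len(bouts),
            total_active_s=float(sum(b.duration_s for b in bouts)),
            duration=FourStats.of(b.duration_s for b in bouts),
            cycles_per_bout=FourStats.of(b.n_cycles for b in bouts),
            median_elevation=FourStats.of(
                b.median_elev_deg for b in bouts if b.median_elev_deg is not None
            ),
            peak_elevation=FourStats.of(
                b.peak_elev_deg for b in bouts if b.peak_elev_deg is not None
            ),
        )

    def to_dict(self) -> dict:
        return {
            "n_bouts": self.n_bouts,
            "total_active_s": self.total_active_s,
            **self.duration.to_dict("active_duration", "_s"),
            **self.cycles_per_bout.to_dict("cycles_per_bout"),
            **self.median_elevation.to_dict("median_elevation_deg"),
            **self.peak_elevation.to_dict("peak_elevation_deg"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ActiveBoutFamily":
        return cls(
            n_bouts=d["n_bouts"],
            total_active_s=d["total_active_s"],
            duration=FourStats.from_dict(d, "active_duration", "_s"),
            cycles_per_bout=FourStats.from_dict(d, "cycles_per_bout"),
            median_elevation=FourStats.from_dict(d, "median_elevation_deg"),
            peak_elevation=FourStats.from_dict(d, "peak_elevation_deg"),
        )


@dataclass
class MetricsReport:
    n_resting_bouts: int
    total_resting_s: float
    resting_duration: FourStats
    n_active_bouts: int
    total_active_s: float
    all_bouts: ActiveBoutFamily
    bouts_gt_long: ActiveBoutFamily
    long_bout_s: float = 10.0
    recording_span_s: float | None = None

    def __post_init__(self) -> None:
        if self.n_resting_bouts < 0 or self.n_active_bouts < 0:
            raise DataError("bout counts must be non-negative")
        if self.bouts_gt_long.total_active_s > self.all_bouts.total_active_s + 1e-9:
            raise DataError("bouts_gt_long totals must not exceed all_bouts totals")
        if (
            self.recording_span_s is not None
            and self.total_active_s > self.recording_span_s + 1e-9
        ):
            raise DataError("total_active_s exceeds recording span")

    def to_dict(self) -> dict:
        return {
            "n_resting_bouts": self.n_resting_bouts,
            "total_resting_s": self.total_resting_s,
            **self.resting_duration.to_dict("resting_duration", "_s"),
            "n_active_bouts": self.n_active_bouts,
            "total_active_s": self.total_active_s,
            "long_bout_s": self.long_bout_s,
            "recording_span_s": self.recording_span_s,
            "all_bouts": self.all_bouts.to_dict(),
            "bouts_gt_long": self.bouts_gt_long.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        return cls(
            n_resting_bouts=d["n_resting_bouts"],
            total_resting_s=d["total_resting_s"],
            resting_duration=FourStats.from_dict(d, "resting_duration", "_s"),
            n_active_bouts=d["n_active_bouts"],
            total_active_s=d["total_active_s"],
            all_bouts=ActiveBoutFamily.from_dict(d["all_bouts"]),
            bouts_gt_long=ActiveBoutFamily.from_dict(d["bouts_gt_long"]),
            long_bout_s=d.get("long_bout_s", 10.0),
            recording_span_s=d.get("recording_span_s"),
        )


# ---------------------------------------------------------------------------
# operations


def smooth_trace(
    trace: ElevationTrace, cutoff_hz: float = 3.0, order: int = 4
) -> ElevationTrace:
    """Zero-phase Butterworth low-pass; output clamped back to [0, 180]."""
    if len(trace) < 2:
        return ElevationTrace(t=trace.t.copy(), phi=trace.phi.copy())
    fs = trace.fs
    if cutoff_hz >= fs / 2 * (1 - 1e-9):
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist rate {fs / 2} Hz"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    padlen = min(3 * (2 * order + 1), len(trace) - 1)
    phi = signal.sosfiltfilt(sos, trace.phi, padlen=padlen)
    return ElevationTrace(t=trace.t.copy(), phi=np.clip(phi, 0.0, 180.0))


def extract_turning_points(trace: ElevationTrace) -> np.ndarray:
    """Indices of a strictly alternating minima/maxima series.

    Both endpoints are included; plateaus are collapsed to their first
    sample.  A constant trace yields a single index.
    """
    phi = trace.phi
    if phi.size == 0:
        return np.array([], dtype=int)
    if phi.size == 1:
        return np.array([0], dtype=int)
    # collapse runs of equal values, keeping the first index of each run
    keep = np.concatenate(([True], np.diff(phi) != 0))
    idx = np.nonzero(keep)[0]
    vals = phi[idx]
    if idx.size == 1:
        return idx
    s = np.sign(np.diff(vals))  # nonzero by construction
    turn = np.nonzero(s[1:] != s[:-1])[0] + 1
    return np.concatenate(([idx[0]], idx[turn], [idx[-1]]))


def prune_extrema(
    values: np.ndarray, indices: np.ndarray, threshold_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Remove sub-threshold ranges from an alternating extrema series.

    Iteratively deletes the adjacent extremum pair with the smallest
    absolute range while that range is below ``threshold_deg`` (leftmost
    pair on ties).  Interior pairs are deleted together, which merges their
    neighbours; a pair touching a series endpoint drops the endpoint
    extremum singly.  On return every adjacent range is >= threshold_deg
    (or fewer than two extrema remain).
    """
    vals = list(map(float, values))
    idxs = list(map(int, indices))
    while len(vals) >= 2:
        ranges = [abs(vals[i + 1] - vals[i]) for i in range(len(vals) - 1)]
        j = int(np.argmin(ranges))
        if ranges[j] >= threshold_deg:
            break
        if j == 0:
            del vals[0], idxs[0]
        elif j == len(ranges) - 1:
            del vals[-1], idxs[-1]
        else:
            del vals[j : j + 2], idxs[j : j + 2]
    return np.array(vals), np.array(idxs, dtype=int)


def detect_cycles(
    trace: ElevationTrace, threshold_deg: float = 10.0, idle_band_deg: float = 2.0
) -> CycleSet:
    """Detect movement cycles in a (smoothed) elevation trace.

    Each maximum surviving :func:`prune_extrema` with a valley on both sides
    defines one cycle.  The cycle start is the last time before the maximum
    at which the angle is within ``idle_band_deg`` of the preceding valley
    value; the cycle end is the first time after the maximum at which the
    angle is within ``idle_band_deg`` of the following valley value.  The
    elevation and lowering ranges are measured from the pruned valley
    values, so both are >= ``threshold_deg`` by construction.
    """
    if not (0 < idle_band_deg < threshold_deg):
        raise ParameterError("idle_band_deg must satisfy 0 < band < threshold")
    cycles: list[MovementCycle] = []
    if len(trace) >= 2:
        tp = extract_turning_points(trace)
        vals, idxs = prune_extrema(trace.phi[tp], tp, threshold_deg)
        phi, t = trace.phi, trace.t
        for k in range(1, len(vals) - 1):
            if not (vals[k] > vals[k - 1] and vals[k] > vals[k + 1]):
                continue  # a valley
            v_prev, v_next = vals[k - 1], vals[k + 1]
            lo, hi = idxs[k - 1], idxs[k + 1]
            peak_region = phi[lo : hi + 1]
            # anchor start: last sample before the peak within the idle band
            # of the preceding valley value
            pre = phi[lo : idxs[k] + 1]
            start_rel = np.nonzero(pre <= v_prev + idle_band_deg)[0]
            i_start = lo + int(start_rel[-1])
            post = phi[idxs[k] : hi + 1]
            end_rel = np.nonzero(post <= v_next + idle_band_deg)[0]
            i_end = idxs[k] + int(end_rel[0])
            span = phi[i_start : i_end + 1]
            i_peak = i_start + int(np.argmax(span))
            peak_val = float(span.max())
            cycles.append(
                MovementCycle(
                    start_s=float(t[i_start]),
                    peak_s=float(t[i_peak]),
                    end_s=float(t[i_end]),
                    rise_deg=peak_val - float(v_prev),
                    fall_deg=peak_val - float(v_next),
                    peak_elev_deg=peak_val,
                    median_elev_deg=float(np.median(span)),
                )
            )
    return CycleSet(cycles=cycles, threshold_deg=threshold_deg, idle_band_deg=idle_band_deg)


def segment_bouts(
    cycles: CycleSet,
    rest_gap_s: float,
    recording_span: tuple[float, float] | float,
    trace: ElevationTrace | None = None,
) -> BoutSet:
    """Partition the recording into alternating active and resting bouts.

    Consecutive cycles whose no-activity gap is <= ``rest_gap_s`` share an
    active bout; a strictly larger gap closes the bout and becomes one
    resting bout spanning the full gap.  Cycle-free time at the recording
    edges becomes a resting bout when longer than ``rest_gap_s`` and edge
    slack otherwise.  When ``trace`` is given, per-bout median and peak
    elevation are computed over each active bout's full span.
    """
    if isinstance(recording_span, tuple):
        t0, t1 = float(recording_span[0]), float(recording_span[1])
    else:
        t0, t1 = 0.0, float(recording_span)
    span = t1 - t0

    groups: list[list[MovementCycle]] = []
    for c in cycles.cycles:
        if groups and c.start_s - groups[-1][-1].end_s <= rest_gap_s:
            groups[-1].append(c)
        else:
            groups.append([c])

    bouts: list[Bout] = []
    lead_slack = trail_slack = 0.0
    prev_end = t0
    for gi, grp in enumerate(groups):
        b_start, b_end = grp[0].start_s, grp[-1].end_s
        gap = b_start - prev_end
        if gap > rest_gap_s:
            bouts.append(Bout(kind="resting", start_s=prev_end, end_s=b_start))
        elif gi == 0:
            lead_slack = gap
        bouts.append(
            Bout(kind="active", start_s=b_start, end_s=b_end, n_cycles=len(grp))
        )
        prev_end = b_end
    tail = t1 - prev_end
    if tail > rest_gap_s:
        bouts.append(Bout(kind="resting", start_s=prev_end, end_s=t1))
    else:
        if groups:
            trail_slack = tail
        else:
            lead_slack = span
    if trace is not None:
        annotate_bout_elevations(bouts, trace)
    return BoutSet(
        bouts=bouts,
        recording_span_s=span,
        lead_slack_s=lead_slack,
        trail_slack_s=trail_slack,
    )


def annotate_bout_elevations(bouts: list[Bout], trace: ElevationTrace) -> None:
    """Fill per-bout median/peak elevation over each active bout's full span."""
    for b in bouts:
        if b.kind != "active":
            continue
        mask = (trace.t >= b.start_s - 1e-9) & (trace.t <= b.end_s + 1e-9)
        seg = trace.phi[mask]
        if seg.size:
            b.median_elev_deg = float(np.median(seg))
            b.peak_elev_deg = float(seg.max())


def compute_metrics(
    bouts: BoutSet,
    trace: ElevationTrace | None = None,
    long_bout_s: float = 10.0,
) -> MetricsReport:
    """Summary metric set over all active bouts and over long active bouts.

    The long-bout family is restricted to active bouts with duration
    strictly greater than ``long_bout_s``.
    """
    if trace is not None:
        annotate_bout_elevations(bouts.bouts, trace)
    active = bouts.active
    resting = bouts.resting
    long_active = [b for b in active if b.duration_s > long_bout_s]
    return MetricsReport(
        n_resting_bouts=len(resting),
        total_resting_s=float(sum(b.duration_s for b in resting)),
        resting_duration=FourStats.of(b.duration_s for b in resting),
        n_active_bouts=len(active),
        total_active_s=float(sum(b.duration_s for b in active)),
        all_bouts=ActiveBoutFamily.of(active),
        bouts_gt_long=ActiveBoutFamily.of(long_active),
        long_bout_s=long_bout_s,
        recording_span_s=bouts.recording_span_s,
    )


def analyze_trace(
    trace: ElevationTrace,
    threshold_deg: float = 10.0,
    rest_gap_s: float = 7.0,
    long_bout_s: float = 10.0,
    idle_band_deg: float = 2.0,
    smooth: bool = False,
    cutoff_hz: float = 3.0,
    order: int = 4,
) -> tuple[ElevationTrace, CycleSet, BoutSet, MetricsReport]:
    """Full pipeline from an elevation trace to the metric report."""
    work = smooth_trace(trace, cutoff_hz, order) if smooth else trace
    cycles = detect_cycles(work, threshold_deg, idle_band_deg)
    span = (float(work.t[0]), float(work.t[-1])) if len(work) else (0.0, 0.0)
    bouts = segment_bouts(cycles, rest_gap_s, span, trace=work)
    report = compute_metrics(bouts, long_bout_s=long_bout_s)
    return work, cycles, bouts, report
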