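"""Core data types, CSV/JSON readers and writers, and the run configuration.

All files are comma-separated UTF-8 with a mandatory header row and '.' as the
decimal mark.  Units are fixed at the file boundary: seconds, m/s^2, rad/s and
degrees.  All times are recording-relative seconds starting at the first
sample; annotation files share this clock.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ParameterError, VocabularyError

logger = logging.getLogger(__name__)

IMU_COLUMNS = (
    "time_s",
    "ax_mps2",
    "ay_mps2",
    "az_mps2",
    "gx_rads",
    "gy_rads",
    "gz_rads",
)
ANNOTATION_COLUMNS = ("start_s", "end_s", "label")
ANNOTATION_LABELS = frozenset({"resting", "propulsion", "non_propulsion"})
ELEVATION_COLUMNS = ("time_s", "elevation_deg")

#: Standard gravity used throughout (m/s^2).
GRAVITY_MPS2 = 9.80665


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise DataError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise DataError(f"{name} contains non-finite values")
    return arr


def _check_time(t: np.ndarray) -> None:
    if t.size >= 2:
        dt = np.diff(t)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise DataError(
                f"time_s not strictly increasing at sample index {int(bad[0]) + 1}"
            )


@dataclass
class ImuRecording:
    """Per-sensor time series of specific force and angular rate.

    ``accel`` is the accelerometer's specific-force reading in the sensor
    frame (m/s^2); at rest it points opposite to gravity with magnitude
    ~9.81.  ``gyro`` is the angular rate in the sensor frame (rad/s).
    """

    sensor_id: str
    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t", 1)
        self.accel = _as_float_array(self.accel, "accel", 2)
        self.gyro = _as_float_array(self.gyro, "gyro", 2)
        if self.accel.shape != (self.t.size, 3):
            raise DataError(
                f"accel shape {self.accel.shape} does not match {self.t.size} samples"
            )
        if self.gyro.shape != (self.t.size, 3):
            raise DataError(
                f"gyro shape {self.gyro.shape} does not match {self.t.size} samples"
            )
        _check_time(self.t)
        if not (self.fs > 0):
            raise DataError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.t.size

    @property
    def span_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0


@dataclass
class ElevationTrace:
    """Uniformly sampled humeral elevation angle.

    ``phi`` is in degrees, 0 = arm hanging (aligned with gravity),
    180 = arm overhead.
    """

    t: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t", 1)
        self.phi = _as_float_array(self.phi, "phi", 1)
        if self.phi.shape != self.t.shape:
            raise DataError("t and phi must have the same length")
        _check_time(self.t)
        if self.phi.size and (self.phi.min() < -1e-9 or self.phi.max() > 180 + 1e-9):
            raise DataError(
                f"phi outside [0, 180]: min={self.phi.min():.3f}, "
                f"max={self.phi.max():.3f}"
            )

    def __len__(self) -> int:
        return self.t.size

    @property
    def fs(self) -> float:
        if len(self) < 2:
            raise DataError("cannot estimate fs from fewer than 2 samples")
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def span_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0


@dataclass
class AnnotationTrack:
    """Video-rated intervals (criterion standard).

    ``intervals`` is a start-sorted list of ``(start_s, end_s, label)`` with
    labels from the closed vocabulary {resting, propulsion, non_propulsion}.
    Membership is half-open: a time t belongs to [start_s, end_s).
    """

    intervals: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        cleaned = []
        for i, (start, end, label) in enumerate(self.intervals):
            start, end = float(start), float(end)
            if label not in ANNOTATION_LABELS:
                raise VocabularyError(
                    f"interval {i + 1}: unknown label {label!r}; "
                    f"expected one of {sorted(ANNOTATION_LABELS)}"
                )
            if not (start < end):
                raise DataError(
                    f"interval {i + 1}: start_s ({start}) must be < end_s ({end})"
                )
            cleaned.append((start, end, label))
        cleaned.sort(key=lambda iv: iv[0])
        for i in range(len(cleaned) - 1):
            if cleaned[i][1] > cleaned[i + 1][0] + 1e-12:
                raise DataError(
                    f"intervals {i + 1} and {i + 2} overlap: "
                    f"{cleaned[i]} vs {cleaned[i + 1]}"
                )
        self.intervals = cleaned

    def __len__(self) -> int:
        return len(self.intervals)

    def select(self, labels: Sequence[str]) -> list[tuple[float, float, str]]:
        wanted = set(labels)
        unknown = wanted - ANNOTATION_LABELS
        if unknown:
            raise VocabularyError(f"unknown label(s): {sorted(unknown)}")
        return [iv for iv in self.intervals if iv[2] in wanted]


@dataclass
class AnalysisConfig:
    """Run configuration shared by all stages.

    The movement threshold, the 7-s rest gap and the 10-s long-bout cut
    carry the published defaults; the idle band and the low-pass settings
    are implementation parameters.
    """

    movement_threshold_deg: float = 10.0
    rest_gap_s: float = 7.0
    long_bout_s: float = 10.0
    idle_band_deg: float = 2.0
    lowpass_cutoff_hz: float = 3.0
    lowpass_order: int = 4
    fs_hz: float | None = None
    seed: int | None = None
    strict_gaps: bool = True

    def __post_init__(self) -> None:
        if not self.movement_threshold_deg > 0:
            raise ParameterError("movement_threshold_deg must be > 0")
        if not self.rest_gap_s > 0:
            raise ParameterError("rest_gap_s must be > 0")
        if self.long_bout_s < 0:
            raise ParameterError("long_bout_s must be >= 0")
        if not (0 < self.idle_band_deg < self.movement_threshold_deg):
            raise ParameterError(
                "idle_band_deg must satisfy 0 < idle_band_deg < movement_threshold_deg"
            )
        if not self.lowpass_cutoff_hz > 0:
            raise ParameterError("lowpass_cutoff_hz must be > 0")
        if self.lowpass_order < 1:
            raise ParameterError("lowpass_order must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise FormatError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**payload)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **{k: v for k, v in kwargs.items() if v is not None})


# ---------------------------------------------------------------------------
# readers / writers


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    return df


def read_imu_recording(
    path: str | Path,
    fs_hint: float | None = None,
    *,
    sensor_id: str | None = None,
    strict_gaps: bool = True,
) -> ImuRecording:
    """Read an IMU CSV (``time_s,ax_mps2,...,gz_rads``) into an ImuRecording.

    ``fs`` is taken from ``fs_hint`` when given, otherwise estimated as the
    reciprocal of the median sample interval.  Timestamp gaps larger than
    1.5 sample periods raise :class:`DataError` unless ``strict_gaps`` is
    False, in which case they are logged.
    """
    df = _read_csv(path, IMU_COLUMNS)
    t = df["time_s"].to_numpy(dtype=float)
    _check_time(t)
    if fs_hint is not None:
        fs = float(fs_hint)
    elif t.size >= 2:
        fs = 1.0 / float(np.median(np.diff(t)))
    else:
        raise DataError(f"{Path(path).name}: cannot estimate fs from <2 samples")
    if t.size >= 2:
        dt = np.diff(t)
        bad = np.nonzero(np.abs(dt - 1.0 / fs) > 0.5 / fs)[0]
        if bad.size:
            msg = (
                f"{Path(path).name}: timestamp gap at sample {int(bad[0]) + 1} "
                f"(dt={dt[bad[0]]:.6f} s vs nominal {1.0 / fs:.6f} s)"
            )
            if strict_gaps:
                raise DataError(msg)
            logger.warning(msg)
    accel = df[["ax_mps2", "ay_mps2", "az_mps2"]].to_numpy(dtype=float)
    gyro = df[["gx_rads", "gy_rads", "gz_rads"]].to_numpy(dtype=float)
    return ImuRecording(
        sensor_id=sensor_id or Path(path).stem, t=t, accel=accel, gyro=gyro, fs=fs
    )


def write_imu_recording(rec: ImuRecording, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": rec.t,
            "ax_mps2": rec.accel[:, 0],
            "ay_mps2": rec.accel[:, 1],
            "az_mps2": rec.accel[:, 2],
            "gx_rads": rec.gyro[:, 0],
            "gy_rads": rec.gyro[:, 1],
            "gz_rads": rec.gyro[:, 2],
        }
    )
    df.to_csv(path, index=False)


def read_annotations(path: str | Path) -> AnnotationTrack:
    """Read an annotation CSV (``start_s,end_s,label``)."""
    df = _read_csv(path, ANNOTATION_COLUMNS)
    intervals = [
        (float(r.start_s), float(r.end_s), str(r.label))
        for r in df.itertuples(index=False)
    ]
    return AnnotationTrack(intervals=intervals)


def write_annotations(track: AnnotationTrack, path: str | Path) -> None:
    pd.DataFrame(track.intervals, columns=list(ANNOTATION_COLUMNS)).to_csv(
        path, index=False
    )


def read_elevation(path: str | Path) -> ElevationTrace:
    """Read an elevation CSV (``time_s,elevation_deg``)."""
    df = _read_csv(path, ELEVATION_COLUMNS)
    return ElevationTrace(
        t=df["time_s"].to_numpy(dtype=float),
        phi=df["elevation_deg"].to_numpy(dtype=float),
    )


def write_elevation(trace: ElevationTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.t, "elevation_deg": trace.phi}).to_csv(
        path, index=False
    )


def write_metrics_report(report, path: str | Path) -> None:
    """Serialize a MetricsReport to JSON at full precision."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, allow_nan=False)
        fh.write("\n")


def read_metrics_report(path: str | Path):
    from .arm_core import MetricsReport

    with open(path, encoding="utf-8") as fh:
        return MetricsReport.from_dict(json.load(fh))
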