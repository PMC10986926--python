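"""Sensor orientation from accelerometer + gyroscope and humeral elevation.

No magnetometer is used anywhere: the orientation estimate is drift-free in
inclination only, and every downstream quantity depends solely on the
estimated direction of gravity relative to the segment.  Heading (rotation
about the world vertical) carries no accuracy contract.

Quaternion convention (asserted in tests): scalar-first ``(w, x, y, z)``,
unit-norm, right-handed, mapping sensor-frame vectors into the world frame.
The world frame has +z up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, DataError
from .io_model import ElevationTrace, ImuRecording

logger = logging.getLogger(__name__)

DEFAULT_FUSION_GAIN = 0.02


# ---------------------------------------------------------------------------
# quaternion helpers (scalar-first)


def quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    pw, px, py, pz = p
    qw, qx, qy, qz = q
    return np.array(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ]
    )


def quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    """Exponential map: rotation vector (rad) -> unit quaternion."""
    angle = float(np.linalg.norm(v))
    if angle < 1e-12:
        # second-order small-angle expansion keeps the map smooth near zero
        return np.array([1.0 - angle * angle / 8.0, v[0] / 2, v[1] / 2, v[2] / 2])
    axis = v / angle
    half = angle / 2.0
    s = np.sin(half)
    return np.array([np.cos(half), axis[0] * s, axis[1] * s, axis[2] * s])


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate sensor-frame vector(s) into the world frame.

    ``q`` is a single quaternion (4,) or a stream (n, 4); ``v`` broadcasts
    accordingly.
    """
    q = np.atleast_2d(q)
    v = np.atleast_2d(v)
    w, xyz = q[:, :1], q[:, 1:]
    t = 2.0 * np.cross(xyz, v)
    out = v + w * t + np.cross(xyz, t)
    return out[0] if out.shape[0] == 1 else out


def quat_conj(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def _quat_align(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Shortest rotation taking unit vector ``a`` onto unit vector ``b``."""
    d = float(np.dot(a, b))
    if d > 1.0 - 1e-12:
        return np.array([1.0, 0.0, 0.0, 0.0])
    if d < -1.0 + 1e-12:
        # 180 deg: any axis orthogonal to a
        axis = np.cross(a, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, np.array([0.0, 1.0, 0.0]))
        axis /= np.linalg.norm(axis)
        return np.array([0.0, *axis])
    axis = np.cross(a, b)
    q = np.array([1.0 + d, *axis])
    return q / np.linalg.norm(q)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class OrientationTrace:
    """Sensor-to-world unit quaternion per sample, scalar-first."""

    t: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (self.t.size, 4):
            raise DataError(f"q must have shape (n, 4), got {self.q.shape}")
        norms = np.linalg.norm(self.q, axis=1)
        if self.q.size and np.max(np.abs(norms - 1.0)) > 1e-9:
            raise DataError("quaternions must be unit-norm within 1e-9")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class CalibrationModel:
    """Humeral long axis expressed in the sensor frame.

    The stored direction is the mean specific-force direction during a
    static arm-hang, i.e. the direction that points up (anti-gravity) in the
    calibration posture; elevation is computed so that this posture reads 0
    degrees.
    """

    long_axis_sensor: np.ndarray

    def __post_init__(self) -> None:
        self.long_axis_sensor = np.asarray(self.long_axis_sensor, dtype=float)
        if self.long_axis_sensor.shape != (3,):
            raise DataError("long_axis_sensor must be a 3-vector")
        n = float(np.linalg.norm(self.long_axis_sensor))
        if abs(n - 1.0) > 1e-9:
            raise DataError(f"long_axis_sensor must be unit-norm (|v|={n})")


# ---------------------------------------------------------------------------
# operations


def fuse_orientation(
    rec: ImuRecording, gain: float = DEFAULT_FUSION_GAIN
) -> OrientationTrace:
    """Complementary-filter sensor fusion of gyroscope and accelerometer.

    The gyroscope is integrated sample-to-sample; each accelerometer sample
    pulls the estimated gravity direction toward the measured specific-force
    direction by the fraction ``gain``.  The resulting inclination is
    drift-free; heading is uncorrected and must not be relied upon.

    Zero-norm accelerometer samples are skipped (gyro-only propagation for
    that step); an all-zero recording raises :class:`DataError`.
    """
    n = len(rec)
    if n == 0:
        raise DataError("empty recording")
    acc_norm = np.linalg.norm(rec.accel, axis=1)
    if np.all(acc_norm < 1e-9):
        raise DataError("all accelerometer samples have zero norm")

    q = np.empty((n, 4))
    # initialize from the first usable accel sample: align measured up with +z
    first = int(np.argmax(acc_norm > 1e-9))
    a0 = rec.accel[first] / acc_norm[first]
    q0 = _quat_align(a0, np.array([0.0, 0.0, 1.0]))
    qk = q0 / np.linalg.norm(q0)
    q[0] = qk

    warned = False
    up = np.array([0.0, 0.0, 1.0])
    for k in range(1, n):
        dt = rec.t[k] - rec.t[k - 1]
        qk = quat_multiply(qk, quat_from_rotvec(rec.gyro[k] * dt))
        if acc_norm[k] > 1e-9:
            a_n = rec.accel[k] / acc_norm[k]
            # estimated up in the sensor frame
            v = quat_rotate(quat_conj(qk), up)
            corr = gain * np.cross(a_n, v)
            qk = quat_multiply(qk, quat_from_rotvec(corr))
        elif not warned:
            logger.warning(
                "zero-norm accelerometer sample at index %d: gyro-only propagation", k
            )
            warned = True
        qk = qk / np.linalg.norm(qk)
        q[k] = qk
    return OrientationTrace(t=rec.t.copy(), q=q)


def calibrate_long_axis(
    rec: ImuRecording, window: tuple[float, float]
) -> CalibrationModel:
    """Derive the humeral long axis from a static arm-hang window.

    The window must span at least 1 s and be quasi-static (mean gyro
    magnitude < 0.05 rad/s); the axis is the unit-normalized mean
    specific-force direction over the window.
    """
    start, end = window
    if end - start < 1.0:
        raise CalibrationError(
            f"calibration window must span >= 1 s, got {end - start:.3f} s"
        )
    mask = (rec.t >= start) & (rec.t <= end)
    if mask.sum() < 2:
        raise CalibrationError("calibration window contains fewer than 2 samples")
    gyro_mag = float(np.mean(np.linalg.norm(rec.gyro[mask], axis=1)))
    if gyro_mag >= 0.05:
        raise CalibrationError(
            f"sensor not quasi-static in calibration window: "
            f"mean |gyro| = {gyro_mag:.4f} rad/s (limit 0.05)"
        )
    mean_acc = rec.accel[mask].mean(axis=0)
    norm = float(np.linalg.norm(mean_acc))
    if norm < 1e-9:
        raise CalibrationError("mean specific force in window has zero norm")
    return CalibrationModel(long_axis_sensor=mean_acc / norm)


def compute_elevation(
    orient: OrientationTrace, calib: CalibrationModel
) -> ElevationTrace:
    """Humeral elevation angle: segment long axis vs the vertical, degrees.

    0 deg = arm hanging (long axis aligned with gravity), 180 deg = arm
    overhead.  Depends only on the inclination of the orientation stream,
    so it is invariant under heading rotations.
    """
    u_world = quat_rotate(orient.q, calib.long_axis_sensor)
    u_world = np.atleast_2d(u_world)
    cosphi = np.clip(u_world[:, 2], -1.0, 1.0)
    phi = np.degrees(np.arccos(cosphi))
    return ElevationTrace(t=orient.t.copy(), phi=phi)


def elevation_from_imu(
    rec: ImuRecording,
    calib_window: tuple[float, float],
    gain: float = DEFAULT_FUSION_GAIN,
) -> ElevationTrace:
    """Convenience pipeline: fuse, calibrate, compute elevation."""
    orient = fuse_orientation(rec, gain=gain)
    calib = calibrate_long_axis(rec, calib_window)
    return compute_elevation(orient, calib)
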