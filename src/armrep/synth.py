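"""Synthetic sessions with exact ground truth, and a forward IMU model.

``generate_session`` realizes a programmed session spec as an elevation
trace built from raised-cosine ramps (differentiable, bounded derivative),
together with the exact ground-truth cycles and bouts.  Ground-truth cycle
boundaries are placed where the continuous ramp crosses the idle band above
the valley value — the same anchoring the detector uses — so that detector
output and truth agree to within grid resolution on noiseless data.
Additive angle noise is applied only after the truth is fixed.

``generate_imu_from_elevation`` models the humerus rotating in a fixed
vertical plane: the sensor-to-world orientation is a rotation about the
world x-axis by the elevation angle, the gyroscope reads the angle rate
about sensor x, and the accelerometer reads gravity in the sensor frame.
At zero elevation the sensor frame coincides with the world frame, so the
calibration posture gives long axis = sensor z.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .arm_core import Bout, BoutSet, CycleSet, MovementCycle
from .errors import SpecError
from .io_model import GRAVITY_MPS2, ElevationTrace, ImuRecording


@dataclass
class BoutSpec:
    """One programmed active bout: ``n_cycles`` raised-cosine cycles.

    ``cycle_amplitude_deg`` is either a fixed amplitude or an inclusive
    (low, high) range sampled uniformly per cycle.  ``cycle_duration_s``
    covers rise + fall (half each); ``idle_at_top_s`` inserts a plateau at
    the apex; ``intra_bout_gap_s`` is the flat no-activity time between
    consecutive cycles of the bout.
    """

    n_cycles: int
    cycle_amplitude_deg: float | tuple[float, float]
    cycle_duration_s: float
    idle_at_top_s: float = 0.0
    intra_bout_gap_s: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise SpecError("n_cycles must be >= 1")
        amp = self.cycle_amplitude_deg
        lo, hi = (amp, amp) if np.isscalar(amp) else (amp[0], amp[1])
        if not (0 < lo <= hi):
            raise SpecError("cycle_amplitude_deg must be positive")
        if not self.cycle_duration_s > 0:
            raise SpecError("cycle_duration_s must be > 0")
        if self.idle_at_top_s < 0 or self.intra_bout_gap_s < 0:
            raise SpecError("idle_at_top_s and intra_bout_gap_s must be >= 0")

    def amplitude_bounds(self) -> tuple[float, float]:
        amp = self.cycle_amplitude_deg
        return (amp, amp) if np.isscalar(amp) else (float(amp[0]), float(amp[1]))


@dataclass
class SessionSpec:
    """Programmable session: bouts of cycles separated by rests."""

    fs_hz: float
    bouts: list[BoutSpec] = field(default_factory=list)
    rests: list[float] = field(default_factory=list)
    baseline_deg: float = 0.0
    lead_s: float = 2.0
    trail_s: float = 2.0
    angle_noise_sd_deg: float = 0.0
    seed: int = 0
    rest_gap_s: float = 7.0
    idle_band_deg: float = 2.0

    def __post_init__(self) -> None:
        if not self.fs_hz > 0:
            raise SpecError("fs_hz must be > 0")
        if len(self.rests) != max(len(self.bouts) - 1, 0):
            raise SpecError(
                f"rests must have {max(len(self.bouts) - 1, 0)} entries "
                f"(one per inter-bout interval), got {len(self.rests)}"
            )
        for r in self.rests:
            if not r > self.rest_gap_s:
                raise SpecError(
                    f"rests: every rest must exceed rest_gap_s={self.rest_gap_s}, got {r}"
                )
        if not (0 <= self.baseline_deg <= 180):
            raise SpecError("baseline_deg must be in [0, 180]")
        for b in self.bouts:
            lo, hi = b.amplitude_bounds()
            if self.baseline_deg + hi > 180:
                raise SpecError("baseline_deg + amplitude must not exceed 180")
            if lo <= self.idle_band_deg:
                raise SpecError(
                    "cycle_amplitude_deg must exceed idle_band_deg "
                    f"({self.idle_band_deg})"
                )
        if self.angle_noise_sd_deg < 0:
            raise SpecError("angle_noise_sd_deg must be >= 0")
        if self.lead_s < 0 or self.trail_s < 0:
            raise SpecError("lead_s and trail_s must be >= 0")

    def to_dict(self) -> dict:
        return {
            "fs_hz": self.fs_hz,
            "baseline_deg": self.baseline_deg,
            "lead_s": self.lead_s,
            "trail_s": self.trail_s,
            "angle_noise_sd_deg": self.angle_noise_sd_deg,
            "seed": self.seed,
            "rest_gap_s": self.rest_gap_s,
            "idle_band_deg": self.idle_band_deg,
            "rests": list(self.rests),
            "bouts": [
                {
                    "n_cycles": b.n_cycles,
                    "cycle_amplitude_deg": (
                        b.cycle_amplitude_deg
                        if np.isscalar(b.cycle_amplitude_deg)
                        else list(b.cycle_amplitude_deg)
                    ),
                    "cycle_duration_s": b.cycle_duration_s,
                    "idle_at_top_s": b.idle_at_top_s,
                    "intra_bout_gap_s": b.intra_bout_gap_s,
                }
                for b in self.bouts
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionSpec":
        d = dict(d)
        bouts = []
        for bd in d.pop("bouts", []):
            bd = dict(bd)
            amp = bd["cycle_amplitude_deg"]
            if isinstance(amp, list):
                bd["cycle_amplitude_deg"] = tuple(amp)
            bouts.append(BoutSpec(**bd))
        return cls(bouts=bouts, **d)

    @classmethod
    def from_json(cls, path: str | Path) -> "SessionSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SyntheticSession:
    trace: ElevationTrace
    truth_cycles: CycleSet
    truth_bouts: BoutSet
    spec: SessionSpec
    clean_trace: ElevationTrace | None = None

    def truth_dict(self) -> dict:
        return {
            "n_cycles": len(self.truth_cycles),
            "cycles": [
                {
                    "start_s": c.start_s,
                    "peak_s": c.peak_s,
                    "end_s": c.end_s,
                    "rise_deg": c.rise_deg,
                    "fall_deg": c.fall_deg,
                    "peak_elev_deg": c.peak_elev_deg,
                    "median_elev_deg": c.median_elev_deg,
                }
                for c in self.truth_cycles.cycles
            ],
            "bouts": [
                {
                    "kind": b.kind,
                    "start_s": b.start_s,
                    "end_s": b.end_s,
                    "n_cycles": b.n_cycles,
                }
                for b in self.truth_bouts.bouts
            ],
            "lead_slack_s": self.truth_bouts.lead_slack_s,
            "trail_slack_s": self.truth_bouts.trail_slack_s,
            "recording_span_s": self.truth_bouts.recording_span_s,
        }


def _band_fraction(amplitude: float, band: float) -> float:
    """Fraction of a raised-cosine ramp spent within ``band`` of the valley."""
    return float(np.arccos(1.0 - 2.0 * band / amplitude) / np.pi)


def generate_session(spec: SessionSpec) -> SyntheticSession:
    """Realize a session spec: elevation trace plus exact ground truth.

    All randomness (per-cycle amplitude sampling, angle noise) flows from
    ``spec.seed``; regenerating from the same spec is bit-identical.
    """
    rng = np.random.default_rng(spec.seed)
    fs, b0, band = spec.fs_hz, spec.baseline_deg, spec.idle_band_deg

    # --- lay out segments on the continuous time axis
    ramps = []  # (t_start, duration, amplitude, +1 rise / -1 fall)
    cycle_truth = []  # (start, peak, end, amplitude) per cycle, grouped by bout
    cursor = spec.lead_s
    bout_groups: list[list[int]] = []
    for bi, bout in enumerate(spec.bouts):
        lo, hi = bout.amplitude_bounds()
        group = []
        for ci in range(bout.n_cycles):
            amp = float(rng.uniform(lo, hi)) if hi > lo else lo
            half = bout.cycle_duration_s / 2.0
            frac = _band_fraction(amp, band)
            rise_start = cursor
            peak_t = rise_start + half
            fall_start = peak_t + bout.idle_at_top_s
            fall_end = fall_start + half
            ramps.append((rise_start, half, amp, +1))
            ramps.append((fall_start, half, amp, -1))
            cycle_truth.append(
                (
                    rise_start + frac * half,  # band crossing on the rise
                    peak_t,
                    fall_start + (1.0 - frac) * half,  # band crossing on the fall
                    amp,
                )
            )
            group.append(len(cycle_truth) - 1)
            cursor = fall_end
            if ci < bout.n_cycles - 1:
                cursor += bout.intra_bout_gap_s
        bout_groups.append(group)
        if bi < len(spec.bouts) - 1:
            cursor += spec.rests[bi]
    cursor += spec.trail_s

    # effective no-activity gaps (truth-boundary to truth-boundary) must
    # respect the rest-gap rule the spec programs
    for group in bout_groups:
        for a, b in zip(group, group[1:]):
            gap = cycle_truth[b][0] - cycle_truth[a][2]
            if gap > spec.rest_gap_s:
                raise SpecError(
                    f"intra_bout_gap_s: effective no-activity gap {gap:.3f} s "
                    f"exceeds rest_gap_s={spec.rest_gap_s} (ramp tails included)"
                )

    n = int(round(cursor * fs)) + 1
    t = np.arange(n) / fs
    phi = np.full(n, b0, dtype=float)
    for t_start, dur, amp, direction in ramps:
        mask = (t >= t_start) & (t <= t_start + dur)
        tau = (t[mask] - t_start) / dur
        if direction > 0:
            phi[mask] = b0 + amp / 2.0 * (1.0 - np.cos(np.pi * tau))
        else:
            phi[mask] = b0 + amp / 2.0 * (1.0 + np.cos(np.pi * tau))
    # plateaus at the apex: samples between a rise end and the next fall start
    for (rs, dur, amp, d1), (fs_, _, _, d2) in zip(ramps, ramps[1:]):
        if d1 > 0 and d2 < 0:
            mask = (t > rs + dur) & (t < fs_)
            phi[mask] = b0 + amp

    clean = ElevationTrace(t=t, phi=np.clip(phi, 0.0, 180.0))

    # --- ground-truth cycles (kinematics measured on the clean trace)
    cycles = []
    for start, peak, end, amp in cycle_truth:
        mask = (t >= start - 1e-12) & (t <= end + 1e-12)
        seg = clean.phi[mask]
        cycles.append(
            MovementCycle(
                start_s=start,
                peak_s=peak,
                end_s=end,
                rise_deg=amp,
                fall_deg=amp,
                peak_elev_deg=b0 + amp,
                median_elev_deg=float(np.median(seg)) if seg.size else b0,
            )
        )
    truth_cycles = CycleSet(
        cycles=cycles, threshold_deg=0.0, idle_band_deg=band
    )

    # --- ground-truth bouts from the programmed grouping
    span_end = float(t[-1])
    bouts: list[Bout] = []
    lead_slack = trail_slack = 0.0
    prev_end = 0.0
    for gi, group in enumerate(bout_groups):
        b_start = cycle_truth[group[0]][0]
        b_end = cycle_truth[group[-1]][2]
        gap = b_start - prev_end
        if gap > spec.rest_gap_s:
            bouts.append(Bout(kind="resting", start_s=prev_end, end_s=b_start))
        elif gi == 0:
            lead_slack = gap
        seg_mask = (t >= b_start - 1e-12) & (t <= b_end + 1e-12)
        seg = clean.phi[seg_mask]
        bouts.append(
            Bout(
                kind="active",
                start_s=b_start,
                end_s=b_end,
                n_cycles=len(group),
                median_elev_deg=float(np.median(seg)) if seg.size else None,
                peak_elev_deg=float(seg.max()) if seg.size else None,
            )
        )
        prev_end = b_end
    tail = span_end - prev_end
    if tail > spec.rest_gap_s:
        bouts.append(Bout(kind="resting", start_s=prev_end, end_s=span_end))
    else:
        if bout_groups:
            trail_slack = tail
        else:
            lead_slack = span_end
    truth_bouts = BoutSet(
        bouts=bouts,
        recording_span_s=span_end,
        lead_slack_s=lead_slack,
        trail_slack_s=trail_slack,
    )

    # --- noise applied only after the truth is fixed
    if spec.angle_noise_sd_deg > 0:
        noisy = clean.phi + rng.normal(0.0, spec.angle_noise_sd_deg, n)
        trace = ElevationTrace(t=t, phi=np.clip(noisy, 0.0, 180.0))
    else:
        trace = clean

    return SyntheticSession(
        trace=trace,
        truth_cycles=truth_cycles,
        truth_bouts=truth_bouts,
        spec=spec,
        clean_trace=clean,
    )


def generate_imu_from_elevation(
    trace: ElevationTrace,
    accel_noise_sd_mps2: float = 0.0,
    gyro_noise_sd_rads: float = 0.0,
    seed: int = 0,
) -> ImuRecording:
    """Forward IMU model for a humerus rotating in a fixed vertical plane.

    Orientation is a rotation about the (fixed, horizontal) world x-axis by
    the elevation angle; gyro is the finite-difference angle rate about
    sensor x; accel is gravity expressed in the sensor frame plus noise.
    """
    rng = np.random.default_rng(seed)
    t = trace.t
    phi_rad = np.radians(trace.phi)
    omega = np.gradient(phi_rad, t) if len(trace) >= 2 else np.zeros_like(phi_rad)
    n = len(trace)
    gyro = np.zeros((n, 3))
    gyro[:, 0] = omega
    accel = np.zeros((n, 3))
    accel[:, 1] = GRAVITY_MPS2 * np.sin(phi_rad)
    accel[:, 2] = GRAVITY_MPS2 * np.cos(phi_rad)
    if gyro_noise_sd_rads > 0:
        gyro = gyro + rng.normal(0.0, gyro_noise_sd_rads, (n, 3))
    if accel_noise_sd_mps2 > 0:
        accel = accel + rng.normal(0.0, accel_noise_sd_mps2, (n, 3))
    fs = 1.0 / float(np.median(np.diff(t))) if n >= 2 else 1.0
    return ImuRecording(sensor_id="synth", t=t.copy(), accel=accel, gyro=gyro, fs=fs)


# ---------------------------------------------------------------------------
# documentation presets (cadence/amplitude ballparks for the two contexts)


def propulsion_like(
    n_bouts: int = 3, cycles_per_bout: int = 10, fs_hz: float = 50.0, seed: int = 0
) -> SessionSpec:
    """Wheelchair-propulsion-like preset: ~1 Hz cadence, 15-30 deg amplitude."""
    return SessionSpec(
        fs_hz=fs_hz,
        bouts=[
            BoutSpec(
                n_cycles=cycles_per_bout,
                cycle_amplitude_deg=(15.0, 30.0),
                cycle_duration_s=1.0,
                intra_bout_gap_s=0.2,
            )
            for _ in range(n_bouts)
        ],
        rests=[12.0] * (n_bouts - 1),
        baseline_deg=10.0,
        seed=seed,
    )


def reaching_like(
    n_bouts: int = 2, cycles_per_bout: int = 3, fs_hz: float = 50.0, seed: int = 0
) -> SessionSpec:
    """Reaching-like preset: ~0.2 Hz cadence, 40-90 deg amplitude."""
    return SessionSpec(
        fs_hz=fs_hz,
        bouts=[
            BoutSpec(
                n_cycles=cycles_per_bout,
                cycle_amplitude_deg=(40.0, 90.0),
                cycle_duration_s=5.0,
                idle_at_top_s=0.5,
                intra_bout_gap_s=1.0,
            )
            for _ in range(n_bouts)
        ],
        rests=[15.0] * (n_bouts - 1),
        baseline_deg=5.0,
        seed=seed,
    )
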