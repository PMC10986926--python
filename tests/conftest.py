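from __future__ import annotations

import numpy as np
import pytest

from armrep.arm_core import CycleSet, MovementCycle
from armrep.synth import BoutSpec, SessionSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cycle(start_s: float, end_s: float, peak_elev: float = 30.0) -> MovementCycle:
    """A hand-built valid cycle for bout-segmentation tests."""
    return MovementCycle(
        start_s=start_s,
        peak_s=(start_s + end_s) / 2.0,
        end_s=end_s,
        rise_deg=peak_elev,
        fall_deg=peak_elev,
        peak_elev_deg=peak_elev,
        median_elev_deg=peak_elev / 2.0,
    )


def make_cycle_set(spans, threshold_deg: float = 10.0) -> CycleSet:
    return CycleSet(
        cycles=[make_cycle(s, e) for s, e in spans], threshold_deg=threshold_deg
    )


def random_session_spec(
    rng: np.random.Generator,
    *,
    min_amplitude: float = 20.0,
    max_amplitude: float = 60.0,
    noise_sd: float = 0.0,
    fs_hz: float = 40.0,
) -> SessionSpec:
    """A structurally valid random session with comfortable gap margins."""
    n_bouts = int(rng.integers(1, 4))
    bouts = []
    for _ in range(n_bouts):
        lo = float(rng.uniform(min_amplitude, max_amplitude - 5.0))
        bouts.append(
            BoutSpec(
                n_cycles=int(rng.integers(1, 6)),
                cycle_amplitude_deg=(lo, lo + 5.0),
                cycle_duration_s=float(rng.uniform(0.8, 2.0)),
                idle_at_top_s=float(rng.uniform(0.0, 0.4)),
                intra_bout_gap_s=float(rng.uniform(0.2, 4.0)),
            )
        )
    rests = [float(rng.uniform(8.5, 20.0)) for _ in range(n_bouts - 1)]

    def edge_time() -> float:
        # keep recording edges away from the 7-s slack/resting-bout boundary
        u = float(rng.uniform(0.0, 12.0))
        return u + 3.0 if u > 6.0 else u

    return SessionSpec(
        fs_hz=fs_hz,
        bouts=bouts,
        rests=rests,
        baseline_deg=float(rng.uniform(0.0, 20.0)),
        lead_s=edge_time(),
        trail_s=edge_time(),
        angle_noise_sd_deg=noise_sd,
        seed=int(rng.integers(0, 2**31)),
    )
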