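import numpy as np
import pytest

from _oracles import brute_detect_cycles, brute_turning_points, random_walk_trace
from armrep import arm_core
from armrep.arm_core import (
    Bout,
    BoutSet,
    compute_metrics,
    detect_cycles,
    extract_turning_points,
    segment_bouts,
    smooth_trace,
)
from armrep.errors import DataError, ParameterError
from armrep.io_model import ElevationTrace
from conftest import make_cycle_set, random_session_spec


def triangle_trace(peak=50.0, duration=4.0, fs=50.0, baseline=0.0):
    n = int(duration * fs) + 1
    t = np.arange(n) / fs
    phi = baseline + peak * (1 - np.abs(t - duration / 2) / (duration / 2))
    return ElevationTrace(t=t, phi=np.clip(phi, 0, 180))


class TestSmoothTrace:
    def test_constant_preserved(self):
        t = np.arange(200) / 50.0
        trace = ElevationTrace(t=t, phi=np.full(200, 42.0))
        out = smooth_trace(trace, 3.0, 4)
        np.testing.assert_allclose(out.phi, 42.0, atol=1e-8)

    def test_passband_sinusoid_attenuation_below_1pct(self):
        from scipy import signal

        fs, f0 = 50.0, 0.5
        # frequency-response oracle for the same zero-phase filter
        sos = signal.butter(4, 3.0, btype="low", fs=fs, output="sos")
        w, h = signal.sosfreqz(sos, worN=[f0], fs=fs)
        expected_gain = np.abs(h[0]) ** 2  # applied forward and backward
        assert expected_gain > 0.99

        t = np.arange(3000) / fs
        phi = 60 + 30 * np.sin(2 * np.pi * f0 * t)
        out = smooth_trace(ElevationTrace(t=t, phi=phi), 3.0, 4)
        core = slice(200, -200)  # ignore edge transients
        amp_ratio = (out.phi[core] - 60).std() / (phi[core] - 60).std()
        assert abs(1 - amp_ratio) < 0.01

    def test_noise_rejection_correlation(self, rng):
        fs = 100.0
        t = np.arange(4000) / fs
        clean = 60 + 30 * np.sin(2 * np.pi * 0.5 * t)
        noisy = clean + 5 * np.sin(2 * np.pi * 20 * t + rng.uniform(0, np.pi))
        out = smooth_trace(ElevationTrace(t=t, phi=np.clip(noisy, 0, 180)), 3.0, 4)
        r = np.corrcoef(out.phi, clean)[0, 1]
        assert r > 0.999

    def test_cutoff_at_nyquist_rejected(self):
        t = np.arange(100) / 10.0
        trace = ElevationTrace(t=t, phi=np.full(100, 10.0))
        with pytest.raises(ParameterError):
            smooth_trace(trace, 5.0, 4)

    def test_output_clamped(self):
        t = np.arange(500) / 50.0
        phi = np.zeros(500)
        phi[240:260] = 180.0
        out = smooth_trace(ElevationTrace(t=t, phi=phi), 10.0, 4)
        assert out.phi.min() >= 0.0 and out.phi.max() <= 180.0


class TestTurningPoints:
    def test_monotone_ramp_two_extrema(self):
        t = np.arange(51) / 50.0
        trace = ElevationTrace(t=t, phi=np.linspace(0, 50, 51))
        idx = extract_turning_points(trace)
        assert list(idx) == [0, 50]

    def test_triangle_three_extrema(self):
        trace = triangle_trace()
        idx = extract_turning_points(trace)
        assert len(idx) == 3
        assert idx[0] == 0 and idx[-1] == len(trace) - 1

    def test_constant_single_point(self):
        trace = ElevationTrace(t=np.arange(10.0), phi=np.full(10, 5.0))
        assert list(extract_turning_points(trace)) == [0]

    def test_plateau_collapsed_to_first_sample(self):
        phi = np.array([0.0, 10.0, 10.0, 10.0, 4.0, 4.0, 8.0])
        trace = ElevationTrace(t=np.arange(7.0), phi=phi)
        assert list(extract_turning_points(trace)) == [0, 1, 4, 6]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(777)
        for _ in range(1000):
            t, phi = random_walk_trace(rng, n=200)
            trace = ElevationTrace(t=t, phi=phi)
            assert list(extract_turning_points(trace)) == brute_turning_points(phi)

    def test_alternation_property(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            t, phi = random_walk_trace(rng)
            idx = extract_turning_points(ElevationTrace(t=t, phi=phi))
            vals = phi[idx]
            d = np.diff(vals)
            assert np.all(d != 0)
            assert np.all(np.sign(d[1:]) != np.sign(d[:-1]))


def five_raises_trace():
    """Five 30-deg raises with three 5-deg wiggles interleaved (fs 20 Hz)."""
    fs = 20.0
    segments = []
    for i in range(5):
        segments += [(30.0, 1.0), (-30.0, 1.0)]
        if i < 3:
            segments += [(5.0, 0.5), (-5.0, 0.5)]
        segments += [(0.0, 1.0)]
    phi_pieces = [np.full(int(1.0 * fs), 2.0)]
    level = 2.0
    for delta, dur in segments:
        n = int(dur * fs)
        phi_pieces.append(np.linspace(level, level + delta, n + 1)[1:])
        level += delta
    phi = np.concatenate(phi_pieces)
    t = np.arange(phi.size) / fs
    return ElevationTrace(t=t, phi=phi)


class TestDetectCycles:
    def test_constant_trace_no_cycles(self):
        trace = ElevationTrace(t=np.arange(100) / 10.0, phi=np.full(100, 20.0))
        assert len(detect_cycles(trace, 10.0, 2.0)) == 0

    def test_empty_trace_no_cycles(self):
        trace = ElevationTrace(t=np.array([]), phi=np.array([]))
        assert len(detect_cycles(trace, 10.0, 2.0)) == 0

    def test_single_triangle_one_cycle(self):
        trace = triangle_trace(peak=50.0, duration=4.0)
        cs = detect_cycles(trace, 10.0, 2.0)
        assert len(cs) == 1
        c = cs.cycles[0]
        assert c.rise_deg == pytest.approx(50.0, abs=1e-9)
        assert c.fall_deg == pytest.approx(50.0, abs=1e-9)
        assert c.peak_elev_deg == pytest.approx(50.0, abs=1e-9)

    def test_five_raises_three_wiggles_yields_five_cycles(self):
        trace = five_raises_trace()
        assert len(detect_cycles(trace, 10.0, 2.0)) == 5

    def test_threshold_monotone_cycle_counts(self):
        trace = five_raises_trace()
        counts = [len(detect_cycles(trace, thr, 2.0)) for thr in (5, 10, 15, 20)]
        assert counts == sorted(counts, reverse=True)

    def test_sub_threshold_band_rejected(self):
        trace = triangle_trace()
        with pytest.raises(ParameterError):
            detect_cycles(trace, 10.0, 10.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2024)
        fails = 0
        for _ in range(300):
            t, phi = random_walk_trace(rng)
            trace = ElevationTrace(t=t, phi=phi)
            cs = detect_cycles(trace, 10.0, 2.0)
            expected = brute_detect_cycles(t, phi, 10.0, 2.0)
            got = [
                (
                    int(np.searchsorted(t, c.start_s)),
                    int(np.searchsorted(t, c.peak_s)),
                    int(np.searchsorted(t, c.end_s)),
                )
                for c in cs.cycles
            ]
            assert got == expected
        assert fails == 0

    def test_rise_fall_at_least_threshold(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            t, phi = random_walk_trace(rng)
            for thr in (5.0, 10.0, 20.0):
                cs = detect_cycles(ElevationTrace(t=t, phi=phi), thr, min(2.0, thr / 3))
                for c in cs.cycles:
                    assert c.rise_deg >= thr - 1e-9
                    assert c.fall_deg >= thr - 1e-9
                    assert c.start_s < c.peak_s < c.end_s

    def test_trailing_incomplete_elevation_not_a_cycle(self):
        fs = 20.0
        up = np.linspace(0, 50, int(2 * fs))
        down = np.linspace(50, 0, int(2 * fs))
        up2 = np.linspace(0, 40, int(1.5 * fs))  # never lowered again
        phi = np.concatenate([up, down, up2])
        t = np.arange(phi.size) / fs
        cs = detect_cycles(ElevationTrace(t=t, phi=phi), 10.0, 2.0)
        assert len(cs) == 1


class TestSegmentBouts:
    def test_two_cycles_small_gap_one_bout(self):
        cs = make_cycle_set([(1.0, 3.0), (6.0, 8.0)])
        bs = segment_bouts(cs, 7.0, 10.0)
        assert [b.kind for b in bs.bouts] == ["active"]
        assert bs.bouts[0].n_cycles == 2
        assert bs.lead_slack_s == pytest.approx(1.0)
        assert bs.trail_slack_s == pytest.approx(2.0)

    def test_two_cycles_gap_8s_two_bouts_one_rest(self):
        cs = make_cycle_set([(0.0, 2.0), (10.0, 12.0)])
        bs = segment_bouts(cs, 7.0, 12.0)
        assert [b.kind for b in bs.bouts] == ["active", "resting", "active"]
        assert bs.bouts[1].duration_s == pytest.approx(8.0)

    def test_gap_exactly_seven_stays_one_bout(self):
        cs = make_cycle_set([(0.0, 2.0), (9.0, 11.0)])
        bs = segment_bouts(cs, 7.0, 11.0)
        assert [b.kind for b in bs.bouts] == ["active"]
        assert bs.bouts[0].n_cycles == 2

    def test_programmed_gaps_2_9_5_12(self):
        spans = []
        cursor = 0.0
        for gap in (None, 2.0, 9.0, 5.0, 12.0):
            if gap is not None:
                cursor += gap
            spans.append((cursor, cursor + 1.0))
            cursor += 1.0
        cs = make_cycle_set(spans)
        bs = segment_bouts(cs, 7.0, cursor)
        kinds = [b.kind for b in bs.bouts]
        assert kinds == ["active", "resting", "active", "resting", "active"]
        assert [b.n_cycles for b in bs.active] == [2, 2, 1]
        assert [b.duration_s for b in bs.resting] == pytest.approx([9.0, 12.0])

    def test_leading_rest_becomes_resting_bout(self):
        cs = make_cycle_set([(20.0, 22.0)])
        bs = segment_bouts(cs, 7.0, 25.0)
        assert [b.kind for b in bs.bouts] == ["resting", "active"]
        assert bs.bouts[0].duration_s == pytest.approx(20.0)
        assert bs.lead_slack_s == 0.0

    def test_empty_cycleset_long_recording_single_rest(self):
        cs = make_cycle_set([])
        bs = segment_bouts(cs, 7.0, 60.0)
        assert [b.kind for b in bs.bouts] == ["resting"]

    def test_empty_cycleset_short_recording_all_slack(self):
        cs = make_cycle_set([])
        bs = segment_bouts(cs, 7.0, 5.0)
        assert bs.bouts == []
        assert bs.lead_slack_s == pytest.approx(5.0)

    def test_conservation_and_count_balance_on_fuzzed_sessions(self):
        from armrep.synth import generate_session

        rng = np.random.default_rng(99)
        for _ in range(50):
            spec = random_session_spec(rng, noise_sd=float(rng.uniform(0, 0.8)))
            sess = generate_session(spec)
            work = (
                arm_core.smooth_trace(sess.trace, 3.0, 4)
                if spec.angle_noise_sd_deg > 0
                else sess.trace
            )
            cs = detect_cycles(work, 10.0, 2.0)
            span = (float(work.t[0]), float(work.t[-1]))
            bs = segment_bouts(cs, 7.0, span)
            total = (
                sum(b.duration_s for b in bs.bouts)
                + bs.lead_slack_s
                + bs.trail_slack_s
            )
            dt = 1.0 / spec.fs_hz
            assert abs(total - bs.recording_span_s) <= dt + 1e-9
            assert abs(len(bs.resting) - len(bs.active)) <= 1


class TestComputeMetrics:
    def test_empty_boutset(self):
        report = compute_metrics(BoutSet(bouts=[], recording_span_s=30.0))
        assert report.n_active_bouts == 0
        assert report.total_active_s == 0.0
        assert report.all_bouts.duration.mean is None

    def test_hand_computed_durations(self):
        bouts = [
            Bout(kind="active", start_s=0.0, end_s=5.0, n_cycles=1),
            Bout(kind="resting", start_s=5.0, end_s=15.0),
            Bout(kind="active", start_s=15.0, end_s=25.0, n_cycles=2),
            Bout(kind="resting", start_s=25.0, end_s=40.0),
            Bout(kind="active", start_s=40.0, end_s=60.0, n_cycles=3),
        ]
        bs = BoutSet(bouts=bouts, recording_span_s=60.0)
        report = compute_metrics(bs, long_bout_s=10.0)
        assert report.total_active_s == pytest.approx(35.0)
        assert report.all_bouts.duration.mean == pytest.approx(35.0 / 3.0)
        # strictly-greater cut: the 10 s bout is excluded
        assert report.bouts_gt_long.n_bouts == 1
        assert report.bouts_gt_long.duration.mean == pytest.approx(20.0)
        assert report.n_resting_bouts == 2
        assert report.total_resting_s == pytest.approx(25.0)

    def test_triangle_bout_median_and_peak(self):
        trace = triangle_trace(peak=50.0, duration=4.0)
        cs = detect_cycles(trace, 10.0, 2.0)
        bs = segment_bouts(cs, 7.0, (float(trace.t[0]), float(trace.t[-1])), trace=trace)
        report = compute_metrics(bs, long_bout_s=10.0)
        bout = bs.active[0]
        mask = (trace.t >= bout.start_s) & (trace.t <= bout.end_s)
        assert bout.peak_elev_deg == pytest.approx(50.0)
        assert bout.median_elev_deg == pytest.approx(float(np.median(trace.phi[mask])))
        assert report.all_bouts.peak_elevation.mean == pytest.approx(50.0)

    def test_gt_long_totals_bounded_by_all(self):
        rng = np.random.default_rng(42)
        from armrep.synth import generate_session

        for _ in range(10):
            sess = generate_session(random_session_spec(rng))
            _, _, _, report = arm_core.analyze_trace(sess.trace)
            assert report.bouts_gt_long.total_active_s <= report.all_bouts.total_active_s + 1e-9
            assert report.bouts_gt_long.n_bouts <= report.all_bouts.n_bouts


class TestTypeInvariants:
    def test_cycle_ordering_enforced(self):
        with pytest.raises(DataError):
            arm_core.MovementCycle(
                start_s=1.0, peak_s=0.5, end_s=2.0,
                rise_deg=20, fall_deg=20, peak_elev_deg=30, median_elev_deg=10,
            )

    def test_boutset_alternation_enforced(self):
        bouts = [
            Bout(kind="active", start_s=0, end_s=5, n_cycles=1),
            Bout(kind="active", start_s=6, end_s=9, n_cycles=1),
        ]
        with pytest.raises(DataError):
            BoutSet(bouts=bouts, recording_span_s=10.0)

    def test_active_bout_needs_cycles(self):
        with pytest.raises(DataError):
            Bout(kind="active", start_s=0, end_s=5, n_cycles=0)
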