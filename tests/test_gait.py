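import numpy as np
import pandas as pd
import pytest

from haltcircuit import (
    BallFit,
    BoutTable,
    GaitTrace,
    SIZDefinition,
    ball_stop_bouts,
    classify_gait,
    define_siz,
    fit_ball,
    flexion_angle,
    grooming_stability,
    siz_metrics,
    swing_durations,
)
from haltcircuit.bouts import bool_runs
from haltcircuit.synthetic import GaitSpec, stance_tips, synth_gait


def sphere_cloud(center, radius, n=200, seed=0):
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return np.asarray(center) + radius * u


def algebraic_sphere_oracle(points):
    """Independent linear least-squares sphere (normal equations)."""
    A = np.hstack([2.0 * points, np.ones((len(points), 1))])
    b = np.sum(points**2, axis=1)
    sol = np.linalg.solve(A.T @ A, A.T @ b)
    c = sol[:3]
    return c, float(np.sqrt(sol[3] + c @ c))


class TestFitBall:
    def test_noiseless_recovery(self):
        pts = sphere_cloud((1.0, 2.0, 3.0), 3.0)
        fit = fit_ball(pts)
        assert np.abs(fit.center - [1, 2, 3]).max() < 1e-6
        assert abs(fit.radius - 3.0) < 1e-6
        assert fit.rms < 1e-6

    def test_agrees_with_algebraic_oracle_noiseless(self):
        pts = sphere_cloud((0.5, -1.0, 2.0), 2.5, seed=3)
        c, r = algebraic_sphere_oracle(pts)
        fit = fit_ball(pts)
        assert np.abs(fit.center - c).max() < 1e-8
        assert abs(fit.radius - r) < 1e-8

    def test_radius_error_small_under_noise(self):
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = sphere_cloud((0, 0, 0), 3.0, n=300, seed=seed)
            pts = pts + rng.normal(0, 0.01, pts.shape)
            errs.append(abs(fit_ball(pts).radius - 3.0))
        assert max(errs) < 0.05

    def test_coplanar_points_rejected(self):
        pts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float
        )
        with pytest.raises(ValueError, match="degenerate"):
            fit_ball(pts)

    def test_deterministic_given_init(self):
        pts = sphere_cloud((0, 0, 0), 3.0, seed=1)
        init = BallFit(center=np.zeros(3), radius=2.0, rms=0.0, iterations=0)
        a, b = fit_ball(pts, init=init), fit_ball(pts, init=init)
        assert np.array_equal(a.center, b.center) and a.radius == b.radius


class TestClassifyGait:
    def test_all_on_surface_single_stance(self):
        ball = BallFit(np.zeros(3), 3.0, 0.0, 0)
        pts = sphere_cloud((0, 0, 0), 3.0, n=100)
        trace = classify_gait(pts, ball, fs=200.0)
        seg = trace.segments
        assert len(seg) == 1 and seg.iloc[0]["label"] == "stance"

    def test_planted_phases_recovered_exactly(self):
        pose, man = synth_gait(GaitSpec(noise_sd_mm=0.0), seed=5)
        ball = fit_ball(stance_tips(pose, man))
        for leg in ("FL", "HR"):
            trace = classify_gait(pose.point(f"{leg}_tarsal_tip"), ball, 200.0)
            got = [
                (int(a), int(b), l)
                for a, b, l in zip(
                    trace.segments.onset,
                    trace.segments.offset,
                    trace.segments.label,
                )
            ]
            assert got == [tuple(s) for s in man["segments"][leg]]

    def test_short_blip_filtered_out(self):
        # 5 ms lift-off blip planted inside a long stance
        fs = 200.0
        ball = BallFit(np.zeros(3), 3.0, 0.0, 0)
        n = 200
        pts = np.tile([0.0, 0.0, 3.0], (n, 1))
        pts[100, 2] = 3.5  # one-frame (5 ms) blip
        trace = classify_gait(pts, ball, fs, min_phase_ms=10.0)
        seg = trace.segments
        assert len(seg) == 1 and seg.iloc[0]["label"] == "stance"
        assert (seg["duration_ms"] >= 10.0).all()

    def test_no_segment_below_min_phase_on_adversarial_noise(self):
        rng = np.random.default_rng(42)
        ball = BallFit(np.zeros(3), 3.0, 0.0, 0)
        for _ in range(20):
            z = 3.0 + rng.choice([0.0, 0.5], size=400, p=[0.6, 0.4])
            pts = np.column_stack([np.zeros(400), np.zeros(400), z])
            trace = classify_gait(pts, ball, 200.0, min_phase_ms=10.0)
            assert (trace.segments["duration_ms"] >= 10.0 - 1e-9).all()

    def test_missing_frame_rate_rejected(self):
        ball = BallFit(np.zeros(3), 3.0, 0.0, 0)
        with pytest.raises(ValueError):
            classify_gait(np.zeros((10, 3)), ball, fs=0.0)


class TestFlexionAngle:
    @pytest.mark.parametrize(
        "prox,joint,dist,expected",
        [
            ((0, 0, 0), (1, 0, 0), (2, 0, 0), 180.0),
            ((0, 0, 0), (1, 0, 0), (1, 1, 0), 90.0),
            ((0, 0, 0), (1, 0, 0), (2, 1, 0), 135.0),
        ],
    )
    def test_hand_computed_angles(self, prox, joint, dist, expected):
        assert flexion_angle(prox, joint, dist) == pytest.approx(expected)

    def test_zero_length_limb_rejected(self):
        with pytest.raises(ValueError):
            flexion_angle((1, 0, 0), (1, 0, 0), (2, 0, 0))

    def test_vectorized_over_frames(self):
        prox = np.zeros((5, 3))
        joint = np.tile([1.0, 0, 0], (5, 1))
        dist = np.tile([1.0, 1.0, 0], (5, 1))
        assert np.allclose(flexion_angle(prox, joint, dist), 90.0)


class TestDefineSiz:
    def test_backward_75th_percentile_oracle(self):
        angles = np.linspace(50, 150, 101)
        siz = define_siz(angles, "backward")
        # sort-based oracle, linear interpolation between closest ranks
        s = np.sort(angles)
        rank = 0.75 * (len(s) - 1)
        lo, hi = int(np.floor(rank)), int(np.ceil(rank))
        expected = s[lo] + (rank - lo) * (s[hi] - s[lo])
        assert siz.threshold == pytest.approx(expected) == pytest.approx(125.0)
        assert siz.side == "above"

    def test_forward_constant_angles(self):
        siz = define_siz([70.0] * 25, "forward")
        assert siz.threshold == 70.0
        assert siz.side == "below"

    def test_interpolation_matches_numpy_for_random_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.uniform(0, 180, size=rng.integers(20, 60))
            assert define_siz(a, "forward").threshold == pytest.approx(
                np.percentile(a, 25)
            )

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            define_siz([100.0] * 5, "backward")


def frame_scan_siz_oracle(angles, in_zone_fn, onsets, i0, i1, fs):
    """Independent per-frame scan of SIZ entries/dwell/swing containment."""
    entries = []
    inside = False
    start = None
    for f in range(i0, i1):
        now = in_zone_fn(angles[f])
        if now and not inside:
            start = f
        if not now and inside:
            entries.append((start, f))
        inside = now
    if inside:
        entries.append((start, i1))
    dwell = [(b - a) / fs for a, b in entries]
    w = sum(1 for a, b in entries if any(a <= o < b for o in onsets))
    return len(entries), dwell, w


class TestSizMetrics:
    def _gait(self, swing, fs=200.0):
        return GaitTrace(swing=np.asarray(swing, bool), fs=fs)

    def test_never_crossing_counts_zero(self):
        angles = np.full(100, 90.0)
        siz = SIZDefinition("backward", 107.0)
        gait = self._gait(np.zeros(100))
        out = siz_metrics(angles, gait, siz, [(0.0, 0.5)])
        row = out.iloc[0]
        assert row["siz_count"] == 0 and row["dwell_times_s"] == []
        assert np.isnan(row["pct_swings_in_siz"]) and row["no_events"]

    def test_two_entries_one_with_swing(self):
        fs = 100.0
        angles = np.full(100, 90.0)
        angles[10:20] = 120.0
        angles[50:70] = 120.0
        swing = np.zeros(100, bool)
        swing[55:60] = True  # onset at frame 55, inside the second entry
        siz = SIZDefinition("backward", 107.0)
        out = siz_metrics(angles, self._gait(swing, fs), siz, [(0.0, 1.0)], fs)
        row = out.iloc[0]
        assert row["siz_count"] == 2
        assert row["pct_swings_in_siz"] == pytest.approx(50.0)
        assert row["dwell_times_s"] == pytest.approx([0.1, 0.2])

    def test_trace_starting_inside_counts_once(self):
        angles = np.full(50, 120.0)
        siz = SIZDefinition("backward", 107.0)
        out = siz_metrics(
            angles, self._gait(np.zeros(50)), siz, [(0.0, 0.25)], 200.0
        )
        assert out.iloc[0]["siz_count"] == 1

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_frame_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        fs = 200.0
        n = 400
        angles = rng.uniform(40, 160, n)
        swing = rng.random(n) < 0.3
        gait = self._gait(swing, fs)
        siz = SIZDefinition(
            rng.choice(["forward", "backward"]), rng.uniform(60, 120)
        )
        windows = [(0.0, 1.0), (1.0, 2.0)]
        out = siz_metrics(angles, gait, siz, windows, fs)
        onsets = gait.swing_onsets()
        for (t0, t1), (_, row) in zip(windows, out.iterrows()):
            count, dwell, w = frame_scan_siz_oracle(
                angles,
                lambda a: a < siz.threshold
                if siz.direction == "forward"
                else a > siz.threshold,
                onsets,
                int(t0 * fs),
                int(t1 * fs),
                fs,
            )
            assert row["siz_count"] == count
            assert row["dwell_times_s"] == pytest.approx(dwell)
            if count:
                assert row["pct_swings_in_siz"] == pytest.approx(
                    100.0 * w / count
                )


class TestBallStopBouts:
    def test_constant_zero_velocity_single_bout(self):
        v = np.zeros(50)  # 1 s at 50 Hz
        bouts = ball_stop_bouts(v, fs=50.0)
        assert len(bouts) == 1
        assert bouts.episodes.iloc[0]["t_end"] == pytest.approx(1.0)

    def test_short_dip_rejected(self):
        v = np.full(100, 5.0)
        v[50:55] = 0.0  # 100 ms dip at 50 Hz
        assert len(ball_stop_bouts(v, fs=50.0)) == 0

    def test_every_bout_meets_minimum_duration(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            v = rng.choice([0.0, 5.0], size=500, p=[0.5, 0.5])
            bouts = ball_stop_bouts(v, fs=50.0)
            assert (bouts.durations >= 0.25 - 1e-9).all()

    def test_planted_bouts_recovered_within_one_sample(self):
        fs = 50.0
        v = np.full(500, 6.0)
        plants = [(100, 150), (300, 320)]
        for a, b in plants:
            v[a:b] = 0.1
        bouts = ball_stop_bouts(v, fs=fs, smooth_ms=1.0)
        got = [
            (round(r.t_start * fs), round(r.t_end * fs))
            for _, r in bouts.episodes.iterrows()
        ]
        assert len(got) == 2
        for (ga, gb), (pa, pb) in zip(got, plants):
            assert abs(ga - pa) <= 1 and abs(gb - pb) <= 1


class TestSwingDurations:
    def _gait_from_segments(self, segs, fs=1000.0):
        n = segs[-1][1]
        swing = np.zeros(n, bool)
        for a, b, lab in segs:
            if lab == "swing":
                swing[a:b] = True
        return GaitTrace(swing=swing, fs=fs)

    def test_median_of_completed_pre_swings(self):
        # swings of 40, 50, 60 ms separated by stance, onset after all three
        segs = [
            (0, 20, "stance"),
            (20, 60, "swing"),
            (60, 80, "stance"),
            (80, 130, "swing"),
            (130, 150, "stance"),
            (150, 210, "swing"),
            (210, 260, "stance"),
        ]
        g = self._gait_from_segments(segs)
        out = swing_durations(g, stim_onset=0.230)
        assert out["pre_median_ms"] == pytest.approx(50.0)

    def test_continuing_swing_full_duration(self):
        segs = [(0, 100, "stance"), (100, 180, "swing"), (180, 220, "stance")]
        g = self._gait_from_segments(segs)
        out = swing_durations(g, stim_onset=0.110)  # 10 ms into an 80 ms swing
        assert out["continuing_swing_ms"] == pytest.approx(80.0)

    def test_onset_mid_stance_undefined(self):
        segs = [(0, 100, "stance"), (100, 150, "swing"), (150, 250, "stance")]
        g = self._gait_from_segments(segs)
        out = swing_durations(g, stim_onset=0.200)
        assert np.isnan(out["continuing_swing_ms"]) and out["onset_in_stance"]

    def test_no_pre_swings_flagged(self):
        segs = [(0, 200, "stance")]
        g = self._gait_from_segments(segs)
        out = swing_durations(g, stim_onset=0.1)
        assert np.isnan(out["pre_median_ms"]) and out["no_pre_swings"]


class TestGroomingStability:
    def _angles(self, feti_by_leg, fs=200.0):
        parts = []
        for leg, arr in feti_by_leg.items():
            parts.append(
                pd.DataFrame(
                    {
                        "frame": np.arange(len(arr)),
                        "leg": leg,
                        "joint": "femur_tibia",
                        "angle_deg": arr,
                    }
                )
            )
        from haltcircuit import JointAngleTrace

        return JointAngleTrace(pd.concat(parts, ignore_index=True), fs=fs)

    def test_constant_angle_zero_sd_and_still_ball(self):
        n = 400
        ang = self._angles({"HL": np.full(n, 90.0), "HR": np.full(n, 90.0)})
        bouts = BoutTable(
            pd.DataFrame(
                {"t_start": [0.5], "t_end": [1.5], "label": ["groom"]}
            )
        )
        rot = np.zeros((100, 3))
        out = grooming_stability(ang, bouts, rot, legs=["HL", "HR"])
        assert out.iloc[0]["feti_sd_deg"] == 0.0
        assert out.iloc[0]["ball_movement"] == 0.0

    def test_sinusoid_sd_closed_form(self):
        fs = 200.0
        t = np.arange(4000) / fs
        A = 12.0
        wave = 90.0 + A * np.sin(2 * np.pi * 5.0 * t)
        ang = self._angles({"HL": wave, "HR": wave}, fs)
        bouts = BoutTable(
            pd.DataFrame(
                {"t_start": [0.0], "t_end": [20.0], "label": ["groom"]}
            )
        )
        rot = np.zeros((1000, 3))
        out = grooming_stability(ang, bouts, rot, legs=["HL", "HR"])
        assert out.iloc[0]["feti_sd_deg"] == pytest.approx(
            A / np.sqrt(2), rel=0.01
        )

    def test_ball_movement_sums_absolute_axis_speeds(self):
        n = 400
        ang = self._angles({"HL": np.full(n, 90.0)})
        bouts = BoutTable(
            pd.DataFrame(
                {"t_start": [0.0], "t_end": [1.0], "label": ["groom"]}
            )
        )
        rot = np.tile([1.0, -2.0, 3.0], (50, 1))
        out = grooming_stability(ang, bouts, rot, legs=["HL"])
        assert out.iloc[0]["ball_movement"] == pytest.approx(6.0)

    def test_too_short_bout_flagged(self):
        ang = self._angles({"HL": np.full(100, 90.0)})
        bouts = BoutTable(
            pd.DataFrame(
                {"t_start": [0.0], "t_end": [0.004], "label": ["groom"]}
            )
        )
        out = grooming_stability(
            ang, bouts, np.zeros((10, 3)), legs=["HL"]
        )
        assert out.iloc[0]["too_short"] and np.isnan(out.iloc[0]["feti_sd_deg"])


class TestBoolRuns:
    def test_runs_identified(self):
        mask = np.array([1, 1, 0, 0, 1, 0, 1, 1, 1], bool)
        assert bool_runs(mask) == [(0, 2), (4, 5), (6, 9)]

    def test_empty_and_all_false(self):
        assert bool_runs(np.array([], bool)) == []
        assert bool_runs(np.zeros(5, bool)) == []
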