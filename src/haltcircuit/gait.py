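"""3D gait kinematics on a spherical treadmill.

Post-processing of triangulated 3D pose of a tethered fly walking on an
air-supported ball: fit the (untracked) ball as a sphere through the tarsal
tip cloud, classify each leg's frames into stance (tip on the ball surface)
versus swing, compute joint flexion angles, define and score the
swing-initiation zone (SIZ) of the femur-tibia joint, detect ball stopping
bouts, and quantify postural stability during grooming.

Conventions: world-frame coordinates in mm, 0-based frame indexing,
half-open segment intervals [onset, offset), pose sampled at 200 Hz and the
ball tracker at 50 Hz by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.optimize import least_squares

from .bouts import BoutTable, bool_runs

__all__ = [
    "LEGS",
    "LEG_JOINTS",
    "BODY_POINTS",
    "Pose3D",
    "BallFit",
    "GaitTrace",
    "JointAngleTrace",
    "SIZDefinition",
    "fit_ball",
    "classify_gait",
    "flexion_angle",
    "joint_angles",
    "define_siz",
    "siz_metrics",
    "ball_stop_bouts",
    "swing_durations",
    "grooming_stability",
]

LEGS = ("FL", "FR", "ML", "MR", "HL", "HR")
LEG_JOINTS = (
    "thorax_coxa",
    "coxa_trochanter",
    "femur_tibia",
    "tibia_tarsus",
    "tarsal_tip",
)
BODY_POINTS = ("notum", "wing_hinge_l", "wing_hinge_r")
#: 33 tracked keypoints: notum, two wing hinges, five joints per leg.
KEYPOINTS = BODY_POINTS + tuple(
    f"{leg}_{joint}" for leg in LEGS for joint in LEG_JOINTS
)


@dataclass
class Pose3D:
    """Wide per-frame 3D keypoint table (columns ``<point>_<axis>``)."""

    data: pd.DataFrame
    fs: float = 200.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("frame rate must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def point(self, name: str) -> np.ndarray:
        """(n_frames, 3) coordinates of one keypoint."""
        cols = [f"{name}_{ax}" for ax in "xyz"]
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise KeyError(f"pose table missing columns {missing}")
        return self.data[cols].to_numpy(dtype=float)

    def tarsal_tips(self, legs: Sequence[str] = LEGS) -> np.ndarray:
        """All tarsal-tip coordinates pooled over legs and frames, (N, 3)."""
        return np.vstack([self.point(f"{leg}_tarsal_tip") for leg in legs])

    @classmethod
    def from_csv(cls, path: str | Path, fs: float = 200.0) -> "Pose3D":
        return cls(pd.read_csv(path), fs=fs)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class BallFit:
    """Fitted sphere: center (mm), radius (mm), rms residual, iterations."""

    center: np.ndarray
    radius: float
    rms: float
    iterations: int

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ValueError("fitted radius must be positive")

    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance to the surface (positive = outside)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return np.linalg.norm(points - self.center, axis=1) - self.radius


@dataclass
class GaitTrace:
    """Per-frame swing/stance classification of one leg plus segments."""

    swing: np.ndarray  # bool per frame, True = swing
    fs: float

    def __post_init__(self) -> None:
        self.swing = np.asarray(self.swing, dtype=bool)
        if self.fs <= 0:
            raise ValueError("frame rate must be positive")

    @property
    def segments(self) -> pd.DataFrame:
        """Tiling segments: onset, offset (half-open frames), label, ms."""
        rows = []
        for a, b in _label_runs(self.swing):
            rows.append(
                (
                    a,
                    b,
                    "swing" if self.swing[a] else "stance",
                    (b - a) / self.fs * 1e3,
                )
            )
        return pd.DataFrame(
            rows, columns=["onset", "offset", "label", "duration_ms"]
        )

    def swing_onsets(self) -> np.ndarray:
        """Frames at which a swing segment begins."""
        seg = self.segments
        return seg.loc[seg["label"] == "swing", "onset"].to_numpy()


@dataclass
class JointAngleTrace:
    """Flexion angles in degrees: long table ``frame, leg, joint, angle_deg``."""

    data: pd.DataFrame
    fs: float = 200.0

    def angle(self, leg: str, joint: str = "femur_tibia") -> np.ndarray:
        df = self.data
        sel = df[(df["leg"] == leg) & (df["joint"] == joint)]
        return sel.sort_values("frame")["angle_deg"].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, fs: float = 200.0) -> "JointAngleTrace":
        return cls(pd.read_csv(path), fs=fs)


@dataclass(frozen=True)
class SIZDefinition:
    """Swing-initiation zone of the femur-tibia angle.

    Forward walking initiates swings from flexed angles, so the zone lies
    below the 25th percentile of swing-onset angles; backward walking from
    extended angles, above the 75th percentile.
    """

    direction: str
    threshold: float

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def side(self) -> str:
        return "below" if self.direction == "forward" else "above"

    def in_zone(self, angles: np.ndarray) -> np.ndarray:
        angles = np.asarray(angles, dtype=float)
        if self.direction == "forward":
            return angles < self.threshold
        return angles > self.threshold


# ---------------------------------------------------------------------------
# sphere fitting


def _algebraic_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Linear least-squares sphere (Coope's method); also the refine init."""
    A = np.hstack([2.0 * points, np.ones((len(points), 1))])
    b = np.sum(points**2, axis=1)
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4 or sv[-1] < 1e-9 * sv[0]:
        raise ValueError(
            "degenerate point cloud: sphere parameters unidentifiable "
            "(points coplanar or too few)"
        )
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("degenerate point cloud: non-positive radius")
    return center, float(np.sqrt(r2))


def fit_ball(
    points: np.ndarray,
    init: BallFit | None = None,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> BallFit:
    """Fit a sphere to tarsal-tip coordinates.

    Iteratively minimizes the squared geometric distance of the points to the
    sphere surface, sum((||p - c|| - r)^2), starting from ``init`` or an
    algebraic least-squares estimate. Deterministic given the init.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be (N, 3)")
    if len(points) < 4:
        raise ValueError("need at least 4 points to fit a sphere")

    if init is None:
        c0, r0 = _algebraic_sphere(points)
    else:
        c0, r0 = init.center, init.radius

    def residual(theta: np.ndarray) -> np.ndarray:
        c, r = theta[:3], theta[3]
        return np.linalg.norm(points - c, axis=1) - r

    res = least_squares(
        residual,
        x0=np.append(c0, r0),
        method="lm",
        max_nfev=max_iter * 5,
        xtol=tol,
        ftol=tol,
        gtol=tol,
    )
    center, radius = res.x[:3], float(res.x[3])
    if radius <= 0:
        raise ValueError("sphere fit collapsed to non-positive radius")
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return BallFit(center=center, radius=radius, rms=rms, iterations=res.nfev)


# ---------------------------------------------------------------------------
# swing / stance


def _label_runs(swing: np.ndarray) -> list[tuple[int, int]]:
    """Half-open runs of constant phase, tiling the trace."""
    n = len(swing)
    if n == 0:
        return []
    changes = list(np.flatnonzero(np.diff(swing.astype(np.int8))) + 1)
    bounds = [0] + changes + [n]
    return list(zip(bounds[:-1], bounds[1:]))


def _filter_short_phases(
    swing: np.ndarray, min_frames: float
) -> np.ndarray:
    """Merge phases shorter than ``min_frames`` into the flanking phase.

    The shortest offending segment is merged first, into the longer flanking
    phase (tie: the preceding one); merging coalesces neighbours, so the
    procedure repeats until every segment is long enough.
    """
    segs = [[a, b] for a, b in _label_runs(swing)]
    labels = [bool(swing[a]) for a, b in segs]
    while len(segs) > 1:
        durations = [b - a for a, b in segs]
        short = [
            i for i, d in enumerate(durations) if d < min_frames
        ]
        if not short:
            break
        i = min(short, key=lambda j: (durations[j], j))
        left = durations[i - 1] if i > 0 else -1
        right = durations[i + 1] if i < len(segs) - 1 else -1
        take_left = left >= right  # tie -> preceding phase
        labels[i] = labels[i - 1] if take_left else labels[i + 1]
        # coalesce equal-label neighbours
        j = i
        while j > 0 and labels[j - 1] == labels[j]:
            segs[j - 1][1] = segs[j][1]
            del segs[j], labels[j]
            j -= 1
        while j < len(segs) - 1 and labels[j + 1] == labels[j]:
            segs[j][1] = segs[j + 1][1]
            del segs[j + 1], labels[j + 1]
    out = np.empty(len(swing), dtype=bool)
    for (a, b), lab in zip(segs, labels):
        out[a:b] = lab
    return out


def classify_gait(
    tips: np.ndarray,
    ball: BallFit,
    fs: float,
    stance_tol_frac: float = 0.0005,
    min_phase_ms: float = 10.0,
) -> GaitTrace:
    """Classify per-frame stance vs swing from tip distance to the ball.

    A tip within ``stance_tol_frac`` of the radius from the surface (default
    0.05%, read literally as a fractional band of 5e-4 x r) is stance; all
    other frames are swing. Phases shorter than ``min_phase_ms`` are merged
    into the flanking phase.
    """
    if fs is None or fs <= 0:
        raise ValueError("frame rate must be positive")
    dist = np.abs(ball.surface_distance(tips))
    swing = dist > stance_tol_frac * ball.radius
    min_frames = min_phase_ms * fs / 1e3
    return GaitTrace(swing=_filter_short_phases(swing, min_frames), fs=fs)


# ---------------------------------------------------------------------------
# joint angles


def flexion_angle(
    p_prox: np.ndarray, p_joint: np.ndarray, p_dist: np.ndarray
) -> np.ndarray | float:
    """Interior angle at ``p_joint`` between the two limb vectors, degrees.

    Accepts single points or (n, 3) per-frame stacks (broadcast).
    """
    a = np.asarray(p_prox, dtype=float) - np.asarray(p_joint, dtype=float)
    b = np.asarray(p_dist, dtype=float) - np.asarray(p_joint, dtype=float)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero-length limb segment: angle undefined")
    cosang = np.clip(np.sum(a * b, axis=-1) / (na * nb), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    return float(ang) if ang.ndim == 0 else ang


#: proximal/distal neighbours defining the flexion angle at each leg joint
_ANGLE_CHAIN = {
    "coxa_trochanter": ("thorax_coxa", "femur_tibia"),
    "femur_tibia": ("coxa_trochanter", "tibia_tarsus"),
    "tibia_tarsus": ("femur_tibia", "tarsal_tip"),
}


def joint_angles(pose: Pose3D, legs: Sequence[str] = LEGS) -> JointAngleTrace:
    """Flexion angles of the interior joints of each leg, per frame."""
    frames = np.arange(pose.n_frames)
    parts = []
    for leg in legs:
        for joint, (prox, dist) in _ANGLE_CHAIN.items():
            ang = flexion_angle(
                pose.point(f"{leg}_{prox}"),
                pose.point(f"{leg}_{joint}"),
                pose.point(f"{leg}_{dist}"),
            )
            parts.append(
                pd.DataFrame(
                    {
                        "frame": frames,
                        "leg": leg,
                        "joint": joint,
                        "angle_deg": ang,
                    }
                )
            )
    return JointAngleTrace(
        pd.concat(parts, ignore_index=True), fs=pose.fs
    )


# ---------------------------------------------------------------------------
# swing-initiation zone


def define_siz(
    swing_onset_angles: Sequence[float],
    direction: str,
    min_samples: int = 20,
) -> SIZDefinition:
    """Swing-initiation-zone threshold from observed swing-onset angles.

    Forward walking: 25th percentile, zone below; backward walking: 75th
    percentile, zone above. Percentiles use linear interpolation between
    closest ranks.
    """
    angles = np.asarray(swing_onset_angles, dtype=float)
    if len(angles) < min_samples:
        raise ValueError(
            f"need at least {min_samples} swing-onset angles, got {len(angles)}"
        )
    if direction == "forward":
        thr = float(np.percentile(angles, 25))
    elif direction == "backward":
        thr = float(np.percentile(angles, 75))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return SIZDefinition(direction=direction, threshold=thr)


def siz_metrics(
    feti_angles: np.ndarray,
    gait: GaitTrace,
    siz: SIZDefinition,
    trial_windows: Sequence[tuple[float, float]],
    fs: float | None = None,
) -> pd.DataFrame:
    """Per-trial SIZ count, dwell times and percentage of swings in SIZ.

    An entry is a threshold crossing into the zone (a trial starting inside
    counts as one entry at its first frame); dwell is the entry-to-exit
    duration; a SIZ event "contains a swing" iff a swing onset falls within
    it. Trials with zero events report count 0 and an undefined percentage
    (NaN, flagged) so they can be excluded from averages.
    """
    fs = fs if fs is not None else gait.fs
    feti_angles = np.asarray(feti_angles, dtype=float)
    in_zone = siz.in_zone(feti_angles)
    onsets = set(gait.swing_onsets().tolist())

    rows = []
    for t0, t1 in trial_windows:
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        i0, i1 = max(i0, 0), min(i1, len(feti_angles))
        runs = [
            (a + i0, b + i0) for a, b in bool_runs(in_zone[i0:i1])
        ]
        dwell = [(b - a) / fs for a, b in runs]
        with_swing = sum(
            1 for a, b in runs if any(a <= f < b for f in onsets)
        )
        n = len(runs)
        rows.append(
            {
                "t_start": t0,
                "t_end": t1,
                "siz_count": n,
                "dwell_times_s": dwell,
                "pct_swings_in_siz": 100.0 * with_swing / n if n else np.nan,
                "no_events": n == 0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stopping, swing durations, grooming stability


def ball_stop_bouts(
    ball_velocity: np.ndarray,
    fs: float = 50.0,
    v_thresh: float = 0.8,
    min_dur_ms: float = 250.0,
    smooth_ms: float | None = None,
) -> BoutTable:
    """Stopping bouts: windowed-average ball speed below ``v_thresh`` mm/s
    sustained for at least ``min_dur_ms``.

    The averaging window defaults to the minimum duration (a 250 ms running
    mean), edge-extended at the trace boundaries.
    """
    v = np.asarray(ball_velocity, dtype=float)
    if smooth_ms is None:
        smooth_ms = min_dur_ms
    w = max(int(round(smooth_ms * fs / 1e3)), 1)
    smoothed = uniform_filter1d(v, size=w, mode="nearest")
    min_frames = min_dur_ms * fs / 1e3
    runs = [
        (a, b) for a, b in bool_runs(smoothed < v_thresh)
        if (b - a) >= min_frames
    ]
    return BoutTable.from_runs(runs, fs, "stop")


def swing_durations(gait: GaitTrace, stim_onset: float) -> dict:
    """Median pre-stimulation swing duration and the continuing swing at onset.

    ``pre_median_ms`` is the median duration of swings completed before the
    optogenetic light onset (NaN if none, flagged); ``continuing_swing_ms``
    is the full duration of the swing in progress at onset, NaN if the onset
    falls in stance.
    """
    onset_frame = stim_onset * gait.fs
    if not (0 <= onset_frame <= len(gait.swing)):
        raise ValueError("stimulation onset outside the trace")
    seg = gait.segments
    swings = seg[seg["label"] == "swing"]
    pre = swings[swings["offset"] <= onset_frame]["duration_ms"]
    cont = swings[
        (swings["onset"] <= onset_frame) & (onset_frame < swings["offset"])
    ]
    return {
        "pre_median_ms": float(pre.median()) if len(pre) else np.nan,
        "no_pre_swings": len(pre) == 0,
        "continuing_swing_ms": (
            float(cont["duration_ms"].iloc[0]) if len(cont) else np.nan
        ),
        "onset_in_stance": len(cont) == 0,
    }


def grooming_stability(
    angles: JointAngleTrace,
    bouts: BoutTable,
    ball_rot: np.ndarray,
    legs: Sequence[str],
    fs_ball: float = 50.0,
) -> pd.DataFrame:
    """Per grooming bout: Fe-Ti angle variability of the stationary legs and
    total ball movement.

    ``feti_sd_deg`` is the standard deviation of the named (non-grooming)
    legs' femur-tibia angles over the bout, averaged across legs; bouts
    shorter than two pose frames are flagged with NaN. Ball movement is the
    sum over the three rotation axes of absolute rotational speed, averaged
    over the bout (a signed sum could cancel).
    """
    ball_rot = np.atleast_2d(np.asarray(ball_rot, dtype=float))
    if ball_rot.shape[1] != 3:
        raise ValueError("ball_rot must be (n, 3) rotational velocities")
    movement = np.sum(np.abs(ball_rot), axis=1)
    feti = {leg: angles.angle(leg, "femur_tibia") for leg in legs}
    n_pose = min(len(a) for a in feti.values())

    rows = []
    for _, ep in bouts.episodes.iterrows():
        a = int(round(ep.t_start * angles.fs))
        b = int(round(ep.t_end * angles.fs))
        if b > n_pose or a < 0:
            raise ValueError(
                f"bout [{ep.t_start}, {ep.t_end}) outside the recording"
            )
        if b - a < 2:
            sd = np.nan
        else:
            sd = float(np.mean([np.std(feti[leg][a:b]) for leg in legs]))
        ia = int(round(ep.t_start * fs_ball))
        ib = max(int(round(ep.t_end * fs_ball)), ia + 1)
        mv = float(np.mean(movement[ia : min(ib, len(movement))]))
        rows.append(
            {
                "t_start": ep.t_start,
                "t_end": ep.t_end,
                "feti_sd_deg": sd,
                "ball_movement": mv,
                "too_short": b - a < 2,
            }
        )
    return pd.DataFrame(rows)
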