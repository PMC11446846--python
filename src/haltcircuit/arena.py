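"""Free-walking behavior from planar arena-tracker tables.

Input is a tracker export: per-frame x/y position (mm), body heading
(degrees), optogenetic stimulation state, and optionally which arena side
the fly occupies (sucrose vs blank in a two-choice assay). From this the
module computes translational and absolute angular velocity, rotation as
the time-integral of absolute angular velocity, pivot and stop bouts,
per-trial distance/rotation over a post-onset window, a two-choice
preference index, and food-zone interaction metrics.

Units: mm, degrees, seconds; 0-based frames; half-open windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .bouts import BoutTable, bool_runs

__all__ = [
    "ArenaTrack",
    "FoodZoneConfig",
    "PreferenceResult",
    "track_kinematics",
    "detect_pivots",
    "detect_stops",
    "trial_metrics",
    "preference_index",
    "food_zone_metrics",
]


@dataclass
class ArenaTrack:
    """Planar trajectory: per-frame x, y, heading, stim state, side label."""

    data: pd.DataFrame  # columns x, y, heading, stim[, side]
    fs: float = 30.0

    def __post_init__(self) -> None:
        for col in ("x", "y", "heading"):
            if col not in self.data.columns:
                raise ValueError(f"track table missing column {col!r}")
        if self.fs <= 0:
            raise ValueError("frame rate must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(dtype=float)

    @property
    def heading(self) -> np.ndarray:
        return self.data["heading"].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path: str | Path, fs: float = 30.0) -> "ArenaTrack":
        return cls(pd.read_csv(path), fs=fs)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class FoodZoneConfig:
    """Geometry of the sucrose-blob interaction assay.

    A fly within ``interaction_radius`` of the blob centre is interacting
    with it; the food zone is the circle of ``zone_diameter`` around the
    blob; metrics are computed within ``post_encounter_window`` seconds of
    the first encounter.
    """

    blob_center: tuple[float, float]
    interaction_radius: float = 3.0
    zone_diameter: float = 6.0
    post_encounter_window: float = 5.0

    def __post_init__(self) -> None:
        if self.interaction_radius <= 0 or self.zone_diameter <= 0:
            raise ValueError("radii must be positive")


@dataclass
class PreferenceResult:
    """Two-choice preference: pi in [-1, 1] plus time on each side (s)."""

    pi: float
    time_sucrose: float
    time_blank: float


def _smooth(x: np.ndarray, window_s: float, fs: float) -> np.ndarray:
    """Centered moving average over ``window_s`` seconds, edge-extended."""
    if window_s is None or window_s <= 0:
        return np.asarray(x, dtype=float)
    w = max(int(round(window_s * fs)), 1)
    return uniform_filter1d(np.asarray(x, dtype=float), size=w, mode="nearest")


def track_kinematics(
    track: ArenaTrack, smooth_window: float = 0.0
) -> pd.DataFrame:
    """Per-frame translational speed, absolute angular speed and rotation.

    Heading is unwrapped before differencing; angular velocity is reported
    as absolute value and rotation is its running time-integral (degrees).
    Velocities are backward differences aligned to the later frame (frame 0
    repeats frame 1 so lengths match).
    """
    if track.n_frames < 2:
        raise ValueError("need at least 2 frames")
    fs = track.fs
    xy = track.xy
    step = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    v_trans = np.concatenate([[step[0]], step]) * fs

    heading = np.unwrap(np.radians(track.heading))
    dh = np.abs(np.degrees(np.diff(heading)))
    v_ang = np.concatenate([[dh[0]], dh]) * fs

    v_trans = _smooth(v_trans, smooth_window, fs)
    v_ang = _smooth(v_ang, smooth_window, fs)
    # rotation integral: no turning accrued before the first difference
    dh_aligned = np.concatenate([[0.0], dh])
    rotation = np.cumsum(_smooth(dh_aligned, 0.0, fs))
    return pd.DataFrame(
        {"v_trans": v_trans, "v_ang": v_ang, "rotation": rotation}
    )


def detect_pivots(
    v_trans: np.ndarray,
    v_ang: np.ndarray,
    fs: float,
    smooth_window: float = 0.5,
    v_ang_thresh: float = 720.0,
    v_trans_thresh: float = 5.0,
) -> BoutTable:
    """On-the-spot turning: smoothed angular speed above two rotations per
    second (720 deg/s) while smoothed translational speed stays below
    5 mm/s."""
    if len(v_trans) != len(v_ang):
        raise ValueError("velocity series must share a clock")
    vt = _smooth(np.asarray(v_trans, float), smooth_window, fs)
    va = _smooth(np.asarray(v_ang, float), smooth_window, fs)
    mask = (va > v_ang_thresh) & (vt < v_trans_thresh)
    return BoutTable.from_runs(bool_runs(mask), fs, "pivot")


def detect_stops(
    v_trans: np.ndarray,
    fs: float,
    variant: str = "food_assay",
    v_thresh: float | None = None,
    min_frames: int | None = None,
    smooth_window: float | None = None,
) -> BoutTable:
    """Stop bouts from smoothed translational velocity.

    ``food_assay``: speed below 2 mm/s sustained for at least ten frames
    (robust to tracker jitter while the fly feeds). ``freewalk``: threshold
    and smoothing are configurable (default 1.5 mm/s; the source convention
    is ambiguous about which constant is the smoothing parameter, so both
    are exposed).
    """
    if variant == "food_assay":
        v_thresh = 2.0 if v_thresh is None else v_thresh
        min_frames = 10 if min_frames is None else min_frames
        smooth_window = 1.0 / fs if smooth_window is None else smooth_window
    elif variant == "freewalk":
        v_thresh = 1.5 if v_thresh is None else v_thresh
        min_frames = 1 if min_frames is None else min_frames
        smooth_window = 0.5 if smooth_window is None else smooth_window
    else:
        raise ValueError(f"unknown stop variant {variant!r}")
    vt = _smooth(np.asarray(v_trans, float), smooth_window, fs)
    runs = [
        (a, b) for a, b in bool_runs(vt < v_thresh) if (b - a) >= min_frames
    ]
    return BoutTable.from_runs(runs, fs, "stop")


def trial_metrics(
    track: ArenaTrack,
    onsets: Sequence[float],
    horizon: float = 2.0,
) -> pd.DataFrame:
    """Path length (mm) and accumulated rotation (deg) per trial window.

    Windows are [onset, onset + horizon); a window extending beyond the
    recording is truncated and flagged.
    """
    fs = track.fs
    xy = track.xy
    heading = np.unwrap(np.radians(track.heading))
    n = track.n_frames
    rows = []
    for onset in onsets:
        i0 = int(round(onset * fs))
        if not (0 <= i0 < n):
            raise ValueError(f"trial onset {onset} s outside the recording")
        i1 = int(round((onset + horizon) * fs))
        # include the window-closing frame so a constant-speed fly covers
        # exactly speed x horizon
        truncated = i1 + 1 > n
        i1 = min(i1 + 1, n)
        seg = xy[i0:i1]
        dist = float(np.sum(np.linalg.norm(np.diff(seg, axis=0), axis=1)))
        rot = float(
            np.sum(np.abs(np.degrees(np.diff(heading[i0:i1]))))
        )
        rows.append(
            {
                "onset": onset,
                "distance_mm": dist,
                "rotation_deg": rot,
                "truncated": truncated,
            }
        )
    return pd.DataFrame(rows)


def preference_index(track: ArenaTrack) -> PreferenceResult:
    """Time-based two-choice preference of sucrose over blank.

    pi = (t_sucrose - t_blank) / (t_sucrose + t_blank) over the assay.
    """
    if "side" not in track.data.columns:
        raise ValueError("track has no 'side' labels")
    side = track.data["side"]
    labeled = side.isin(["sucrose", "blank"])
    if not labeled.any():
        raise ValueError("no frames labeled sucrose or blank")
    dt = 1.0 / track.fs
    t_suc = float((side == "sucrose").sum() * dt)
    t_blk = float((side == "blank").sum() * dt)
    return PreferenceResult(
        pi=(t_suc - t_blk) / (t_suc + t_blk),
        time_sucrose=t_suc,
        time_blank=t_blk,
    )


def food_zone_metrics(
    track: ArenaTrack,
    cfg: FoodZoneConfig,
    encounter_frame: int | None = None,
) -> dict:
    """Stopping and velocities in the food zone after the first encounter.

    ``encounter_frame`` must be the first frame with blob distance at or
    below the interaction radius (validated; inferred when omitted). Metrics
    are restricted to in-zone frames within the post-encounter window; stops
    use the food-assay definition. A fly that never encounters the blob
    yields an empty, flagged result.
    """
    d = np.linalg.norm(track.xy - np.asarray(cfg.blob_center), axis=1)
    interacting = d <= cfg.interaction_radius
    if not interacting.any():
        if encounter_frame is not None:
            raise ValueError(
                "encounter_frame given but the fly never reaches the blob"
            )
        return {
            "encountered": False,
            "encounter_frame": None,
            "stop_bout_durations_s": [],
            "v_trans_in_zone": np.nan,
            "v_ang_in_zone": np.nan,
        }
    first = int(np.flatnonzero(interacting)[0])
    if encounter_frame is None:
        encounter_frame = first
    elif encounter_frame != first:
        raise ValueError(
            f"encounter_frame {encounter_frame} inconsistent with geometry "
            f"(first interaction at frame {first})"
        )

    fs = track.fs
    i1 = min(
        encounter_frame + int(round(cfg.post_encounter_window * fs)),
        track.n_frames,
    )
    kin = track_kinematics(track)
    in_zone = d < cfg.zone_diameter / 2.0
    sel = np.zeros(track.n_frames, dtype=bool)
    sel[encounter_frame:i1] = True
    sel &= in_zone

    stops = detect_stops(
        kin["v_trans"].to_numpy()[encounter_frame:i1], fs, "food_assay"
    )
    return {
        "encountered": True,
        "encounter_frame": encounter_frame,
        "stop_bout_durations_s": stops.durations.tolist(),
        "v_trans_in_zone": float(kin.loc[sel, "v_trans"].mean()),
        "v_ang_in_zone": float(kin.loc[sel, "v_ang"].mean()),
    }
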