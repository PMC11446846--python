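"""Synthetic inputs with planted ground truth for every pipeline stage.

Four generator families emulate the four input classes consumed by the
package: connectome dumps with planted circuit motifs, 3D pose on a
spherical treadmill with known sphere and swing/stance phases, planar arena
trajectories with known stop/pivot/food-zone episodes, and fluorescence
traces with known activity-velocity coupling. Each generator is
deterministic under a fixed seed and returns a JSON-serializable
ground-truth manifest alongside the data, so round-trip tests never parse
prose.

Default scales mimic the regimes of the real assays: 200 Hz pose, 50 Hz
ball tracker, 30 Hz arena video, a few Hz imaging, and 150/50 Hz Poisson
stimulation. The generators target structure, not realism: they do not
reproduce tracker artifacts, occlusions, or photobleaching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gait import LEGS, LEG_JOINTS, Pose3D

__all__ = [
    "Population",
    "ConnectionRule",
    "MotifSpec",
    "GaitSpec",
    "TrackSpec",
    "TraceSpec",
    "synth_connectome",
    "synth_gait",
    "synth_track",
    "synth_traces",
    "walk_off_motif",
    "stance_tips",
]


# ---------------------------------------------------------------------------
# connectome motifs


@dataclass(frozen=True)
class Population:
    """Named neuron group with a shared neurotransmitter and class tag."""

    name: str
    size: int
    nt: str = "ACh"
    class_tag: str = "other"

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("population size must be >= 1")


@dataclass(frozen=True)
class ConnectionRule:
    """All-to-all rule between two groups with Bernoulli edge inclusion.

    ``count_mean`` parametrizes the synapse count as 1 + Poisson(mean - 1),
    guaranteeing counts >= 1.
    """

    source: str
    target: str
    count_mean: float = 10.0
    probability: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("probability must lie in [0, 1]")
        if self.count_mean < 1:
            raise ValueError("count_mean must be >= 1")


@dataclass
class MotifSpec:
    """Populations, connection rules, and named planted pathway patterns."""

    populations: list[Population]
    rules: list[ConnectionRule] = field(default_factory=list)
    motifs: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        known = set(names)
        for r in self.rules:
            if r.source not in known or r.target not in known:
                raise ValueError(
                    f"rule {r.source}->{r.target} references unknown group"
                )


def synth_connectome(
    spec: MotifSpec, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Neuron and edge tables realizing a motif spec, plus the manifest.

    Ids are assigned sequentially by population order. The manifest records
    the id range of every group and the planted motifs verbatim.
    """
    rng = np.random.default_rng(seed)
    rows = []
    ids: dict[str, list[int]] = {}
    next_id = 0
    for pop in spec.populations:
        ids[pop.name] = list(range(next_id, next_id + pop.size))
        for k, nid in enumerate(ids[pop.name]):
            rows.append(
                {
                    "id": nid,
                    "label": f"{pop.name}_{k}",
                    "hemisphere": "left" if k % 2 == 0 else "right",
                    "nt": pop.nt,
                    "class_tag": pop.class_tag,
                }
            )
        next_id += pop.size
    neurons = pd.DataFrame(rows)

    erows = []
    for rule in spec.rules:
        for pre in ids[rule.source]:
            for post in ids[rule.target]:
                if pre == post:
                    continue
                if rng.random() <= rule.probability:
                    count = 1 + rng.poisson(rule.count_mean - 1)
                    erows.append({"pre": pre, "post": post, "count": count})
    edges = pd.DataFrame(erows, columns=["pre", "post", "count"])

    manifest = {
        "seed": seed,
        "populations": {name: nids for name, nids in ids.items()},
        "motifs": list(spec.motifs),
    }
    return neurons, edges, manifest


def walk_off_motif(
    n_walk: int = 1,
    n_halt: int = 1,
    n_dn: int = 1,
    walk_count: float = 12.0,
    halt_count: float = 12.0,
) -> MotifSpec:
    """Canonical walk-OFF motif: excitatory walk group and GABAergic halt
    group both converging on a descending-neuron readout group.

    The manifest predicts that co-stimulating the halt group lowers the DN
    rate relative to walk-only stimulation, and that silencing the halt
    group (the DN's only inhibitory afferent) can only raise the DN rate.
    """
    return MotifSpec(
        populations=[
            Population("walk", n_walk, nt="ACh", class_tag="walk"),
            Population("halt", n_halt, nt="GABA", class_tag="halt"),
            Population("dn", n_dn, nt="ACh", class_tag="DN"),
        ],
        rules=[
            ConnectionRule("walk", "dn", count_mean=walk_count),
            ConnectionRule("halt", "dn", count_mean=halt_count),
        ],
        motifs=[
            {
                "name": "walk-OFF",
                "inhibitor": "halt",
                "readout": "dn",
                "driver": "walk",
                "costim_effect": "decrease",
                "silencing_effect": "nonnegative",
            }
        ],
    )


# ---------------------------------------------------------------------------
# gait on the ball


@dataclass
class GaitSpec:
    """Stepping pattern on a sphere with planted swing/stance phases."""

    ball_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ball_radius: float = 3.0  # 6 mm treadmill
    fs: float = 200.0
    duration_s: float = 3.0
    stance_ms: float = 80.0
    swing_ms: float = 40.0
    phase_offsets_ms: dict[str, float] | None = None
    swing_clearance_mm: float = 0.3
    noise_sd_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.stance_ms < 10 or self.swing_ms < 10:
            raise ValueError("phase durations must be >= the 10 ms minimum")
        if self.noise_sd_mm < 0:
            raise ValueError("noise sd must be >= 0")
        if self.phase_offsets_ms is None:
            # alternating tripod-like offsets
            self.phase_offsets_ms = {
                leg: (0.0 if i % 2 == 0 else self.stance_ms)
                for i, leg in enumerate(LEGS)
            }


#: anchor directions (unit-ish vectors from ball center) for each leg's
#: contact point; distinct so the pooled tip cloud is well-conditioned.
_LEG_DIRS = {
    "FL": (-0.5, 0.6, 0.62),
    "FR": (0.5, 0.6, 0.62),
    "ML": (-0.7, 0.0, 0.71),
    "MR": (0.7, 0.0, 0.71),
    "HL": (-0.5, -0.6, 0.62),
    "HR": (0.5, -0.6, 0.62),
}


def synth_gait(
    spec: GaitSpec, seed: int = 0
) -> tuple[Pose3D, dict]:
    """Pose table with tips on the sphere during stance, lifted during swing.

    The manifest carries the true sphere and, per leg, the planted phase
    segments as half-open [onset, offset) frame intervals. Swing clearance
    below about three noise standard deviations triggers a warning: the
    phases may be unrecoverable from the noisy tips.
    """
    import warnings

    if spec.noise_sd_mm > 0 and spec.swing_clearance_mm < 3 * spec.noise_sd_mm:
        warnings.warn(
            "swing clearance below the noise floor; planted phases may be "
            "unrecoverable",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    fs = spec.fs
    n = int(round(spec.duration_s * fs))
    center = np.asarray(spec.ball_center, dtype=float)
    r = spec.ball_radius
    stance_f = int(round(spec.stance_ms * fs / 1e3))
    swing_f = int(round(spec.swing_ms * fs / 1e3))
    cycle = stance_f + swing_f

    cols: dict[str, np.ndarray] = {"frame": np.arange(n)}
    segments: dict[str, list[list]] = {}
    notum = center + np.array([0.0, 0.0, r + 2.5])
    for name, offset in (
        ("notum", np.zeros(3)),
        ("wing_hinge_l", np.array([-0.4, -0.3, -0.3])),
        ("wing_hinge_r", np.array([0.4, -0.3, -0.3])),
    ):
        p = notum + offset
        for ax, val in zip("xyz", p):
            cols[f"{name}_{ax}"] = np.full(n, val)

    for leg in LEGS:
        direction = np.asarray(_LEG_DIRS[leg], dtype=float)
        direction /= np.linalg.norm(direction)
        contact = center + r * direction
        off_f = int(round(spec.phase_offsets_ms[leg] * fs / 1e3))

        swing_mask = np.zeros(n, dtype=bool)
        segs: list[list] = []
        t = -off_f % cycle - cycle  # cycle phase at frame 0
        frame = t
        # walk whole cycles covering [0, n)
        while frame < n:
            s0, s1 = frame, frame + stance_f
            w0, w1 = frame + stance_f, frame + cycle
            for a, b, lab in ((s0, s1, "stance"), (w0, w1, "swing")):
                a2, b2 = max(a, 0), min(b, n)
                if b2 > a2:
                    segs.append([a2, b2, lab])
                    if lab == "swing":
                        swing_mask[a2:b2] = True
            frame += cycle
        segments[leg] = segs

        lift = np.zeros(n)
        for a, b, lab in segs:
            if lab == "swing":
                m = b - a
                lift[a:b] = spec.swing_clearance_mm * np.sin(
                    np.pi * (np.arange(m) + 0.5) / m
                )
        tips = contact[None, :] + lift[:, None] * direction[None, :]
        if spec.noise_sd_mm > 0:
            tips = tips + rng.normal(0.0, spec.noise_sd_mm, size=tips.shape)

        # simple articulated chain from a body anchor down to the tip, with
        # a lateral bow so joint angles are non-degenerate
        anchor = notum + 0.8 * (contact - notum) / np.linalg.norm(
            contact - notum
        )
        lateral = np.cross(direction, [0.0, 0.0, 1.0])
        if np.linalg.norm(lateral) < 1e-6:
            lateral = np.array([1.0, 0.0, 0.0])
        lateral /= np.linalg.norm(lateral)
        for j, joint in enumerate(LEG_JOINTS):
            if joint == "tarsal_tip":
                pts = tips
            else:
                frac = (j + 1) / len(LEG_JOINTS)
                bow = 0.4 * np.sin(np.pi * frac)
                pts = (
                    anchor[None, :]
                    + frac * (tips - anchor[None, :])
                    + bow * lateral[None, :]
                )
            for ax_i, ax in enumerate("xyz"):
                cols[f"{leg}_{joint}_{ax}"] = pts[:, ax_i]

    pose = Pose3D(pd.DataFrame(cols), fs=fs)
    manifest = {
        "seed": seed,
        "ball_center": [float(c) for c in center],
        "ball_radius": float(r),
        "fs": fs,
        "segments": segments,
        "noise_sd_mm": spec.noise_sd_mm,
        "swing_clearance_mm": spec.swing_clearance_mm,
    }
    return pose, manifest


def stance_tips(pose: Pose3D, manifest: dict) -> np.ndarray:
    """Pooled tarsal-tip coordinates restricted to ground-truth stance frames.

    Swing tips hover above the surface, so a sphere fit to the full cloud is
    biased outward; the stance-only cloud sits on the sphere (up to noise)
    and is the right input for a recovery round trip.
    """
    parts = []
    for leg, segs in manifest["segments"].items():
        tips = pose.point(f"{leg}_tarsal_tip")
        for a, b, lab in segs:
            if lab == "stance":
                parts.append(tips[a:b])
    return np.vstack(parts)


# ---------------------------------------------------------------------------
# arena trajectories


@dataclass
class TrackSpec:
    """Ordered behavioral segment plan realized as a planar trajectory.

    Each plan entry is ``(behavior, duration_s, speed_mm_s, angular_deg_s)``
    with behavior one of walk, stop, pivot, approach_blob.
    """

    plan: list[tuple[str, float, float, float]]
    fs: float = 30.0
    start_xy: tuple[float, float] = (-15.0, 0.0)
    start_heading: float = 0.0
    blob_center: tuple[float, float] = (0.0, 0.0)
    noise_sd_mm: float = 0.0
    stim_epochs: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = {"walk", "stop", "pivot", "approach_blob"}
        for beh, dur, _, _ in self.plan:
            if beh not in known:
                raise ValueError(f"unknown behavior {beh!r}")
            if dur <= 0:
                raise ValueError("plan durations must be positive")


def synth_track(
    spec: TrackSpec, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Arena-track table (x, y, heading, stim) plus episode ground truth."""
    rng = np.random.default_rng(seed)
    fs = spec.fs
    dt = 1.0 / fs
    xy = [np.asarray(spec.start_xy, dtype=float)]
    heading = [spec.start_heading]
    episodes = []
    t = 0.0
    for beh, dur, speed, ang in spec.plan:
        n = int(round(dur * fs))
        episodes.append(
            {"label": beh, "t_start": t, "t_end": t + n * dt}
        )
        for _ in range(n):
            h = heading[-1]
            if beh == "approach_blob":
                delta = np.asarray(spec.blob_center) - xy[-1]
                h = np.degrees(np.arctan2(delta[1], delta[0]))
            elif beh == "pivot":
                h = h + ang * dt
            elif beh == "walk":
                h = h + ang * dt
            step = speed * dt if beh != "stop" else 0.0
            if beh == "pivot":
                step = speed * dt  # slow drift while spinning
            new = xy[-1] + step * np.array(
                [np.cos(np.radians(h)), np.sin(np.radians(h))]
            )
            xy.append(new)
            heading.append(h % 360.0)
        t += n * dt
    xy = np.array(xy[:-1]) if len(xy) > 1 else np.array(xy)
    heading_arr = np.array(heading[: len(xy)])
    if spec.noise_sd_mm > 0:
        xy = xy + rng.normal(0.0, spec.noise_sd_mm, size=xy.shape)

    n_total = len(xy)
    stim = np.zeros(n_total, dtype=int)
    for t0, t1 in spec.stim_epochs:
        stim[int(round(t0 * fs)) : int(round(t1 * fs))] = 1

    df = pd.DataFrame(
        {
            "x": xy[:, 0],
            "y": xy[:, 1],
            "heading": heading_arr,
            "stim": stim,
        }
    )

    d_blob = np.linalg.norm(xy - np.asarray(spec.blob_center), axis=1)
    inside = np.flatnonzero(d_blob <= 3.0)
    manifest = {
        "seed": seed,
        "fs": fs,
        "episodes": episodes,
        "blob_center": list(spec.blob_center),
        "encounter_frame": int(inside[0]) if inside.size else None,
    }
    return df, manifest


# ---------------------------------------------------------------------------
# fluorescence traces


@dataclass
class TraceSpec:
    """Activity coupled to a reference series at a planted lag and gain."""

    duration_s: float = 120.0
    fs_ref: float = 50.0
    fs_img: float = 5.0
    lag_s: float = 0.2  # positive: activity lags the reference
    gain: float = 1.0
    kernel_tau_s: float = 0.5  # calcium-indicator decay
    baseline: float = 100.0
    noise_sd: float = 0.5
    ref_smooth_s: float = 0.5

    def __post_init__(self) -> None:
        if self.kernel_tau_s <= 0:
            raise ValueError("kernel time constant must be positive")


def synth_traces(
    spec: TraceSpec, seed: int = 0
) -> tuple[dict, np.ndarray, dict]:
    """Two-channel fluorescence coupled to a smooth reference series.

    Green = baseline x (1 + gain x kernel-convolved, lag-shifted reference)
    plus noise; red = baseline plus noise (gain-free). Returns
    (channels dict, reference series at ``fs_ref``, manifest).
    """
    from scipy.ndimage import gaussian_filter1d, shift as nd_shift

    rng = np.random.default_rng(seed)
    n_ref = int(round(spec.duration_s * spec.fs_ref))
    ref = gaussian_filter1d(
        rng.standard_normal(n_ref), sigma=spec.ref_smooth_s * spec.fs_ref
    )
    sd = ref.std()
    ref = (ref - ref.mean()) / (sd if sd > 0 else 1.0)
    ref = np.maximum(ref + 1.0, 0.0)  # non-negative, velocity-like

    # causal exponential kernel at the reference clock
    tk = np.arange(0, 5 * spec.kernel_tau_s, 1.0 / spec.fs_ref)
    kernel = np.exp(-tk / spec.kernel_tau_s)
    kernel /= kernel.sum()
    driven = np.convolve(ref, kernel)[:n_ref]
    lag_samples = spec.lag_s * spec.fs_ref
    driven = nd_shift(driven, lag_samples, order=1, mode="nearest")

    # image at the slow clock by block averaging
    from .traces import block_average

    green_hi = spec.baseline * (1.0 + spec.gain * driven)
    green = block_average(green_hi, spec.fs_ref, spec.fs_img)
    red = np.full_like(green, spec.baseline)
    if spec.noise_sd > 0:
        green = green + rng.normal(0.0, spec.noise_sd, size=green.shape)
        red = red + rng.normal(0.0, spec.noise_sd, size=red.shape)

    channels = {"green": green, "red": red, "fs": spec.fs_img}
    manifest = {
        "seed": seed,
        "lag_s": spec.lag_s,
        # activity trails the reference, so the activity-leads-velocity
        # cross-correlation peaks at minus the planted lag
        "xcorr_peak_lag_s": -spec.lag_s,
        "gain": spec.gain,
        "kernel_tau_s": spec.kernel_tau_s,
        "fs_ref": spec.fs_ref,
        "fs_img": spec.fs_img,
    }
    return channels, ref, manifest
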