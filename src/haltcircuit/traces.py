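"""Fluorescence-trace analysis: dF/F, response AUC, ratiometric z-scores,
pixel-wise behavior correlation and activity-velocity cross-correlation.

Three baseline conventions for dF/F = (F - F0)/F0 are supported, matching
common stimulation and movement-triggered designs:

- ``pre_mean``: F0 is the mean fluorescence over the 2 s before stimulation;
- ``pre_p10``: F0 is the 10th percentile over the 2 s before stimulation
  (robust to activity in the baseline window, used for muscle imaging);
- ``pre_move_median``: F0 is the median over the 300 ms before movement
  initiation.

Imaging runs slow (2-6 Hz) against fast behavior (50-200 Hz); alignment
block-averages the behavior down to the imaging clock rather than inventing
imaging samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceTrace",
    "EthogramSeries",
    "CorrelationMap",
    "BASELINE_MODES",
    "dff",
    "response_auc",
    "zscored_ratio",
    "pixel_correlation_map",
    "activity_velocity_xcorr",
    "block_average",
]

#: dF/F baseline conventions: (window length s, statistic).
BASELINE_MODES = {
    "pre_mean": (2.0, "mean"),
    "pre_p10": (2.0, "p10"),
    "pre_move_median": (0.3, "median"),
}


@dataclass
class FluorescenceTrace:
    """Per-ROI, per-channel fluorescence with stimulation epochs."""

    green: np.ndarray
    fs: float
    red: np.ndarray | None = None
    stim_epochs: list[tuple[float, float]] = field(default_factory=list)
    movement_onsets: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green, dtype=float)
        if self.red is not None:
            self.red = np.asarray(self.red, dtype=float)
            if self.red.shape != self.green.shape:
                raise ValueError("green and red channels must be co-sampled")
        if not np.all(np.isfinite(self.green)):
            raise ValueError("fluorescence must be finite")
        dur = len(self.green) / self.fs
        for t0, t1 in self.stim_epochs:
            if not (0 <= t0 < t1 <= dur + 1e-9):
                raise ValueError(f"epoch [{t0}, {t1}) outside the recording")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.green)) / self.fs


@dataclass
class EthogramSeries:
    """Binary per-frame indicators, one column per behavior label."""

    data: pd.DataFrame
    fs: float

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("ethogram values must be 0 or 1")

    def series(self, label: str) -> np.ndarray:
        return self.data[label].to_numpy(dtype=float)


@dataclass
class CorrelationMap:
    """Per-pixel Pearson r against a reference series, with a validity mask."""

    r: np.ndarray
    valid: np.ndarray  # False where the pixel was constant (r reported as 0)

    def __post_init__(self) -> None:
        if np.nanmax(np.abs(self.r), initial=0.0) > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")


def dff(
    trace: FluorescenceTrace | np.ndarray,
    reference_time: float,
    baseline_mode: str = "pre_mean",
    fs: float | None = None,
) -> np.ndarray:
    """Baseline-normalized fluorescence change (F - F0)/F0.

    ``reference_time`` is the stimulation onset (or movement initiation for
    ``pre_move_median``); the baseline window ends there. F0 must be
    positive for the normalization to be defined.
    """
    if baseline_mode not in BASELINE_MODES:
        raise ValueError(f"unknown baseline mode {baseline_mode!r}")
    if isinstance(trace, FluorescenceTrace):
        f, fs = trace.green, trace.fs
    else:
        f = np.asarray(trace, dtype=float)
        if fs is None:
            raise ValueError("fs required for a bare array")
    win, stat = BASELINE_MODES[baseline_mode]
    i1 = int(round(reference_time * fs))
    i0 = i1 - int(round(win * fs))
    if i0 < 0 or i1 > len(f) or i1 <= i0:
        raise ValueError(
            f"baseline window [{i0}, {i1}) does not fit before "
            f"reference_time {reference_time} s"
        )
    base = f[i0:i1]
    if stat == "mean":
        f0 = float(np.mean(base))
    elif stat == "median":
        f0 = float(np.median(base))
    else:  # 10th percentile, linear interpolation between closest ranks
        f0 = float(np.percentile(base, 10))
    if f0 <= 0:
        raise ValueError(f"baseline F0 = {f0} is not positive")
    return (f - f0) / f0


def response_auc(
    dff_series: np.ndarray,
    fs: float,
    stim_onset: float,
    window: tuple[float, float] = (0.0, 2.0),
) -> float:
    """Trapezoidal area under dF/F over ``window`` seconds post-stimulation.

    Units are seconds (dF/F is dimensionless).
    """
    y = np.asarray(dff_series, dtype=float)
    i0 = int(round((stim_onset + window[0]) * fs))
    i1 = int(round((stim_onset + window[1]) * fs))
    if not (0 <= i0 < i1 <= len(y) - 0):
        raise ValueError("AUC window outside the recording")
    i1 = min(i1 + 1, len(y))  # include the closing sample for the trapezoid
    return float(np.trapezoid(y[i0:i1], dx=1.0 / fs))


def zscored_ratio(green: np.ndarray, red: np.ndarray) -> np.ndarray:
    """z-scored dR/R of the ratio R = green/red.

    The red channel is a calcium-insensitive reference, so multiplicative
    artifacts common to both channels cancel in R. dR/R is taken against the
    recording-median R and z-scored to mean 0, sd 1 over the recording.
    """
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if green.shape != red.shape:
        raise ValueError("channels must be co-sampled")
    if np.any(red <= 0):
        raise ValueError("red channel must be positive throughout")
    r = green / red
    r0 = np.median(r)
    if r0 <= 0:
        raise ValueError("median ratio is not positive")
    drr = (r - r0) / r0
    sd = np.std(drr)
    if sd == 0:
        raise ValueError("constant ratio: z-score undefined")
    return (drr - np.mean(drr)) / sd


def block_average(series: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Downsample by averaging non-overlapping blocks onto a slower clock."""
    series = np.asarray(series, dtype=float)
    if fs_out > fs_in:
        raise ValueError("block averaging only downsamples")
    factor = fs_in / fs_out
    n_out = int(np.floor(len(series) / factor))
    edges = np.round(np.arange(n_out + 1) * factor).astype(int)
    return np.array(
        [series[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
    )


def pixel_correlation_map(
    movie: np.ndarray,
    reference: np.ndarray,
    fs_movie: float | None = None,
    fs_reference: float | None = None,
) -> CorrelationMap:
    """Pearson correlation of every pixel's time series with a reference.

    ``movie`` is (T, ...) with time first. A faster reference (behavior or
    velocity) is block-averaged onto the movie clock. Constant pixels have
    undefined r; they are reported as 0 and masked invalid.
    """
    movie = np.asarray(movie, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if fs_movie is not None and fs_reference is not None and fs_reference > fs_movie:
        ref = block_average(ref, fs_reference, fs_movie)
    if len(ref) != movie.shape[0]:
        raise ValueError(
            f"reference length {len(ref)} != movie frames {movie.shape[0]} "
            "after resampling"
        )
    ref_c = ref - ref.mean()
    ref_ss = float(ref_c @ ref_c)
    if ref_ss == 0:
        raise ValueError("constant reference series")
    flat = movie.reshape(movie.shape[0], -1)
    px = flat - flat.mean(axis=0)
    px_ss = np.sum(px**2, axis=0)
    valid = px_ss > 0
    r = np.zeros(flat.shape[1])
    r[valid] = (ref_c @ px[:, valid]) / np.sqrt(px_ss[valid] * ref_ss)
    r = np.clip(r, -1.0, 1.0)
    shape = movie.shape[1:]
    return CorrelationMap(r=r.reshape(shape), valid=valid.reshape(shape))


def activity_velocity_xcorr(
    activity: np.ndarray | Sequence[np.ndarray],
    velocity: np.ndarray | Sequence[np.ndarray],
    fs: float,
    max_lag: float = 2.0,
) -> pd.DataFrame:
    """Normalized cross-correlation of neural activity with velocity.

    Returns r at lags in [-max_lag, +max_lag] (seconds); a positive lag
    means activity leads velocity. Passing lists of arrays pools recordings
    by concatenation after removing each recording's mean (cross-products
    never straddle a recording boundary).
    """
    acts = [np.asarray(a, float) for a in _as_list(activity)]
    vels = [np.asarray(v, float) for v in _as_list(velocity)]
    if len(acts) != len(vels):
        raise ValueError("need one velocity series per activity series")
    max_shift = int(round(max_lag * fs))
    if any(len(a) <= max_shift for a in acts):
        raise ValueError("max_lag must be shorter than every recording")
    acts = [a - a.mean() for a in acts]
    vels = [v - v.mean() for v in vels]
    den = np.sqrt(
        sum(float(a @ a) for a in acts) * sum(float(v @ v) for v in vels)
    )
    if den == 0:
        raise ValueError("zero-variance input")

    lags = np.arange(-max_shift, max_shift + 1)
    r = np.empty(len(lags))
    for i, k in enumerate(lags):
        num = 0.0
        for a, v in zip(acts, vels):
            if k >= 0:  # activity leads: a(t) vs v(t + k)
                num += float(a[: len(a) - k] @ v[k:])
            else:
                num += float(a[-k:] @ v[: len(v) + k])
        r[i] = num / den
    return pd.DataFrame({"lag_s": lags / fs, "r": r})


def _as_list(x) -> list:
    if isinstance(x, np.ndarray):
        return [x]
    if isinstance(x, (list, tuple)) and x and np.ndim(x[0]) >= 1:
        return list(x)
    return [np.asarray(x)]
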