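"""Connectome-constrained leaky integrate-and-fire network simulation.

Every neuron is a leaky integrate-and-fire unit: the membrane potential
relaxes toward rest with time constant ``tau_mem``, jumps by the signed
synaptic weight (synapse count x ``w_unit``) when a presynaptic spike
arrives after a fixed conduction delay, and emits a spike on reaching
threshold, after which it is clamped at reset for an absolute refractory
period. Neurons have no intrinsic drive: with no external input the network
is silent. Stimulation adds homogeneous Poisson spike trains to chosen
neurons; silencing severs a neuron's outgoing synapses while leaving its
own spiking intact.

Integration is forward Euler on a fixed grid (default 0.05 ms). Synaptic
events are applied after the membrane-decay update of each step; delays are
rounded to the nearest step. Two synaptic kernels are available: an
instantaneous voltage jump (``delta``, the default) and a current-based
exponential kernel (``exp``) whose time-integrated effect matches the jump.

Default membrane constants follow the published code of the reference
whole-brain model and can all be overridden via :class:`LIFParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter1d

from .connectome import SignedConnectome, WeightMatrix, build_weight_matrix

__all__ = [
    "LIFParams",
    "StimulusEpoch",
    "StimulusProtocol",
    "SpikeRaster",
    "RateResult",
    "SweepResult",
    "poisson_train",
    "simulate",
    "firing_rates",
    "top_responders",
    "rate_sweep",
    "protocol_from_dict",
]


@dataclass(frozen=True)
class LIFParams:
    """Membrane, synapse and integration constants (mV / ms units)."""

    v_rest: float = -52.0
    v_thresh: float = -45.0
    v_reset: float = -52.0
    tau_mem: float = 20.0
    t_refract: float = 2.2
    tau_syn: float = 5.0
    syn_delay: float = 1.8
    w_unit: float = 0.275
    dt: float = 0.05
    #: mV added per external (Poisson) input spike; suprathreshold by default
    #: so a stimulated neuron follows its input train up to refractoriness.
    stim_w: float = 7.5
    #: synaptic kernel: "delta" (voltage jump) or "exp" (filtered current).
    kernel: str = "delta"

    def __post_init__(self) -> None:
        if not (self.v_reset <= self.v_rest < self.v_thresh):
            raise ValueError(
                "require v_reset <= v_rest < v_thresh, got "
                f"{self.v_reset}, {self.v_rest}, {self.v_thresh}"
            )
        for name in ("tau_mem", "tau_syn", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.t_refract < 0 or self.syn_delay < 0:
            raise ValueError("t_refract and syn_delay must be non-negative")
        if self.kernel not in ("delta", "exp"):
            raise ValueError(f"unknown synaptic kernel {self.kernel!r}")


@dataclass(frozen=True)
class StimulusEpoch:
    """Poisson input at ``rate`` Hz to ``targets`` over [t_start, t_end) s."""

    targets: tuple[int, ...]
    rate: float
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        if self.rate < 0:
            raise ValueError(f"Poisson rate must be >= 0, got {self.rate}")
        if not (0 <= self.t_start <= self.t_end):
            raise ValueError("require 0 <= t_start <= t_end")


@dataclass(frozen=True)
class StimulusProtocol:
    """What is injected: epochs, silenced set, duration, trials, seed.

    The standard protocol in this line of work is 30 trials of 1,000 ms.
    """

    epochs: tuple[StimulusEpoch, ...] = ()
    silenced: frozenset[int] = frozenset()
    duration: float = 1.0
    n_trials: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "epochs", tuple(self.epochs))
        object.__setattr__(self, "silenced", frozenset(self.silenced))
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for ep in self.epochs:
            if ep.t_end > self.duration + 1e-12:
                raise ValueError(
                    f"epoch [{ep.t_start}, {ep.t_end}) exceeds duration "
                    f"{self.duration}"
                )


@dataclass
class SpikeRaster:
    """Per-trial, per-neuron ordered spike times in seconds."""

    spikes: list[dict[int, np.ndarray]]
    ids: list[int]
    duration: float
    dt: float

    @property
    def n_trials(self) -> int:
        return len(self.spikes)

    def counts(self, window: tuple[float, float] | None = None) -> pd.Series:
        """Total spike count per neuron over all trials (optionally windowed)."""
        out = {}
        for nid in self.ids:
            c = 0
            for trial in self.spikes:
                t = trial.get(nid)
                if t is None or len(t) == 0:
                    continue
                if window is None:
                    c += len(t)
                else:
                    c += int(np.sum((t >= window[0]) & (t < window[1])))
            out[nid] = c
        return pd.Series(out, name="count")

    def to_frame(self) -> pd.DataFrame:
        """Long table ``trial,neuron,spike_time_s``."""
        rows = []
        for k, trial in enumerate(self.spikes):
            for nid in sorted(trial):
                for t in trial[nid]:
                    rows.append((k, nid, float(t)))
        return pd.DataFrame(rows, columns=["trial", "neuron", "spike_time_s"])


@dataclass
class RateResult:
    """Trial-averaged firing rates, scalar over a window or time-resolved."""

    ids: list[int]
    window: tuple[float, float]
    scalar: pd.Series | None = None
    bin_centers: np.ndarray | None = None
    timecourse: np.ndarray | None = None  # (n_neurons, n_bins), Hz
    smooth_sigma_ms: float | None = None

    def rate(self, nid: int) -> float:
        if self.scalar is None:
            raise ValueError("no scalar rates; time-resolved result")
        return float(self.scalar[nid])


@dataclass
class SweepResult:
    """Readout rates over a 2-D grid of stimulation-rate combinations."""

    axis1_ids: tuple[int, ...]
    axis1_rates: np.ndarray
    axis2_ids: tuple[int, ...]
    axis2_rates: np.ndarray
    readout_ids: tuple[int, ...]
    grid: np.ndarray  # (len(axis1_rates), len(axis2_rates)), Hz
    silenced: frozenset[int] = frozenset()
    silenced_grid: np.ndarray | None = None
    difference: np.ndarray | None = None  # silenced - intact

    def to_frame(self, which: str = "grid") -> pd.DataFrame:
        g = getattr(self, "grid" if which == "grid" else which)
        if g is None:
            raise ValueError(f"{which} not computed")
        return pd.DataFrame(
            g,
            index=pd.Index(self.axis1_rates, name="axis1_rate_hz"),
            columns=pd.Index(self.axis2_rates, name="axis2_rate_hz"),
        )


# ---------------------------------------------------------------------------
# stimulus generation


def _stream(seed: int, trial: int, neuron: int) -> np.random.Generator:
    """Independent counter-based stream per (trial, stimulated neuron).

    Keyed on the protocol seed so adding a readout or reordering epochs never
    perturbs existing streams.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(trial, neuron))
    )


def poisson_train(
    rate: float,
    t_start: float,
    t_end: float,
    dt: float = 0.05,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Homogeneous Poisson spike times on the dt grid, within [t_start, t_end).

    ``dt`` is in ms, times in seconds. Bin counts are Poisson(rate*dt), so a
    bin may carry several spikes; repeated times are returned as repeats.
    """
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if t_end < t_start:
        raise ValueError("t_end must be >= t_start")
    if rng is None:
        rng = np.random.default_rng()
    dt_s = dt * 1e-3
    n_bins = int(round((t_end - t_start) / dt_s))
    if n_bins <= 0 or rate == 0:
        return np.empty(0)
    counts = rng.poisson(rate * dt_s, size=n_bins)
    idx = np.repeat(np.nonzero(counts)[0], counts[counts > 0])
    return t_start + idx * dt_s


def _external_counts(
    protocol: StimulusProtocol, trial: int, dt_s: float, n_steps: int
) -> dict[int, np.ndarray]:
    """Per stimulated neuron: Poisson spike count per integration step."""
    out: dict[int, np.ndarray] = {}
    # One stream per (trial, neuron); a neuron in several epochs draws its
    # epochs sequentially from its own stream.
    by_neuron: dict[int, list[StimulusEpoch]] = {}
    for ep in protocol.epochs:
        for nid in ep.targets:
            by_neuron.setdefault(nid, []).append(ep)
    for nid, eps in by_neuron.items():
        rng = _stream(protocol.seed, trial, nid)
        counts = np.zeros(n_steps, dtype=np.int64)
        for ep in eps:
            i0 = int(round(ep.t_start / dt_s))
            i1 = int(round(ep.t_end / dt_s))
            if i1 > i0 and ep.rate > 0:
                counts[i0:i1] += rng.poisson(ep.rate * dt_s, size=i1 - i0)
        out[nid] = counts
    return out


# ---------------------------------------------------------------------------
# engine


def simulate(
    weights: WeightMatrix | SignedConnectome,
    params: LIFParams,
    protocol: StimulusProtocol,
) -> SpikeRaster:
    """Forward-integrate the LIF network under a stimulation protocol.

    Silenced neurons keep integrating and spiking but their outgoing weights
    are severed before integration, so their spikes reach no one. With an
    empty epoch list the raster is empty for every neuron and trial.
    """
    if isinstance(weights, SignedConnectome):
        weights = build_weight_matrix(weights, params.w_unit)
    ids = weights.ids
    index = weights.index
    n = len(ids)

    for ep in protocol.epochs:
        for nid in ep.targets:
            if nid not in index:
                raise KeyError(f"stimulus target {nid} not in the network")
    for nid in protocol.silenced:
        if nid not in index:
            raise KeyError(f"silenced neuron {nid} not in the network")

    dt_s = params.dt * 1e-3
    n_steps_f = protocol.duration / dt_s
    n_steps = int(round(n_steps_f))
    if abs(n_steps_f - n_steps) > 1e-6:
        raise ValueError(
            f"dt {params.dt} ms does not divide duration {protocol.duration} s"
        )

    # Sever outgoing synapses of silenced neurons (CSR row zeroing).
    W = weights.matrix.tocsr(copy=True)
    if protocol.silenced:
        rows = [index[i] for i in protocol.silenced]
        mask = np.ones(n, dtype=bool)
        mask[rows] = False
        W = sp.diags(mask.astype(float)) @ W
        W = W.tocsr()
    WT = W.T.tocsr()  # post x pre, for gathering increments per step

    delay_steps = max(int(round(params.syn_delay / params.dt)), 1)
    ref_steps = int(round(params.t_refract / params.dt))
    decay = params.dt / params.tau_mem
    syn_decay = params.dt / params.tau_syn

    # All trials evolve in lockstep: state arrays are (n_trials, n) and one
    # step loop serves every trial, which is what makes the 30-trial protocol
    # affordable in pure numpy.
    T = protocol.n_trials
    ext_rows_list: list[np.ndarray] = []
    ext_counts_list: list[np.ndarray] = []
    for trial in range(T):
        ext = _external_counts(protocol, trial, dt_s, n_steps)
        ext_rows_list.append(np.array([index[i] for i in ext], dtype=np.intp))
        ext_counts_list.append(
            np.vstack(list(ext.values()))
            if ext
            else np.zeros((0, n_steps), dtype=np.int64)
        )
    # stimulated neuron set is protocol-wide; build a dense (T, k, steps)
    stim_rows = ext_rows_list[0]
    ext_counts = np.stack(ext_counts_list)  # (T, k, n_steps)

    v = np.full((T, n), params.v_rest)
    i_syn = np.zeros((T, n))  # used by the "exp" kernel only
    ref_until = np.zeros((T, n), dtype=np.int64)
    buf = np.zeros((delay_steps + 1, T, n))  # ring buffer of increments
    spike_rec: list[tuple[int, np.ndarray, np.ndarray]] = []

    W_dense = None
    if n <= 512:  # dense matmul is faster for small nets
        W_dense = W.toarray()

    for t in range(n_steps):
        active = ref_until <= t
        # membrane decay toward rest
        v += np.where(active, decay * (params.v_rest - v), 0.0)
        # synaptic events scheduled for this step
        slot = t % (delay_steps + 1)
        inc = buf[slot]
        if params.kernel == "delta":
            v += np.where(active, inc, 0.0)
        else:
            i_syn += inc / (params.tau_syn * 1e-3)  # mV/s current
            v += np.where(active, i_syn * dt_s, 0.0)
            i_syn -= syn_decay * i_syn
        inc[:] = 0.0
        # external Poisson input (direct, undelayed injection)
        if stim_rows.size:
            hits = ext_counts[:, :, t]  # (T, k)
            if hits.any():
                add = np.zeros((T, n))
                add[:, stim_rows] = hits * params.stim_w
                v += np.where(active, add, 0.0)
        # threshold, reset, schedule deliveries
        spiking = active & (v >= params.v_thresh)
        if spiking.any():
            tr_idx, nn_idx = np.nonzero(spiking)
            v[tr_idx, nn_idx] = params.v_reset
            ref_until[tr_idx, nn_idx] = t + 1 + ref_steps
            dest = (t + delay_steps) % (delay_steps + 1)
            spk = spiking.astype(float)
            if W_dense is not None:
                buf[dest] += spk @ W_dense
            else:
                buf[dest] += spk @ W
            spike_rec.append((t, tr_idx, nn_idx))

    trials: list[dict[int, list[float]]] = [dict() for _ in range(T)]
    for t, tr_idx, nn_idx in spike_rec:
        for tr, k in zip(tr_idx, nn_idx):
            trials[tr].setdefault(ids[k], []).append(t * dt_s)
    trials_arr = [
        {nid: np.asarray(ts, dtype=float) for nid, ts in d.items()}
        for d in trials
    ]

    return SpikeRaster(
        spikes=trials_arr, ids=ids, duration=protocol.duration, dt=params.dt
    )


# ---------------------------------------------------------------------------
# rates and rankings


def firing_rates(
    raster: SpikeRaster,
    window: tuple[float, float] | None = None,
    bin_ms: float | None = None,
    smooth_sigma_ms: float | None = 25.0,
) -> RateResult:
    """Trial-averaged firing rates.

    Scalar mode (``bin_ms`` None): spikes in ``window`` divided by
    (trials x window length). Time-resolved mode: per-bin rate in Hz,
    optionally smoothed with a Gaussian kernel of ``smooth_sigma_ms``.
    """
    if window is None:
        window = (0.0, raster.duration)
    t0, t1 = window
    if not (0.0 <= t0 < t1 <= raster.duration + 1e-12):
        raise ValueError(f"invalid window {window}")

    if bin_ms is None:
        counts = raster.counts(window)
        scalar = counts / (raster.n_trials * (t1 - t0))
        return RateResult(ids=raster.ids, window=window, scalar=scalar)

    bin_s = bin_ms * 1e-3
    edges = np.arange(t0, t1 + bin_s * 0.5, bin_s)
    centers = 0.5 * (edges[:-1] + edges[1:])
    tc = np.zeros((len(raster.ids), len(centers)))
    for k, nid in enumerate(raster.ids):
        for trial in raster.spikes:
            t = trial.get(nid)
            if t is not None and len(t):
                tc[k] += np.histogram(t, bins=edges)[0]
    tc /= raster.n_trials * bin_s
    if smooth_sigma_ms is not None and smooth_sigma_ms > 0:
        tc = gaussian_filter1d(
            tc, sigma=smooth_sigma_ms / bin_ms, axis=1, mode="constant"
        )
    return RateResult(
        ids=raster.ids,
        window=window,
        bin_centers=centers,
        timecourse=tc,
        smooth_sigma_ms=smooth_sigma_ms,
    )


def top_responders(
    rates: RateResult, k: int = 100, stat: str = "mean"
) -> list[int]:
    """Ids of the ``k`` most active neurons, descending; ties by ascending id.

    ``stat`` is "mean" (scalar/mean rate) or "peak" (peak of the smoothed
    time-resolved rate).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if stat == "mean":
        if rates.scalar is not None:
            values = {nid: float(rates.scalar[nid]) for nid in rates.ids}
        else:
            values = {
                nid: float(np.mean(rates.timecourse[i]))
                for i, nid in enumerate(rates.ids)
            }
    elif stat == "peak":
        if rates.timecourse is None:
            raise ValueError("peak ranking needs a time-resolved RateResult")
        values = {
            nid: float(np.max(rates.timecourse[i]))
            for i, nid in enumerate(rates.ids)
        }
    else:
        raise ValueError(f"unknown ranking statistic {stat!r}")
    order = sorted(rates.ids, key=lambda nid: (-values[nid], nid))
    return order[:k]


def rate_sweep(
    conn: SignedConnectome,
    params: LIFParams,
    axis1: tuple[Sequence[int], Sequence[float]],
    axis2: tuple[Sequence[int], Sequence[float]],
    readout_ids: Sequence[int],
    silenced: Iterable[int] = (),
    duration: float = 1.0,
    n_trials: int = 30,
    seed: int = 0,
    window: tuple[float, float] | None = None,
) -> SweepResult:
    """Readout rates while co-stimulating two neuron groups over a rate grid.

    One full simulate-and-average evaluation per grid cell; the grid value is
    the mean trial-averaged rate across ``readout_ids``. With a non-empty
    ``silenced`` set a paired grid is computed in the silenced model and the
    difference grid (silenced minus intact) reported.
    """
    ids1, rates1 = tuple(axis1[0]), np.asarray(axis1[1], dtype=float)
    ids2, rates2 = tuple(axis2[0]), np.asarray(axis2[1], dtype=float)
    readout_ids = tuple(readout_ids)
    silenced = frozenset(silenced)
    if rates1.size == 0 or rates2.size == 0:
        raise ValueError("rate axes must be non-empty")
    if (rates1 < 0).any() or (rates2 < 0).any():
        raise ValueError("stimulation rates must be non-negative")
    bad = silenced & set(readout_ids)
    if bad:
        raise ValueError(
            f"readout neurons {sorted(bad)} are silenced; readout undefined"
        )

    weights = build_weight_matrix(conn, params.w_unit)

    def cell(r1: float, r2: float, sil: frozenset[int]) -> float:
        epochs = []
        if r1 > 0:
            epochs.append(StimulusEpoch(ids1, r1, 0.0, duration))
        if r2 > 0:
            epochs.append(StimulusEpoch(ids2, r2, 0.0, duration))
        proto = StimulusProtocol(
            epochs=tuple(epochs),
            silenced=sil,
            duration=duration,
            n_trials=n_trials,
            seed=seed,
        )
        raster = simulate(weights, params, proto)
        rr = firing_rates(raster, window=window)
        return float(np.mean([rr.rate(i) for i in readout_ids]))

    grid = np.array(
        [[cell(r1, r2, frozenset()) for r2 in rates2] for r1 in rates1]
    )
    silenced_grid = difference = None
    if silenced:
        silenced_grid = np.array(
            [[cell(r1, r2, silenced) for r2 in rates2] for r1 in rates1]
        )
        difference = silenced_grid - grid

    return SweepResult(
        axis1_ids=ids1,
        axis1_rates=rates1,
        axis2_ids=ids2,
        axis2_rates=rates2,
        readout_ids=readout_ids,
        grid=grid,
        silenced=silenced,
        silenced_grid=silenced_grid,
        difference=difference,
    )


# ---------------------------------------------------------------------------
# config plumbing


def protocol_from_dict(cfg: Mapping) -> tuple[LIFParams, StimulusProtocol]:
    """Build (LIFParams, StimulusProtocol) from a config mapping.

    Recognized keys: ``duration_s, n_trials, dt_ms, seed, epochs[], silenced[],
    lif{...}``; epoch entries carry ``targets, rate_hz, t_start_s, t_end_s``.
    """
    lif_kwargs = dict(cfg.get("lif", {}))
    if "dt_ms" in cfg:
        lif_kwargs["dt"] = float(cfg["dt_ms"])
    params = LIFParams(**lif_kwargs)
    duration = float(cfg.get("duration_s", 1.0))
    epochs = tuple(
        StimulusEpoch(
            targets=tuple(int(i) for i in ep["targets"]),
            rate=float(ep["rate_hz"]),
            t_start=float(ep.get("t_start_s", 0.0)),
            t_end=float(ep.get("t_end_s", duration)),
        )
        for ep in cfg.get("epochs", [])
    )
    protocol = StimulusProtocol(
        epochs=epochs,
        silenced=frozenset(int(i) for i in cfg.get("silenced", [])),
        duration=duration,
        n_trials=int(cfg.get("n_trials", 30)),
        seed=int(cfg.get("seed", 0)),
    )
    return params, protocol


def load_protocol(path: str | Path) -> tuple[LIFParams, StimulusProtocol]:
    """Load a YAML protocol config file."""
    import yaml

    with open(path) as fh:
        return protocol_from_dict(yaml.safe_load(fh))
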