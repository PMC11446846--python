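# Methods

## Network model

The simulator implements a connectome-constrained network of leaky
integrate-and-fire neurons. The membrane potential of each neuron relaxes
toward rest with time constant `tau_mem`; a presynaptic spike increments the
postsynaptic potential, after a fixed conduction delay, by
`sign(pre) * synapse_count * w_unit`, where the sign is -1 for GABAergic and
glutamatergic presynaptic neurons and +1 for all other (including unknown)
neurotransmitter predictions. Reaching threshold emits a spike, resets the
potential, and clamps the neuron at reset for an absolute refractory period
during which inputs are ignored. The network has no intrinsic drive: with no
external input every rate is exactly zero. Stimulation injects homogeneous
Poisson spike trains of a chosen rate directly into target neurons;
silencing severs a neuron's outgoing synapses before integration while
leaving its own integration and spiking intact, mirroring output-level
optogenetic silencing.

Default constants (all overridable in `LIFParams`, each defined in exactly
one place) are taken from the reference whole-brain model's published code:
rest and reset -52 mV, threshold -45 mV, membrane time constant 20 ms,
absolute refractory period 2.2 ms, conduction delay 1.8 ms, and 0.275 mV of
depolarization per synapse per spike. Each external input spike injects
`stim_w` = 7.5 mV, deliberately suprathreshold so a stimulated neuron
follows its input train up to refractory losses; this makes "stimulate at
150 Hz" directly interpretable and is exposed as a parameter.

### Numerics

Integration is forward Euler on a fixed grid, 0.05 ms by default; `dt` must
divide the trial duration. Within a step the order is: membrane decay, then
delivery of delayed synaptic events, then external input, then threshold
test and reset. Delays are rounded to the nearest step (minimum one step).
Two synaptic kernels are available: the default instantaneous voltage jump,
and a current-based exponential kernel (`tau_syn`, default 5 ms) whose
time-integrated effect equals the jump; the delta kernel is the one checked
spike-for-spike against a brute-force scalar Euler reference in the tests.
All trials integrate in lockstep as a (trials x neurons) state array, which
is what makes the 30-trial protocol affordable in pure numpy; the engine
switches from dense to sparse weight matmuls above 512 neurons.

Per-trial randomness comes from counter-based streams keyed on
(protocol seed, trial, stimulated neuron id), so adding a readout, removing
an epoch, or reordering epochs never perturbs existing streams; identical
protocol and seed give bit-identical rasters, and protocol-level silencing
equals structural silencing exactly under matched seeds. Poisson trains are
drawn as per-bin Poisson counts (a bin may carry several spikes), so the
count statistics are exactly Poisson at any rate.

### Rates, rankings, sweeps

Trial-averaged rates are reported either as a scalar over a window
(spikes / (trials x window length)) or time-resolved in bins, smoothed with
a 25 ms Gaussian kernel by default. The "top responders" ranking statistic
is the mean rate over the analysis window, ties broken by ascending id,
with peak-of-smoothed-rate selectable — the window itself is a parameter
because heat-map and scalar comparisons legitimately differ. Rate sweeps
evaluate a full simulate-and-average per grid cell over two stimulation-rate
axes; with a silenced set the paired grid is computed in the silenced model
and the difference (silenced minus intact) reported, the sign convention
that makes release of inhibition non-negative.

## Gait pipeline

The treadmill ball is not tracked, so it is fitted as a sphere to the
tarsal-tip cloud: an algebraic linear least-squares estimate (Coope's
method) initializes a Levenberg–Marquardt refinement of the geometric
residual `||p - c|| - r`. Coplanar or near-coplanar clouds are rejected by a
singular-value test. Stance is a tip within 0.05% of the radius of the
surface. That band is read literally as a fractional band of 5e-4 x r; it is
suspiciously tight for real data, so it is a config scalar
(`stance_tol_frac`) and a 5% reading is one keyword away. Phases shorter
than 10 ms are merged, shortest first, into the longer flanking phase
(ties to the preceding phase); the output therefore never contains a
segment below the floor, which is asserted on adversarial fixtures.

The swing-initiation zone is the 25th percentile (forward walking, zone
below) or 75th percentile (backward, zone above) of femur–tibia angles at
swing onset, using linear interpolation between closest ranks so thresholds
are reproducible. A zone entry is a strict crossing (previous frame outside,
current inside); a trace starting inside counts once at its first frame. A
zone event contains a swing iff a swing onset falls within its half-open
interval. Trials with zero events report an undefined percentage (NaN,
flagged) and are meant to be excluded from averages.

Ball stop bouts are maximal runs of windowed mean speed below 0.8 mm/s
lasting at least 250 ms; the averaging window defaults to a 250 ms running
mean (the definition does not fix the windowing; instantaneous velocity is
one parameter away). Ball movement during grooming sums absolute rotational
speeds over the three axes — a signed sum could cancel — and the stability
readout is the standard deviation of the non-grooming legs' femur–tibia
angle per manually scored bout (bouts under two frames are flagged).
Frames are 0-based and all segment intervals half-open; coordinates are
world-frame mm with no assumed axis orientation.

## Arena pipeline

Heading is unwrapped before differencing; angular velocity is reported as
absolute value and rotation as its running time-integral, which makes
rotation additive over windows. Velocities are backward differences aligned
to the later frame; smoothing is a centered moving average. Pivots require
smoothed angular speed above two rotations per second (interpreted as
720 deg/s) and translational speed below 5 mm/s, both after 0.5 s smoothing.
The food-assay stop definition is smoothed speed below 2 mm/s for at least
ten frames; the free-walk variant exposes both the threshold and the
smoothing window (default 1.5 mm/s) because the source convention does not
disambiguate which constant is which. Trial metrics integrate path length
and rotation over [onset, onset + 2 s), including the window-closing frame
so a constant-speed trajectory covers exactly speed x horizon. The
preference index is the standard two-choice time-based index
(t_sucrose - t_blank) / (t_sucrose + t_blank), which is invariant to
resampling. Food-zone metrics validate that the supplied encounter frame is
the geometric first approach within 3 mm of the blob and restrict to
in-zone frames within 5 s after it.

## Fluorescence pipeline

Three dF/F baselines are implemented: mean of the 2 s pre-stimulation
window, 10th percentile of that window (robust when the baseline contains
activity), and median of the 300 ms before movement initiation. F0 must be
positive; dF/F is invariant to global gain. Response AUC is the trapezoidal
integral over 0–2 s post-stimulation. The ratiometric readout z-scores
dR/R of R = green/red against the recording-median baseline over the whole
recording; the baseline and z-scoring windows are package choices (per-bout
variants are not implemented) and multiplicative artifacts common to both
channels cancel exactly. Pixel-wise maps are plain Pearson correlations,
with constant pixels reported as 0 under a validity mask.
Activity–velocity cross-correlation normalizes by total variance over lags
in [-max_lag, +max_lag]; a positive lag means activity leads velocity.
Recordings are pooled by per-recording mean removal with cross-products
never straddling a boundary, and multi-rate alignment block-averages the
fast behavioral series down to the imaging clock rather than inventing
imaging samples. No smoothing is applied before the cross-correlation.

## Synthetic data

The generators produce the four input classes with machine-readable
ground-truth manifests (JSON documents) and are deterministic under a fixed
seed. Default scales mimic the real assays: 200 Hz pose, 50 Hz ball
tracker, 30 Hz arena video, a few Hz imaging, 150 Hz stimulation of
walking-command neurons and 50 Hz where a weaker drive is wanted. The
walk-OFF motif plants an excitatory walking group and a GABAergic halting
group converging on a descending-neuron readout, and its manifest predicts
the sign of co-stimulation and silencing effects, which the simulator
verifies. The gait generator places each leg's contact point on the true
sphere and lifts the tip along the radial direction during swing with a
half-sine profile (0.3 mm clearance); it warns when the clearance falls
below about three noise standard deviations, where recovery is no longer
guaranteed. Because swing tips hover above the surface, sphere-recovery
round trips fit the stance-only cloud (`stance_tips`). The generators
target structure, not realism: no tracker jitter models, occlusions,
photobleaching, or fitted parameters from real recordings, so passing
round trips demonstrate correctness of the definitions, not robustness to
real-world artifacts.

## Test problem sizes

The spike-exact oracle comparisons run 5-neuron motifs for 0.5 s trials
over 20 seeds; walk-OFF replication uses 30 generator seeds at 8 trials of
0.5 s; sweep checks use 2 x 3 grids at 6 trials; lag recovery uses 100
seeds of 2-minute recordings; brute-force agreement suites use 100
randomized fixtures per metric. These sizes were chosen to exercise the
contracts densely while keeping the default test run fast on one CPU.

## Known limitations

- Conductance-based synapses, plasticity, and multi-compartment neurons are
  out of scope; full-brain (130k-neuron) runs are supported in principle
  through the sparse path but not performance-tuned.
- The descending-neuron rate thresholds used for wiring-diagram display
  (10.3 and 20 Hz) are accepted as configurable constants with no derivation.
- Hemisphere labels are metadata only; no automatic mirror pairing.
- Autapses are retained as ordinary edges.
- Grooming bouts are consumed as input (manually scored), not detected.
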