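# Methods

## Substrate model

The chip model (`ChipSpec`) is a small set of resource constants: 512
neuron circuits, 256 hardware synapses (unsigned weight rows) per circuit,
2 synapses per signed weight (separate excitatory/inhibitory rows), 64
weight levels per synapse (6 bit), 64 event labels distinguishable per
synapse row, 2 events processed per interface clock cycle, and routing
fan-out stages (2, 32, 2, 256) whose product bounds a neuron's fan-out at
32 768.  All of these are overridable from YAML/JSON, and all planner
arithmetic is derived from them rather than hard-coded.

Circuit combining is restricted to powers of two (1, 2, 4, …, 512).  Pure
ceiling arithmetic would allocate 7 circuits for 784 signed inputs
(⌈1568/256⌉); the power-of-two rule allocates 8, which is what the
hardware's circuit-shorting topology supports and what both worked
examples require (8 circuits for fan-in 784, 4 for fan-in 484).  With this
rule `neurons_per_run(cpn) · cpn == n_circuits` holds exactly, which the
planner relies on.

`event_cycle_us` defaults to 8 ns: two events per 8 ns cycle matches a
250 MHz sustained event rate.  The membrane-recording ADC range is modeled
as a symmetric dimensionless interval (default ±2.0 around a leak of 0 and
threshold of 1); the true hardware range is calibration-dependent, so it is
a parameter, not a claim.

## Partition planner

A layer of `size` neurons with signed fan-in `f` gets
`cpn = circuits_per_neuron(f)` and runs in `⌈size / (512/cpn)⌉` parts;
`parts_override` can force more parts (used to model bandwidth-motivated
splitting — the planner does not itself predict bandwidth-driven splits,
it only enforces that an override is not below the resource minimum).
Layers are never co-placed: the readout always occupies its own run(s).

Sparse receptive-field projections map through shared synapse rows: one
row addresses up to 64 neurons via event labels, so a fan-in-27 projection
onto 484 neurons lays out as 8 blocks of 27×64 signed synapses.
Feasibility in one run requires enough neuron columns (neurons × circuits
≤ 512) and enough rows (blocks × fan-in × 2 ≤ 512, the two synapse
arrays).  Receptive-field grids use ceiling division with zero-padded
borders (⌈64/3⌉² = 484); border neurons keep the nominal kernel-volume
fan-in for planning even though some of their taps fall on padding.
Convolutions are handled by spatial unrolling: each output pixel of each
output channel is one neuron with kernel-volume fan-in.

## Execution graph

Populations carry an execution-instance annotation; every projection
crossing an instance boundary becomes a record/translate/playback link.
Scheduling is by topological generations of the instance DAG — instances
in one generation are mutually independent (concurrency-eligible on a
larger system) and generations run sequentially, so the number of stages
equals the longest dependency path.  Within a stage, instances run in
sorted id order for reproducibility.  Event timestamps cross instance
boundaries unchanged (streams are buffered, not real-time), and merged
streams are ordered by (sample, time, source, neuron) so ties are stable.

Within one instance, feed-forward projections act in the same lattice bin,
in topological population order; projections that close a cycle inside an
instance act with a one-bin delay.  Recurrence *across* instances is a
scheduling error: it would require concurrent emulation, which sequential
substrate reuse cannot provide.

Partition invariance — the property that a partitioned run is bit-identical
to a monolithic run of the same feed-forward dynamics — holds by
construction: events are rasterized identically on both paths, every layer
is integrated by the same kernel with the same matrix-product shapes, and
replayed events land in the bins they were recorded in.  The test suite
checks this exactly (no tolerance) on randomized networks.

## Dynamics and numerics

Synapses are current-based (CUBA).  Integration uses an exact per-bin
propagator: both exponential decays are exact over a bin, and the membrane
increment per unit of bin-start synaptic current is the analytically
integrated response kappa = (1/g_l)·τ_s/(τ_m−τ_s)·(a_m−a_s) (with the
τ_m = τ_s limit handled separately).  Events are assigned to bins by
floor(t/δt) and treated as impulses at the bin start, so for grid-aligned
events the single-spike subthreshold response is exact at the lattice
points, and for off-grid events the error is first order in δt.  The
recorded trace value at bin t is the membrane at time (t+1)·δt.  Spike
detection is per bin after the membrane update: all neurons at or above
threshold fire, reset to E_r, and (if τ_ref > 0) hold for the refractory
bins.  δt defaults to 0.5 µs and is configurable; the trainer requires
τ_ref = 0 (the default — the networks trained here use none).

Constrained mode quantizes each projection with round-half-to-even at a
scale that maps the largest |weight| to level 63 (overridable), passes
injected events through the bandwidth FIFO, and clips recorded traces to
the readout range.  The bandwidth model serves each cycle's backlog first,
then arrivals, two per cycle; surplus arrivals enter a bounded FIFO
(default depth 32, a parameter since the hardware queue depth is not
public) and overflow is dropped.  Kept + dropped always equals the input
count.

The hardware-in-the-loop trace scale factor is the least-squares scalar
a = Σ hw·ref / Σ hw² over unclipped bins, undefined (an error) when every
bin is clipped.

## Encoders

Linear TTFS: t = T − round(T/δt · (x − x_min)/(x_max − x_min))·δt with
round-half-to-even, x_min/x_max dataset-global.  A pixel at x_min maps to
t = T, which lies outside the half-open observation window [0, T) and is
therefore suppressed rather than emitted at the edge.  Current-based TTFS:
drive a = x + x_min_bias on a leaky membrane with infinite refractory
period; closed-form spike time −τ_en·ln(1 − ϑ_en/(τ_en·a)), silent when
the asymptote τ_en·a stays below ϑ_en.  These times are kept at full float
resolution (the event interface is far finer than δt); combined with
pre-encoding Gaussian jitter (clamped back to [0, 1]) this de-duplicates
quantized pixel values and reduces simultaneous events at the bandwidth
bottleneck.

## Training

BPTT is explicit reverse-mode differentiation through the unrolled
lattice, written against the same recursions the emulator integrates.  The
spike nonlinearity uses a hard threshold forward and the fast-sigmoid
surrogate derivative 1/(β|v−ϑ|+1)² backward (β configurable, default 10 —
the surrogate family is a design choice; nothing in the modeled training
procedure pins a specific function).  Gradients flow through the reset
(v⁺ = v + (E_r−v)·z) with the same surrogate.  For verification, a smooth
relaxation h(x) = 1/2 + x/(β|x|+1), whose derivative equals the surrogate
exactly, replaces the threshold so that finite differences of the smoothed
model check the backward sweep; the suite requires 1e-4 relative
agreement.

Constrained/mixed training substitutes recorded forward observables into
the ideal lattice (straight-through): the constrained emulator runs the
partitioned network and its recorded hidden spike trains replace the ideal
forward spikes, while membrane states and surrogate slopes come from the
ideal dynamics.  Evaluation under a constrained backend decodes the
constrained (clipped) readout traces.

The loss is cross-entropy over softmaxed decoded scores plus three
optional penalties: mean squared hidden spike count (firing rate), squared
excess of |readout trace| over a saturation bound, and squared excess of
|weight| over a range bound.  The penalty functional forms are this
package's choices; the three regularization targets themselves (rate,
readout saturation, weight range) are standard for keeping dynamics within
substrate limits.  Dropout masks hidden spikes without inverted scaling,
so the expected spike count injected downstream scales by (1−p).  Adam
defaults to lr 1e-3, betas (0.9, 0.999); schedules are constant,
per-epoch exponential decay, or halving at a configured epoch set; early
stopping tracks validation accuracy with a patience counter and the
best-on-validation weights are kept.  Metrics average over the configured
seed set.  All randomness flows from one experiment seed through named
sub-seeds (SHA-256 based, < 2³¹), making runs bitwise reproducible.

## Synthetic task

The fixture generator places one bright 2×2 blob per class at
class-disjoint positions on an 8×8 image (positions/intensities
configurable; overlapping supports are rejected), adds N(0, 0.05²) pixel
noise, and clamps to [0, 1].  Encoded with the linear TTFS scheme this is
a task whose classes are separable by which input neurons spike early —
deliberately easy, so that end-to-end learning failures indicate gradient
or execution bugs rather than task difficulty.  The standard evaluation
uses 96/48/48 train/val/test samples, a 24-neuron hidden layer, and 50
epochs, which trains in seconds.  What passing shows: the forward
dynamics, partitioned execution, substitution training and decoding are
consistent end to end, and constrained-mode artifacts (6-bit weights,
bandwidth FIFO, trace clipping) cost essentially no accuracy on a
well-margined task.  What it does not show: performance on natural-image
statistics, robustness to heavy bandwidth pressure, analog device
mismatch, or the accuracy of the published full-scale benchmarks — the
MNIST/EuroSAT presets describe those topologies and training setups, but
running them requires the datasets and long training, and the hardware
numbers additionally depend on the physical substrate.

## Known limitations

- The bandwidth FIFO serves events in deterministic FIFO order at cycle
  granularity; the real interface's arbitration details are not public.
- Constrained-mode trace clipping is applied to the recorded lattice
  samples, not within the analog dynamics (matching the role of a readout
  ADC, but not modeling saturation feedback on the membrane itself).
- Recurrent instances integrate bin-interleaved with one-bin delays on
  back edges and are supported in ideal mode; the bit-exact partition
  invariance claim covers feed-forward networks only (recurrence cannot
  cross instance boundaries at all).
- The trainer handles feed-forward chains; arbitrary DAG training is not
  implemented (the execution graph itself supports DAGs).
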