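# snnpart

Partitioned emulation of spiking neural networks that are larger than the
neuromorphic substrate they run on.

Analog neuromorphic chips allocate physical circuits per neuron and per
synapse, so a single chip caps both the neuron count and the synaptic fan-in
of any network it can emulate.  Feed-forward networks (and networks whose
recurrence fits inside one allocation) can nevertheless be run by
*partitioning*: split the network into execution instances that each fit the
substrate, run them sequentially while recording every boundary spike, and
play the recorded events back into dependent instances.  Because spikes are
events in time that can be recorded and replayed exactly, partitioning does
not change the emulated dynamics — it only costs wall-clock time.

This package models that workflow end to end, for a single-chip substrate
with (by default) 512 neuron circuits, 256 hardware synapses of fan-in per
circuit, two 6-bit synapses per signed weight, 64 event labels per synapse
row, and an event interface that handles two spikes per clock cycle:

- `snnpart.substrate` — the chip resource model and capacity arithmetic
  (circuit combining for large fan-in, neurons per run, fan-out/fan-in
  limits).
- `snnpart.planner` — partition planning: circuits per neuron, runs per
  layer, label-addressed sparse receptive-field layouts, convolution
  unrolling, and run-count projection for whole topologies.
- `snnpart.netgraph` — populations/projections annotated with execution
  instances, automatic derivation of inter-execution record/playback links,
  topological scheduling, and sequential partitioned execution.
- `snnpart.emulator` — leaky integrate-and-fire (LIF) and leaky-integrator
  (LI) dynamics on a fixed time lattice, in an `ideal` mode and in a
  `constrained` mode with 6-bit weight quantization, an event-bandwidth
  FIFO model, and range-clipped membrane recording.
- `snnpart.encoders` — two time-to-first-spike (TTFS) image encoders
  (linear latency code, and constant-current LIF encoder with bias and
  jitter).
- `snnpart.training` — surrogate-gradient backpropagation through time,
  max-over-time / last-value readout decodings, firing-rate, saturation and
  weight-range regularizers, and hardware-in-the-loop style training where
  the constrained forward observables are substituted into the ideal
  backward pass.
- `snnpart.synth` / `snnpart.config` / `snnpart.io` / `snnpart.cli` —
  synthetic fixture tasks, experiment configs and presets, event/trace
  file formats, manifests, and the `snnpart` command line.

## The model

Neuron dynamics are current-based LIF:

    τ_m dv/dt = −(v − E_l) + I/g_l,
    I(t) = Σ_i w_i Θ(t − t_i) exp(−(t − t_i)/τ_s),

integrated with an exact per-bin propagator on a lattice of step δt
(0.5 µs by default); a spike is emitted when v ≥ ϑ, with reset to E_r.
Readout neurons are leaky integrators whose membrane traces are decoded
into class scores s_k = max_t v_k(t) or s_k = v_k(T).  A signed fan-in of
`f` needs the smallest power of two `p` of combined neuron circuits with
`256·p ≥ 2·f`, leaving `512/p` logical neurons per run.

## Worked example

Plan the full-resolution 784 → 256 → 10 dense classifier on the default
chip:

```
$ snnpart plan --preset mnist
layer          size  fan-in  circ/nrn  nrn/run  runs
----------------------------------------------------
hidden          256     784         8       64     4
readout          10     256         2      256     1
total runs: 5
```

The 784 signed inputs need 2·784 = 1568 hardware synapses, i.e. 8 combined
circuits per neuron, so only 64 logical neurons fit per run and the
256-unit hidden layer splits into 4 parts; with the readout run that makes
5 sequential runs.  The sparse-input 12288 → 484 → 128 → 10 network
(`--preset eurosat`) plans to 10 runs: its first layer would fit in one run
through 64-label row sharing, but is split into 8 parts to reduce per-run
input bandwidth.

Training on the built-in synthetic 3-class TTFS task (no downloads):

```
$ snnpart train --preset synthetic --backend constrained --bandwidth-limit \
      --seed 1 --outdir out/
test accuracy 0.979; artifacts in out/
```

The synthetic task is separable by first-spike times, so even the
constrained backend (6-bit quantized weights, event bandwidth limit on)
classifies almost every test image correctly; `out/metrics.json` holds the
per-epoch history.

The full MNIST / EuroSAT experiments are shipped only as presets: they
need dataset downloads and long training runs, and the published hardware
accuracies additionally depend on the analog substrate itself, so they are
documented optional runs rather than tested ones.

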