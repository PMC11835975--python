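"""Numerical LIF/LI emulation standing in for the analog substrate.

Dynamics follow the current-based (CUBA) leaky integrate-and-fire model

    tau_m dv/dt = -(v - E_l) + I / g_l
    I(t) = sum_i w_i Theta(t - t_i) exp(-(t - t_i) / tau_s)

integrated with exponential Euler on a fixed lattice of step ``dt``: both
state decays are exact between bins and input events contribute impulse
increments at their bin.  Two modes are supported:

* ``ideal`` — float weights, no substrate artifacts; used for gradient
  estimation and as the fidelity reference.
* ``constrained`` — 6-bit signed weight quantization, an event-bandwidth
  limit on injected spikes, and range-clipped membrane recording; stands in
  for the analog chip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import UndefinedScaleError, ValidationError
from .substrate import ChipSpec

__all__ = [
    "LIFParams",
    "EventBatch",
    "TraceBatch",
    "integrate_instance",
    "integrate_layer",
    "quantize_weights",
    "dequantize_weights",
    "auto_scale",
    "apply_bandwidth_limit",
    "itl_scale_factor",
]


@dataclass(frozen=True)
class LIFParams:
    """Neuron parameters.  Times in µs; potentials and conductance in
    mutually consistent arbitrary units (defaults are dimensionless with
    leak at 0 and threshold at 1)."""

    tau_m: float = 10.0
    g_l: float = 1.0
    e_l: float = 0.0
    v_th: float = 1.0
    e_r: float = 0.0
    tau_s: float = 5.0
    tau_ref: float = 0.0
    leaky_integrate_only: bool = False

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.tau_s <= 0:
            raise ValidationError("tau_m and tau_s must be positive")
        if self.g_l <= 0:
            raise ValidationError("g_l must be positive")
        if self.tau_ref < 0:
            raise ValidationError("tau_ref must be >= 0")
        if not self.leaky_integrate_only and not self.v_th > self.e_r:
            raise ValidationError("spiking neurons require v_th > e_r")


@dataclass
class EventBatch:
    """A batch of timestamped spike events.

    ``samples``, ``times`` (µs) and ``neurons`` are parallel arrays; one row
    per event.  ``n_samples`` / ``n_neurons`` fix the batch and population
    sizes even when trailing samples or neurons are silent.
    """

    samples: np.ndarray
    times: np.ndarray
    neurons: np.ndarray
    n_samples: int
    n_neurons: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.neurons = np.asarray(self.neurons, dtype=np.int64)
        if not (len(self.samples) == len(self.times) == len(self.neurons)):
            raise ValidationError("event arrays must have equal length")
        if len(self.times) and (self.times < 0).any():
            raise ValidationError("event times must be non-negative")
        if len(self.neurons) and (
            (self.neurons < 0).any() or (self.neurons >= self.n_neurons).any()
        ):
            raise ValidationError("neuron indices out of range")

    @classmethod
    def empty(cls, n_samples: int, n_neurons: int) -> "EventBatch":
        z = np.zeros(0)
        return cls(z, z, z, n_samples, n_neurons)

    def __len__(self) -> int:
        return len(self.times)

    def sorted(self) -> "EventBatch":
        """Canonical order: (sample, time, neuron)."""
        order = np.lexsort((self.neurons, self.times, self.samples))
        return EventBatch(
            self.samples[order], self.times[order], self.neurons[order],
            self.n_samples, self.n_neurons,
        )

    def to_raster(self, n_bins: int, dt: float) -> np.ndarray:
        """Binary raster (n_samples, n_bins, n_neurons); bin = floor(t/dt).

        Events at or beyond ``n_bins * dt`` fall outside the window and are
        ignored.  Multiple events of one neuron in one bin collapse to one
        (a hardware synapse row transmits at most one spike per label per
        lattice step at this resolution).
        """
        raster = np.zeros((self.n_samples, n_bins, self.n_neurons))
        if len(self) == 0:
            return raster
        bins = np.floor(self.times / dt).astype(np.int64)
        keep = bins < n_bins
        raster[self.samples[keep], bins[keep], self.neurons[keep]] = 1.0
        return raster

    @classmethod
    def from_raster(cls, raster: np.ndarray, dt: float) -> "EventBatch":
        """Inverse of :meth:`to_raster`; event times are bin starts."""
        s, b, n = np.nonzero(raster)
        return cls(s, b * dt, n, raster.shape[0], raster.shape[2])

    @staticmethod
    def merge(batches: list["EventBatch"], n_samples: int, n_neurons: int) -> "EventBatch":
        """Merge streams; ties broken by (time, position in ``batches``, neuron)."""
        if not batches:
            return EventBatch.empty(n_samples, n_neurons)
        samples = np.concatenate([b.samples for b in batches])
        times = np.concatenate([b.times for b in batches])
        neurons = np.concatenate([b.neurons for b in batches])
        source = np.concatenate(
            [np.full(len(b), i, dtype=np.int64) for i, b in enumerate(batches)]
        )
        order = np.lexsort((neurons, source, times, samples))
        return EventBatch(samples[order], times[order], neurons[order], n_samples, n_neurons)


@dataclass
class TraceBatch:
    """Membrane traces on the dt lattice: shape (n_samples, n_bins, n_neurons)."""

    values: np.ndarray
    dt: float
    clipped: np.ndarray | None = None  # per-sample flag, constrained mode only

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


# --------------------------------------------------------------------------
# weight quantization
# --------------------------------------------------------------------------

def quantize_weights(w: np.ndarray, scale: float, weight_levels: int = 64) -> np.ndarray:
    """Map real weights to signed integers in ±(weight_levels − 1).

    ``round(w * scale)`` (round-half-to-even) clipped to the 6-bit signed
    range; the value used in constrained dynamics is the integer divided by
    ``scale``.
    """
    if scale <= 0:
        raise ValidationError("quantization scale must be positive")
    w = np.asarray(w, dtype=np.float64)
    if not np.isfinite(w).all():
        raise ValidationError("weights must be finite")
    wmax = weight_levels - 1
    return np.clip(np.round(w * scale), -wmax, wmax).astype(np.int64)


def dequantize_weights(q: np.ndarray, scale: float) -> np.ndarray:
    return np.asarray(q, dtype=np.float64) / scale


def auto_scale(w: np.ndarray, weight_levels: int = 64) -> float:
    """Scale mapping the largest |weight| onto the top quantization level."""
    amax = float(np.max(np.abs(w))) if np.asarray(w).size else 0.0
    return (weight_levels - 1) / amax if amax > 0 else 1.0


# --------------------------------------------------------------------------
# event bandwidth model
# --------------------------------------------------------------------------

def apply_bandwidth_limit(
    events: EventBatch,
    spec: ChipSpec = ChipSpec(),
    cycle: float | None = None,
    queue_depth: int = 32,
) -> tuple[EventBatch, int]:
    """FIFO model of the event interface: limited sends per clock cycle.

    Per sample, events are binned by ``cycle`` (default: the spec's event
    clock).  Each cycle transmits at most ``max_events_per_cycle`` spikes,
    backlog first; surplus arrivals enter a bounded FIFO (``queue_depth``)
    and are sent, delayed, in following cycles; arrivals finding the queue
    full are dropped.  Returns the kept (possibly delayed) events and the
    drop count; kept + dropped equals the input count.
    """
    cycle = spec.event_cycle_us if cycle is None else cycle
    if cycle <= 0:
        raise ValidationError("cycle must be positive")
    if len(events) == 0:
        return EventBatch.empty(events.n_samples, events.n_neurons), 0

    ev = events.sorted()
    out_s, out_t, out_n = [], [], []
    dropped = 0
    cap = spec.max_events_per_cycle
    for s in range(ev.n_samples):
        mask = ev.samples == s
        times = ev.times[mask]
        neurons = ev.neurons[mask]
        if len(times) == 0:
            continue
        cycles = np.floor(times / cycle).astype(np.int64)
        queue: list[tuple[float, int]] = []
        i = 0
        c = int(cycles[0]) if len(cycles) else 0
        n_ev = len(times)
        while i < n_ev or queue:
            budget = cap
            # backlog is served first, delayed to the current cycle start
            while queue and budget:
                t0, n0 = queue.pop(0)
                out_s.append(s); out_t.append(max(t0, c * cycle)); out_n.append(n0)
                budget -= 1
            while i < n_ev and cycles[i] == c:
                if budget:
                    out_s.append(s); out_t.append(times[i]); out_n.append(neurons[i])
                    budget -= 1
                elif len(queue) < queue_depth:
                    queue.append((times[i], int(neurons[i])))
                else:
                    dropped += 1
                i += 1
            if queue:
                c += 1
            elif i < n_ev:
                c = int(cycles[i])
    kept = EventBatch(
        np.array(out_s), np.array(out_t), np.array(out_n),
        ev.n_samples, ev.n_neurons,
    ).sorted()
    assert len(kept) + dropped == len(events)
    return kept, dropped


# --------------------------------------------------------------------------
# integration kernels
# --------------------------------------------------------------------------

def lif_coefficients(params: LIFParams, dt: float) -> tuple[float, float, float]:
    """Per-bin propagation constants (a_s, a_m, kappa).

    Both decays are exact over one bin; ``kappa`` is the exact membrane
    increment per unit of bin-start synaptic current, obtained by
    analytically integrating the exponentially decaying current against the
    membrane kernel:

        kappa = (1/g_l) * tau_s/(tau_m - tau_s) * (a_m - a_s)

    (limit ``(dt/tau_m) * a_m / g_l`` when the time constants coincide).
    With input events aligned to bin starts the single-event subthreshold
    response is then exact on the lattice; the recorded value at bin ``t``
    is the membrane at time ``(t+1)*dt``.
    """
    a_s = math.exp(-dt / params.tau_s)
    a_m = math.exp(-dt / params.tau_m)
    if params.tau_m == params.tau_s:
        kappa = dt / params.tau_m * a_m / params.g_l
    else:
        kappa = params.tau_s / (params.tau_m - params.tau_s) * (a_m - a_s) / params.g_l
    return a_s, a_m, kappa


def integrate_layer(
    drive: np.ndarray,
    params: LIFParams,
    dt: float,
    return_states: bool = False,
):
    """Exponential-Euler integration of one population.

    ``drive[b, t, n]`` is the summed synaptic weight arriving in bin ``t``
    (impulse increments to the synaptic current).  Returns ``(v_rec, z)``
    where ``v_rec`` are the pre-reset membrane values recorded per bin and
    ``z`` the binary spike raster (all zeros for leaky integrators).  With
    ``return_states`` the synaptic current and post-reset membrane are
    returned too (needed by BPTT).
    """
    B, n_bins, N = drive.shape
    a_s, a_m, c = lif_coefficients(params, dt)
    ref_bins = int(round(params.tau_ref / dt)) if params.tau_ref > 0 else 0

    I = np.zeros((B, N))
    v = np.full((B, N), params.e_l)
    refrac = np.zeros((B, N), dtype=np.int64)

    v_rec = np.empty((B, n_bins, N))
    z_rec = np.zeros((B, n_bins, N))
    I_rec = np.empty((B, n_bins, N)) if return_states else None
    v_post_rec = np.empty((B, n_bins, N)) if return_states else None

    spiking = not params.leaky_integrate_only
    for t in range(n_bins):
        I = a_s * I + drive[:, t, :]
        v = params.e_l + (v - params.e_l) * a_m + c * I
        if ref_bins:
            held = refrac > 0
            v = np.where(held, params.e_r, v)
            refrac = np.maximum(refrac - 1, 0)
        v_rec[:, t, :] = v
        if spiking:
            z = (v >= params.v_th).astype(np.float64)
            z_rec[:, t, :] = z
            v = v + (params.e_r - v) * z
            if ref_bins:
                refrac = np.where(z > 0, ref_bins, refrac)
        if return_states:
            I_rec[:, t, :] = I
            v_post_rec[:, t, :] = v
    if return_states:
        return v_rec, z_rec, I_rec, v_post_rec
    return v_rec, z_rec


def integrate_instance(
    events: EventBatch,
    weights: np.ndarray,
    params: LIFParams,
    T: float,
    dt: float,
    mode: str = "ideal",
    spec: ChipSpec = ChipSpec(),
    weight_scale: float | None = None,
    bandwidth_limit: bool = True,
    queue_depth: int = 32,
) -> tuple[EventBatch, TraceBatch, int]:
    """Run one execution instance: input events through ``weights`` into one
    population of identical neurons.

    In ``constrained`` mode the weights are quantized to the substrate's
    levels (``weight_scale`` defaults to mapping max |w| to the top level),
    injected events pass the bandwidth limit, and recorded traces are clipped
    to the readout range.  Returns (output events, traces, dropped events).
    """
    if mode not in ("ideal", "constrained"):
        raise ValidationError(f"mode must be 'ideal' or 'constrained', got {mode!r}")
    weights = np.asarray(weights, dtype=np.float64)
    if not np.isfinite(weights).all():
        raise ValidationError("weights must be finite")
    if weights.shape[0] != events.n_neurons:
        raise ValidationError(
            f"weights fan-in {weights.shape[0]} != event population {events.n_neurons}"
        )
    n_bins = math.ceil(T / dt)
    dropped = 0
    if mode == "constrained":
        if bandwidth_limit:
            events, dropped = apply_bandwidth_limit(events, spec, queue_depth=queue_depth)
        scale = auto_scale(weights, spec.weight_levels) if weight_scale is None else weight_scale
        weights = dequantize_weights(quantize_weights(weights, scale, spec.weight_levels), scale)
    raster = events.to_raster(n_bins, dt)
    drive = raster @ weights
    v_rec, z = integrate_layer(drive, params, dt)
    clipped = None
    if mode == "constrained":
        lo, hi = spec.readout_range
        clipped = ((v_rec < lo) | (v_rec > hi)).any(axis=(1, 2))
        v_rec = np.clip(v_rec, lo, hi)
    out = EventBatch.from_raster(z, dt)
    return out, TraceBatch(v_rec, dt, clipped), dropped


# --------------------------------------------------------------------------
# hardware-in-the-loop trace scaling
# --------------------------------------------------------------------------

def itl_scale_factor(
    hw: np.ndarray,
    ref: np.ndarray,
    readout_range: tuple[float, float] | None = None,
) -> float:
    """Least-squares scalar ``a`` minimizing ||a·hw − ref||² over unclipped bins.

    Maps recorded (hardware-like) membrane dynamics onto the idealized
    software dynamics used for gradient estimation.  Bins where ``hw`` sits
    at the readout clipping bounds are excluded.
    """
    hw = np.asarray(hw, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if hw.shape != ref.shape:
        raise ValidationError("trace shapes must match")
    mask = np.ones(hw.shape, dtype=bool)
    if readout_range is not None:
        lo, hi = readout_range
        mask = (hw > lo) & (hw < hi)
    denom = float(np.sum(hw[mask] ** 2))
    if not mask.any() or denom == 0.0:
        raise UndefinedScaleError("scale factor undefined: all bins clipped or zero")
    return float(np.sum(hw[mask] * ref[mask]) / denom)
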