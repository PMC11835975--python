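"""Execution-instance graph: partitioned networks and their sequential runs.

A network is a set of populations and projections, each population annotated
with the execution instance it is placed on.  Projections whose endpoints
live on different instances become inter-execution projections: the source
instance's spikes are recorded, translated on the host, and played back into
the target instance.  Instances are run in topological stages; instances in
one stage have no mutual dependency and could run concurrently on a larger
substrate, sequential reuse of one substrate runs them one after another —
the two are equivalent because event streams are buffered, not real-time.

Within one instance, feed-forward projections propagate in the same lattice
bin (signals travel through the synapse array continuously); projections
that close a cycle inside an instance (recurrence) use the previous bin's
spikes.  Recurrence across instances is rejected: it would need concurrent
emulation, which a sequential substrate cannot provide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .emulator import (
    EventBatch,
    TraceBatch,
    LIFParams,
    apply_bandwidth_limit,
    auto_scale,
    dequantize_weights,
    integrate_layer,
    lif_coefficients,
    quantize_weights,
)
from .errors import ConfigurationError, SchedulingError, ValidationError
from .substrate import ChipSpec

__all__ = [
    "Population",
    "Projection",
    "ExecutionInstance",
    "InterExecutionProjection",
    "Network",
    "derive_inter_execution",
    "schedule",
    "run",
    "RunResult",
]


@dataclass
class Population:
    name: str
    size: int
    params: LIFParams = field(default_factory=LIFParams)
    execution_instance: str | None = None
    is_input: bool = False
    record_spikes: bool = True
    record_membrane: bool = False

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValidationError(f"population {self.name!r}: size must be >= 1")


@dataclass
class Projection:
    """Synaptic projection; ``weights`` is a dense (src_size, tgt_size) matrix.

    Sparse connectivity (receptive fields, explicit pair lists) is expressed
    through zeros in the matrix; ``connectivity`` records the intent for
    planning and serialization.
    """

    source: str
    target: str
    weights: np.ndarray
    connectivity: str = "dense"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 2:
            raise ValidationError("projection weights must be a 2-D matrix")
        if not np.isfinite(self.weights).all():
            raise ValidationError(
                f"projection {self.source}->{self.target}: weights must be finite"
            )

    @classmethod
    def from_pairs(
        cls, source: str, target: str, src_size: int, tgt_size: int,
        pairs: list[tuple[int, int, float]],
    ) -> "Projection":
        w = np.zeros((src_size, tgt_size))
        for i, j, wij in pairs:
            if not (0 <= i < src_size and 0 <= j < tgt_size):
                raise ValidationError(
                    f"projection {source}->{target}: pair ({i},{j}) out of range"
                )
            w[i, j] = wij
        return cls(source, target, w, connectivity="explicit")


@dataclass
class ExecutionInstance:
    id: str
    populations: list[str]
    spec: ChipSpec = field(default_factory=ChipSpec)
    backend: str = "ideal"  # 'ideal' | 'constrained'


@dataclass
class InterExecutionProjection:
    """Record/translate/playback link between two instances.

    ``translation`` maps source neuron id to the event label under which the
    replayed spike enters the target instance (identity by default; the host
    does the translation, so routing constraints of the two instances are
    decoupled).
    """

    source_instance: str
    target_instance: str
    projection: Projection
    translation: dict[int, int]


@dataclass
class Network:
    populations: dict[str, Population]
    projections: list[Projection]
    instances: dict[str, ExecutionInstance] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for proj in self.projections:
            for end in (proj.source, proj.target):
                if end not in self.populations:
                    raise ConfigurationError(f"projection references unknown population {end!r}")
            src, tgt = self.populations[proj.source], self.populations[proj.target]
            if proj.weights.shape != (src.size, tgt.size):
                raise ConfigurationError(
                    f"projection {proj.source}->{proj.target}: weight shape "
                    f"{proj.weights.shape} != ({src.size}, {tgt.size})"
                )
        if not self.instances:
            self._build_instances()

    def _build_instances(self) -> None:
        for pop in self.populations.values():
            if pop.is_input:
                continue
            if pop.execution_instance is None:
                raise ConfigurationError(
                    f"population {pop.name!r} is not assigned to an execution instance"
                )
            inst = self.instances.setdefault(
                pop.execution_instance,
                ExecutionInstance(pop.execution_instance, []),
            )
            inst.populations.append(pop.name)

    @classmethod
    def chain(
        cls,
        sizes: list[int],
        weights: list[np.ndarray],
        hidden_params: LIFParams,
        readout_params: LIFParams | None = None,
        partitioned: bool = True,
        backend: str = "ideal",
        spec: ChipSpec | None = None,
    ) -> "Network":
        """Convenience constructor for a feed-forward chain
        input → hidden… → readout (leaky-integrator readout).

        ``partitioned=True`` puts each non-input layer in its own execution
        instance; otherwise the whole chain shares one instance.
        """
        if len(weights) != len(sizes) - 1:
            raise ConfigurationError("need one weight matrix per projection")
        if readout_params is None:
            readout_params = LIFParams(
                tau_m=hidden_params.tau_m, g_l=hidden_params.g_l,
                e_l=hidden_params.e_l, tau_s=hidden_params.tau_s,
                leaky_integrate_only=True,
            )
        pops: dict[str, Population] = {}
        names = []
        for i, size in enumerate(sizes):
            if i == 0:
                name = "input"
                pops[name] = Population(name, size, is_input=True)
            else:
                is_readout = i == len(sizes) - 1
                name = "readout" if is_readout else f"hidden{i}"
                inst = name if partitioned else "all"
                pops[name] = Population(
                    name, size,
                    params=readout_params if is_readout else hidden_params,
                    execution_instance=inst,
                    record_membrane=is_readout,
                )
            names.append(name)
        projs = [
            Projection(names[i], names[i + 1], weights[i]) for i in range(len(weights))
        ]
        net = cls(pops, projs)
        for inst in net.instances.values():
            inst.backend = backend
            if spec is not None:
                inst.spec = spec
        return net

    def instance_of(self, pop_name: str) -> str | None:
        return self.populations[pop_name].execution_instance


def derive_inter_execution(network: Network) -> list[InterExecutionProjection]:
    """Extract the record/playback links implied by the instance annotation.

    One link per projection whose endpoints live on different instances
    (projections from input populations are stimuli, not links).
    """
    links = []
    for proj in network.projections:
        src_pop = network.populations[proj.source]
        tgt_pop = network.populations[proj.target]
        if src_pop.is_input:
            continue
        if tgt_pop.is_input:
            raise ConfigurationError(f"projection targets input population {tgt_pop.name!r}")
        src_inst = src_pop.execution_instance
        tgt_inst = tgt_pop.execution_instance
        if src_inst is None or tgt_inst is None:
            raise ConfigurationError("all non-input populations need an instance assignment")
        if src_inst != tgt_inst:
            links.append(
                InterExecutionProjection(
                    src_inst, tgt_inst, proj,
                    translation={i: i for i in range(src_pop.size)},
                )
            )
    return links


def schedule(network: Network) -> list[list[str]]:
    """Topological stages of the instance DAG.

    Instances within one stage have no mutual dependency and are
    concurrency-eligible; stages run sequentially.  Within a stage the order
    is deterministic (sorted by instance id).  A cycle between instances
    means recurrence spans executions, which sequential emulation cannot
    honor.
    """
    g = nx.DiGraph()
    g.add_nodes_from(network.instances)
    for link in derive_inter_execution(network):
        g.add_edge(link.source_instance, link.target_instance)
    if not nx.is_directed_acyclic_graph(g):
        raise SchedulingError(
            "recurrent dependency between execution instances; recurrence must "
            "be confined to a single instance"
        )
    return [sorted(gen) for gen in nx.topological_generations(g)]


@dataclass
class RunResult:
    """Observables of one partitioned run, keyed by instance and population."""

    events: dict[str, dict[str, EventBatch]]
    traces: dict[str, dict[str, TraceBatch]]
    dropped: dict[str, int]
    schedule: list[list[str]]

    def spikes(self, pop: str) -> EventBatch:
        for per_inst in self.events.values():
            if pop in per_inst:
                return per_inst[pop]
        raise KeyError(pop)

    def trace(self, pop: str) -> TraceBatch:
        for per_inst in self.traces.values():
            if pop in per_inst:
                return per_inst[pop]
        raise KeyError(pop)


def _instance_pop_order(network: Network, inst: ExecutionInstance) -> tuple[list[str], set]:
    """Topological order of an instance's populations; returns (order,
    back_edges) where back edges are within-instance projections that close a
    cycle and therefore act with one-bin delay."""
    members = set(inst.populations)
    g = nx.DiGraph()
    g.add_nodes_from(sorted(members))
    internal = [
        p for p in network.projections
        if p.source in members and p.target in members
    ]
    back = set()
    for p in internal:
        g.add_edge(p.source, p.target)
    try:
        order = [n for n in nx.lexicographical_topological_sort(g)]
        return order, back
    except nx.NetworkXUnfeasible:
        # recurrent instance: break cycles greedily, flagged edges get one-bin delay
        g2 = nx.DiGraph()
        g2.add_nodes_from(sorted(members))
        for p in internal:
            g2.add_edge(p.source, p.target)
            if not nx.is_directed_acyclic_graph(g2):
                g2.remove_edge(p.source, p.target)
                back.add((p.source, p.target))
        order = [n for n in nx.lexicographical_topological_sort(g2)]
        return order, back


def _run_instance(
    network: Network,
    inst: ExecutionInstance,
    ext_rasters: dict[str, np.ndarray],
    n_bins: int,
    dt: float,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], int]:
    """Integrate all populations of one instance.

    ``ext_rasters`` supplies the spike rasters of populations outside the
    instance (stimuli and replayed events).  Returns spike rasters and
    membrane traces per member population plus the dropped-event count.
    """
    constrained = inst.backend == "constrained"
    spec = inst.spec
    order, back_edges = _instance_pop_order(network, inst)
    rasters: dict[str, np.ndarray] = dict(ext_rasters)
    traces: dict[str, np.ndarray] = {}
    n_samples = next(iter(ext_rasters.values())).shape[0] if ext_rasters else 1
    dropped = 0

    def weight_of(proj: Projection) -> np.ndarray:
        if not constrained:
            return proj.weights
        scale = auto_scale(proj.weights, spec.weight_levels)
        return dequantize_weights(
            quantize_weights(proj.weights, scale, spec.weight_levels), scale
        )

    if back_edges:
        dropped += _run_instance_recurrent(
            network, inst, order, back_edges, rasters, traces, n_bins, dt, weight_of
        )
    else:
        for name in order:
            pop = network.populations[name]
            incoming = [p for p in network.projections if p.target == name]
            drive = np.zeros((n_samples, n_bins, pop.size))
            for proj in incoming:
                if proj.source not in rasters:
                    raise ConfigurationError(
                        f"no spike data for source population {proj.source!r} "
                        f"feeding {name!r}"
                    )
                drive += rasters[proj.source] @ weight_of(proj)
            v, z = integrate_layer(drive, pop.params, dt)
            if constrained:
                lo, hi = spec.readout_range
                v = np.clip(v, lo, hi)
            rasters[name] = z
            traces[name] = v
    return (
        {n: rasters[n] for n in inst.populations},
        traces,
        dropped,
    )


def _run_instance_recurrent(
    network, inst, order, back_edges, rasters, traces, n_bins, dt, weight_of
) -> int:
    """Bin-interleaved integration for instances with internal recurrence.
    Back-edge projections read the previous bin's spikes."""
    members = list(order)
    pops = {n: network.populations[n] for n in members}
    n_samples = next(iter(rasters.values())).shape[0]
    state = {}
    for n in members:
        p = pops[n].params
        state[n] = {
            "I": np.zeros((n_samples, pops[n].size)),
            "v": np.full((n_samples, pops[n].size), p.e_l),
            "z_prev": np.zeros((n_samples, pops[n].size)),
        }
        rasters[n] = np.zeros((n_samples, n_bins, pops[n].size))
        traces[n] = np.zeros((n_samples, n_bins, pops[n].size))
    for t in range(n_bins):
        for n in members:
            p = pops[n].params
            a_s, a_m, c = lif_coefficients(p, dt)
            drive = np.zeros((n_samples, pops[n].size))
            for proj in network.projections:
                if proj.target != n:
                    continue
                w = weight_of(proj)
                if (proj.source, proj.target) in back_edges:
                    drive += state[proj.source]["z_prev"] @ w
                elif proj.source in state:
                    drive += rasters[proj.source][:, t, :] @ w
                else:
                    drive += rasters[proj.source][:, t, :] @ w
            st = state[n]
            st["I"] = a_s * st["I"] + drive
            st["v"] = p.e_l + (st["v"] - p.e_l) * a_m + c * st["I"]
            traces[n][:, t, :] = st["v"]
            if not p.leaky_integrate_only:
                z = (st["v"] >= p.v_th).astype(np.float64)
                rasters[n][:, t, :] = z
                st["v"] = st["v"] + (p.e_r - st["v"]) * z
        for n in members:
            state[n]["z_prev"] = rasters[n][:, t, :]
    return 0


def run(
    network: Network,
    stimuli: dict[str, EventBatch],
    T: float,
    dt: float,
    bandwidth_limit: bool = False,
    queue_depth: int = 32,
) -> RunResult:
    """Execute a partitioned network sequentially, stage by stage.

    Each instance's output spikes are recorded as events (timestamps are bin
    starts), translated on the host, and played back unchanged into
    dependent instances — buffering makes sequential and concurrent
    execution equivalent.  ``bandwidth_limit`` additionally applies the
    event-interface FIFO model to events injected into constrained
    instances.
    """
    stages = schedule(network)
    links = derive_inter_execution(network)
    n_bins = math.ceil(T / dt)

    input_pops = [p for p in network.populations.values() if p.is_input]
    for pop in input_pops:
        if pop.name not in stimuli:
            raise ConfigurationError(f"missing stimulus for input population {pop.name!r}")
    n_samples = next(iter(stimuli.values())).n_samples if stimuli else 1

    recorded_events: dict[str, EventBatch] = dict(stimuli)
    result = RunResult(events={}, traces={}, dropped={}, schedule=stages)

    for stage in stages:
        for inst_id in stage:
            inst = network.instances[inst_id]
            members = set(inst.populations)
            # populations outside this instance that feed it
            ext_sources: dict[str, list] = {}
            for proj in network.projections:
                if proj.target in members and proj.source not in members:
                    ext_sources.setdefault(proj.source, [])
            ext_rasters: dict[str, np.ndarray] = {}
            dropped = 0
            incoming_links = [l for l in links if l.target_instance == inst_id]
            for src_name in ext_sources:
                if src_name not in recorded_events:
                    raise ConfigurationError(
                        f"instance {inst_id!r} needs events from {src_name!r} "
                        "which have not been recorded yet"
                    )
                ev = recorded_events[src_name]
                if inst.backend == "constrained" and bandwidth_limit:
                    ev, d = apply_bandwidth_limit(ev, inst.spec, queue_depth=queue_depth)
                    dropped += d
                ext_rasters[src_name] = ev.to_raster(n_bins, dt)
            try:
                rasters, traces, d2 = _run_instance(
                    network, inst, ext_rasters, n_bins, dt
                )
            except Exception as exc:  # annotate backend failures with the instance id
                raise type(exc)(f"[instance {inst_id}] {exc}") from exc
            dropped += d2
            result.events[inst_id] = {}
            result.traces[inst_id] = {}
            result.dropped[inst_id] = dropped
            for name in inst.populations:
                pop = network.populations[name]
                ev = EventBatch.from_raster(rasters[name], dt)
                recorded_events[name] = ev  # host-side record for playback
                if pop.record_spikes:
                    result.events[inst_id][name] = ev
                if pop.record_membrane:
                    result.traces[inst_id][name] = TraceBatch(traces[name], dt)
    return result
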