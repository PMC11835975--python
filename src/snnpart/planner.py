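"""Partition planner: how a layered network splits into single-substrate runs.

Given layer sizes and per-neuron signed fan-in, the planner decides how many
circuits each logical neuron needs, how many neurons therefore fit into one
run, and how many sequential runs each layer (and the whole network) costs.
It also handles sparse receptive-field layers, which map through shared
synapse rows addressed by event labels, and spatial unrolling of
convolutional layers (each output pixel becomes one neuron with kernel-volume
fan-in).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ValidationError
from .substrate import ChipSpec, circuits_per_neuron, neurons_per_run

__all__ = [
    "LayerPlan",
    "PartitionPlan",
    "SparseBlockLayout",
    "plan_layer",
    "plan_network",
    "sparse_label_fit",
    "receptive_field_grid",
    "unroll_conv",
    "project_runs",
]


@dataclass(frozen=True)
class LayerPlan:
    name: str
    size: int
    fan_in_signed: int
    circuits_per_neuron: int
    neurons_per_run: int
    n_runs: int
    parts_override: int | None = None

    def as_row(self) -> dict:
        return {
            "layer": self.name,
            "size": self.size,
            "fan_in": self.fan_in_signed,
            "circuits/neuron": self.circuits_per_neuron,
            "neurons/run": self.neurons_per_run,
            "runs": self.n_runs,
        }


@dataclass(frozen=True)
class PartitionPlan:
    layers: tuple[LayerPlan, ...]

    @property
    def total_runs(self) -> int:
        return sum(lp.n_runs for lp in self.layers)

    def table(self) -> str:
        """Human-readable per-layer table, used by the ``plan`` CLI subcommand."""
        header = f"{'layer':<12}{'size':>7}{'fan-in':>8}{'circ/nrn':>10}{'nrn/run':>9}{'runs':>6}"
        lines = [header, "-" * len(header)]
        for lp in self.layers:
            lines.append(
                f"{lp.name:<12}{lp.size:>7}{lp.fan_in_signed:>8}"
                f"{lp.circuits_per_neuron:>10}{lp.neurons_per_run:>9}{lp.n_runs:>6}"
            )
        lines.append(f"total runs: {self.total_runs}")
        return "\n".join(lines)


def plan_layer(
    size: int,
    fan_in_signed: int,
    spec: ChipSpec = ChipSpec(),
    parts_override: int | None = None,
    name: str = "layer",
) -> LayerPlan:
    """Plan one layer: circuits per neuron, neurons per run, number of runs.

    ``parts_override`` forces at least that many parts; it models splitting a
    layer beyond the resource minimum to reduce per-run input bandwidth.
    """
    if size < 1:
        raise ValidationError(f"layer size must be >= 1, got {size}")
    cpn = circuits_per_neuron(fan_in_signed, spec)
    npr = neurons_per_run(cpn, spec)
    n_runs = math.ceil(size / npr)
    if parts_override is not None:
        if parts_override < n_runs:
            raise ValidationError(
                f"parts_override={parts_override} below resource minimum {n_runs}"
            )
        n_runs = parts_override
    return LayerPlan(name, size, fan_in_signed, cpn, npr, n_runs, parts_override)


def plan_network(
    layers: list[tuple],
    spec: ChipSpec = ChipSpec(),
    overrides: dict[str | int, int] | None = None,
) -> PartitionPlan:
    """Plan a layered network given ``[(name, size, fan_in_signed), ...]``.

    ``layers`` entries may also be ``(size, fan_in)`` pairs, in which case
    layers are named by index.  ``overrides`` maps layer name (or index) to a
    ``parts_override``.  The readout layer is planned like any other layer but
    always occupies its own run(s): layers are never co-placed.
    """
    overrides = overrides or {}
    plans = []
    for i, entry in enumerate(layers):
        if len(entry) == 3:
            name, size, fan_in = entry
        else:
            size, fan_in = entry
            name = f"layer{i}"
        po = overrides.get(name, overrides.get(i))
        plans.append(plan_layer(size, fan_in, spec, parts_override=po, name=name))
    return PartitionPlan(tuple(plans))


@dataclass(frozen=True)
class SparseBlockLayout:
    """Block layout of a sparse receptive-field projection on the synapse array."""

    rows_per_block: int
    neurons_per_block: int
    n_blocks: int
    feasible: bool


def sparse_label_fit(
    receptive_field_size: int,
    n_neurons: int,
    spec: ChipSpec = ChipSpec(),
) -> SparseBlockLayout:
    """Lay out a sparse projection in blocks of (receptive field × label count).

    One synapse row distinguishes ``labels_per_row`` event labels, so a block
    of ``receptive_field_size`` signed rows can feed up to that many neurons.
    Feasibility in a single run requires enough neuron columns for all
    neurons (one circuit each at this small fan-in) and enough synapse rows
    for all blocks.
    """
    if receptive_field_size < 1:
        raise ValidationError("receptive_field_size must be >= 1")
    if n_neurons < 1:
        raise ValidationError("n_neurons must be >= 1")
    neurons_per_block = spec.labels_per_row
    n_blocks = math.ceil(n_neurons / neurons_per_block)
    cpn = circuits_per_neuron(receptive_field_size, spec)
    total_rows = 2 * spec.fan_in_per_circuit  # two synapse arrays (top/bottom)
    rows_needed = n_blocks * receptive_field_size * spec.synapses_per_signed_weight
    feasible = n_neurons * cpn <= spec.n_circuits and rows_needed <= total_rows
    return SparseBlockLayout(
        rows_per_block=receptive_field_size,
        neurons_per_block=neurons_per_block,
        n_blocks=n_blocks,
        feasible=feasible,
    )


def receptive_field_grid(
    input_shape: tuple[int, int, int],
    kernel: tuple[int, int, int],
    stride: int,
) -> tuple[int, list[list[int]]]:
    """Tile an H×W×C input with kh×kw×kc receptive fields at the given stride.

    The grid uses ceiling division with zero-padded borders: grid side
    ``ceil(H/stride)`` (likewise for W), so every spatial position is covered.
    Returns the neuron count and, per neuron, the flat indices (row-major
    H, W, C) of its in-bounds input pixels; padded positions contribute no
    index.  With stride >= kernel the per-neuron index sets are disjoint.
    """
    if stride < 1:
        raise ValidationError(f"stride must be >= 1, got {stride}")
    H, W, C = input_shape
    kh, kw, kc = kernel
    if kh > H or kw > W or kc > C:
        raise ValidationError(f"kernel {kernel} exceeds input {input_shape}")
    grid_h = math.ceil(H / stride)
    grid_w = math.ceil(W / stride)
    index_lists: list[list[int]] = []
    for gy in range(grid_h):
        for gx in range(grid_w):
            idx = []
            for dy in range(kh):
                y = gy * stride + dy
                if y >= H:
                    continue
                for dx in range(kw):
                    x = gx * stride + dx
                    if x >= W:
                        continue
                    for c in range(kc):
                        idx.append((y * W + x) * C + c)
            index_lists.append(idx)
    return grid_h * grid_w, index_lists


def unroll_conv(
    input_shape: tuple[int, int, int],
    kernel_hw: tuple[int, int],
    out_channels: int,
    stride: int,
) -> tuple[int, int]:
    """Spatially unroll a convolution: (neuron count, per-neuron signed fan-in).

    Each output pixel of each output channel becomes one neuron whose fan-in
    is the kernel volume W×H×C_in.
    """
    H, W, C = input_shape
    kh, kw = kernel_hw
    grid_h = math.ceil(H / stride)
    grid_w = math.ceil(W / stride)
    return grid_h * grid_w * out_channels, kh * kw * C


def project_runs(
    topology: list[tuple],
    spec: ChipSpec = ChipSpec(),
    overrides: dict | None = None,
) -> int:
    """Project the single-substrate run count for a named topology.

    ``topology`` is the layer sequence after convolution unrolling, as
    accepted by :func:`plan_network`.  An empty topology needs zero runs.
    """
    if not topology:
        return 0
    return plan_network(topology, spec, overrides).total_runs
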