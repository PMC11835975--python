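"""Resource model of a single-chip analog neuromorphic substrate.

The substrate exposes a fixed budget of neuron circuits, hardware synapses
(fan-in rows), event labels and event bandwidth.  A signed software weight
costs two unsigned hardware synapses (one excitatory, one inhibitory row),
and several physical neuron circuits can be shorted together to multiply
the fan-in of one logical neuron at the cost of neuron count.  All capacity
arithmetic used by the partition planner lives here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .errors import CapacityError, ValidationError

__all__ = [
    "ChipSpec",
    "circuits_per_neuron",
    "neurons_per_run",
    "max_fanout",
    "max_signed_fan_in",
]


@dataclass(frozen=True)
class ChipSpec:
    """Resource constants of one substrate allocation (defaults: single BSS-2-class chip).

    Parameters
    ----------
    n_circuits
        Physical neuron circuits on the chip.  Must be a power of two so that
        every allowed circuits-per-neuron value divides it exactly.
    fan_in_per_circuit
        Hardware synapses (unsigned weight rows) feeding one neuron circuit.
    synapses_per_signed_weight
        Hardware synapses consumed by one signed software weight.
    weight_levels
        Resolution of one hardware synapse (64 = 6 bit).
    labels_per_row
        Distinct event labels a synapse row can decode; bounds how many
        neurons a sparse row can address.
    max_events_per_cycle
        Spikes the event interface processes per clock cycle.
    event_cycle_us
        Duration of one event-interface clock cycle in µs.  2 events per
        8 ns cycle matches a 250 MHz sustained event rate.
    readout_range
        Dimensionless clipping bounds of the membrane sampling ADC.
    fanout_factors
        Multiplicative routing stages; their product is the maximum on-chip
        fan-out of a single neuron.
    """

    n_circuits: int = 512
    fan_in_per_circuit: int = 256
    synapses_per_signed_weight: int = 2
    weight_levels: int = 64
    labels_per_row: int = 64
    max_events_per_cycle: int = 2
    event_cycle_us: float = 0.008
    readout_range: tuple[float, float] = (-2.0, 2.0)
    fanout_factors: tuple[int, ...] = (2, 32, 2, 256)

    def __post_init__(self) -> None:
        counts = {
            "n_circuits": self.n_circuits,
            "fan_in_per_circuit": self.fan_in_per_circuit,
            "synapses_per_signed_weight": self.synapses_per_signed_weight,
            "weight_levels": self.weight_levels,
            "labels_per_row": self.labels_per_row,
            "max_events_per_cycle": self.max_events_per_cycle,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValidationError(f"{name} must be a positive integer, got {value!r}")
        if self.n_circuits & (self.n_circuits - 1):
            raise ValidationError(
                "n_circuits must be a power of two so every circuits-per-neuron "
                f"value divides it, got {self.n_circuits}"
            )
        lo, hi = self.readout_range
        if not hi > lo:
            raise ValidationError(f"readout_range must satisfy lo < hi, got {self.readout_range}")
        if self.event_cycle_us <= 0:
            raise ValidationError("event_cycle_us must be positive")
        if any(f < 1 for f in self.fanout_factors):
            raise ValidationError("fanout factors must be >= 1")

    # -- construction from config files ------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "ChipSpec":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown ChipSpec keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("readout_range", "fanout_factors"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ChipSpec":
        """Load a spec from YAML or JSON; omitted fields keep their defaults."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def with_overrides(self, **kwargs) -> "ChipSpec":
        return replace(self, **kwargs)


def max_fanout(spec: ChipSpec = ChipSpec()) -> int:
    """Maximum on-chip fan-out of one neuron: the product of the routing stages."""
    return math.prod(spec.fanout_factors)


def max_signed_fan_in(spec: ChipSpec = ChipSpec()) -> int:
    """Signed weights available when the whole chip feeds a single logical neuron."""
    return spec.n_circuits * spec.fan_in_per_circuit // spec.synapses_per_signed_weight


def circuits_per_neuron(fan_in_signed: int, spec: ChipSpec = ChipSpec()) -> int:
    """Physical circuits that must be shorted to host ``fan_in_signed`` signed inputs.

    Circuits combine in powers of two.  The result is the smallest power of
    two ``p`` with ``p * fan_in_per_circuit >= synapses_per_signed_weight *
    fan_in_signed``.

    Raises
    ------
    CapacityError
        If even the full chip cannot host the requested fan-in.
    """
    if fan_in_signed < 1:
        raise ValidationError(f"fan_in_signed must be >= 1, got {fan_in_signed}")
    limit = max_signed_fan_in(spec)
    if fan_in_signed > limit:
        raise CapacityError(
            f"fan-in of {fan_in_signed} signed weights exceeds the full-chip "
            f"limit of {limit} ({spec.n_circuits} circuits x "
            f"{spec.fan_in_per_circuit} synapses / "
            f"{spec.synapses_per_signed_weight} per signed weight)"
        )
    rows_needed = spec.synapses_per_signed_weight * fan_in_signed
    p = 1
    while p * spec.fan_in_per_circuit < rows_needed:
        p *= 2
    return p


def neurons_per_run(cpn: int, spec: ChipSpec = ChipSpec()) -> int:
    """Logical neurons available in one run when each uses ``cpn`` circuits."""
    if cpn < 1 or spec.n_circuits % cpn:
        raise ValidationError(
            f"circuits-per-neuron must divide n_circuits={spec.n_circuits}, got {cpn}"
        )
    return spec.n_circuits // cpn
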