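"""Experiment configuration: schema-checked YAML/JSON loading and presets."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .emulator import LIFParams
from .encoders import EncoderConfig
from .errors import ConfigurationError
from .planner import PartitionPlan, plan_network
from .substrate import ChipSpec
from .training import TrainConfig

__all__ = ["ExperimentConfig", "load_experiment", "load_preset", "available_presets"]

_TOP_KEYS = {"name", "input", "layers", "encoder", "augmentation", "train", "chip", "neurons"}
_LAYER_KEYS = {"name", "size", "fan_in", "connectivity", "kernel", "stride", "parts"}


@dataclass
class ExperimentConfig:
    name: str
    input_shape: tuple[int, ...]
    layers: list[dict]
    encoder: EncoderConfig
    train: TrainConfig
    chip: ChipSpec
    neuron_params: LIFParams = field(default_factory=LIFParams)
    augmentation: dict = field(default_factory=dict)

    def plan(self) -> PartitionPlan:
        """Partition plan of this experiment's topology on its chip."""
        entries = [(l["name"], l["size"], l["fan_in"]) for l in self.layers]
        overrides = {l["name"]: l["parts"] for l in self.layers if "parts" in l}
        return plan_network(entries, self.chip, overrides)


def _tupleize(d: dict, keys: tuple[str, ...]) -> dict:
    return {k: tuple(v) if k in keys and isinstance(v, list) else v for k, v in d.items()}


def _build(data: dict, source: str) -> ExperimentConfig:
    if not isinstance(data, dict) or not data:
        raise ConfigurationError(f"{source}: empty or non-mapping experiment config")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"{source}: unknown top-level keys {sorted(unknown)}")
    missing = {"name", "input", "layers"} - set(data)
    if missing:
        raise ConfigurationError(f"{source}: missing required keys {sorted(missing)}")
    layers = data["layers"]
    for l in layers:
        bad = set(l) - _LAYER_KEYS
        if bad:
            raise ConfigurationError(f"{source}: unknown layer keys {sorted(bad)}")
        if "size" not in l or "fan_in" not in l:
            raise ConfigurationError(f"{source}: layer needs 'size' and 'fan_in': {l}")
    try:
        encoder = EncoderConfig(**(data.get("encoder") or {}))
        train = TrainConfig(**_tupleize(data.get("train") or {},
                                        ("hidden_sizes", "halve_at", "betas", "seeds")))
        chip = ChipSpec.from_dict(data.get("chip") or {})
        neuron_params = LIFParams(**(data.get("neurons") or {}))
    except TypeError as exc:
        raise ConfigurationError(f"{source}: {exc}") from exc
    return ExperimentConfig(
        name=data["name"],
        input_shape=tuple(data["input"]["shape"]),
        layers=layers,
        encoder=encoder,
        train=train,
        chip=chip,
        neuron_params=neuron_params,
        augmentation=data.get("augmentation") or {},
    )


def load_experiment(path: str | Path) -> ExperimentConfig:
    """Load and validate an experiment description from YAML or JSON."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return _build(data, str(path))


def available_presets() -> list[str]:
    pkg = resources.files("snnpart") / "presets"
    return sorted(p.name.removesuffix(".yaml") for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> ExperimentConfig:
    """Load a packaged preset (``mnist`` or ``eurosat``)."""
    pkg = resources.files("snnpart") / "presets" / f"{name}.yaml"
    try:
        text = pkg.read_text()
    except FileNotFoundError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {available_presets()}"
        )
    return _build(yaml.safe_load(text), f"preset:{name}")
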