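"""File formats: event CSV, trace/weight HDF5, run manifests, seed fan-out.

Events are plain CSV with columns ``sample_id,time_us,population,neuron_id``
over a half-open window [0, T); traces and weights go to HDF5.  A run
manifest records everything needed to reproduce a run (config hash, seed,
schedule, artifact paths, dropped-event counts, versions) and round-trips
losslessly through JSON.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .emulator import EventBatch, TraceBatch
from .errors import ValidationError

__all__ = [
    "read_events",
    "write_events",
    "write_traces",
    "read_traces",
    "write_weights",
    "read_weights",
    "RunManifest",
    "derive_seed",
    "config_hash",
]

_HEADER = ["sample_id", "time_us", "population", "neuron_id"]


def write_events(path: str | Path, batches: dict[str, EventBatch]) -> None:
    """Write per-population event batches to one CSV, canonically ordered."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_HEADER)
        for pop in sorted(batches):
            b = batches[pop].sorted()
            for s, t, n in zip(b.samples, b.times, b.neurons):
                w.writerow([int(s), repr(float(t)), pop, int(n)])


def read_events(
    path: str | Path,
    sizes: dict[str, int] | None = None,
    n_samples: int | None = None,
) -> dict[str, EventBatch]:
    """Read event CSV back into per-population batches (ordering normalized).

    ``sizes`` / ``n_samples`` fix population and batch sizes; by default
    they are inferred as max index + 1.  Malformed rows raise with their
    line number.
    """
    rows: dict[str, list] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if lineno == 1:
                if row != _HEADER:
                    raise ValidationError(f"line 1: expected header {_HEADER}, got {row}")
                continue
            if not row:
                continue
            try:
                s, t, pop, n = int(row[0]), float(row[1]), row[2], int(row[3])
            except (ValueError, IndexError) as exc:
                raise ValidationError(f"line {lineno}: malformed event row {row}: {exc}")
            if t < 0:
                raise ValidationError(f"line {lineno}: negative event time {t}")
            if s < 0 or n < 0:
                raise ValidationError(f"line {lineno}: negative index in {row}")
            rows.setdefault(pop, []).append((s, t, n))
    out = {}
    for pop, evs in rows.items():
        arr = np.array(evs, dtype=np.float64).reshape(-1, 3)
        ns = n_samples or int(arr[:, 0].max()) + 1
        nn = (sizes or {}).get(pop) or int(arr[:, 2].max()) + 1
        out[pop] = EventBatch(arr[:, 0], arr[:, 1], arr[:, 2], ns, nn).sorted()
    return out


def write_traces(path: str | Path, traces: dict[str, TraceBatch]) -> None:
    with h5py.File(path, "w") as f:
        for pop, tb in traces.items():
            g = f.create_group(pop)
            g.create_dataset("values", data=tb.values)
            g.attrs["dt"] = tb.dt
            if tb.clipped is not None:
                g.create_dataset("clipped", data=tb.clipped)


def read_traces(path: str | Path) -> dict[str, TraceBatch]:
    out = {}
    with h5py.File(path, "r") as f:
        for pop in f:
            g = f[pop]
            clipped = g["clipped"][()] if "clipped" in g else None
            out[pop] = TraceBatch(g["values"][()], float(g.attrs["dt"]), clipped)
    return out


def write_weights(path: str | Path, weights: list[np.ndarray]) -> None:
    with h5py.File(path, "w") as f:
        for i, w in enumerate(weights):
            f.create_dataset(f"layer{i}", data=w)


def read_weights(path: str | Path) -> list[np.ndarray]:
    with h5py.File(path, "r") as f:
        return [f[k][()] for k in sorted(f, key=lambda k: int(k.removeprefix("layer")))]


# --------------------------------------------------------------------------
# manifests & seeds
# --------------------------------------------------------------------------

def config_hash(obj) -> str:
    """Stable hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def derive_seed(seed: int, name: str) -> int:
    """Fan one experiment seed out into independent named sub-seeds (< 2^31)."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    schedule: list[list[str]]
    event_files: dict[str, str] = field(default_factory=dict)
    trace_files: dict[str, str] = field(default_factory=dict)
    dropped_events: dict[str, int] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunManifest":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))

    def validate_files(self) -> None:
        for f in [*self.event_files.values(), *self.trace_files.values()]:
            if not Path(f).exists():
                raise ValidationError(f"manifest references missing file {f}")
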