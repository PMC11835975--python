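"""Synthetic image tasks: downloads-free fixtures for encoders and training.

Each class is a set of bright rectangular blobs at fixed, class-disjoint
positions on an otherwise dark image; additive Gaussian noise perturbs the
intensities.  Under a TTFS encoding the blob pixels of class ``k`` spike
early at class-specific input indices, so the classes are separable by
first-spike times by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoders import EncoderConfig, encode_images
from .errors import ValidationError

__all__ = ["SyntheticTaskSpec", "generate_synthetic_images", "SpikeDataset", "make_spike_dataset"]


@dataclass(frozen=True)
class SyntheticTaskSpec:
    """Conditions of the synthetic classification task.

    ``blobs`` maps each class to a list of ``(y, x, h, w, intensity)``
    rectangles; defaults place one 2×2 blob per class on an 8×8 image with
    mild intensity noise.
    """

    n_classes: int = 3
    image_shape: tuple[int, int] = (8, 8)
    blobs: tuple[tuple[tuple[int, int, int, int, float], ...], ...] | None = None
    noise_std: float = 0.05
    n_samples: int = 48
    seed: int = 0

    def resolved_blobs(self):
        if self.blobs is not None:
            if len(self.blobs) != self.n_classes:
                raise ValidationError("need one blob list per class")
            return self.blobs
        H, W = self.image_shape
        out = []
        for k in range(self.n_classes):
            y = (k * 3) % max(H - 1, 1)
            x = (k * 3) % max(W - 1, 1)
            out.append(((y, x, 2, 2, 1.0),))
        return tuple(out)


def _blob_mask(shape, blob):
    y, x, h, w, _ = blob
    H, W = shape
    m = np.zeros(shape, dtype=bool)
    m[y:min(y + h, H), x:min(x + w, W)] = True
    return m


def generate_synthetic_images(spec: SyntheticTaskSpec) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic labeled batch: (images (n, H, W), labels (n,)).

    Class blob supports must be pairwise disjoint so classes stay
    distinguishable; overlap raises a validation error.  Pixel values are
    clamped to [0, 1] so both encoders accept them.
    """
    blobs = spec.resolved_blobs()
    masks = []
    for per_class in blobs:
        m = np.zeros(spec.image_shape, dtype=bool)
        for b in per_class:
            m |= _blob_mask(spec.image_shape, b)
        masks.append(m)
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if (masks[i] & masks[j]).any():
                raise ValidationError(f"blob supports of classes {i} and {j} overlap")
    rng = np.random.default_rng(spec.seed)
    labels = rng.integers(0, spec.n_classes, size=spec.n_samples)
    images = np.zeros((spec.n_samples, *spec.image_shape))
    for i, k in enumerate(labels):
        for b in blobs[k]:
            images[i][_blob_mask(spec.image_shape, b)] = b[4]
    if spec.noise_std > 0:
        images += rng.normal(0.0, spec.noise_std, images.shape)
    return np.clip(images, 0.0, 1.0), labels.astype(np.int64)


@dataclass
class SpikeDataset:
    """Pre-encoded spike rasters with train/val/test splits."""

    train: tuple[np.ndarray, np.ndarray]
    val: tuple[np.ndarray, np.ndarray]
    test: tuple[np.ndarray, np.ndarray]


def make_spike_dataset(
    task: SyntheticTaskSpec,
    enc: EncoderConfig,
    n_train: int,
    n_val: int,
    n_test: int,
) -> SpikeDataset:
    """Generate, encode and split a synthetic task into spike rasters.

    The three splits use distinct sub-seeds derived from the task seed, so
    test images are never seen in training.
    """
    import math

    n_bins = math.ceil(enc.T / enc.dt)
    splits = []
    for offset, n in ((1, n_train), (2, n_val), (3, n_test)):
        sub = SyntheticTaskSpec(
            n_classes=task.n_classes, image_shape=task.image_shape, blobs=task.blobs,
            noise_std=task.noise_std, n_samples=n, seed=task.seed * 1000 + offset,
        )
        images, labels = generate_synthetic_images(sub)
        events = encode_images(images, enc)
        splits.append((events.to_raster(n_bins, enc.dt), labels))
    return SpikeDataset(*splits)
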