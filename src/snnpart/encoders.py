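"""Time-to-first-spike (TTFS) image encoders.

Two schemes turn pixel intensities into single spikes whose latency
decreases with intensity:

* ``linear`` — spike time falls linearly with intensity on the dt lattice:
  ``t = T − round(T/dt · (x − x_min)/(x_max − x_min)) · dt``.  The brightest
  pixel spikes at 0; a pixel at ``x_min`` maps to ``t = T``, the end of the
  observation window, and emits no event.
* ``lif_current`` — the pixel value (plus a bias pushing toward early
  spiking) drives a leaky integrator with infinite refractory period:
  ``dv/dt = −v/τ_en + x + x_min_bias``; the spike happens when ``v`` crosses
  ``ϑ_en``, in closed form ``t = −τ_en · ln(1 − ϑ_en/(τ_en·(x + x_min_bias)))``.
  Too-dim pixels (asymptotic membrane below threshold) stay silent.  Times
  are computed at full float resolution (the event interface is much finer
  than the dt lattice), which together with pre-encoding Gaussian jitter
  de-duplicates quantized pixel values and spreads simultaneous events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .emulator import EventBatch
from .errors import ValidationError

__all__ = [
    "EncoderConfig",
    "ttfs_linear",
    "ttfs_lif_current",
    "jitter",
    "encode_images",
    "spike_stats",
]


@dataclass(frozen=True)
class EncoderConfig:
    scheme: str = "linear"          # 'linear' | 'lif_current'
    T: float = 30.0                 # observation window per image, µs
    dt: float = 0.5                 # lattice step, µs
    x_min: float = 0.0              # dataset-global pixel bounds (linear scheme)
    x_max: float = 1.0
    x_min_bias: float = 0.2         # bias toward early spiking (lif scheme)
    tau_en: float = 8.0             # encoder membrane time constant, µs
    theta_en: float = 1.0           # encoder threshold
    sigma_in: float = 0.0           # pre-encoding Gaussian jitter std
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("linear", "lif_current"):
            raise ValidationError(f"unknown encoder scheme {self.scheme!r}")
        if not self.x_max > self.x_min:
            raise ValidationError("x_max must exceed x_min")
        if self.tau_en <= 0 or self.theta_en <= 0:
            raise ValidationError("tau_en and theta_en must be positive")
        if self.sigma_in < 0:
            raise ValidationError("sigma_in must be >= 0")
        if self.T <= 0 or self.dt <= 0:
            raise ValidationError("T and dt must be positive")


def ttfs_linear(x: np.ndarray | float, cfg: EncoderConfig) -> np.ndarray:
    """Linear TTFS spike times; NaN where no event is emitted.

    Pixel values are clamped to [x_min, x_max]; rounding to the lattice is
    round-half-to-even.  Times land on the dt grid in [0, T); the value
    mapping exactly to T (x = x_min) is outside the window.
    """
    x = np.clip(np.asarray(x, dtype=np.float64), cfg.x_min, cfg.x_max)
    frac = (x - cfg.x_min) / (cfg.x_max - cfg.x_min)
    t = cfg.T - np.round(cfg.T / cfg.dt * frac) * cfg.dt
    return np.where(t < cfg.T, t, np.nan)


def ttfs_lif_current(x: np.ndarray | float, cfg: EncoderConfig) -> np.ndarray:
    """Constant-current LIF TTFS spike times; NaN where no event is emitted.

    The drive ``a = x + x_min_bias`` charges a membrane toward the
    asymptote ``τ_en·a``; only pixels whose asymptote exceeds ``ϑ_en``
    spike, at ``t = −τ_en ln(1 − ϑ_en/(τ_en·a))``.  Times beyond the window
    ``[0, T)`` are suppressed.
    """
    x = np.asarray(x, dtype=np.float64)
    a = x + cfg.x_min_bias
    asymptote = cfg.tau_en * a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = -cfg.tau_en * np.log(1.0 - cfg.theta_en / asymptote)
    t = np.where((asymptote > cfg.theta_en) & (t < cfg.T), t, np.nan)
    return t


def jitter(image: np.ndarray, sigma_in: float, seed: int | np.random.Generator) -> np.ndarray:
    """Add i.i.d. N(0, sigma_in²) per pixel; identity at sigma_in = 0."""
    if sigma_in < 0:
        raise ValidationError("sigma_in must be >= 0")
    image = np.asarray(image, dtype=np.float64)
    if sigma_in == 0:
        return image.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return image + rng.normal(0.0, sigma_in, size=image.shape)


def encode_images(images: np.ndarray, cfg: EncoderConfig) -> EventBatch:
    """Encode a batch of images (n, ...) into one spike per active pixel.

    Jitter (if configured) is applied before encoding and jittered values
    are clamped to [0, 1] so the lif-current scheme's domain holds.  Flat
    pixel index = input neuron index.
    """
    images = np.asarray(images, dtype=np.float64)
    n = images.shape[0]
    flat = images.reshape(n, -1)
    if cfg.sigma_in > 0:
        rng = np.random.default_rng(cfg.seed)
        flat = np.clip(jitter(flat, cfg.sigma_in, rng), 0.0, 1.0)
    if cfg.scheme == "linear":
        t = ttfs_linear(flat, cfg)
    else:
        t = ttfs_lif_current(flat, cfg)
    s, pix = np.nonzero(~np.isnan(t))
    return EventBatch(s, t[s, pix], pix, n_samples=n, n_neurons=flat.shape[1]).sorted()


def spike_stats(events: EventBatch, bin_width: float, T: float) -> tuple[float, float]:
    """(mean spikes per bin, max of per-bin means) over a batch.

    Events are binned at ``bin_width``; counts are averaged across samples
    per bin, then reduced by mean resp. max over bins.
    """
    if events.n_samples < 1:
        raise ValidationError("empty batch")
    n_bins = math.ceil(T / bin_width)
    if len(events) == 0:
        return 0.0, 0.0
    bins = np.floor(events.times / bin_width).astype(np.int64)
    keep = bins < n_bins
    counts = np.zeros((events.n_samples, n_bins))
    np.add.at(counts, (events.samples[keep], bins[keep]), 1.0)
    per_bin_mean = counts.mean(axis=0)
    return float(per_bin_mean.mean()), float(per_bin_mean.max())
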