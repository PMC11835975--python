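"""Surrogate-gradient BPTT training of (partitioned) feed-forward SNNs.

The forward pass unrolls the exponential-Euler LIF dynamics on the dt
lattice; the backward pass is explicit reverse-mode differentiation through
the unrolled lattice (BPTT) with the spike nonlinearity replaced by a
fast-sigmoid surrogate derivative ``1/(β|v−ϑ|+1)²`` (SuperSpike family).

Two execution styles are supported per layer:

* ``ideal`` — the differentiable software dynamics themselves produce the
  forward observables.
* ``constrained`` — the forward observables (hidden spike trains, readout
  traces) are recorded from the constrained emulator via the partitioned
  execution machinery (record/playback between execution instances), then
  substituted into the ideal lattice for the backward pass
  (hardware-in-the-loop, straight-through).

Readout scores come from leaky-integrator membrane traces, decoded either
as max-over-time ``s_k = max_t v_k(t)`` or as the last observed value
``s_k = v_k(T)``, and trained with cross-entropy plus optional
regularization of hidden firing rates, readout saturation and weight range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .emulator import EventBatch, LIFParams, lif_coefficients
from .errors import ValidationError
from .netgraph import Network, run as run_network
from .substrate import ChipSpec

__all__ = [
    "TrainConfig",
    "ChainModel",
    "surrogate_heaviside",
    "smooth_heaviside",
    "decode_max_over_time",
    "decode_last",
    "loss",
    "fit",
    "FitResult",
]


# --------------------------------------------------------------------------
# surrogate spike function
# --------------------------------------------------------------------------

def fast_sigmoid_grad(x: np.ndarray, beta: float) -> np.ndarray:
    """Fast-sigmoid surrogate derivative 1/(β|x|+1)²; peaks at 1 for x=0."""
    return 1.0 / (beta * np.abs(x) + 1.0) ** 2


def surrogate_heaviside(x: np.ndarray, beta: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Hard threshold with surrogate backward slope: (step(x), 1/(β|x|+1)²)."""
    if beta <= 0:
        raise ValidationError("beta must be positive")
    return (x >= 0).astype(np.float64), fast_sigmoid_grad(x, beta)


def smooth_heaviside(x: np.ndarray, beta: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Smooth relaxation whose derivative equals the surrogate exactly.

    ``h(x) = 1/2 + x/(β|x|+1)`` has d h/dx = 1/(β|x|+1)².  Used only to
    verify the BPTT backward pass against finite differences: on the
    smoothed model the surrogate backward *is* the true gradient.
    """
    if beta <= 0:
        raise ValidationError("beta must be positive")
    return 0.5 + x / (beta * np.abs(x) + 1.0), fast_sigmoid_grad(x, beta)


# --------------------------------------------------------------------------
# decodings
# --------------------------------------------------------------------------

def decode_max_over_time(traces: np.ndarray) -> np.ndarray:
    """Scores s_k = max_t v_k(t); traces shaped (batch, bins, classes)."""
    if traces.size == 0:
        raise ValidationError("empty traces")
    return traces.max(axis=1)


def decode_last(traces: np.ndarray) -> np.ndarray:
    """Scores s_k = v_k(T): the final lattice bin."""
    if traces.size == 0:
        raise ValidationError("empty traces")
    return traces[:, -1, :]


def _decode_backward(traces: np.ndarray, decoding: str, dscores: np.ndarray) -> np.ndarray:
    g = np.zeros_like(traces)
    if decoding == "max_over_time":
        idx = traces.argmax(axis=1)  # (B, K)
        B, K = idx.shape
        b, k = np.meshgrid(np.arange(B), np.arange(K), indexing="ij")
        g[b, idx, k] = dscores
    elif decoding == "last_value":
        g[:, -1, :] = dscores
    else:
        raise ValidationError(f"unknown decoding {decoding!r}")
    return g


# --------------------------------------------------------------------------
# loss
# --------------------------------------------------------------------------

def _softmax(s: np.ndarray) -> np.ndarray:
    e = np.exp(s - s.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def loss(
    scores: np.ndarray,
    labels: np.ndarray,
    hidden_spikes: list[np.ndarray] | None = None,
    readout_traces: np.ndarray | None = None,
    weights: list[np.ndarray] | None = None,
    reg_weights: tuple[float, float, float] = (0.0, 0.0, 0.0),
    sat_bound: float = 1.5,
    weight_bound: float = 1.0,
) -> float:
    """Cross-entropy of softmaxed scores plus the three regularizers
    (hidden firing rate, readout saturation, weight range)."""
    value, _, _, _, _ = _loss_and_grads(
        scores, labels, hidden_spikes or [], readout_traces, weights or [],
        reg_weights, sat_bound, weight_bound,
    )
    return value


def _loss_and_grads(
    scores, labels, hidden_spikes, readout_traces, weights,
    reg_weights, sat_bound, weight_bound,
):
    labels = np.asarray(labels)
    B, K = scores.shape
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= K:
        raise ValidationError("label out of range")
    p = _softmax(scores)
    ce = float(-np.mean(np.log(p[np.arange(B), labels] + 1e-300)))
    dscores = p.copy()
    dscores[np.arange(B), labels] -= 1.0
    dscores /= B

    rate_w, sat_w, weight_w = reg_weights
    total = ce
    g_hidden = [np.zeros_like(z) for z in hidden_spikes]
    if rate_w and hidden_spikes:
        for li, z in enumerate(hidden_spikes):
            counts = z.sum(axis=1)  # (B, N) spike count per neuron
            total += rate_w * float(np.mean(counts**2))
            g_hidden[li] += rate_w * 2.0 * counts[:, None, :] / counts.size
    g_traces = None
    if readout_traces is not None:
        g_traces = np.zeros_like(readout_traces)
        if sat_w:
            excess = np.maximum(np.abs(readout_traces) - sat_bound, 0.0)
            total += sat_w * float(np.mean(excess**2))
            g_traces += (
                sat_w * 2.0 * excess * np.sign(readout_traces) / readout_traces.size
            )
    g_weights = [np.zeros_like(w) for w in weights]
    if weight_w and weights:
        for wi, w in enumerate(weights):
            excess = np.maximum(np.abs(w) - weight_bound, 0.0)
            total += weight_w * float(np.mean(excess**2))
            g_weights[wi] += weight_w * 2.0 * excess * np.sign(w) / w.size
    return total, dscores, g_hidden, g_traces, g_weights


# --------------------------------------------------------------------------
# differentiable chain model
# --------------------------------------------------------------------------

class ChainModel:
    """Feed-forward chain input → hidden LIF … → LI readout with explicit BPTT.

    Holds one weight matrix per projection.  ``forward`` caches every state
    needed by ``backward``; both support substituting recorded spike trains
    for hidden layers (straight-through hardware-in-the-loop)."""

    def __init__(
        self,
        sizes: list[int],
        hidden_params: LIFParams,
        readout_params: LIFParams,
        beta: float = 10.0,
    ):
        if len(sizes) < 2:
            raise ValidationError("need at least input and readout layers")
        if hidden_params.tau_ref != 0:
            raise ValidationError("trainer supports tau_ref = 0 only")
        if not readout_params.leaky_integrate_only:
            raise ValidationError("readout must be leaky-integrate-only")
        self.sizes = list(sizes)
        self.hidden_params = hidden_params
        self.readout_params = readout_params
        self.beta = beta
        self.weights: list[np.ndarray] = []

    @property
    def n_layers(self) -> int:
        return len(self.sizes) - 1

    def init_weights(self, rng: np.random.Generator, scale: float = 1.0) -> None:
        self.weights = [
            rng.normal(0.0, scale / math.sqrt(self.sizes[i]), (self.sizes[i], self.sizes[i + 1]))
            for i in range(self.n_layers)
        ]

    def _coeffs(self, params: LIFParams, dt: float):
        return lif_coefficients(params, dt)

    def forward(
        self,
        in_raster: np.ndarray,
        dt: float,
        spike_mode: str = "hard",
        dropout_masks: list[np.ndarray] | None = None,
        z_overrides: dict[int, np.ndarray] | None = None,
    ) -> dict:
        """Unroll the chain; returns a cache with per-layer states.

        ``z_overrides`` maps hidden-layer index (0-based) to a recorded spike
        raster substituted for the layer's output (forward observable from
        the constrained emulator); gradients still flow through the ideal
        membrane via the surrogate.
        """
        spike_fn = smooth_heaviside if spike_mode == "smooth" else surrogate_heaviside
        z_overrides = z_overrides or {}
        B, n_bins, _ = in_raster.shape
        layers = []
        z_prev = in_raster
        for l, W in enumerate(self.weights):
            is_readout = l == self.n_layers - 1
            params = self.readout_params if is_readout else self.hidden_params
            a_s, a_m, c = self._coeffs(params, dt)
            mask = None
            if dropout_masks is not None and l > 0:
                mask = dropout_masks[l - 1]
            inp = z_prev if mask is None else z_prev * mask
            J = inp @ W
            N = W.shape[1]
            I = np.zeros((B, N))
            v_post = np.full((B, N), params.e_l)
            I_rec = np.empty((B, n_bins, N))
            v_pre_rec = np.empty((B, n_bins, N))
            z_rec = None if is_readout else np.empty((B, n_bins, N))
            zd_rec = None if is_readout else np.empty((B, n_bins, N))
            for t in range(n_bins):
                I = a_s * I + J[:, t, :]
                v_pre = params.e_l + (v_post - params.e_l) * a_m + c * I
                I_rec[:, t, :] = I
                v_pre_rec[:, t, :] = v_pre
                if is_readout:
                    v_post = v_pre
                else:
                    z, zd = spike_fn(v_pre - params.v_th, self.beta)
                    if l in z_overrides:
                        z = z_overrides[l][:, t, :]
                    z_rec[:, t, :] = z
                    zd_rec[:, t, :] = zd
                    v_post = v_pre + (params.e_r - v_pre) * z
            layers.append(
                dict(
                    inp=inp, mask=mask, J=J, I=I_rec, v_pre=v_pre_rec,
                    z=z_rec, zd=zd_rec, params=params, coeffs=(a_s, a_m, c),
                )
            )
            z_prev = z_rec
        return dict(layers=layers, n_bins=n_bins, batch=B)

    def readout_traces(self, cache: dict) -> np.ndarray:
        return cache["layers"][-1]["v_pre"]

    def hidden_spikes(self, cache: dict) -> list[np.ndarray]:
        return [lay["z"] for lay in cache["layers"][:-1]]

    def backward(
        self,
        cache: dict,
        g_readout_traces: np.ndarray,
        g_hidden_spikes: list[np.ndarray] | None = None,
    ) -> list[np.ndarray]:
        """Reverse-mode sweep over layers and time; returns dL/dW per layer."""
        layers = cache["layers"]
        n_bins = cache["n_bins"]
        grads = [np.zeros_like(W) for W in self.weights]
        gZ_next: np.ndarray | None = None  # dL/d(output raster of layer below)
        for l in reversed(range(self.n_layers)):
            lay = layers[l]
            a_s, a_m, c = lay["coeffs"]
            params = lay["params"]
            is_readout = l == self.n_layers - 1
            B = cache["batch"]
            N = self.weights[l].shape[1]
            gJ = np.empty((B, n_bins, N))
            g_pre_next = np.zeros((B, N))
            gI_next = np.zeros((B, N))
            for t in reversed(range(n_bins)):
                if is_readout:
                    g_pre = g_readout_traces[:, t, :] + a_m * g_pre_next
                else:
                    v_pre = lay["v_pre"][:, t, :]
                    z = lay["z"][:, t, :]
                    zd = lay["zd"][:, t, :]
                    g_post = a_m * g_pre_next
                    gz = g_post * (params.e_r - v_pre)
                    if gZ_next is not None:
                        gz = gz + gZ_next[:, t, :]
                    if g_hidden_spikes is not None:
                        gz = gz + g_hidden_spikes[l][:, t, :]
                    g_pre = g_post * (1.0 - z) + gz * zd
                gI = c * g_pre + a_s * gI_next
                gJ[:, t, :] = gI
                g_pre_next = g_pre
                gI_next = gI
            inp = lay["inp"]
            grads[l] = np.einsum("btm,btn->mn", inp, gJ)
            if l > 0:
                g_inp = gJ @ self.weights[l].T
                if lay["mask"] is not None:
                    g_inp = g_inp * lay["mask"]
                gZ_next = g_inp
        return grads


# --------------------------------------------------------------------------
# Adam
# --------------------------------------------------------------------------

class _Adam:
    def __init__(self, shapes, lr, betas):
        self.lr = lr
        self.b1, self.b2 = betas
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, weights, grads):
        self.t += 1
        for i, (w, g) in enumerate(zip(weights, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            w -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)


# --------------------------------------------------------------------------
# training loop
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.  Times in µs.

    The defaults are deliberately generic; presets override them per task.
    ``lr_decay`` applies per epoch under the exponential schedule;
    ``halve_at`` lists the epochs after which the rate is halved under the
    halving schedule.
    """

    hidden_sizes: tuple[int, ...] = (32,)
    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    epochs: int = 50
    batch_size: int = 32
    dropout_p: float = 0.0
    lr_schedule: str = "constant"  # 'constant' | 'exponential' | 'halving'
    lr_decay: float = 0.97
    halve_at: tuple[int, ...] = (10, 20, 30, 40, 50, 60)
    rate_w: float = 0.0
    sat_w: float = 0.0
    weight_w: float = 0.0
    sat_bound: float = 1.5
    weight_bound: float = 1.0
    patience: int = 25
    decoding: str = "max_over_time"  # 'max_over_time' | 'last_value'
    beta: float = 10.0
    init_scale: float = 1.0
    seeds: tuple[int, ...] = (0,)
    T: float = 30.0
    dt: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_p < 1:
            raise ValidationError("dropout_p must be in [0, 1)")
        if self.patience < 1:
            raise ValidationError("patience must be >= 1")
        if self.decoding not in ("max_over_time", "last_value"):
            raise ValidationError(f"unknown decoding {self.decoding!r}")
        if self.lr_schedule not in ("constant", "exponential", "halving"):
            raise ValidationError(f"unknown lr schedule {self.lr_schedule!r}")


@dataclass
class FitResult:
    weights: list[np.ndarray]
    history: list[dict]
    test_accuracy: float
    per_seed: list[dict] = field(default_factory=list)


def _decode(traces: np.ndarray, decoding: str) -> np.ndarray:
    return decode_max_over_time(traces) if decoding == "max_over_time" else decode_last(traces)


def _hidden_params_default() -> LIFParams:
    return LIFParams()


def _build_chain_network(model: ChainModel, backend, spec: ChipSpec) -> Network:
    backends = backend if isinstance(backend, (list, tuple)) else [backend] * model.n_layers
    net = Network.chain(
        model.sizes, [w.copy() for w in model.weights],
        hidden_params=model.hidden_params, readout_params=model.readout_params,
        partitioned=True, spec=spec,
    )
    order = [f"hidden{i}" for i in range(1, model.n_layers)] + ["readout"]
    for inst_id, b in zip(order, backends):
        net.instances[inst_id].backend = b
    return net


def _constrained_forward(
    model: ChainModel, rasters: np.ndarray, backend, spec: ChipSpec,
    dt: float, bandwidth_limit: bool,
) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Record forward observables by running the partitioned emulation.

    Returns recorded hidden spike rasters (per hidden-layer index) and the
    constrained readout traces."""
    net = _build_chain_network(model, backend, spec)
    T = rasters.shape[1] * dt
    stim = {"input": EventBatch.from_raster(rasters, dt)}
    res = run_network(net, stim, T, dt, bandwidth_limit=bandwidth_limit)
    n_bins = rasters.shape[1]
    overrides = {}
    for i in range(model.n_layers - 1):
        ev = res.spikes(f"hidden{i + 1}")
        overrides[i] = ev.to_raster(n_bins, dt)
    return overrides, res.trace("readout").values


def predict(
    model: ChainModel,
    rasters: np.ndarray,
    cfg: TrainConfig,
    backend="ideal",
    spec: ChipSpec | None = None,
    bandwidth_limit: bool = False,
) -> np.ndarray:
    """Class scores for a raster batch under the given backend."""
    spec = spec or ChipSpec()
    if backend == "ideal":
        cache = model.forward(rasters, cfg.dt)
        traces = model.readout_traces(cache)
    else:
        _, traces = _constrained_forward(model, rasters, backend, spec, cfg.dt, bandwidth_limit)
    return _decode(traces, cfg.decoding)


def _accuracy(scores: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean(scores.argmax(axis=1) == labels))


def fit(
    dataset,
    cfg: TrainConfig,
    hidden_params: LIFParams | None = None,
    readout_params: LIFParams | None = None,
    backend="ideal",
    spec: ChipSpec | None = None,
    bandwidth_limit: bool = False,
) -> FitResult:
    """Train the chain on a dataset of pre-encoded spike rasters.

    ``dataset`` provides ``train/val/test`` splits as ``(rasters, labels)``
    tuples (see :class:`snnpart.synth.SpikeDataset`).  Per configured seed,
    the model is trained with Adam, the learning-rate schedule and early
    stopping on validation accuracy; the best-on-validation weights are
    evaluated on the test split.  Metrics are averaged over the seed set;
    the returned weights are those of the first seed.
    """
    spec = spec or ChipSpec()
    hidden_params = hidden_params or _hidden_params_default()
    if readout_params is None:
        readout_params = LIFParams(
            tau_m=hidden_params.tau_m, g_l=hidden_params.g_l, e_l=hidden_params.e_l,
            tau_s=hidden_params.tau_s, leaky_integrate_only=True,
        )
    x_tr, y_tr = dataset.train
    x_va, y_va = dataset.val
    x_te, y_te = dataset.test
    sizes = [x_tr.shape[2], *cfg.hidden_sizes, int(y_tr.max()) + 1]

    per_seed = []
    first_weights = None
    first_history = None
    for seed in cfg.seeds:
        rng = np.random.default_rng(seed)
        model = ChainModel(sizes, hidden_params, readout_params, beta=cfg.beta)
        model.init_weights(rng, cfg.init_scale)
        opt = _Adam([w.shape for w in model.weights], cfg.lr, cfg.betas)
        best_val, best_weights, since_best = -1.0, [w.copy() for w in model.weights], 0
        history = []
        n = len(y_tr)
        for epoch in range(cfg.epochs):
            if cfg.lr_schedule == "exponential":
                opt.lr = cfg.lr * cfg.lr_decay**epoch
            elif cfg.lr_schedule == "halving":
                opt.lr = cfg.lr * 0.5 ** sum(1 for e in cfg.halve_at if epoch >= e)
            perm = rng.permutation(n)
            ep_loss, ep_correct = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = perm[start:start + cfg.batch_size]
                xb, yb = x_tr[idx], y_tr[idx]
                overrides = {}
                if backend != "ideal":
                    overrides, _ = _constrained_forward(
                        model, xb, backend, spec, cfg.dt, bandwidth_limit
                    )
                masks = None
                if cfg.dropout_p > 0:
                    masks = [
                        (rng.random((len(idx), xb.shape[1], model.sizes[i + 1]))
                         >= cfg.dropout_p).astype(np.float64)
                        for i in range(model.n_layers - 1)
                    ]
                cache = model.forward(
                    xb, cfg.dt, dropout_masks=masks, z_overrides=overrides
                )
                traces = model.readout_traces(cache)
                scores = _decode(traces, cfg.decoding)
                value, dscores, g_hidden, g_traces, g_w_reg = _loss_and_grads(
                    scores, yb, model.hidden_spikes(cache), traces, model.weights,
                    (cfg.rate_w, cfg.sat_w, cfg.weight_w), cfg.sat_bound, cfg.weight_bound,
                )
                if not np.isfinite(value):
                    raise ValidationError(
                        f"training diverged at epoch {epoch}: loss={value!r}, "
                        f"|w|max={max(np.abs(w).max() for w in model.weights):.3g}"
                    )
                gV = _decode_backward(traces, cfg.decoding, dscores)
                if g_traces is not None:
                    gV = gV + g_traces
                grads = model.backward(cache, gV, g_hidden)
                grads = [g + gr for g, gr in zip(grads, g_w_reg)]
                opt.step(model.weights, grads)
                ep_loss += value * len(idx)
                ep_correct += int((scores.argmax(axis=1) == yb).sum())
            val_scores = predict(model, x_va, cfg, backend, spec, bandwidth_limit)
            val_acc = _accuracy(val_scores, y_va)
            history.append(
                dict(epoch=epoch, lr=opt.lr, train_loss=ep_loss / n,
                     train_acc=ep_correct / n, val_acc=val_acc)
            )
            if val_acc > best_val:
                best_val, since_best = val_acc, 0
                best_weights = [w.copy() for w in model.weights]
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        model.weights = best_weights
        test_acc = _accuracy(
            predict(model, x_te, cfg, backend, spec, bandwidth_limit), y_te
        )
        per_seed.append(dict(seed=seed, val_acc=best_val, test_acc=test_acc))
        if first_weights is None:
            first_weights, first_history = best_weights, history
    return FitResult(
        weights=first_weights,
        history=first_history,
        test_accuracy=float(np.mean([s["test_acc"] for s in per_seed])),
        per_seed=per_seed,
    )
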