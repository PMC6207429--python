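"""Layered convolutional network with recordable feature maps and attention hooks.

The model is the standard ventral-stream abstraction: a stack of 3x3
convolutions, each followed by positive rectification (ReLU), with 2x2 max
pooling interspersed.  The activity of unit (i, j) in feature map k of layer
l is

    x_ij^lk = [ (W^lk * X^(l-1))_ij ]_+

where * is 2-D convolution and [.]_+ is rectification.  Attention enters at
the rectification stage of targeted layers, either multiplicatively (scaling
the ReLU slope),

    x = (1 + m) [I]_+ ,

or additively (a bias injected before rectification, scaled by the layer's
mean activity level mu_l),

    x = [I + mu_l m]_+ .

For feature-based attention the modulation m is constant across space within
a feature map; for spatial attention it varies with position.

The network is implemented directly in numpy (forward and reverse pass), so
that the attention hook and the per-feature-map activity gradients — the two
quantities everything else in this package is built on — are fully
transparent.  A small fixture network trained on synthetic grating stimuli
stands in for a large pretrained model; its architecture, optimizer and
accuracy floor are configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import stimuli as st

__all__ = [
    "ArchitectureConfig",
    "TrainingConfig",
    "AttentionField",
    "ForwardResult",
    "NetworkModel",
    "TrainingError",
    "train_fixture_network",
    "attach_binary_readouts",
    "attach_color_readout",
    "record_spatially_averaged_activity",
    "compute_layer_means",
    "VGG16_LAYER_MEANS",
]

#: Mean activity levels mu_l for the 13 convolutional layers of a VGG-16
#: network responding to natural images; loadable as fixed values when the
#: model is run in VGG-16 mode with externally supplied weights.
VGG16_LAYER_MEANS: tuple[float, ...] = (
    20, 100, 150, 150, 240, 240, 150, 150, 80, 20, 20, 10, 1,
)


class ConfigurationError(ValueError):
    """Inconsistent model/attention configuration."""


class TrainingError(RuntimeError):
    """Fixture training failed to reach the configured accuracy floor."""


@dataclass(frozen=True)
class ArchitectureConfig:
    """Fixture network layout.

    ``n_maps[i]`` is the number of feature maps of convolutional layer i+1;
    ``pool_after`` lists the (1-based) layers followed by a 2x2 max pool.
    """

    n_maps: tuple[int, ...] = (8, 16, 16, 32, 32)
    pool_after: tuple[int, ...] = (2, 4)
    input_size: int = st.DEFAULT_SIZE
    n_channels: int = 3
    kernel: int = 3
    input_mean: float = 0.5  # subtracted from pixels before the first convolution

    def __post_init__(self) -> None:
        size = self.input_size
        for layer in range(1, len(self.n_maps) + 1):
            if layer in self.pool_after:
                if size % 2:
                    raise ConfigurationError(
                        f"layer {layer} output size {size} not divisible by 2 for pooling"
                    )
                size //= 2

    @property
    def n_layers(self) -> int:
        return len(self.n_maps)

    def layer_shapes(self) -> list[tuple[int, int, int]]:
        """(K, H, W) of each convolutional layer's feature maps (pre-pool)."""
        shapes = []
        size = self.input_size
        for layer, k in enumerate(self.n_maps, start=1):
            shapes.append((k, size, size))
            if layer in self.pool_after:
                size //= 2
        return shapes


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer settings for the fixture network."""

    epochs: int = 40
    batch_size: int = 32
    learning_rate: float = 1e-2
    weight_decay: float = 0.0
    holdout_fraction: float = 0.2
    accuracy_floor: float = 0.10  # ~4.5x chance for 45 classes


@dataclass
class AttentionField:
    """Per-layer modulation coefficients.

    ``values[l]`` holds the modulation for (1-based) layer ``l`` as an array
    of shape ``(K,)`` (feature attention; constant over space) or
    ``(K, H, W)`` (spatial or combined attention).  Layers absent from the
    mapping are unmodulated.
    """

    mode: str = "multiplicative"  # or "additive"
    values: dict[int, np.ndarray] = field(default_factory=dict)
    clamp_gain: bool = False  # clamp multiplicative gain at 0 instead of going negative

    def __post_init__(self) -> None:
        if self.mode not in ("multiplicative", "additive"):
            raise ConfigurationError(f"unknown attention mode {self.mode!r}")


@dataclass
class ForwardResult:
    """Activations and readout scores from one forward pass."""

    activations: list[np.ndarray]  # per layer: (N, K, H, W), post-ReLU, pre-pool
    pooled: np.ndarray  # (N, K_last) spatially averaged final-layer activity
    logits: np.ndarray | None = None  # (N, C) softmax-head logits
    probs: np.ndarray | None = None  # (N, C) softmax-head probabilities
    cache: dict | None = None  # internal tensors for the reverse pass


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """'Same' 3x3 convolution: x (N,Kin,H,W), w (Kout,Kin,3,3) -> (N,Kout,H,W)."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    sw = sliding_window_view(xp, (3, 3), axis=(2, 3))
    return np.einsum("nkhwab,okab->nohw", sw, w, optimize=True) + b[None, :, None, None]


def _conv2d_backward(
    x: np.ndarray, w: np.ndarray, d_out: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a same-padded 3x3 convolution. Returns (dx, dw, db)."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    sw = sliding_window_view(xp, (3, 3), axis=(2, 3))
    dw = np.einsum("nkhwab,nohw->okab", sw, d_out, optimize=True)
    db = d_out.sum(axis=(0, 2, 3))
    dp = np.pad(d_out, ((0, 0), (0, 0), (2, 2), (2, 2)))
    sw_d = sliding_window_view(dp, (3, 3), axis=(2, 3))
    w_rot = w[:, :, ::-1, ::-1]
    dxp = np.einsum("nohwab,okab->nkhw", sw_d, w_rot, optimize=True)
    return dxp[:, :, 1:-1, 1:-1], dw, db


def _maxpool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 max pool; returns pooled output and flat argmax for the backward pass."""
    n, k, h, w = x.shape
    xr = x.reshape(n, k, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    windows = xr.reshape(n, k, h // 2, w // 2, 4)
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool_backward(d_out: np.ndarray, idx: np.ndarray, shape: tuple) -> np.ndarray:
    n, k, h, w = shape
    d_windows = np.zeros((n, k, h // 2, w // 2, 4))
    np.put_along_axis(d_windows, idx[..., None], d_out[..., None], axis=-1)
    return (
        d_windows.reshape(n, k, h // 2, w // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, k, h, w)
    )


class NetworkModel:
    """Convolution + rectification + pooling stack with attachable readouts.

    Readouts
    --------
    * ``head`` — the native N-way softmax classifier on spatially pooled
      final-layer features (trained jointly with the convolutional weights).
    * ``binary_readouts`` — one logistic-regression detector per condition,
      trained post hoc on the same pooled features.
    * ``color_readout`` — a 5-way softmax color classifier on pooled features.
    """

    def __init__(self, arch: ArchitectureConfig, rng: np.random.Generator | None = None):
        self.arch = arch
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        k_in = arch.n_channels
        for k_out in arch.n_maps:
            scale = np.sqrt(2.0 / (k_in * arch.kernel**2))
            self.weights.append(
                rng.standard_normal((k_out, k_in, arch.kernel, arch.kernel)) * scale
            )
            self.biases.append(np.zeros(k_out))
            k_in = k_out
        self.classes: list[str] = []
        self.head_w: np.ndarray | None = None  # (C, K_last)
        self.head_b: np.ndarray | None = None  # (C,)
        self.binary_readouts: dict = {}  # condition -> (w (K,), b float)
        self.color_readout: tuple[np.ndarray, np.ndarray] | None = None
        self.layer_means: np.ndarray | None = None  # mu_l per layer

    # -- forward -----------------------------------------------------------

    def _modulation(self, attention: AttentionField | None, layer: int):
        if attention is None or layer not in attention.values:
            return None
        m = np.asarray(attention.values[layer], dtype=np.float64)
        k = self.arch.n_maps[layer - 1]
        if m.ndim == 1:
            if m.shape[0] != k:
                raise ConfigurationError(
                    f"attention for layer {layer} has {m.shape[0]} maps, expected {k}"
                )
            return m[None, :, None, None]
        if m.ndim == 3:
            expect = self.arch.layer_shapes()[layer - 1]
            if m.shape != expect:
                raise ConfigurationError(
                    f"attention for layer {layer} has shape {m.shape}, expected {expect}"
                )
            return m[None]
        raise ConfigurationError("attention values must be (K,) or (K,H,W)")

    def forward(
        self,
        x: np.ndarray,
        attention: AttentionField | None = None,
        keep_cache: bool = False,
    ) -> ForwardResult:
        """Run the network on a batch ``x`` of shape ``(N, 3, H, W)``."""
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != (
            self.arch.n_channels,
            self.arch.input_size,
            self.arch.input_size,
        ):
            raise ConfigurationError(
                f"input shape {x.shape[1:]} does not match model input "
                f"({self.arch.n_channels}, {self.arch.input_size}, {self.arch.input_size})"
            )
        if attention is not None:
            unknown = set(attention.values) - set(range(1, self.arch.n_layers + 1))
            if unknown:
                raise ConfigurationError(f"attention targets unknown layers {unknown}")
        activations: list[np.ndarray] = []
        cache: dict = {"inputs": [], "relu_grad": [], "pool_idx": [], "pool_shape": []}
        current = x - self.arch.input_mean
        for layer in range(1, self.arch.n_layers + 1):
            w, b = self.weights[layer - 1], self.biases[layer - 1]
            if keep_cache:
                cache["inputs"].append(current)
            pre = _conv2d(current, w, b)
            m = self._modulation(attention, layer)
            if m is None:
                act = np.maximum(pre, 0.0)
                relu_grad = (pre > 0).astype(np.float64) if keep_cache else None
            elif attention.mode == "multiplicative":
                gain = 1.0 + m
                if attention.clamp_gain:
                    gain = np.maximum(gain, 0.0)
                act = gain * np.maximum(pre, 0.0)
                relu_grad = gain * (pre > 0) if keep_cache else None
            else:  # additive
                if self.layer_means is None:
                    raise ConfigurationError(
                        "additive attention requires layer_means (compute_layer_means)"
                    )
                shifted = pre + self.layer_means[layer - 1] * m
                act = np.maximum(shifted, 0.0)
                relu_grad = (shifted > 0).astype(np.float64) if keep_cache else None
            activations.append(act)
            if keep_cache:
                cache["relu_grad"].append(relu_grad)
            if layer in self.arch.pool_after:
                current, idx = _maxpool(act)
                if keep_cache:
                    cache["pool_idx"].append(idx)
                    cache["pool_shape"].append(act.shape)
            else:
                current = act
                if keep_cache:
                    cache["pool_idx"].append(None)
                    cache["pool_shape"].append(None)
        pooled = activations[-1].mean(axis=(2, 3))
        logits = probs = None
        if self.head_w is not None:
            logits = pooled @ self.head_w.T + self.head_b
            probs = _softmax(logits)
        return ForwardResult(
            activations=activations,
            pooled=pooled,
            logits=logits,
            probs=probs,
            cache=cache if keep_cache else None,
        )

    # -- reverse pass ------------------------------------------------------

    def backward_activity_grads(
        self, result: ForwardResult, d_pooled: np.ndarray, weight_grads: bool = False
    ):
        """Backpropagate a gradient w.r.t. pooled final-layer features.

        ``d_pooled`` has shape ``(N, K_last)``.  Returns a list of per-layer
        arrays ``dE/dx`` of shape ``(N, K, H, W)`` — gradients with respect to
        the post-rectification feature-map activities — and, if
        ``weight_grads``, also lists of convolution weight/bias gradients.
        """
        if result.cache is None:
            raise ConfigurationError("forward pass must be run with keep_cache=True")
        cache = result.cache
        n_layers = self.arch.n_layers
        h, w = result.activations[-1].shape[2:]
        d_act = np.broadcast_to(
            d_pooled[:, :, None, None] / (h * w), result.activations[-1].shape
        ).copy()
        d_x = [None] * n_layers
        d_ws = [None] * n_layers
        d_bs = [None] * n_layers
        for layer in range(n_layers, 0, -1):
            i = layer - 1
            d_x[i] = d_act
            d_pre = d_act * cache["relu_grad"][i]
            d_in, dw, db = _conv2d_backward(cache["inputs"][i], self.weights[i], d_pre)
            if weight_grads:
                d_ws[i], d_bs[i] = dw, db
            if layer > 1:
                if (layer - 1) in self.arch.pool_after:
                    d_act = _maxpool_backward(
                        d_in, cache["pool_idx"][i - 1], cache["pool_shape"][i - 1]
                    )
                else:
                    d_act = d_in
        if weight_grads:
            return d_x, d_ws, d_bs
        return d_x

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"conv{i}_w"] = w
            arrays[f"conv{i}_b"] = b
        if self.head_w is not None:
            arrays["head_w"], arrays["head_b"] = self.head_w, self.head_b
        if self.layer_means is not None:
            arrays["layer_means"] = self.layer_means
        for cond, (w, b) in self.binary_readouts.items():
            arrays[f"bin_{cond}_w"] = w
            arrays[f"bin_{cond}_b"] = np.asarray([b])
        if self.color_readout is not None:
            arrays["color_w"], arrays["color_b"] = self.color_readout
        np.savez(directory / "weights.npz", **arrays)
        manifest = {
            "n_maps": list(self.arch.n_maps),
            "pool_after": list(self.arch.pool_after),
            "input_size": self.arch.input_size,
            "n_channels": self.arch.n_channels,
            "input_mean": self.arch.input_mean,
            "classes": self.classes,
            "binary_conditions": [str(c) for c in self.binary_readouts],
        }
        (directory / "architecture.json").write_text(json.dumps(manifest, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "NetworkModel":
        directory = Path(directory)
        manifest = json.loads((directory / "architecture.json").read_text())
        arch = ArchitectureConfig(
            n_maps=tuple(manifest["n_maps"]),
            pool_after=tuple(manifest["pool_after"]),
            input_size=manifest["input_size"],
            n_channels=manifest["n_channels"],
            input_mean=manifest.get("input_mean", 0.5),
        )
        model = cls(arch)
        data = np.load(directory / "weights.npz")
        for i in range(arch.n_layers):
            model.weights[i] = data[f"conv{i}_w"]
            model.biases[i] = data[f"conv{i}_b"]
        if "head_w" in data:
            model.head_w, model.head_b = data["head_w"], data["head_b"]
        if "layer_means" in data:
            model.layer_means = data["layer_means"]
        model.classes = list(manifest["classes"])
        for cond in manifest["binary_conditions"]:
            model.binary_readouts[cond] = (
                data[f"bin_{cond}_w"], float(data[f"bin_{cond}_b"][0])
            )
        if "color_w" in data:
            model.color_readout = (data["color_w"], data["color_b"])
        return model


# ---------------------------------------------------------------------------
# Fixture training


def _adam_step(param, grad, state, lr, t, beta1=0.9, beta2=0.999, eps=1e-8):
    m, v = state
    m[:] = beta1 * m + (1 - beta1) * grad
    v[:] = beta2 * v + (1 - beta2) * grad**2
    mhat = m / (1 - beta1**t)
    vhat = v / (1 - beta2**t)
    param -= lr * mhat / (np.sqrt(vhat) + eps)


def train_fixture_network(
    train_set: st.StimulusSet | None = None,
    arch: ArchitectureConfig | None = None,
    config: TrainingConfig | None = None,
    seed: int = 0,
    n_per_class: int = 8,
) -> NetworkModel:
    """Train a small fixture network to classify orientation x color classes.

    If no training set is given, one is generated: ``n_per_class`` randomly
    phased and degraded full-field gratings for each of the 45 orientation x
    color classes.  A softmax head on spatially pooled final-layer features is
    trained jointly with the convolutional weights (Adam, cross-entropy).
    Raises :class:`TrainingError` if held-out accuracy stays below the
    configured floor.
    """
    arch = arch or ArchitectureConfig()
    if arch.n_layers < 4:
        raise ConfigurationError("fixture needs at least 4 convolutional layers")
    config = config or TrainingConfig()
    rng = np.random.default_rng(seed)
    if train_set is None:
        train_set = st.full_field_training_set(
            n_per_class, size=arch.input_size, seed=rng
        )
    classes = sorted({lab.category for img in train_set.items for lab in img.labels})
    class_index = {c: i for i, c in enumerate(classes)}
    x = st.stack_pixels(train_set)
    y = np.array(
        [class_index[next(iter(img.categories))] for img in train_set.items]
    )
    n = len(y)
    perm = rng.permutation(n)
    n_hold = max(1, int(round(config.holdout_fraction * n)))
    hold, train = perm[:n_hold], perm[n_hold:]

    model = NetworkModel(arch, rng)
    model.classes = classes
    k_last = arch.n_maps[-1]
    model.head_w = rng.standard_normal((len(classes), k_last)) * 0.01
    model.head_b = np.zeros(len(classes))

    params = model.weights + model.biases + [model.head_w, model.head_b]
    states = [(np.zeros_like(p), np.zeros_like(p)) for p in params]
    t = 0
    for epoch in range(config.epochs):
        order = rng.permutation(train)
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, yb = x[batch], y[batch]
            res = model.forward(xb, keep_cache=True)
            probs = res.probs
            d_logits = probs.copy()
            d_logits[np.arange(len(yb)), yb] -= 1.0
            d_logits /= len(yb)
            d_pooled = d_logits @ model.head_w
            d_head_w = d_logits.T @ res.pooled
            d_head_b = d_logits.sum(axis=0)
            _, d_ws, d_bs = model.backward_activity_grads(
                res, d_pooled, weight_grads=True
            )
            t += 1
            grads = d_ws + d_bs + [d_head_w, d_head_b]
            for p, g, s in zip(params, grads, states):
                if config.weight_decay:
                    g = g + config.weight_decay * p
                _adam_step(p, g, s, config.learning_rate, t)
    res = model.forward(x[hold])
    acc = float((res.probs.argmax(axis=1) == y[hold]).mean())
    model.holdout_accuracy = acc
    if acc < config.accuracy_floor:
        raise TrainingError(
            f"held-out accuracy {acc:.3f} below floor {config.accuracy_floor:.3f} "
            f"(n_holdout={n_hold}, classes={len(classes)}, epochs={config.epochs})"
        )
    return model


# ---------------------------------------------------------------------------
# Post-hoc readouts


def _pooled_features(model: NetworkModel, x: np.ndarray, batch: int = 64) -> np.ndarray:
    feats = []
    for start in range(0, len(x), batch):
        feats.append(model.forward(x[start : start + batch]).pooled)
    return np.concatenate(feats)


def attach_binary_readouts(
    model: NetworkModel,
    conditions: Sequence[object],
    train_set: st.StimulusSet,
    condition_of: "callable" = None,
    seed: int = 0,
) -> NetworkModel:
    """Attach one logistic-regression detector per condition.

    Each detector is trained on spatially pooled final-layer features of the
    (single-condition, full-field) training stimuli: positives are images
    whose labels match the condition, negatives a balanced subsample of the
    rest.  The native softmax head is left untouched so that category
    gradients remain available.
    """
    from sklearn.linear_model import LogisticRegression

    if condition_of is None:
        condition_of = lambda img, cond: img.contains_orientation(cond)
    rng = np.random.default_rng(seed)
    x = st.stack_pixels(train_set)
    feats = _pooled_features(model, x)
    if np.allclose(feats.std(axis=0), 0):
        raise TrainingError("degenerate (all-constant) features; cannot fit readouts")
    for cond in conditions:
        pos = np.array([condition_of(img, cond) for img in train_set.items])
        n_pos = int(pos.sum())
        if n_pos == 0 or n_pos == len(pos):
            raise TrainingError(f"condition {cond!r} has no positives or no negatives")
        neg_idx = np.flatnonzero(~pos)
        keep_neg = rng.choice(neg_idx, size=min(n_pos, len(neg_idx)), replace=False)
        idx = np.concatenate([np.flatnonzero(pos), keep_neg])
        clf = LogisticRegression(max_iter=2000)
        clf.fit(feats[idx], pos[idx].astype(int))
        model.binary_readouts[cond] = (clf.coef_[0].copy(), float(clf.intercept_[0]))
    return model


def attach_color_readout(
    model: NetworkModel, train_set: st.StimulusSet, seed: int = 0
) -> NetworkModel:
    """Attach a 5-way softmax color classifier on pooled final-layer features."""
    from sklearn.linear_model import LogisticRegression

    x = st.stack_pixels(train_set)
    feats = _pooled_features(model, x)
    colors = [next(iter(img.labels)).color for img in train_set.items]
    y = np.array([st.COLORS.index(c) for c in colors])
    if len(np.unique(y)) != len(st.COLORS):
        raise TrainingError("color readout training set must cover all 5 colors")
    clf = LogisticRegression(max_iter=2000)
    clf.fit(feats, y)
    # order rows by canonical color index
    w = np.zeros((len(st.COLORS), feats.shape[1]))
    b = np.zeros(len(st.COLORS))
    for row, cls in enumerate(clf.classes_):
        w[cls] = clf.coef_[row]
        b[cls] = clf.intercept_[row]
    model.color_readout = (w, b)
    return model


def binary_probability(
    model: NetworkModel, pooled: np.ndarray, condition: object
) -> np.ndarray:
    """Detector probability for one condition from pooled features."""
    if condition not in model.binary_readouts:
        raise ConfigurationError(f"no binary readout for condition {condition!r}")
    w, b = model.binary_readouts[condition]
    z = pooled @ w + b
    return 1.0 / (1.0 + np.exp(-z))


def color_probabilities(model: NetworkModel, pooled: np.ndarray) -> np.ndarray:
    """5-way color classifier probabilities from pooled features."""
    if model.color_readout is None:
        raise ConfigurationError("no color readout attached")
    w, b = model.color_readout
    return _softmax(pooled @ w.T + b)


# ---------------------------------------------------------------------------
# Recording utilities


def record_spatially_averaged_activity(
    activations: Sequence[np.ndarray],
) -> list[np.ndarray]:
    """Spatial mean of every feature map: per layer an ``(N, K)`` array."""
    return [act.mean(axis=(2, 3)) for act in activations]


def compute_layer_means(
    model: NetworkModel, images: np.ndarray, batch: int = 64
) -> np.ndarray:
    """Mean activity mu_l over all units, maps and images, per layer.

    The result is stored on the model (required for additive attention).
    """
    sums = np.zeros(model.arch.n_layers)
    counts = np.zeros(model.arch.n_layers)
    for start in range(0, len(images), batch):
        res = model.forward(images[start : start + batch])
        for i, act in enumerate(res.activations):
            sums[i] += act.sum()
            counts[i] += act.size
    mu = sums / counts
    model.layer_means = mu
    return mu
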