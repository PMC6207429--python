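"""Gradient values: per-feature-map activity changes that improve classification.

The gradient value of feature map (l, k) for condition c is the negated
error gradient of the classifier with respect to the map's activity,
averaged over space and over images of the condition:

    g_c^lk = -(1/N_c) sum_n (1/HW) sum_ij dE(n)/dx_ij^lk

For the native N-way softmax head, E(n) is the cross-entropy between the
softmax output and a one-hot target for condition c.  For detection-task
gradients the error is the binary (or 5-way color) readout's cross-entropy,
and images the readout already classifies correctly contribute zero — they
are masked out before averaging, so a perfect classifier yields an all-zero
table.  Gradient magnitudes shrink toward early layers (chain-rule
attenuation); when gradients drive attention they are therefore normalized
by the maximum absolute value at each layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .network import (
    ConfigurationError,
    NetworkModel,
    binary_probability,
    color_probabilities,
)
from .tuning import TuningTable

__all__ = [
    "GradientTable",
    "compute_category_gradients",
    "compute_task_gradients",
    "compute_color_task_gradients",
    "normalize_gradients",
    "correlate_tuning_gradients",
]


@dataclass
class GradientTable(TuningTable):
    """Per-layer gradient values g_c^lk; same layout as :class:`TuningTable`."""

    task: str = "category_softmax"
    normalized: bool = False
    degenerate_layers: tuple[int, ...] = ()


def _spatial_mean_grads(model, x, d_pooled_fn, batch=32):
    """Accumulate per-map, spatially averaged dE/dx summed over images.

    ``d_pooled_fn(res, sl)`` returns the gradient of the total (summed) error
    w.r.t. pooled final-layer features for the batch slice ``sl``.
    """
    n_layers = model.arch.n_layers
    sums = [np.zeros(k) for k in model.arch.n_maps]
    for start in range(0, len(x), batch):
        sl = slice(start, start + batch)
        res = model.forward(x[sl], keep_cache=True)
        d_pooled = d_pooled_fn(res, sl)
        d_x = model.backward_activity_grads(res, d_pooled)
        for i in range(n_layers):
            sums[i] += d_x[i].mean(axis=(2, 3)).sum(axis=0)
    return sums


def compute_category_gradients(
    model: NetworkModel,
    images_by_condition: dict[object, np.ndarray],
    batch: int = 32,
) -> GradientTable:
    """Gradient values from the native N-way softmax cross-entropy.

    ``images_by_condition[c]`` are images whose correct class is ``c`` (one
    of ``model.classes``); the target is the one-hot vector for ``c``.
    """
    if model.head_w is None:
        raise ConfigurationError("model has no softmax head")
    conditions = list(images_by_condition)
    values = {
        layer: np.zeros((k, len(conditions)))
        for layer, k in enumerate(model.arch.n_maps, start=1)
    }
    for ci, cond in enumerate(conditions):
        x = images_by_condition[cond]
        if len(x) == 0:
            raise ValueError(f"no images for condition {cond!r}")
        target = model.classes.index(cond)

        def d_pooled_fn(res, sl):
            d_logits = res.probs.copy()
            d_logits[:, target] -= 1.0  # dE/dlogits for summed cross-entropy
            return d_logits @ model.head_w

        sums = _spatial_mean_grads(model, x, d_pooled_fn, batch)
        for layer in values:
            values[layer][:, ci] = -sums[layer - 1] / len(x)
    return GradientTable(conditions=conditions, values=values, task="category_softmax")


def compute_task_gradients(
    model: NetworkModel,
    images_by_condition: dict[object, tuple[np.ndarray, np.ndarray]],
    batch: int = 32,
) -> GradientTable:
    """Gradient values from the binary detection readouts, with masking.

    ``images_by_condition[c]`` is ``(x, y)``: a balanced test-like image set
    and binary presence labels for condition ``c``.  Per-image contributions
    are zeroed for images the readout classifies correctly (decision at
    probability 0.5), so the values are driven entirely by the errors.
    """
    conditions = list(images_by_condition)
    values = {
        layer: np.zeros((k, len(conditions)))
        for layer, k in enumerate(model.arch.n_maps, start=1)
    }
    any_wrong = False
    for ci, cond in enumerate(conditions):
        x, y = images_by_condition[cond]
        y = np.asarray(y, dtype=float)

        def d_pooled_fn(res, sl):
            w, b = model.binary_readouts[cond]
            p = binary_probability(model, res.pooled, cond)
            yb = y[sl]
            wrong = (p >= 0.5) != (yb >= 0.5)
            dz = np.where(wrong, p - yb, 0.0)  # masked CE gradient wrt logit
            return dz[:, None] * w[None, :]

        w_, _ = model.binary_readouts.get(cond, (None, None))
        if w_ is None:
            raise ConfigurationError(f"no binary readout for condition {cond!r}")
        sums = _spatial_mean_grads(model, x, d_pooled_fn, batch)
        for layer in values:
            values[layer][:, ci] = -sums[layer - 1] / len(x)
        p_all = binary_probability(
            model, _pooled_all(model, x, batch), cond
        )
        any_wrong |= bool((((p_all >= 0.5) != (y >= 0.5))).any())
    if not any_wrong:
        import warnings

        warnings.warn(
            "all images correctly classified; gradient table is identically zero"
        )
    return GradientTable(conditions=conditions, values=values, task="binary_detection")


def compute_color_task_gradients(
    model: NetworkModel,
    images_by_condition: dict[object, tuple[np.ndarray, np.ndarray]],
    batch: int = 32,
) -> GradientTable:
    """Gradient values for the cross-featural color-classification task.

    For each attended orientation, ``images_by_condition[o]`` is ``(x,
    color_targets)``: two-grating images containing orientation ``o`` and the
    color index of the grating with that orientation.  The error is the 5-way
    color readout's cross-entropy with that color as target; correctly
    classified images are masked out.
    """
    conditions = list(images_by_condition)
    values = {
        layer: np.zeros((k, len(conditions)))
        for layer, k in enumerate(model.arch.n_maps, start=1)
    }
    w_color, _ = model.color_readout if model.color_readout else (None, None)
    if w_color is None:
        raise ConfigurationError("no color readout attached")
    for ci, cond in enumerate(conditions):
        x, targets = images_by_condition[cond]
        targets = np.asarray(targets, dtype=int)

        def d_pooled_fn(res, sl):
            probs = color_probabilities(model, res.pooled)
            tb = targets[sl]
            d_logits = probs.copy()
            d_logits[np.arange(len(tb)), tb] -= 1.0
            correct = probs.argmax(axis=1) == tb
            d_logits[correct] = 0.0
            return d_logits @ w_color

        sums = _spatial_mean_grads(model, x, d_pooled_fn, batch)
        for layer in values:
            values[layer][:, ci] = -sums[layer - 1] / len(x)
    return GradientTable(
        conditions=conditions, values=values, task="color_classification"
    )


def _pooled_all(model, x, batch=64):
    return np.concatenate(
        [model.forward(x[s : s + batch]).pooled for s in range(0, len(x), batch)]
    )


def normalize_gradients(table: GradientTable) -> GradientTable:
    """Scale each layer by its maximum absolute value (idempotent).

    Layers that are identically zero are left unchanged and flagged in
    ``degenerate_layers``.
    """
    values = {}
    degenerate = []
    for layer, v in table.values.items():
        m = np.abs(v).max()
        if m == 0:
            values[layer] = v.copy()
            degenerate.append(layer)
        else:
            values[layer] = v / m
    return GradientTable(
        conditions=list(table.conditions),
        values=values,
        dead={layer: d.copy() for layer, d in table.dead.items()},
        task=table.task,
        normalized=True,
        degenerate_layers=tuple(degenerate),
    )


def correlate_tuning_gradients(
    tuning: TuningTable,
    grads: GradientTable,
    n_shuffles: int = 0,
    seed: int | np.random.Generator | None = None,
) -> dict[int, dict[str, float]]:
    """Per-layer mean Pearson correlation between tuning and gradient curves.

    For every feature map, the correlation across conditions between its
    tuning values and its gradient values is computed; maps whose either
    curve has zero variance are skipped.  The shuffled control pairs each
    map's tuning curve with a random other map's gradient curve (within the
    layer).  Returns per layer: ``mean``, ``sem``, ``n`` and (if shuffles
    requested) ``shuffled_mean``, ``shuffled_sem``.
    """
    if list(tuning.conditions) != list(grads.conditions):
        raise ValueError("tuning and gradient tables must share condition order")
    rng = np.random.default_rng(seed)
    out: dict[int, dict[str, float]] = {}

    def _map_correlations(f, g, pairing):
        rs = []
        for k, j in pairing:
            a, b = f[k], g[j]
            if a.std() == 0 or b.std() == 0:
                continue
            rs.append(stats.pearsonr(a, b)[0])
        return np.asarray(rs)

    for layer in tuning.layers:
        f, g = tuning.values[layer], grads.values[layer]
        k = f.shape[0]
        rs = _map_correlations(f, g, [(i, i) for i in range(k)])
        entry = {
            "mean": float(rs.mean()) if len(rs) else np.nan,
            "sem": float(stats.sem(rs)) if len(rs) > 1 else np.nan,
            "n": int(len(rs)),
        }
        if n_shuffles > 0:
            shuffled = []
            for _ in range(n_shuffles):
                perm = rng.permutation(k)
                rs_s = _map_correlations(f, g, list(enumerate(perm)))
                shuffled.extend(rs_s.tolist())
            shuffled = np.asarray(shuffled)
            entry["shuffled_mean"] = float(shuffled.mean()) if len(shuffled) else np.nan
            entry["shuffled_sem"] = (
                float(stats.sem(shuffled)) if len(shuffled) > 1 else np.nan
            )
        out[layer] = entry
    return out
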