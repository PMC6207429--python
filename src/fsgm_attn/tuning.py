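"""Feature-map tuning values, tuning quality, preference order, shuffled controls.

A feature map's tuning value for a condition c (an object category or a
grating orientation) is its standardized mean response deviation,

    f_c = ( mean_{n in c} r(n) - rbar ) / std_n r(n) ,

where r(n) is the spatially averaged activity of the map in response to
image n, rbar the mean over all images, and the denominator the population
(root-mean-square) standard deviation over all images.  Tuning quality is
max_c |f_c|; the condition with the largest f is the map's preferred
condition, the smallest its anti-preferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .network import NetworkModel, record_spatially_averaged_activity

__all__ = [
    "ActivityRecord",
    "TuningTable",
    "record_responses",
    "compute_tuning_values",
    "tuning_quality",
    "shuffled_tuning_quality",
    "preference_order",
]

#: Responses with population standard deviation below this are "dead" maps.
DEAD_STD = 1e-12


@dataclass
class ActivityRecord:
    """Spatially averaged responses r^lk(n) with per-image condition labels.

    ``responses[l]`` is an ``(N, K_l)`` array for 1-based layer ``l``;
    ``labels`` holds one condition index per image into ``conditions``.
    """

    responses: dict[int, np.ndarray]
    labels: np.ndarray
    conditions: list

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        n = len(self.labels)
        for layer, r in self.responses.items():
            if r.shape[0] != n:
                raise ValueError(f"layer {layer}: {r.shape[0]} rows for {n} labels")
            if not np.all(np.isfinite(r)):
                raise ValueError(f"layer {layer}: non-finite responses")
        if self.labels.min(initial=0) < 0 or (
            n and self.labels.max() >= len(self.conditions)
        ):
            raise ValueError("labels must index into conditions")

    @property
    def layers(self) -> list[int]:
        return sorted(self.responses)

    @property
    def n_images(self) -> int:
        return len(self.labels)


@dataclass
class TuningTable:
    """Per-layer tuning (or gradient) values f_c^lk with dead-map flags.

    ``values[l]`` is ``(K_l, C)``; ``dead[l]`` is a boolean ``(K_l,)`` vector
    marking zero-variance maps (their values are 0 by convention).
    """

    conditions: list
    values: dict[int, np.ndarray]
    dead: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for layer, v in self.values.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"layer {layer}: non-finite tuning values")
            self.dead.setdefault(layer, np.zeros(v.shape[0], dtype=bool))

    @property
    def layers(self) -> list[int]:
        return sorted(self.values)

    def condition_index(self, condition) -> int:
        return self.conditions.index(condition)

    def column(self, condition) -> dict[int, np.ndarray]:
        """Values for one condition: per layer a ``(K_l,)`` vector."""
        c = self.condition_index(condition)
        return {layer: v[:, c] for layer, v in self.values.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for layer in self.layers:
            v = self.values[layer]
            for k in range(v.shape[0]):
                for c, cond in enumerate(self.conditions):
                    rows.append(
                        {
                            "layer": layer,
                            "feature_map": k,
                            "condition": cond,
                            "tuning_value": v[k, c],
                            "dead_flag": bool(self.dead[layer][k]),
                        }
                    )
        return pd.DataFrame(rows)


def record_responses(
    model: NetworkModel,
    images: np.ndarray,
    labels: Sequence[int],
    conditions: list,
    batch: int = 64,
) -> ActivityRecord:
    """Forward a labelled image population and collect r^lk per layer."""
    per_layer: list[list[np.ndarray]] = [[] for _ in range(model.arch.n_layers)]
    for start in range(0, len(images), batch):
        res = model.forward(images[start : start + batch])
        for i, r in enumerate(record_spatially_averaged_activity(res.activations)):
            per_layer[i].append(r)
    responses = {
        layer: np.concatenate(chunks)
        for layer, chunks in enumerate(per_layer, start=1)
    }
    return ActivityRecord(responses=responses, labels=np.asarray(labels), conditions=conditions)


def compute_tuning_values(record: ActivityRecord) -> TuningTable:
    """Standardized per-condition mean response deviations (population std)."""
    n_cond = len(record.conditions)
    if n_cond < 1:
        raise ValueError("record has no conditions")
    counts = np.bincount(record.labels, minlength=n_cond)
    if (counts < 2).any():
        bad = [record.conditions[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"conditions with fewer than 2 images: {bad}")
    values: dict[int, np.ndarray] = {}
    dead: dict[int, np.ndarray] = {}
    onehot = np.eye(n_cond)[record.labels]  # (N, C)
    for layer, r in record.responses.items():
        rbar = r.mean(axis=0)  # (K,)
        std = np.sqrt(((r - rbar) ** 2).mean(axis=0))  # population std, (K,)
        cond_mean = (onehot.T @ r) / counts[:, None]  # (C, K)
        is_dead = std < DEAD_STD
        safe_std = np.where(is_dead, 1.0, std)
        f = (cond_mean.T - rbar[:, None]) / safe_std[:, None]  # (K, C)
        f[is_dead] = 0.0
        values[layer] = f
        dead[layer] = is_dead
    return TuningTable(conditions=list(record.conditions), values=values, dead=dead)


def tuning_quality(table: TuningTable) -> dict[int, np.ndarray]:
    """Per-feature-map quality: maximum absolute tuning value, per layer."""
    return {layer: np.abs(v).max(axis=1) for layer, v in table.values.items()}


def shuffled_tuning_quality(
    record: ActivityRecord,
    n_shuffles: int,
    seed: int | np.random.Generator | None = None,
) -> dict[int, np.ndarray]:
    """Chance-level tuning quality from within-layer response shuffles.

    For each shuffle, all individual image responses at a layer are permuted
    across both images and feature maps (preserving the layer's multiset of
    responses), tuning is recomputed, and per-map qualities collected.
    Returns per layer an array of shape ``(n_shuffles, K_l)``.
    """
    rng = np.random.default_rng(seed)
    out: dict[int, list[np.ndarray]] = {layer: [] for layer in record.layers}
    for _ in range(n_shuffles):
        shuffled = {}
        for layer, r in record.responses.items():
            flat = r.ravel().copy()
            rng.shuffle(flat)
            shuffled[layer] = flat.reshape(r.shape)
        rec = ActivityRecord(
            responses=shuffled, labels=record.labels, conditions=record.conditions
        )
        q = tuning_quality(compute_tuning_values(rec))
        for layer in record.layers:
            out[layer].append(q[layer])
    return {
        layer: (np.stack(v) if v else np.empty((0, record.responses[layer].shape[1])))
        for layer, v in out.items()
    }


def preference_order(
    table: TuningTable, layer: int, feature_map: int
) -> tuple[list, object, object]:
    """Conditions sorted by descending tuning value (ties by condition index).

    Returns ``(ordered_conditions, preferred, anti_preferred)``.
    """
    f = table.values[layer][feature_map]
    order = np.lexsort((np.arange(len(f)), -f))
    ordered = [table.conditions[i] for i in order]
    return ordered, ordered[0], ordered[-1]
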