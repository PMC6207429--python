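"""Construction of attention fields and strength (beta) sweeps.

Feature-based attention modulates every unit of a feature map identically:
the modulation for map (l, k) when condition c is attended is beta * v_c^lk,
where v is the map's tuning value (or its layer-normalized gradient value).
In the positive-only variant values are rectified before use; the negated
variant flips their sign (a control that should hurt performance).  Spatial
attention sets the modulation to +beta inside the attended quadrant and
-beta outside; combined feature + spatial attention adds the two terms under
a single shared beta.

Default strength ranges follow experimental practice in this line of work:
object-category attention up to 11.85, orientation attention up to 4.8,
spatial attention up to 1, stepped by 0.15; when attention targets all
layers simultaneously the strength grid is scaled by 1/10.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .network import AttentionField, ConfigurationError, NetworkModel
from .tuning import TuningTable

__all__ = [
    "AttentionConfig",
    "BETA_MAX",
    "BETA_STEP",
    "default_beta_grid",
    "build_attention_field",
    "sweep_beta",
]

#: Maximum attention strengths per task family.
BETA_MAX = {"object": 11.85, "orientation": 4.8, "spatial": 1.0}

#: Default grid step for strength sweeps.
BETA_STEP = 0.15

SOURCES = ("tuning", "gradient", "spatial", "feature_spatial", "negated_tuning")


@dataclass(frozen=True)
class AttentionConfig:
    """Everything needed to build one attention field.

    ``source`` selects what drives the modulation; ``layers`` the (1-based)
    convolutional layers it targets; ``beta`` the overall strength.  For
    spatial / combined sources ``attended_quadrant`` must be set; for feature
    sources ``attended_condition`` must name a column of the value table.
    ``all_layers_scale`` marks configurations that target every layer, whose
    strength grid is a tenth of the single-layer one.
    """

    source: str
    layers: tuple[int, ...]
    beta: float = 0.0
    mode: str = "multiplicative"
    sign: str = "bidirectional"  # or "positive_only"
    attended_condition: object = None
    attended_quadrant: int | None = None
    all_layers_scale: bool = False
    clamp_gain: bool = False

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ConfigurationError(f"unknown source {self.source!r}")
        if self.sign not in ("bidirectional", "positive_only"):
            raise ConfigurationError(f"unknown sign handling {self.sign!r}")
        if self.beta < 0:
            raise ConfigurationError("beta must be >= 0")
        if self.source in ("spatial", "feature_spatial") and self.attended_quadrant is None:
            raise ConfigurationError(f"source {self.source!r} needs attended_quadrant")
        if self.source != "spatial" and self.attended_condition is None:
            raise ConfigurationError(f"source {self.source!r} needs attended_condition")


def _quadrant_mask(shape: tuple[int, int, int], quadrant: int) -> np.ndarray:
    """+1 inside the attended quadrant, -1 outside; shape (K, H, W)."""
    k, h, w = shape
    mask = -np.ones((h, w))
    r0 = (quadrant // 2) * (h // 2)
    c0 = (quadrant % 2) * (w // 2)
    mask[r0 : r0 + (h + 1) // 2, c0 : c0 + (w + 1) // 2] = 1.0
    return np.broadcast_to(mask, (k, h, w)).copy()


def build_attention_field(
    config: AttentionConfig,
    table: TuningTable | None,
    model: NetworkModel,
) -> AttentionField:
    """Materialize an :class:`AttentionField` for the model's geometry."""
    shapes = model.arch.layer_shapes()
    for layer in config.layers:
        if not 1 <= layer <= model.arch.n_layers:
            raise ConfigurationError(f"layer {layer} outside model (1..{model.arch.n_layers})")
    values: dict[int, np.ndarray] = {}
    feature_column = None
    if config.source in ("tuning", "gradient", "negated_tuning", "feature_spatial"):
        if table is None:
            raise ConfigurationError("feature-based attention needs a value table")
        if config.source == "gradient" and not getattr(table, "normalized", True):
            from .gradients import normalize_gradients

            table = normalize_gradients(table)
        if config.attended_condition not in table.conditions:
            raise ConfigurationError(
                f"condition {config.attended_condition!r} not in value table"
            )
        feature_column = table.column(config.attended_condition)
    for layer in config.layers:
        shape = shapes[layer - 1]
        if config.source == "spatial":
            values[layer] = config.beta * _quadrant_mask(shape, config.attended_quadrant)
            continue
        v = feature_column[layer].astype(np.float64).copy()
        if config.sign == "positive_only":
            v = np.maximum(v, 0.0)
        if config.source == "negated_tuning":
            v = -v
        if config.source == "feature_spatial":
            # literal sum of the two component fields (element-wise exact)
            s = _quadrant_mask(shape, config.attended_quadrant)
            values[layer] = config.beta * v[:, None, None] + config.beta * s
        else:
            values[layer] = config.beta * v
    return AttentionField(mode=config.mode, values=values, clamp_gain=config.clamp_gain)


def default_beta_grid(
    task: str = "orientation",
    step: float = BETA_STEP,
    beta_max: float | None = None,
    all_layers: bool = False,
) -> np.ndarray:
    """Strength grid from 0 to the task's maximum in ``step`` increments."""
    top = beta_max if beta_max is not None else BETA_MAX[task]
    scale = 0.1 if all_layers else 1.0
    n = int(np.floor(top / step + 1e-9))
    return scale * step * np.arange(n + 1)


def sweep_beta(
    model: NetworkModel,
    images: np.ndarray,
    is_positive: np.ndarray,
    condition: object,
    config_template: AttentionConfig,
    beta_grid: Sequence[float],
    table: TuningTable | None = None,
    batch: int = 64,
) -> tuple[pd.DataFrame, float]:
    """Detection rates across an attention-strength grid.

    Returns a frame with one row per beta (columns beta, TP, FP, TN, FN,
    performance) and the best-performing beta (argmax of performance, ties to
    the smaller beta).  The grid must contain 0 so the baseline is always
    present.
    """
    from .evaluate import evaluate_detection

    beta_grid = np.asarray(list(beta_grid), dtype=float)
    if len(beta_grid) == 0:
        raise ConfigurationError("beta grid must be non-empty")
    if not np.any(beta_grid == 0):
        raise ConfigurationError("beta grid must include 0 (the baseline)")
    rows = []
    for beta in beta_grid:
        cfg = replace(config_template, beta=float(beta))
        attn = (
            None
            if beta == 0
            else build_attention_field(cfg, table, model)
        )
        outcome = evaluate_detection(
            model, images, is_positive, condition, attention=attn, batch=batch
        )
        rows.append(
            {
                "beta": float(beta),
                "TP": outcome.tp,
                "FP": outcome.fp,
                "TN": outcome.tn,
                "FN": outcome.fn,
                "performance": outcome.performance,
            }
        )
    frame = pd.DataFrame(rows)
    best_idx = int(frame["performance"].to_numpy().argmax())  # first max: smaller beta
    return frame, float(frame["beta"].iloc[best_idx])
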