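"""Detection scoring, signal-detection metrics, ROC sweeps, beta matching.

Detection performance on a balanced test set is the average of the true
positive and true negative rates.  Signal detection theory summarizes the
decision behavior with two quantities computed from the true and false
positive rates via the inverse standard normal CDF (Phi^-1):

    criteria     c  = -0.5 (Phi^-1(TP) + Phi^-1(FP))
    sensitivity  d' =       Phi^-1(TP) - Phi^-1(FP)

A positive c means a stricter threshold (fewer positives); larger d' means
better separation of the positive and negative score distributions.  To keep
the terms finite, FP below 0.01 is set to 0.01 and TP above 0.99 to 0.99
(only this asymmetric pair of clips is applied by default, mirroring
standard practice; a symmetric variant is available behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .network import AttentionField, NetworkModel, binary_probability

__all__ = [
    "DetectionOutcome",
    "SDTMetrics",
    "evaluate_detection",
    "detection_decisions",
    "sdt_metrics",
    "roc_threshold_sweep",
    "match_beta_to_point",
]


@dataclass(frozen=True)
class DetectionOutcome:
    """Per-class decision rates for one detection condition."""

    tp: float
    fp: float
    tn: float
    fn: float
    n_positives: int
    n_negatives: int
    condition: object = None
    attention: str = "none"

    @property
    def performance(self) -> float:
        """Average of the true positive and true negative rates."""
        return 0.5 * (self.tp + self.tn)


@dataclass(frozen=True)
class SDTMetrics:
    criteria: float
    sensitivity: float
    tp_clipped: bool = False
    fp_clipped: bool = False


def detection_decisions(
    model: NetworkModel,
    images: np.ndarray,
    condition: object,
    attention: AttentionField | None = None,
    threshold: float = 0.5,
    batch: int = 64,
) -> np.ndarray:
    """Binary readout decisions (probability >= threshold) per image."""
    probs = []
    for start in range(0, len(images), batch):
        res = model.forward(images[start : start + batch], attention=attention)
        probs.append(binary_probability(model, res.pooled, condition))
    return np.concatenate(probs) >= threshold


def evaluate_detection(
    model: NetworkModel,
    images: np.ndarray,
    is_positive: np.ndarray,
    condition: object,
    attention: AttentionField | None = None,
    batch: int = 64,
) -> DetectionOutcome:
    """Score a balanced detection set with the condition's binary readout."""
    is_positive = np.asarray(is_positive, dtype=bool)
    n_pos = int(is_positive.sum())
    n_neg = int(len(is_positive) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative images")
    if n_pos != n_neg:
        warnings.warn(
            f"unbalanced set ({n_pos} positives, {n_neg} negatives); "
            "rates are still per-class"
        )
    decided = detection_decisions(model, images, condition, attention, batch=batch)
    tp = float(decided[is_positive].mean())
    fp = float(decided[~is_positive].mean())
    return DetectionOutcome(
        tp=tp,
        fp=fp,
        tn=1.0 - fp,
        fn=1.0 - tp,
        n_positives=n_pos,
        n_negatives=n_neg,
        condition=condition,
        attention="none" if attention is None else "applied",
    )


def sdt_metrics(tp: float, fp: float, symmetric_clip: bool = False) -> SDTMetrics:
    """Criteria and sensitivity from true/false positive rates, with clipping."""
    if not (0.0 <= tp <= 1.0 and 0.0 <= fp <= 1.0):
        raise ValueError(f"rates must lie in [0, 1]: TP={tp}, FP={fp}")
    tp_c = min(tp, 0.99)
    fp_c = max(fp, 0.01)
    if symmetric_clip:
        tp_c = max(tp_c, 0.01)
        fp_c = min(fp_c, 0.99)
    z_tp = norm.ppf(tp_c)
    z_fp = norm.ppf(fp_c)
    return SDTMetrics(
        criteria=float(-0.5 * (z_tp + z_fp)),
        sensitivity=float(z_tp - z_fp),
        tp_clipped=tp_c != tp,
        fp_clipped=fp_c != fp,
    )


def roc_threshold_sweep(
    model: NetworkModel,
    images: np.ndarray,
    is_positive: np.ndarray,
    condition: object,
    thresholds: Sequence[float] | None = None,
    batch: int = 64,
) -> np.ndarray:
    """(FP, TP) pairs as the readout's decision threshold is swept.

    No attention is applied; the curve characterizes what adjusting the
    downstream readout alone can achieve.  Returns an array of shape
    ``(n_thresholds, 3)`` with columns (threshold, FP, TP), ordered by
    increasing threshold (TP and FP are non-increasing along it).
    """
    is_positive = np.asarray(is_positive, dtype=bool)
    probs = []
    for start in range(0, len(images), batch):
        res = model.forward(images[start : start + batch])
        probs.append(binary_probability(model, res.pooled, condition))
    probs = np.concatenate(probs)
    if thresholds is None:
        thresholds = np.concatenate([[-np.inf], np.unique(probs), [np.inf]])
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    rows = []
    for th in thresholds:
        decided = probs >= th
        rows.append([th, decided[~is_positive].mean(), decided[is_positive].mean()])
    return np.asarray(rows)


def match_beta_to_point(
    betas: Sequence[float],
    fp_tp_curve: np.ndarray,
    point: tuple[float, float],
) -> float:
    """Beta of the sweep sample nearest (Euclidean) to a behavioral point.

    ``fp_tp_curve`` is ``(n, 2)`` with columns (FP, TP), one row per beta.
    Ties go to the smaller beta.
    """
    betas = np.asarray(list(betas), dtype=float)
    curve = np.asarray(fp_tp_curve, dtype=float)
    if curve.shape != (len(betas), 2):
        raise ValueError("curve must be (n_betas, 2) of (FP, TP)")
    if len(betas) == 0:
        raise ValueError("sweep must be non-empty")
    d2 = ((curve - np.asarray(point)) ** 2).sum(axis=1)
    near = d2 <= d2.min() * (1 + 1e-9) + 1e-15  # ties to numerical tolerance
    return float(betas[near].min())  # tie rule: smaller beta
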