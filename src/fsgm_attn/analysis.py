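"""Propagation analyses: activity-ratio fits, feature matching, performance links.

Attention applied at one layer changes activity at every later layer.  To
characterize those changes the spatially averaged activity of each feature
map in response to a full-field grating is recorded with and without
attention, and their ratio taken (color-averaged, for stimuli whose
orientation is both present and attended).  Under the feature-similarity
gain model (FSGM) the ratio should exceed one for orientations the map
prefers and fall below one for those it does not: ordering the nine ratios
from most to least preferred, collapsing them to five points (best ratio,
then means of successive preference pairs) and fitting a least-squares line
should give a negative slope and an intercept above one.  The feature
matching (FM) alternative predicts amplification whenever the stimulus
matches the attended feature regardless of preference; a map counts as FM
when attending its preferred orientation helps more with the preferred
stimulus present AND attending its anti-preferred helps more with the
anti-preferred present — the second clause is what separates FM from FSGM.

Two per-image measures link activity changes to performance: the slope of
attention ratios regressed on tuning values (FSGM-like behavior, image by
image), and the change in the cosine between the layer's activity and a
"positive classification" direction in a PCA-reduced activity space
(classification-aligned behavior).  Both are correlated with true-positive
rate changes, and the two correlations compared by bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from . import stimuli as st
from .attention import AttentionConfig, build_attention_field
from .evaluate import detection_decisions
from .network import AttentionField, NetworkModel, record_spatially_averaged_activity
from .tuning import TuningTable, preference_order

__all__ = [
    "ActivityRatioRecord",
    "RatioLineFit",
    "VectorAngleMeasure",
    "BootstrapComparison",
    "record_activity_ratios",
    "fsgm_ratio_fit",
    "ols_line",
    "feature_matching_fraction",
    "per_image_fsgm_slope",
    "vector_angle_measure",
    "correlate_and_bootstrap",
]

#: Baseline activities below this are excluded from ratio analyses.
ZERO_BASELINE = 1e-8

#: Recording-protocol default attention strength.
RATIO_BETA = 0.5


@dataclass
class ActivityRatioRecord:
    """With-attention / without-attention activity ratios.

    ``ratios[l]`` has shape ``(K_l, n_attended, n_stimulus)``: the ratio for
    feature map k of layer l when orientation ``orientations[a]`` is attended
    and orientation ``orientations[s]`` is shown (color-averaged, full-field).
    ``valid[l]`` marks entries whose baseline activity exceeded the
    zero-baseline floor; ``n_excluded[l]`` counts the rest.
    """

    orientations: list
    ratios: dict[int, np.ndarray]
    valid: dict[int, np.ndarray]
    n_excluded: dict[int, int]
    applied_layers: tuple[int, ...]
    beta: float
    mode: str

    def diagonal(self, layer: int) -> tuple[np.ndarray, np.ndarray]:
        """Ratios (and validity) where the attended orientation is present:
        shape ``(K, n_orientations)``."""
        r = self.ratios[layer]
        idx = np.arange(r.shape[1])
        return r[:, idx, idx], self.valid[layer][:, idx, idx]


def record_activity_ratios(
    model: NetworkModel,
    table: TuningTable,
    config_template: AttentionConfig,
    orientations: Sequence[float] = st.ORIENTATIONS,
    colors: Sequence[str] = st.COLORS,
    frequency: float = st.DEFAULT_FREQUENCY,
    attended: Sequence[float] | None = None,
    batch: int = 64,
) -> ActivityRatioRecord:
    """Record color-averaged activity ratios over the full stimulus grid.

    Full-field gratings for every orientation x color combination (fixed
    phase, no degradation) are shown once without attention and once per
    attended orientation, with the field built from ``config_template`` (its
    ``beta`` defaults to the recording-protocol value 0.5).
    """
    if config_template.beta == 0:
        config_template = replace(config_template, beta=RATIO_BETA)
    attended = list(orientations) if attended is None else list(attended)
    size = model.arch.input_size
    grid = [
        st.make_full_field_grating(st.GratingSpec(o, c, frequency, 0.0, size))
        for o in orientations
        for c in colors
    ]
    x = st.stack_pixels(grid)
    n_ori, n_col = len(orientations), len(colors)

    def color_averaged(attention: AttentionField | None) -> dict[int, np.ndarray]:
        per_layer = [[] for _ in range(model.arch.n_layers)]
        for start in range(0, len(x), batch):
            res = model.forward(x[start : start + batch], attention=attention)
            for i, r in enumerate(record_spatially_averaged_activity(res.activations)):
                per_layer[i].append(r)
        out = {}
        for i, chunks in enumerate(per_layer):
            r = np.concatenate(chunks)  # (n_ori*n_col, K)
            out[i + 1] = r.reshape(n_ori, n_col, -1).mean(axis=1).T  # (K, n_ori)
        return out

    base = color_averaged(None)
    ratios: dict[int, np.ndarray] = {}
    valid: dict[int, np.ndarray] = {}
    for layer, r0 in base.items():
        k = r0.shape[0]
        ratios[layer] = np.full((k, len(attended), n_ori), np.nan)
        valid[layer] = np.zeros((k, len(attended), n_ori), dtype=bool)
    for ai, att_ori in enumerate(attended):
        cfg = replace(config_template, attended_condition=att_ori)
        field = build_attention_field(cfg, table, model)
        with_att = color_averaged(field)
        for layer, r1 in with_att.items():
            r0 = base[layer]
            ok = r0 > ZERO_BASELINE
            ratios[layer][:, ai, :][ok] = (r1[ok] / r0[ok])
            valid[layer][:, ai, :] = ok
    n_excluded = {
        layer: int((~valid[layer]).sum()) for layer in valid
    }
    return ActivityRatioRecord(
        orientations=list(orientations),
        ratios=ratios,
        valid=valid,
        n_excluded=n_excluded,
        applied_layers=tuple(config_template.layers),
        beta=float(config_template.beta),
        mode=config_template.mode,
    )


@dataclass
class RatioLineFit:
    """Least-squares line through the five preference-ordered ratio points.

    ``slope`` and ``intercept`` are per feature map (intercept at preference
    position 0, i.e. the most preferred orientation; stored raw — plots
    conventionally report ``intercept - 1``).  ``valid`` marks maps with all
    nine ratios available.
    """

    slope: np.ndarray
    intercept: np.ndarray
    valid: np.ndarray
    points: np.ndarray  # (K, 5)


def ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ordinary least-squares slope and intercept (intercept at x=0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    dx = x - xbar
    slope = float((dx * (y - ybar)).sum() / (dx * dx).sum())
    return slope, float(ybar - slope * xbar)


def _pair_collapse(ordered: np.ndarray) -> np.ndarray:
    """Nine preference-ordered ratios -> five points: best, then pair means."""
    if ordered.shape[-1] != 9:
        raise ValueError("expected 9 preference-ordered ratios")
    return np.stack(
        [
            ordered[..., 0],
            ordered[..., 1:3].mean(axis=-1),
            ordered[..., 3:5].mean(axis=-1),
            ordered[..., 5:7].mean(axis=-1),
            ordered[..., 7:9].mean(axis=-1),
        ],
        axis=-1,
    )


def fsgm_ratio_fit(
    record: ActivityRatioRecord, table: TuningTable, layer: int
) -> RatioLineFit:
    """Per-feature-map slope/intercept of the preference-ordered ratio line."""
    diag, ok = record.diagonal(layer)
    k, n_ori = diag.shape
    if n_ori != 9:
        raise ValueError(f"FSGM ratio fit requires 9 orientations, got {n_ori}")
    f = table.values[layer]
    if f.shape != (k, n_ori):
        raise ValueError("tuning table does not match the ratio record")
    slope = np.full(k, np.nan)
    intercept = np.full(k, np.nan)
    points = np.full((k, 5), np.nan)
    valid = ok.all(axis=1) & ~table.dead[layer]
    x5 = np.arange(5.0)
    for i in np.flatnonzero(valid):
        order = np.lexsort((np.arange(n_ori), -f[i]))
        pts = _pair_collapse(diag[i, order])
        points[i] = pts
        slope[i], intercept[i] = ols_line(x5, pts)
    return RatioLineFit(slope=slope, intercept=intercept, valid=valid, points=points)


def feature_matching_fraction(
    record: ActivityRatioRecord, table: TuningTable, layer: int
) -> float:
    """Fraction of feature maps showing feature-matching behavior at a layer.

    A map is FM iff (1) with its preferred orientation attended, the ratio is
    larger when the preferred stimulus is present than when the anti-preferred
    is, and (2) with its anti-preferred attended, the ratio is larger when the
    anti-preferred stimulus is present than when the preferred is.
    """
    r = record.ratios[layer]
    ok = record.valid[layer]
    f = table.values[layer]
    orientations = record.orientations
    n_fm = 0
    n_eval = 0
    for k in range(r.shape[0]):
        if table.dead[layer][k]:
            continue
        ordered, pref, anti = preference_order(table, layer, k)
        pi = orientations.index(pref)
        ai = orientations.index(anti)
        needed = ok[k, pi, pi] and ok[k, pi, ai] and ok[k, ai, ai] and ok[k, ai, pi]
        if not needed:
            continue
        n_eval += 1
        if r[k, pi, pi] > r[k, pi, ai] and r[k, ai, ai] > r[k, ai, pi]:
            n_fm += 1
    return n_fm / n_eval if n_eval else np.nan


def per_image_fsgm_slope(
    model: NetworkModel,
    images: np.ndarray,
    attention: AttentionField,
    tuning_for_condition: np.ndarray,
    dead: np.ndarray,
    layer: int,
    batch: int = 64,
) -> np.ndarray:
    """Per-image slope of attention ratios regressed on tuning values.

    For each image (all containing the attended orientation), the ratio of
    with-attention to without-attention spatially averaged activity of every
    live feature map at ``layer`` is regressed on the maps' tuning values for
    the attended orientation; the OLS slope is the image's FSGM-likeness.
    Maps with near-zero baseline are excluded image by image.
    """

    def record(att):
        out = []
        for start in range(0, len(images), batch):
            res = model.forward(images[start : start + batch], attention=att)
            out.append(res.activations[layer - 1].mean(axis=(2, 3)))
        return np.concatenate(out)

    r0 = record(None)
    r1 = record(attention)
    slopes = np.full(len(images), np.nan)
    for n in range(len(images)):
        ok = (r0[n] > ZERO_BASELINE) & ~dead
        if ok.sum() < 2 or tuning_for_condition[ok].std() == 0:
            continue
        ratio = r1[n, ok] / r0[n, ok]
        slopes[n], _ = ols_line(tuning_for_condition[ok], ratio)
    return slopes


@dataclass
class VectorAngleMeasure:
    """Cosine alignment with the positive-classification direction."""

    median_cos_without: float
    median_cos_with: float
    n_components: int
    retained_variance: float

    @property
    def difference(self) -> float:
        return self.median_cos_with - self.median_cos_without


def vector_angle_measure(
    model: NetworkModel,
    all_images: np.ndarray,
    condition: object,
    present_images: np.ndarray,
    attention: AttentionField,
    layer: int,
    variance_floor: float = 0.90,
    batch: int = 64,
) -> VectorAngleMeasure:
    """Attention's shift of activity toward the positive-classification axis.

    A PCA basis retaining at least ``variance_floor`` of the variance is
    fitted on the layer's (spatially averaged) responses to ``all_images``
    without attention.  The positive-classification direction is the mean
    reduced response over images the readout classifies positive (true and
    false positives, no attention).  For ``present_images`` (which contain
    the condition), the cosine between each reduced response and that
    direction is computed with and without attention; the medians and their
    difference summarize the shift.
    """
    from sklearn.decomposition import PCA

    def responses(x, att=None):
        out = []
        for start in range(0, len(x), batch):
            res = model.forward(x[start : start + batch], attention=att)
            out.append(res.activations[layer - 1].mean(axis=(2, 3)))
        return np.concatenate(out)

    r_all = responses(all_images)
    if np.allclose(r_all.std(axis=0), 0):
        raise ValueError("degenerate activity (zero variance); cannot fit PCA")
    pca = PCA(n_components=variance_floor, svd_solver="full")
    pca.fit(r_all)
    classified_pos = detection_decisions(model, all_images, condition, batch=batch)
    if not classified_pos.any():
        raise ValueError("no images classified positive; direction undefined")
    direction = pca.transform(r_all[classified_pos]).mean(axis=0)
    norm_d = np.linalg.norm(direction)
    if norm_d == 0:
        raise ValueError("zero positive-classification direction")

    def cosines(att):
        z = pca.transform(responses(present_images, att))
        norms = np.linalg.norm(z, axis=1)
        ok = norms > 0
        return (z[ok] @ direction) / (norms[ok] * norm_d)

    cos0 = cosines(None)
    cos1 = cosines(attention)
    return VectorAngleMeasure(
        median_cos_without=float(np.median(cos0)),
        median_cos_with=float(np.median(cos1)),
        n_components=int(pca.n_components_),
        retained_variance=float(pca.explained_variance_ratio_.sum()),
    )


@dataclass
class BootstrapComparison:
    """Two activity-performance correlations and their bootstrap comparison."""

    correlation_a: float
    correlation_b: float
    boot_a: np.ndarray
    boot_b: np.ndarray
    p_value: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]


def correlate_and_bootstrap(
    pairs_a: np.ndarray,
    pairs_b: np.ndarray,
    n_boot: int = 100,
    seed: int | np.random.Generator | None = None,
    use_percentile_ci: bool = False,
) -> BootstrapComparison:
    """Pearson correlations of two measure-performance pairings, compared.

    ``pairs_a`` and ``pairs_b`` are ``(n, 2)`` arrays of (measure,
    performance-change) pairs.  Both coefficients are recomputed on ``n_boot``
    resamples (with replacement; shared resample indices when the two span the
    same experimental units) and compared with a two-sided paired t-test on
    the replicate differences.  ``use_percentile_ci`` additionally reports
    95% percentile intervals of the replicates (always included in the
    result; the flag is kept for API clarity).
    """
    rng = np.random.default_rng(seed)
    pairs_a = np.asarray(pairs_a, dtype=float)
    pairs_b = np.asarray(pairs_b, dtype=float)

    def corr(p):
        if p[:, 0].std() == 0 or p[:, 1].std() == 0:
            return np.nan
        return stats.pearsonr(p[:, 0], p[:, 1])[0]

    r_a, r_b = corr(pairs_a), corr(pairs_b)
    paired = len(pairs_a) == len(pairs_b)
    boot_a = np.empty(n_boot)
    boot_b = np.empty(n_boot)
    for i in range(n_boot):
        idx_a = rng.integers(0, len(pairs_a), size=len(pairs_a))
        idx_b = idx_a if paired else rng.integers(0, len(pairs_b), size=len(pairs_b))
        boot_a[i] = corr(pairs_a[idx_a])
        boot_b[i] = corr(pairs_b[idx_b])
    good = np.isfinite(boot_a) & np.isfinite(boot_b)
    if good.sum() >= 2:
        if paired:
            p = float(stats.ttest_rel(boot_a[good], boot_b[good]).pvalue)
        else:
            p = float(stats.ttest_ind(boot_a[good], boot_b[good]).pvalue)
    else:
        p = np.nan
    ci = lambda b: tuple(np.percentile(b[np.isfinite(b)], [2.5, 97.5]))
    return BootstrapComparison(
        correlation_a=float(r_a),
        correlation_b=float(r_b),
        boot_a=boot_a,
        boot_b=boot_b,
        p_value=p,
        ci_a=ci(boot_a),
        ci_b=ci(boot_b),
    )
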