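"""Synthetic visual stimuli: colored oriented gratings and composite test images.

All experiments in this package run on programmatically generated stimuli, so
no external image data is ever required.  The basic element is a full-field
sinusoidal luminance grating rendered in one of five named colors.  Composite
test images place two half-size gratings in random quadrants (the remaining
quadrants black), transparently merge two images (pixel-wise mean), or tile
four half-resolution images on a 2x2 grid.

Conventions
-----------
* Images are ``(size, size, 3)`` float arrays with values in ``[0, 1]``.
* Orientation is in degrees in ``[0, 180)``; a 0-degree grating varies along
  the row (vertical) axis, i.e. it has horizontal stripes.
* Spatial frequency is in cycles per pixel (default 0.025).
* Quadrants are indexed 0 = top-left, 1 = top-right, 2 = bottom-left,
  3 = bottom-right; ``None`` marks a full-field stimulus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PALETTE",
    "ORIENTATIONS",
    "COLORS",
    "GratingSpec",
    "StimulusLabel",
    "ImageStimulus",
    "StimulusSet",
    "make_full_field_grating",
    "make_two_grating_image",
    "make_merged_image",
    "make_array_image",
    "build_balanced_detection_set",
    "two_grating_recipe",
    "full_field_training_set",
    "stack_pixels",
    "save_stimulus_set",
    "load_stimulus_set",
]

#: RGB triplets for the five named grating colors.  The palette is a package
#: constant so that train and test stimuli always use identical colors.
PALETTE: dict[str, tuple[float, float, float]] = {
    "red": (1.0, 0.0, 0.0),
    "green": (0.0, 1.0, 0.0),
    "blue": (0.0, 0.0, 1.0),
    "orange": (1.0, 0.5, 0.0),
    "purple": (0.5, 0.0, 1.0),
}

#: The nine grating orientations used throughout (degrees).
ORIENTATIONS: tuple[int, ...] = tuple(range(0, 180, 20))

#: Color names in canonical order.
COLORS: tuple[str, ...] = ("red", "green", "blue", "orange", "purple")

#: Default spatial frequency in cycles per pixel.
DEFAULT_FREQUENCY = 0.025

#: Default canvas size in pixels for the small fixture-scale stimuli.
DEFAULT_SIZE = 64


class StimulusError(ValueError):
    """Invalid stimulus specification or construction request."""


def category_label(orientation: float, color: str) -> str:
    """Canonical class label for an orientation x color combination."""
    return f"ori{int(round(orientation))}_{color}"


@dataclass(frozen=True)
class GratingSpec:
    """Parameters of a full-field sinusoidal grating.

    Parameters
    ----------
    orientation
        Grating orientation in degrees, in ``[0, 180)``.
    color
        One of the five palette color names.
    frequency
        Spatial frequency in cycles per pixel (> 0).
    phase
        Phase offset in radians.
    size
        Side length of the square canvas in pixels (>= 8).
    """

    orientation: float
    color: str
    frequency: float = DEFAULT_FREQUENCY
    phase: float = 0.0
    size: int = DEFAULT_SIZE

    def __post_init__(self) -> None:
        if not (0.0 <= self.orientation < 180.0):
            raise StimulusError(f"orientation must be in [0, 180): {self.orientation}")
        if self.color not in PALETTE:
            raise StimulusError(
                f"unknown color {self.color!r}; choose from {sorted(PALETTE)}"
            )
        if self.frequency <= 0:
            raise StimulusError("frequency must be > 0")
        if self.size < 8:
            raise StimulusError("size must be >= 8 pixels")


@dataclass(frozen=True)
class StimulusLabel:
    """One labelled component of an image (a grating or composite tile)."""

    orientation: float
    color: str
    quadrant: int | None = None  # None = full-field

    def __post_init__(self) -> None:
        if self.quadrant is not None and self.quadrant not in (0, 1, 2, 3):
            raise StimulusError(f"quadrant must be in 0..3 or None: {self.quadrant}")

    @property
    def category(self) -> str:
        return category_label(self.orientation, self.color)


@dataclass
class ImageStimulus:
    """A labelled RGB image with pixel values in [0, 1]."""

    pixels: np.ndarray  # (H, W, 3)
    labels: tuple[StimulusLabel, ...] = ()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise StimulusError(f"pixels must be (H, W, 3): {self.pixels.shape}")
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1 + 1e-12:
            raise StimulusError("pixel values must lie in [0, 1]")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def categories(self) -> frozenset[str]:
        return frozenset(lab.category for lab in self.labels)

    @property
    def orientations(self) -> frozenset[float]:
        return frozenset(lab.orientation for lab in self.labels)

    def contains_orientation(self, orientation: float) -> bool:
        return any(np.isclose(lab.orientation, orientation) for lab in self.labels)


@dataclass
class StimulusSet:
    """An ordered collection of stimuli for one detection condition."""

    items: list[ImageStimulus]
    condition: object = None
    is_positive: np.ndarray | None = None  # bool per item; None for train sets

    def __post_init__(self) -> None:
        if self.is_positive is not None:
            self.is_positive = np.asarray(self.is_positive, dtype=bool)
            if len(self.is_positive) != len(self.items):
                raise StimulusError("is_positive length must match items")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def positive_fraction(self) -> float:
        if self.is_positive is None:
            raise StimulusError("set carries no positive/negative labels")
        return float(np.mean(self.is_positive))


def _grating_luminance(spec: GratingSpec) -> np.ndarray:
    """Luminance pattern 0.5 + 0.5 sin(2 pi f (i cos t + j sin t) + phase)."""
    theta = np.deg2rad(spec.orientation)
    i, j = np.meshgrid(
        np.arange(spec.size), np.arange(spec.size), indexing="ij"
    )
    t = i * np.cos(theta) + j * np.sin(theta)
    return 0.5 + 0.5 * np.sin(2.0 * np.pi * spec.frequency * t + spec.phase)


def _degrade(
    pixels: np.ndarray,
    fraction: float,
    rng: np.random.Generator,
    block_range: tuple[int, int] = (4, 16),
) -> np.ndarray:
    """Zero exactly ``floor(fraction * size**2)`` pixels in contiguous blocks.

    Square blocks with side drawn uniformly from ``block_range`` are placed
    uniformly at random (clipped at the borders, overlaps allowed) until the
    number of uniquely zeroed pixels reaches the target; excess pixels of the
    final block are un-zeroed so the count is exact.
    """
    size = pixels.shape[0]
    target = int(np.floor(fraction * size * size))
    if target == 0:
        return pixels
    mask = np.zeros((size, size), dtype=bool)
    count = 0
    while count < target:
        side = int(rng.integers(block_range[0], block_range[1] + 1))
        r = int(rng.integers(0, size))
        c = int(rng.integers(0, size))
        block = np.zeros_like(mask)
        block[r : min(r + side, size), c : min(c + side, size)] = True
        new = block & ~mask
        n_new = int(new.sum())
        if count + n_new > target:
            # trim the surplus from the newly covered pixels (row-major order)
            excess = count + n_new - target
            idx = np.flatnonzero(new.ravel())
            new.ravel()[idx[n_new - excess :]] = False
        mask |= new
        count = int(mask.sum())
    out = pixels.copy()
    out[mask] = 0.0
    return out


def make_full_field_grating(
    spec: GratingSpec,
    degrade_fraction: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> ImageStimulus:
    """Render a full-field colored grating, optionally block-degraded.

    Parameters
    ----------
    spec
        Grating parameters.
    degrade_fraction
        Fraction of pixels (in ``[0, 0.7]``) to zero out in contiguous
        blocks, emulating the random degradation used to diversify the
        training stimuli.
    seed
        Seed or generator for block placement; required only if
        ``degrade_fraction > 0``.
    """
    if not (0.0 <= degrade_fraction <= 0.7):
        raise StimulusError(f"degrade_fraction must be in [0, 0.7]: {degrade_fraction}")
    lum = _grating_luminance(spec)
    rgb = np.asarray(PALETTE[spec.color])
    pixels = lum[:, :, None] * rgb[None, None, :]
    if degrade_fraction > 0:
        rng = np.random.default_rng(seed)
        pixels = _degrade(pixels, degrade_fraction, rng)
    return ImageStimulus(
        pixels=pixels,
        labels=(StimulusLabel(spec.orientation, spec.color, quadrant=None),),
    )


def make_two_grating_image(
    spec_a: GratingSpec,
    spec_b: GratingSpec,
    canvas_size: int = DEFAULT_SIZE,
    seed: int | np.random.Generator | None = None,
) -> ImageStimulus:
    """Place two half-size gratings in two random quadrants; the rest is black.

    The two gratings must differ in both orientation and color.  Labels record
    the quadrant of each grating.
    """
    if np.isclose(spec_a.orientation, spec_b.orientation):
        raise StimulusError("the two gratings must have different orientations")
    if spec_a.color == spec_b.color:
        raise StimulusError("the two gratings must have different colors")
    if canvas_size % 2 != 0:
        raise StimulusError("canvas_size must be even")
    rng = np.random.default_rng(seed)
    half = canvas_size // 2
    quadrants = rng.choice(4, size=2, replace=False)
    canvas = np.zeros((canvas_size, canvas_size, 3))
    labels = []
    for spec, quad in zip((spec_a, spec_b), quadrants):
        patch = make_full_field_grating(replace(spec, size=half)).pixels
        r0 = (quad // 2) * half
        c0 = (quad % 2) * half
        canvas[r0 : r0 + half, c0 : c0 + half] = patch
        labels.append(StimulusLabel(spec.orientation, spec.color, quadrant=int(quad)))
    return ImageStimulus(pixels=canvas, labels=tuple(labels))


def make_merged_image(image_a: ImageStimulus, image_b: ImageStimulus) -> ImageStimulus:
    """Transparently overlay two images: each is halved, then they are summed."""
    if image_a.pixels.shape != image_b.pixels.shape:
        raise StimulusError(
            f"shape mismatch: {image_a.pixels.shape} vs {image_b.pixels.shape}"
        )
    pixels = (image_a.pixels + image_b.pixels) / 2.0
    return ImageStimulus(pixels=pixels, labels=image_a.labels + image_b.labels)


def _block_mean_downscale(pixels: np.ndarray, factor: int = 2) -> np.ndarray:
    h, w, c = pixels.shape
    if h % factor or w % factor:
        raise StimulusError("image dimensions must be divisible by the scale factor")
    return pixels.reshape(h // factor, factor, w // factor, factor, c).mean(axis=(1, 3))


def make_array_image(
    images: Sequence[ImageStimulus], canvas_size: int | None = None
) -> ImageStimulus:
    """Tile four half-resolution images on a 2x2 grid.

    Downscaling uses block-mean resampling.  The four inputs must carry
    distinct category labels.
    """
    if len(images) != 4:
        raise StimulusError("exactly 4 images required")
    cats = [img.categories for img in images]
    for i in range(4):
        for j in range(i + 1, 4):
            if cats[i] & cats[j]:
                raise StimulusError("array tiles must have distinct categories")
    if canvas_size is None:
        canvas_size = images[0].size
    if any(img.size != canvas_size for img in images):
        raise StimulusError("all inputs must match the canvas size")
    half = canvas_size // 2
    canvas = np.zeros((canvas_size, canvas_size, 3))
    labels = []
    for quad, img in enumerate(images):
        tile = _block_mean_downscale(img.pixels, img.size // half)
        r0 = (quad // 2) * half
        c0 = (quad % 2) * half
        canvas[r0 : r0 + half, c0 : c0 + half] = tile
        for lab in img.labels:
            labels.append(StimulusLabel(lab.orientation, lab.color, quadrant=quad))
    return ImageStimulus(pixels=canvas, labels=tuple(labels))


def two_grating_recipe(
    orientation: float,
    canvas_size: int = DEFAULT_SIZE,
    frequency: float = DEFAULT_FREQUENCY,
    quadrant: int | None = None,
    random_phase: bool = True,
) -> Callable[[bool, np.random.Generator], ImageStimulus]:
    """Recipe producing two-grating quadrant test images for one condition.

    A positive image contains a grating at ``orientation`` (placed in
    ``quadrant`` if given, otherwise in a random quadrant); a negative image
    contains two gratings at other orientations.  Colors are always distinct
    within an image.
    """
    others = [o for o in ORIENTATIONS if not np.isclose(o, orientation)]

    def build(positive: bool, rng: np.random.Generator) -> ImageStimulus:
        colors = rng.choice(len(COLORS), size=2, replace=False)
        phases = rng.uniform(0, 2 * np.pi, size=2) if random_phase else (0.0, 0.0)
        if positive:
            ori_a = orientation
            ori_b = others[rng.integers(len(others))]
        else:
            pick = rng.choice(len(others), size=2, replace=False)
            ori_a, ori_b = others[pick[0]], others[pick[1]]
        spec_a = GratingSpec(ori_a, COLORS[colors[0]], frequency, phases[0], canvas_size)
        spec_b = GratingSpec(ori_b, COLORS[colors[1]], frequency, phases[1], canvas_size)
        img = make_two_grating_image(spec_a, spec_b, canvas_size, seed=rng)
        if positive and quadrant is not None:
            # re-draw until the target grating lands in the attended quadrant
            while img.labels[0].quadrant != quadrant:
                img = make_two_grating_image(spec_a, spec_b, canvas_size, seed=rng)
        return img

    return build


def build_balanced_detection_set(
    condition: object,
    n: int,
    generator: Callable[[bool, np.random.Generator], ImageStimulus],
    seed: int | np.random.Generator | None = None,
) -> StimulusSet:
    """Build a 50/50 balanced detection test set of ``n`` images.

    ``generator(positive, rng)`` must return an image that does (or does not)
    contain the searched-for condition.  Order of positives and negatives is
    shuffled deterministically by the seed.
    """
    if n % 2 != 0:
        raise StimulusError("n must be even for a balanced set")
    rng = np.random.default_rng(seed)
    flags = np.array([True] * (n // 2) + [False] * (n // 2))
    rng.shuffle(flags)
    items = [generator(bool(flag), rng) for flag in flags]
    return StimulusSet(items=items, condition=condition, is_positive=flags)


def full_field_training_set(
    n_per_class: int,
    size: int = DEFAULT_SIZE,
    frequency: float = DEFAULT_FREQUENCY,
    degrade: bool = True,
    seed: int | np.random.Generator | None = None,
) -> StimulusSet:
    """Full-field gratings covering all orientation x color classes.

    Each image has a random phase and (if ``degrade``) a random block
    degradation drawn uniformly from 0-70% of pixels, which diversifies the
    training stimuli.
    """
    rng = np.random.default_rng(seed)
    items = []
    for orientation in ORIENTATIONS:
        for color in COLORS:
            for _ in range(n_per_class):
                spec = GratingSpec(
                    orientation, color, frequency, rng.uniform(0, 2 * np.pi), size
                )
                frac = rng.uniform(0.0, 0.7) if degrade else 0.0
                items.append(make_full_field_grating(spec, frac, seed=rng))
    return StimulusSet(items=items)


def stack_pixels(stimuli: Sequence[ImageStimulus] | StimulusSet) -> np.ndarray:
    """Stack stimuli into a ``(N, 3, H, W)`` array (channels-first)."""
    items = stimuli.items if isinstance(stimuli, StimulusSet) else list(stimuli)
    return np.stack([img.pixels.transpose(2, 0, 1) for img in items])


# ---------------------------------------------------------------------------
# Disk round-trip: PNG images plus a JSON-lines label manifest


def save_stimulus_set(stim_set: StimulusSet, directory: str | Path) -> Path:
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.jsonl"
    with manifest.open("w") as fh:
        for i, img in enumerate(stim_set.items):
            fname = f"stim_{i:05d}.png"
            arr = np.clip(np.round(img.pixels * 255), 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(directory / fname)
            record = {
                "filename": fname,
                "labels": [
                    {"orientation": lab.orientation, "color": lab.color,
                     "quadrant": lab.quadrant}
                    for lab in img.labels
                ],
                "condition": stim_set.condition,
                "positive": (
                    bool(stim_set.is_positive[i])
                    if stim_set.is_positive is not None
                    else None
                ),
            }
            fh.write(json.dumps(record) + "\n")
    return manifest


def load_stimulus_set(directory: str | Path) -> StimulusSet:
    from PIL import Image

    directory = Path(directory)
    items, flags, condition = [], [], None
    with (directory / "manifest.jsonl").open() as fh:
        for line in fh:
            rec = json.loads(line)
            arr = np.asarray(Image.open(directory / rec["filename"]), dtype=np.float64)
            labels = tuple(
                StimulusLabel(lab["orientation"], lab["color"], lab["quadrant"])
                for lab in rec["labels"]
            )
            items.append(ImageStimulus(pixels=arr / 255.0, labels=labels))
            condition = rec["condition"]
            flags.append(rec["positive"])
    is_positive = None if any(f is None for f in flags) else np.asarray(flags, bool)
    return StimulusSet(items=items, condition=condition, is_positive=is_positive)
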