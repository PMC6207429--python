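# Methods

This package studies how gain modulation of the kind attributed to visual
attention changes the behavior of a layered convolutional model of the
ventral stream. It implements the feature-similarity gain model (FSGM) —
attention scales a neuron's activity in proportion to its mean-subtracted
preference for the attended feature — together with a gradient-based
alternative, and measures the behavioral (detection rates, signal-detection
metrics) and neural (activity-ratio) consequences.

## Model

The network is a stack of 3×3 convolutions with rectification and
interspersed 2×2 max pooling:

    x_ij^lk = [ (W^lk ⋆ X^(l-1))_ij ]_+

where `x_ij^lk` is the activity of the unit at position (i, j) of feature
map k in layer l, ⋆ is 2-D convolution and `[·]_+` is the rectifier. Pixels
are centered (−0.5) before the first convolution, the usual mean-subtraction
preprocessing for networks of this family. The network, including the
reverse pass used for training and for gradient values, is implemented
directly in numpy so that the attention hook and the per-unit gradients are
fully transparent; the backward pass is validated against central finite
differences in the test suite.

Attention enters at the rectifier of targeted layers in one of two modes:

* multiplicative — `x = (1 + β f_c^lk) [I]_+` (the ReLU slope is scaled);
* additive — `x = [I + μ_l β f_c^lk]_+`, where μ_l is the layer's mean
  activity level over a reference image population.

`f_c^lk` is the value driving the modulation (tuning or normalized gradient
value for the attended condition c), β ≥ 0 the overall strength. In the
bidirectional variant values are used as-is; in the positive-only variant
they are rectified first. Spatial attention replaces the value with ±1
depending on whether the unit's position lies in the attended quadrant;
combined feature + spatial attention adds the two terms under one shared β.
Eq.-literal behavior is kept for large β: the multiplicative gain may go
negative (a `clamp_gain` flag clamps it at zero when unwanted).

Tuning values are standardized mean response deviations: the spatially
averaged response of a feature map to images of condition c, minus its mean
response over all images, divided by the population (root-mean-square)
standard deviation over all images. Maps with zero response variance are
flagged "dead" and assigned 0. Gradient values are negated classifier-error
gradients with respect to feature-map activity, averaged over space and
images; for detection tasks, images the readout already classifies
correctly are masked out before averaging (the masking reproduces the
stated property that correct classifications contribute no gradient; a loss
that vanishes at correct classification would be an alternative mechanism).
When gradients drive attention they are normalized per layer by the maximum
absolute value, since raw magnitudes shrink with chain-rule depth.

## Fixture network and synthetic stimuli

No pretrained weights or natural-image data are used. The stimulus family
is full-field sinusoidal gratings at nine orientations (0°–160° in 20°
steps) in five colors (red, green, blue, orange, purple; fixed RGB
palette), spatial frequency 0.025 cycles/pixel, random phase. Training
images are diversified by zeroing random square blocks (side 4–16 px)
covering a uniformly drawn 0–70% of pixels; the zeroed count is exact to
the pixel. Composite test images place two half-size gratings of different
orientation and color in two random quadrants (rest black); merged images
average two images pixel-wise; array images tile four block-mean-downscaled
images 2×2. Detection test sets are balanced 50/50.

The fixture network (default: five convolutional layers of 8–32 maps,
pools after layers 2 and 4, 64-px canvas) is trained end-to-end with Adam
(lr 1e-2, 40 epochs, batch 32, cross-entropy) to classify the 45
orientation×color classes from spatially pooled final-layer features, with
a held-out split and a configurable accuracy floor. Binary detection
readouts (one logistic regression per orientation), a 5-way color softmax,
and the native 45-way head coexist; the native head serves the
category-gradient computation.

Distributed experiments (test suite and `scripts/acceptance.py`) run a
reduced instance — 32-px canvas, feature maps (6, 8, 8, 12, 24), 8–12
training images per class, 40–100 test images per orientation — the
problem size at which the full pipeline (training, sweeps, recordings,
bootstrap) completes in a few CPU-minutes while every directional effect is
still resolvable. At 0.025 cycles/pixel a 16-px quadrant patch contains
under half a grating cycle, so absolute detection performance is modest
(mid-50s %); the attention effects of interest are differences against the
β=0 baseline, which are robust at this scale.

## Analyses

* Detection performance is the mean of true-positive and true-negative
  rates on balanced sets. Criteria `c = −0.5(Φ⁻¹(TP) + Φ⁻¹(FP))` and
  sensitivity `d′ = Φ⁻¹(TP) − Φ⁻¹(FP)`, with FP < 0.01 floored at 0.01 and
  TP > 0.99 capped at 0.99 (exactly this asymmetric pair by default, the
  convention in the source analyses; symmetric clipping is a flag). ROC
  curves come from sweeping the readout threshold with no attention.
  Model-to-behavior matching picks the sweep sample (0.15-step β grid)
  nearest to a given (FP, TP) point, ties to the smaller β.
* Activity ratios: spatially averaged activity with attention divided by
  without, on full-field gratings, color-averaged, for stimuli whose
  orientation is present and attended (present-only; the attended-absent
  stimuli feed only the feature-matching criteria). Baselines below 1e-8
  are excluded and counted. Ordering a map's nine ratios from most to least
  preferred, collapsing to five points (best ratio, then means of
  successive preference pairs — pair-averaging mirrors the classic
  electrophysiology analysis), and fitting an ordinary least-squares line
  gives the FSGM signature: negative slope, intercept > 1. The intercept is
  defined at preference position 0 and stored raw; reports subtract 1.
  Recording-protocol default β = 0.5.
* Feature matching (FM): a map is FM iff attending its preferred
  orientation yields a larger ratio with the preferred stimulus present
  than with the anti-preferred present, AND attending its anti-preferred
  yields a larger ratio with the anti-preferred present than with the
  preferred. The second clause excludes pure-FSGM maps by construction.
* Per-image measures: (i) the OLS slope of a single image's activity
  ratios regressed on tuning values (β recovers exactly when attention is
  applied at the recorded layer in multiplicative mode); (ii) the change in
  the median cosine between the layer's activity and a positive-
  classification direction — the mean activity over images classified
  positive — in a PCA space retaining ≥ 90% variance. The PCA is fitted on
  the pooled no-attention responses to all images (positives + negatives).
  Both measures pair with true-positive-rate changes; their correlations
  are compared over 100 bootstrap replicates (shared resample indices when
  the units coincide) with a two-sided paired t-test — statistically
  unconventional but kept as the protocol's literal comparison; percentile
  intervals of the replicates are reported alongside.

## Numerical choices and edge cases

* Population (not Bessel-corrected) standard deviation in the tuning
  denominator, matching the plain mean-square form of the definition.
* Preference ties break by ascending condition index.
* β grids step 0.15 and include 0; when attention targets all layers at
  once the grid is scaled by 1/10. Default maxima: 11.85 (object tasks),
  4.8 (orientation), 1.0 (spatial).
* Combined feature+spatial fields are built as the exact element-wise sum
  of the two component fields; one shared β (per-component strengths would
  be an extension).
* Nearest-β matching uses discrete sweep samples, no interpolation; tie
  tolerance 1e-9 relative on squared distance.
* Degradation can also be applied to test stimuli but is off by default:
  its purpose is training-set diversity.
* Zero-variance layers are left unchanged (and flagged) by gradient
  normalization; dead maps are excluded from ratio fits and FM counts.
* Weight persistence uses an .npz container with a JSON architecture
  manifest; cross-platform bit-exactness is not promised (1e-6 relative).

## What the synthetic stimuli do and do not show

The grating family exercises every mechanism the package implements —
tuning estimation, gain propagation, detection readouts, SDT, ratio
analyses — under fully controlled conditions. It does not emulate natural
image statistics, object category structure, or the over-representation of
particular orientations in natural scenes; absolute performance figures at
fixture scale are therefore not comparable to networks trained on natural
images, and passing tests certify the mechanisms and their directional
effects, not natural-image performance levels. The category-task machinery
(merged/array composites, balanced category sets) is exercised with
orientation×color classes standing in for object categories.

## Known limitations

* The fixture is feed-forward and noise-free; recurrence, correlated
  variability and skip connections are out of scope.
* The color-classification cross-featural task is implemented and tested
  for mechanism (gradients via the 5-way color readout), but its
  layer-by-layer correlation structure is only meaningful on deeper
  networks.
* FM fractions at fixture depth are small: with five layers there is
  little room for FSGM effects to transform downstream.
* Behavioral datasets for β-matching are user-supplied (label, FP, TP)
  points; none ship with the package.
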