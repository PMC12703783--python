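# Methods

This note documents the models, numerical choices and study conditions
behind `orchardet`, in the spirit of a methods appendix: what each stage
computes, which parameters matter, what the synthetic data emulate, and
what the tests do and do not establish about real orchard imagery.

## Pipeline model and assumptions

The pipeline is a two-stream detector: a *semantic* stream that runs the
detector on an enhanced image F(I, M), and a *baseline* stream that runs
it on the raw image, fused convexly with a data-dependent weight λ.  The
enhancement is driven entirely by a class-agnostic binary mask M obtained
from text-prompted segmentation, so the approach assumes (a) a
vision-language embedding in which text and image-tile similarity is
meaningful, and (b) a promptable segmenter that turns a handful of seed
points into a structurally faithful mask.  Neither model is trained or
bundled here; both sit behind callable seams, and everything downstream of
the seams is exact, deterministic numpy.

All modules operate untrained, with identity-style initializations chosen
so the forward passes are analytically predictable (see below).  Training
loops, augmentation and gradients are out of scope.

## Stage-by-stage detail

**Tiling and prompting.** Tiles are square (`tile_size`, default 16 px) on
a stride (default 8 px); when the stride does not cover the image exactly a
final row/column of tiles is clamped flush to the border, so coverage is
total without resizing.  Similarities are cosines, clipped to [−1, 1];
normalization is min-max, with zero-range maps flagged degenerate rather
than divided by zero.  Prompt selection is greedy thresholded peak-picking:
tile centers in non-increasing activation order (row-major tie-break),
keeping points with activation ≥ `rel_threshold`·max (default 0.7) that are
at Chebyshev distance ≥ `min_separation` (default: the tile size) from
every kept point, up to `max_points` (default 5).  These defaults are
design choices, exposed in the config.

**Mask prior.** The segmenter is invoked once with the full point set.
The reference backend grows a region per seed — 4-connected breadth-first
collection of pixels whose Euclidean RGB distance (0–255 scale) to the
seed pixel's color is ≤ `color_tol` (default 60), capped at
`max_region_pixels` with deterministic row-major ring truncation — and
unions the per-seed regions.  Postprocessing removes 4-connected
components below `min_component_area` (default 25 px, sized to suppress
speckle from the textured synthetic fruits) and fills enclosed holes; it
is idempotent.  Masks on disk are 8-bit PNG {0, 255}, thresholded at ≥128
on load.

**Saliency adapter.** All maps are single-channel; the mask itself is the
H×W input plane, and the default widths keep it that way (wider variants
would only matter for parameter-count accounting).  The layer
normalization inside the refinement is interpreted as the spatial
standardization (x − μ)/√(σ² + ε) over all H·W entries with a learnable
affine (scale, shift); the final Ŝ applies the same standardization once
more without affine, exactly in the order the operators are composed.
That the map is standardized twice in close succession is a faithful
reading of the stage's definition and is preserved as such.  ε defaults to
1e−5; convolutions use zero padding and preserve shape; a constant input
standardizes to exact zeros (the constant case is detected explicitly so
no floating-point summation residue leaks through).  Initialization is
identity-like — center tap 1, zero biases, unit affine — making the
untrained cascade predictable: an all-zero mask yields S ≡ 0.5, S′ ≡ 0,
Ŝ ≡ 0.  A seeded Gaussian init exists for training scenarios.

**Enhancement.** The modulation coefficient reuses the standardize-plus-
affine reading of layer normalization; the gain map (1 + δ⊙Ŝ) is a single
channel broadcast over RGB.  The residual branch's BatchNorm runs in
inference mode on stored running statistics (batch statistics are
ill-defined for single-image inference), and its denominator uses the raw
running variance with no extra stabilizer — the variance is validated
strictly positive — so that identity initialization is exact at the bit
level: with a zero mask upstream, F_fer = 2·I exactly, and with the
residual disabled F_fer = I.  The enhanced array stays in image space
(3×H×W) and is *not* clipped to [0, 1]; detectors consume real-valued
arrays, and only the PNG preview path clips.

**Adaptive fusion.** The global descriptor z is the spatial mean of the
refined saliency map.  It is taken from S′ by default rather than Ŝ: the
standardized Ŝ has mean ≈ 0 by construction, so pooling it would carry no
information; both sources remain selectable (`awe.source`).  The regressor
is a one-hidden-layer MLP (width 16, seeded Gaussian init; a zero-init
mode gives the analytically known λ = 0.5).  Fusion happens by default on
the dense prediction grids — the only representation in which the convex
combination of two detector outputs is well defined — followed by a single
decode + NMS; a decoded-box alternative (`wbf` mode) clusters same-class
boxes across streams at IoU ≥ 0.55 and fuses scores/boxes by the same
convex weighting, with λ = 0/1 special-cased to reproduce one stream
exactly.

**Detector and metrics.** The mock detector partitions the image into an
8×8 cell grid; per cell the class scores are clipped cosines between the
cell's mean color and per-class prototype colors, objectness is the max
class score, and the box is a fixed cell-centered square of 2 cell-widths
per side — matched to the object scale of the synthetic scenes (fruits
span roughly 2×2 cells), since a one-cell box could never reach IoU 0.5
with any instance and would make every AP identically zero.  Decoding
keeps cells with objectness ≥ 0.95 (score = objectness × class score);
NMS is greedy per class, descending score, position tie-break, suppressing
at IoU ≥ threshold.  AP uses COCO-style 101-point interpolation with
greedy one-to-one matching (highest IoU, ties to the lowest ground-truth
index); AP@[.50:.95] averages thresholds 0.50:0.05:0.95.  Precision and
"Recall@all" are computed at IoU 0.5 over all retained detections (no
score cut beyond decoding) — "over all retained detections" being the
reading adopted for the otherwise underspecified Recall@all.  Classes with
neither ground truth nor detections are undefined (NaN) and excluded from
macro means.

**Ablation semantics.** The runner executes baseline / +MSA / +MSA+FER /
+MSA+FER+AWE with a shared seed.  With MSA active but FER off, the
enhanced stream input is I ⊙ (1 + Ŝ): the saliency gain with a unit
modulation coefficient and no residual — the minimal way the adapter can
influence detection without the recomposer.  With AWE off but an enhanced
stream present, λ is fixed at 0.5 (static equal blending, the scheme the
estimator is meant to replace).  A degenerate heatmap or empty prompt set
degrades the run to the baseline stream (λ = 0) with a logged warning; a
detector should not fail because a heatmap is flat.  Multi-class operation
runs the pipeline once per registry class and keeps each run's detections
of the queried class, ids following registry order.

## Synthetic study conditions

Scenes are 128×128 px with 1–3 non-overlapping elliptical fruits (radii
12–18 px, ≥4 px gap), per-instance color jitter ±8, per-pixel speckle
σ = 6, up to 3 leaf-shaped occluders, and a low-frequency background color
field (±8 around the base, bilinearly interpolated from a 9×9 node grid).
Occluders are rejected whenever they would push any instance below 60%
visible pixels, so every fruit stays detectable.  Ground-truth boxes are
tight bounds of the full (pre-occlusion) masks; both full and visible
masks are retained.  Identical (spec, seed) pairs are bit-identical.

The mock encoders live in 3-d RGB space: text → normalized class base
color, tile → normalized mean color.  Because cosine similarity in the
positive RGB octant is permissive, the palette is the binding design
constraint, and it was chosen to satisfy three properties simultaneously
under the default conditions: (i) a tile fully inside a fruit beats every
pure-background tile's cosine by ≥ 0.05; (ii) ≥ 90% of selected prompt
points (tile 16, stride 8, k 5, τ 0.7) fall inside fruit masks; (iii)
region growing from an in-fruit seed recovers the visible mask at
IoU ≥ 0.7 on ≥ 90% of instances.  Property (ii) fails structurally for
"maximally distinct" palettes: any distractor with a *low* cosine to the
query drags the minimum of the similarity map down, which lowers the
relative 0.7 cut and lets partially-covered boundary tiles (whose centers
sit just outside the mask) through.  The default palette therefore uses
hue-similar warm classes — peach (230, 45, 40), apricot (240, 120, 45),
plum (220, 60, 120), echoing the subtle inter-cultivar similarity of real
orchard data — against near-coincident neutral distractors (background
(105, 105, 108), leaves (88, 92, 84)), and fruit radii large enough that
the second ring of non-suppressed tile centers lands inside the fruit.

What the generator does *not* emulate: perspective and scale variation,
specular highlights and shading, fruit-on-fruit occlusion, soft shadows,
textured foliage, class imbalance, and any photometric gap between text
semantics and color prototypes.  Passing tests therefore demonstrate the
*mechanics* of the pipeline — contracts, determinism, fusion algebra,
metric correctness and the qualitative recovery behavior of
prompting/segmentation — not detection accuracy on real orchard imagery,
which depends on the quality of the plugged-in encoder, segmenter and
detector.

## Numerical and degenerate-input choices

- Constant similarity maps → degenerate heatmap flag → pipeline falls back
  to the baseline stream (λ = 0) instead of raising.
- Constant inputs to spatial standardization → exact zeros.
- Cosines are clipped to [−1, 1]; zero-norm embeddings raise.
- Fusion at λ exactly 0 or 1 returns the untouched stream (bit-identical),
  in both dense and box modes.
- All tie-breaks are total orders: row-major for prompt activations,
  (score, ymin, xmin, class) for detections, lowest index for ground-truth
  matching — so every run is deterministic given (inputs, seed).
- Seeds: the global seed propagates to sub-module seeds (seed+1, +2, +3,
  mod 2³¹) unless overridden.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
50 scenes for the recovery rates, 20 scenes for the fused-vs-baseline
regression, a 10-image set for the ablation table, 100–1000 seeded draws
for the oracle and range contracts.  These sizes keep the whole suite
within a few tens of seconds on one CPU while leaving the measured rates
well away from their thresholds.

## Known limitations

- Untrained identity-initialized modules mean the enhancement can perturb
  as well as help: the fused-vs-baseline AP comparison is a seeded
  regression (slack 0.02), not a theorem, and its sign varies with the
  scene sample.
- The box-level (`wbf`) fusion realizes the convex combination on decoded
  sets by clustering; it is a pragmatic companion to the dense mode, not a
  claim about the best box-fusion scheme.
- The region grower is a test double for a promptable segmenter: it
  assumes color-compact objects and will leak through any color bridge
  between object and background.
- Adapters for real encoder/segmenter/detector checkpoints are deliberate
  non-goals here; the seams accept any callable with the documented
  signatures.
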