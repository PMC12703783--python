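# orchardet

Prompt-guided tri-modal few-shot fruit detection for orchard imagery.

Monitoring fruit cultivars in orchards — for variety inventory, digital
archiving or phenotyping — runs into a chronic annotation shortage: new
cultivars appear faster than bounding boxes can be drawn, and the fruits
themselves are small, occluded by foliage, and visually similar across
varieties.  `orchardet` implements a detection pipeline that compensates for
sparse supervision with two extra modalities: a free-text class name and a
structural segmentation prior.  It is aimed at researchers in plant
phenotyping and agricultural computer vision who want a fully testable,
dependency-light reference implementation of this kind of two-stream
semantic-fusion detector, with every external model behind a pluggable seam.

## The method

For an image *I* and a class name *C*, the pipeline computes

```
ŷ = AWE( YOLO(F(I, M)), YOLO(I) ),   M = SPGM(I, CLIP(I, C)),   F(I, M) = SFM(I, M)
```

in five stages:

1. **Text-prompted attention.** *I* is divided into square tiles on a
   stride; each tile embedding is compared with the text embedding by
   cosine similarity, s_ij = ⟨z_t, z_ij⟩.  Min-max normalization gives a
   tile-resolution heatmap A ∈ [0,1], and a greedy thresholded peak-picker
   with Chebyshev spatial suppression selects prompt points *p*.
2. **Semantic prior (SPGM).** A promptable segmenter maps (I, p) to a
   class-agnostic binary mask M.  The shipped reference backend is a
   deterministic color region grower; an adapter around a real promptable
   segmentation model satisfies the same contract.
3. **Mask-Saliency Adapter (MSA).**
   S = σ(C₃(M)),  S′ = ReLU(LN(C₁(S))),  Ŝ = (S′ − μ)/√(σ² + ε), where LN
   is spatial standardization (mean/population variance over all H·W
   entries) with a learnable affine.
4. **Feature Enhancement Recomposer (FER).**
   δ = σ(LN(C₁(Ŝ))),  F_mod = I ⊙ (1 + δ ∗ Ŝ) with the single-channel gain
   broadcast over the 3 channels, plus a residual branch
   R = BatchNorm(C₁(I)); the enhanced array is F_fer = F_mod + R.
5. **Attention-Aware Weight Estimator (AWE).**
   z = GAP(S′),  λ = σ(W₂·ReLU(W₁z + b₁) + b₂) ∈ (0,1), and the enhanced
   and raw detector streams are blended convexly,
   ŷ = λ·YOLO(F_fer) + (1 − λ)·YOLO(I) — by default on the dense
   pre-decoding prediction grids, followed by one decode + NMS.

Evaluation reports AP@0.5, AP@0.75, AP@[.50:.95] (COCO-style 101-point
interpolation), Precision and Recall over all retained detections, and an
ablation runner executes the incremental variants baseline / +MSA /
+MSA+FER / +MSA+FER+AWE.

No pretrained weights are bundled.  The encoder, segmenter and detector
seams are plain callables; the shipped defaults are deterministic color
mocks operating in 3-d RGB embedding space, paired with a seeded synthetic
orchard-scene generator (textured elliptical fruits, leaf occluders,
cluttered background, ground-truth boxes and masks), so the entire pipeline
is exercised offline at desk scale.

## Worked example

Generate a scene and run the full pipeline on it:

```sh
python -c "
from orchardet import SceneSpec, generate_scene
from orchardet import io as oio
oio.write_image('scene.png', generate_scene(SceneSpec(), 5).image)"

orchardet prompt-map --image scene.png --text plum --points points.json
# 95 15 1.0000

orchardet detect --image scene.png --text plum --out result.json --seed 5
# INFO orchardet: config hash 38e225a5e0a2aa58, seed 5
# INFO orchardet: 4 detections, lambda=0.3951687630572973
```

Scene 5 contains a single plum with ground-truth box (80, 4, 106, 33).
The prompt stage puts its highest-activation point (activation 1.0) at
pixel (95, 15), inside the fruit; the fused result (`result.json`) carries
λ = 0.3952 — the estimator leaned toward the raw stream for this scene —
and four detections, all class 2 ("plum"), led by box (72, 8, 104, 40) at
score 0.9876, which overlaps the ground truth at IoU 0.51.  The lower-
scored neighbors are grid-quantization duplicates of the same fruit; the
evaluation module ranks them after the primary hit, so AP@0.5 is unharmed.

Dataset-level workflow:

```sh
orchardet gen-data --n 20 --out data/ --seed 42
orchardet ablate --data data/test --out ablation.csv --seed 42
orchardet eval --data data/val --seed 42
```

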