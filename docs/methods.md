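# Methods

## Problem setting

Supervised retinal-vessel segmentation normally needs dense pixel
annotations for dozens of fundus photographs.  `vesselshot` instead casts
the problem as few-shot semantic segmentation: because no two people share
a vascular tree, **each annotated image is treated as its own class** and
its overlapping patches as the class members.  An episode is then a C-way
K-shot task — C image-classes, K annotated support patches per class, and
query patches from the same classes whose masks the model must infer.
Training samples a fresh episode every iteration; at test time, unseen
images have no annotated support of their own, so their queries are guided
by the *validation* split's fixed support set (support sharing).

## Preprocessing

Every image passes through a fixed chain before patching: gamma
correction, green-channel separation, CLAHE, and field-of-view masking.

* **Gamma** (default 1.2, configurable): mild brightening; the value is a
  common choice in fundus work and is deliberately exposed since no single
  value suits all cameras.
* **CLAHE** (clip limit 2.0 in the histogram-count convention, 8x8 tile
  grid): local contrast enhancement on the green plane.  skimage's
  `equalize_adapthist` implements the operation; the clip limit is divided
  by the 256-bin histogram size to obtain its normalized parameter.
* **Ordering**: gamma -> green -> CLAHE -> FOV mask.  CLAHE is applied to
  the green plane rather than the color image; applying it before channel
  separation would equalize channels that are discarded anyway.
* **Patching**: square templates slide with a fixed stride (224 px /
  stride 64, i.e. 160 px overlap, at study scale; 64 px / stride 48 at
  desk scale).  When the image extent minus the template is not a stride
  multiple, one extra border-flush origin is appended per axis so no
  tissue is dropped; overlapping probability patches are averaged when a
  full image is reassembled.  Windows are half-open, origins 0-based.

Binary masks are cropped with the patches unchanged; when a mask must be
brought to a feature-map scale it is resized by linear interpolation and
thresholded at 0.5.

## Model

Both variants share one encoder/decoder skeleton (reference widths):

* encoder — the first four convolution modules of VGG16 with ordinary
  3x3 kernels: widths 64,64 | 128,128 | 256,256,256 | 512,512,512 with
  2x2 max-pooling between modules;
* decoder — four bilinear up-samplings interleaved with convolutions of
  widths 512,256 | 256,128 | 128,64 | 64,32,3,1; the final 1-channel map
  is the vessel logit, mapped to probability by a sigmoid.

Five **feature positions** l = 1..5 are defined as the four module outputs
before their pooling plus the map after the fourth pooling, giving spatial
sides s, s/2, s/4, s/8, s/16 for a patch side s.

**Class prototypes** are extracted by mask average pooling: at position l
the support feature map is multiplied elementwise by the (resized,
binarized) vessel annotation and averaged over *all* spatial positions —
the normalizer is the full area W*H, not the mask sum, so sparse masks
yield proportionally small prototypes and an empty mask yields the zero
vector.  K-shot prototypes are merged by an elementwise mean, which makes
the forward pass invariant to support order.

**Guidance** applies the prototype as a 1x1 inner-product kernel over the
query feature map: each location's score is the dot product of the
prototype with the query feature vector there.  (Cosine similarity can be
swapped in; the inner product is the default realization.)

* The **baseline** variant computes the prototype only at l=5,
  concatenates the guidance grid with the deepest query feature, and
  decodes.
* The **upgraded** variant computes prototypes at all five positions,
  fuses each guidance grid into the matching decoder stage by channel
  concatenation together with the skip-connected query feature, and first
  passes the deepest query feature through the MSA block.  Zeroing the
  l=1..4 guidance grids (an exposed ablation hook) reduces the pass to a
  baseline-like one.

**MSA** (multi-scale attention) applies an embedded-Gaussian non-local
block at two scales of the l=5 query map (scales 1 and 2; scale 2 is
average-pooled, attended, and bilinearly resized back), sums the branches
and mixes them with a 1x1 convolution.  Affinity rows are softmax
normalized; the non-local output projection starts at zero, so each block
begins as the identity.  The attended map feeds both the l=5 guidance and
the decoder input.

### Numerical and initialization choices

The networks are implemented on the package's own numpy autograd engine
(reverse-mode, im2col convolutions, exact bilinear adjoints); float32 in
training, float64 in gradient checks, which pass at 1e-5 relative error.

* Activations are **leaky ReLU (slope 0.1)** on every convolution except
  the logits head.  The architecture has no normalization layers, and at
  desk-scale widths (8 channels in the first block) plain ReLU collapses
  under Adam: units die, the MSA branch stops receiving gradient, and the
  model settles at the class base rate.  The leak keeps every unit
  trainable; it changes nothing at zero input (leaky(0)=0).
* The logits-head bias starts at the **log-odds of a 10% foreground
  prior**, the standard initialization for imbalanced dense prediction;
  it removes the early epochs otherwise spent fitting the base rate.
* All other weights are He-normal from the model seed.  Up-sampling is
  bilinear everywhere.  A `pretrained_encoder` flag exists but no weights
  are bundled (tests need no downloads); it currently rejects activation.
* `channel_scale` multiplies every width (floor 1) except the 3- and
  1-channel output head; the graph is identical at every scale.

## Training

The loss is binary cross-entropy between the query probability maps and
their annotations, averaged over pixels within each map and over the C*K
maps of the episode; probabilities are clamped to [1e-7, 1-1e-7] before
the logs.  The optimizer is Adam.  After each epoch the model is scored on
fixed validation episodes and the weights with the best validation
*accuracy* are retained (accuracy rather than loss, matching the per-epoch
accuracy tracking of the study protocol).

Two named schedules:

| setting | study scale | desk scale |
| --- | --- | --- |
| patch / stride | 224 / 64 | 64 / 48 |
| image size | ~565 (DRIVE-like) | 160 |
| channel scale | 1.0 | 0.125 |
| learning rate | 1e-4 | 3e-3 |
| epochs x iterations | 30 x 100 | 10 x 20 |
| C-way K-shot | 5w3s..3w5s presets | 3w3s |

The study-scale values are the defaults of `TrainConfig`/`ModelConfig`.
The desk scale (in `vesselshot.protocols`) is the package's CPU-sized
reference experiment: with 15x fewer updates and an 8x narrower model the
Adam step is raised to 3e-3.  A full desk training run takes ~90 s on one
CPU core.  The shorter ensemble-member schedule (8 x 15) and the member
seeds decorrelated from the run seed (members are meant to be independent
models) keep the three-member cross-domain experiment near five minutes.

## Evaluation

Confusion counts use a strict `p > 0.5` rule and by default score only
pixels inside the field-of-view mask (a flag disables the restriction for
parity with implementations that score everything).  Sensitivity,
specificity, accuracy and F1 follow the standard confusion-matrix
formulas; zero-denominator cases are reported as NaN with a flag, never
silently as 0.  AUC is the Mann-Whitney statistic (probability that a
random vessel pixel outranks a random background pixel, ties at 1/2),
computed from average ranks.  Split-level numbers aggregate counts
(micro-average); per-patch rows are also emitted.

## Ensemble

For N1 member models, a pixel is voted vessel when strictly more than T1
members give it probability strictly above T (defaults T=0.5, T1=1 for
three members — "at least 2 of 3"; for general N1 the default T1 is
floor(N1/2)).  The fused probability is the member maximum on voted
pixels and the member minimum elsewhere.  Strict inequalities are kept
deliberately: with >= variants, a pixel at exactly T would flip.  A
consequence verified in the tests: binarizing the fused map at T always
reproduces the vote map exactly.

## Synthetic corpus

The generator emulates only what this pipeline relies on in real fundus
photographs: dark, curved, branching, tapering structures (diameters
2-10 px) on a brighter low-frequency background inside a circular FOV,
plus Gaussian sensor noise; the green channel carries the strongest
vessel contrast.  Centerlines are curvature-perturbed random walks that
branch with small probability and are steered back when they approach the
FOV rim; the ground-truth mask is the exact disc-stamped rasterization,
so a perfect-oracle predictor scores 1.0 on every metric — the end-to-end
plumbing check.  Geometry is seeded per (corpus seed, class index):
bit-identical regeneration, intra-class patch correlation, inter-class
variation.  Vessel-pixel fractions fall in [0.03, 0.20] across seeds
(measured over 100 generations).

Four preset "domains" (thin / thick / noisy / target) vary vessel width,
contrast, noise and background level for the cross-domain ensemble
experiment.

What the generator does **not** model: optic disc and fovea, pathology
(detachment areas, leakage points), vessel-crossing appearance, camera
vignetting, and inter-annotator variability.  Passing desk-scale tests
therefore demonstrates that the method and implementation work — episodic
prototype guidance segments held-out synthetic "patients" — not that the
performance transfers to public fundus benchmarks such as DRIVE, STARE or
CHASE_DB1.

## Known limitations

* The desk protocol has visible seed variance; single runs can land in a
  base-rate plateau (the reason the prior-odds bias initialization
  exists).  The reference experiments therefore report three seeds.
* The baseline variant, having neither skips nor low-level guidance, is
  markedly weaker than the upgraded variant at desk scale — consistent in
  direction, larger in magnitude, than the study-scale gap.
* CLAHE's clip-limit convention differs between toolkits; the package
  documents and converts the common histogram-count convention.
* No data augmentation, learning-rate schedules or early stopping beyond
  best-checkpoint retention are implemented (none are part of the
  protocol).
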