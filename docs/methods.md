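# Methods

## Problem and pipeline

Resin ducts in *Pinus* wood are small, roughly circular canals whose
abundance per annual ring is a standardized proxy for a tree's resin
defense investment. Quantifying them traditionally means an expert
marking every duct and every ring boundary on a flatbed scan of an
increment core — images a few hundred pixels tall and tens of
thousands wide at 2400 dpi.

`ductseg` automates the chain

    core scan I(x, y)
      → per-pixel class probabilities P = [P_R, P_D, P_B]
        (ring boundary, resin duct, background; P_R + P_D + P_B = 1)
      → duct label map D (components 1..L) and ring label map R (labels 1..K)
      → per-ring records: width (mm), area (mm²), duct count, duct coverage.

Every stage is a pure function of rasters, so the stack can be tested
from either end: perfect "oracle" probability maps isolate the
post-processing, and a trained network exercises the whole chain.

## Segmentation network

A downscaled attention U-Net maps 128×128 RGB patches to 3-class
softmax maps. The encoder applies two (3×3 conv → batch norm → ReLU)
blocks per level followed by 2×2 max pooling; filter counts double per
level from 4 up to 64 in the bottleneck — a quarter of the customary
U-Net widths, adequate for a 128 px input. The decoder mirrors the
encoder with nearest-neighbour ×2 upsampling (plus a 3×3 convolution)
and skip connections gated by additive soft attention:
`alpha = sigma(psi(relu(Wx·x + Wg·g)))`, with the gating signal `g`
taken from the coarser decoder level and all projections 1×1
convolutions; the skip feature is scaled per pixel by `alpha`. The
head is a 1×1 convolution to three channels with per-pixel softmax.

The network and its training loop are implemented directly on numpy as
a small channels-last layer library (`ductseg.nn.layers`) using the
shift-and-add convolution formulation (one BLAS matmul per kernel tap).
Backward passes are hand-derived and pinned by central-difference
gradient checks run in float64; optimisation is Adam with the standard
defaults. This keeps the package importable and trainable on a plain
CPU with no framework dependency; at the model's scale (≈138 k
parameters) a training epoch on 200 patches takes seconds.

### Training protocol

* patches: random crops with the constraint that each patch contains at
  least one foreground (boundary or duct) pixel, drawn by rejection with
  a 10 000-retry cap; the full-scale default is 1500 patches per core.
* split: 80 % train / 20 % validation of the pooled patches.
* augmentation (each with probability 1/2, identical transform on image
  and mask): vertical flip, horizontal flip, rotation within ±10°,
  shear within ±5°. Mask resampling is nearest-neighbour so labels stay
  in {0, 1, 2}. The exact ranges are configurable; the defaults are
  deliberately conservative.
* loss: unweighted categorical cross-entropy (per-class weights are
  exposed as an option but off by default).
* early stopping: training ends when validation loss has not improved
  for 10 consecutive epochs; the weights of the best validation epoch
  are restored.
* batch size 32 (16 in the scaled-down benchmark) and learning rate
  1e-3; both configurable, neither critical on the synthetic task.

## Tiled whole-core inference

Cores are far wider than the network input, so prediction slides a
128 px window with a 20 px stride in both axes, averaging the class
probabilities of all tiles covering each pixel; the mean of normalised
vectors is normalised, so the per-pixel sum stays 1. Tile anchors are
multiples of the stride plus a final anchor flush with the far edge;
images narrower than one window are reflection-padded and the output
cropped. Accumulation is a running sum plus a coverage count divided
once at the end, which is memory-bounded and independent of tile
order. Equivalence with an explicit enumerate-all-tiles average is
asserted to 1e-6.

## Duct extraction

1. **Local adaptive threshold.** A pixel is marked iff
   `P_D > mean_{25×25} + 0.05`. The window matches the typical duct
   diameter (20–30 px at 2400 dpi); the offset guards against noise.
   Near borders the window shrinks to its in-image part rather than
   padding, so the thin top/bottom margins are not biased. One side
   effect: ducts whose diameter approaches the window size can lose a
   few interior pixels (their neighbourhood mean approaches 1); the
   component itself is never lost.
2. **Shape filter.** Components (8-connectivity) are removed iff
   circularity < 0.9 **and** area < 0.5 × the mean component area, the
   mean taken over all components *before* any removal (single pass).
   Circularity is 4πA/P² with the Crofton 4-direction perimeter
   estimator, which scores rasterized disks of radius ≥ 10 above 0.9 —
   making the 0.9 cut meaningful on digital data — while elongated
   spurious responses score far lower. (The estimator under-measures
   corner-heavy contours: a digital square scores ≈ 0.89 rather than
   the continuous π/4.) Removed components are kept in a separate
   audit table.

## Ring segmentation

1. **Suppression.** `P_R` pixels below their 25×25 in-image local mean
   are zeroed; the rest keep their value (no binarisation). A uniform
   map passes unchanged (the ≥ comparison carries a 1e-9 relative
   float guard).
2. **Watershed.** The suppressed map is flooded as an elevation
   surface from its regional minima — the zero plateaus between
   boundary crests — with no imposed markers; crest pixels are
   assigned to a basin, so labels always partition the raster. A
   perfectly flat raster yields a single region.
3. **Region merging.** Watershed over-segments noisy maps, so every
   region smaller than 1500 px is merged into the neighbour sharing
   the longest common boundary, defined as the count of 4-adjacent
   pixel pairs across the interface. Merging proceeds smallest-region
   first to fixpoint (a single pass could leave undersized remnants);
   ties go to the larger neighbour, then the lower label. The
   implementation maintains an incremental region-adjacency graph
   (pair counts are exactly additive under merging); a brute-force
   recompute-from-raster merger serves as its oracle in the tests.
   Final labels are renumbered 1..K by centroid column, i.e. in
   chronological order along the core.

## Measurement

With `s = 25.4 / dpi` mm per pixel (dpi 2400 by default):

* width: the longest run of the ring's label along the row
  `floor(height/2)`, × `s`. The longest-run rule is robust to curved
  boundaries touching the centerline twice; a ring absent from the
  centerline yields width 0 plus a warning.
* area: label pixel count × `s²`.
* duct count: connected components of (ring mask AND duct support);
  a duct straddling a boundary counts once in each ring it intersects.
* coverage: duct pixels in the ring / ring pixels, in [0, 1].

Records are stored at full precision; rounding is left to
presentation.

## Evaluation

Object-level, partial-overlap matching: a truth object overlapped by
≥ 1 predicted pixel is a TP, otherwise FN; a prediction overlapping no
truth object is an FP. Counting is truth-sided — several predictions
on one truth object inflate neither TP nor FP — which keeps
TP + FN equal to the number of annotated objects (the convention under
which the published tables' TP+FN totals equal their annotation
counts). SEN = TP/(TP+FN), PREC = TP/(TP+FP). Ring-boundary truth
objects are the individual boundary bands; predicted boundaries are
the pixel interfaces between adjacent ring regions of the segmented
map.

## Synthetic cores

The generator emulates the statistical structure of scanned cores with
exact ground truth: per-ring base tone with an earlywood→latewood
darkening ramp (so plain global thresholding is non-trivial), dark
near-vertical boundary bands (3 px thick by default, optionally
sinusoidally wobbled to emulate curved boundaries), dark duct disks of
radius 10–15 px (matching the observed 20–30 px diameters) placed
non-overlapping and strictly inside ring interiors, additive Gaussian
noise (sd 0.03), and mild wood colouring. Default ring widths are
drawn from 60–220 px — inside the 0.5–5 mm (47–472 px at 2400 dpi)
range of real rings, with the upper end trimmed to keep desk-scale
runs fast. Everything is reproducible from one integer seed.

What the generator does *not* model: real wood texture (tracheid
banding, grain), false/missing rings, scanning artefacts, cracks, and
species differences. Passing tests therefore demonstrate correctness
of the algorithmic chain and learnability of the idealised structure,
not field-ready accuracy on real cores.

## Benchmarks and problem sizes

* **Oracle round trip** (`ductseg.experiments.oracle_roundtrip`):
  20 seeded cores, 4 rings each, height 150 px. On perfect one-hot
  maps the stack must recover every duct (SEN = PREC = 1), the exact
  ring count, widths within 2 px and coverage consistent with the
  detected geometry to 1e-6.
* **Scaled-down end-to-end**
  (`ductseg.experiments.scaled_down_benchmark`): 5 training cores
  (height 160 px, 5 rings, widths 60–140 px), 40 patches per core
  (200 total), early stopping patience 10 with a 40-epoch cap, then
  object-level scoring on 2 held-out cores. These sizes keep a full
  run in minutes on one CPU core while leaving the task non-trivial;
  they are the package's reference conditions, not tuned per run.

## Known limitations

* The numpy network trains at desk scale only; full-scale training
  (~74 000 patches) wants a GPU framework and is out of scope here.
* Watershed on weak, discontinuous boundary evidence can merge
  neighbouring rings (under-segmentation) — the merge threshold only
  corrects over-segmentation.
* The duct/boundary appearance model is achromatic apart from a fixed
  wood tint; colour-based features are not exercised.
* The circularity threshold inherits the Crofton estimator's bias on
  very small (radius < 5 px) components.
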