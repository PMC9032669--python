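# Methods

`weedvision` classifies the plants in a multi-plant image of an early-season
corn field into corn (**Crop**), narrow-leaf weeds (**NLW** — grasses and
sedges) and broadleaf weeds (**BLW**), the two herbicide-selectivity groups
plus the crop.  The system is a five-stage pipeline: acquire → segment →
extract regions of interest (ROIs) → classify each ROI → report.  This note
records the models, the tunable parameters, the numerical choices, and what
the synthetic test bed does and does not demonstrate.

## Vegetation segmentation

Vegetation is separated from soil by thresholding in HSV, where hue is
decorrelated from brightness, so the green band survives sun/cloud swings.
All channels use the byte convention (hue in [0, 180), S and V in [0, 255]).
A pixel is vegetation iff, channel-wise and bounds inclusive,

    Hl ≤ H ≤ Hh,  Sl ≤ S ≤ Sh,  Vl ≤ V ≤ Vh,

with defaults `Hl=33, Hh=95, Sl=34, Sh=255, Vl=60, Vh=250` — hand-tuned
values for green vegetation over bare soil under variable daylight.  The
byte-range hue reading (33–95 ≈ 66°–190°) is the convention under which
`Sh=255`/`Vh=250` are natural; all six bounds are configurable.

The raw mask is cleaned by **opening** (erosion then dilation — removes
salt artifacts smaller than the structuring element) followed by
**closing** (dilation then erosion — fills comparable holes), both with the
same structuring element, a solid 5×5 square by default (disk available).
Outside the image counts as background, so these operators behave as the
literal set definitions restricted to the frame; tests compare them against
a brute-force evaluation of those definitions.

Connected components of the cleaned mask are labelled (8-connectivity by
default, so corner-touching leaf fragments stay one plant; 4 available) and
re-indexed 1..K in raster order of each component's first pixel, which makes
every downstream output deterministic.  Components smaller than `min_area`
(default 400 px, intended for full-resolution field images; pass a
scene-appropriate value for small images — the synthetic tests use 150 px)
are discarded as residual noise.  Each surviving component's bounding box,
optionally padded (default 0) and clipped to the frame, is cropped **from
the original RGB image** to give one ROI patch per plant.  The exact
minimum-area value and any box padding used in the original field study are
not published; both defaults here are the package's own choices and are
exposed as parameters.

## Texture descriptor (rotation-invariant uniform LBP)

For a centre pixel g_c and P neighbours g_0..g_{P−1} on a circle of radius
R (p = 0 due east, counter-clockwise), the local binary pattern code is
Σ_p s(g_p − g_c)·2^p with s(x) = 1 for x ≥ 0 — ties count as 1, so a
constant patch yields the all-ones pattern.  A pattern is *uniform* when
its circular 0↔1 transition count U (wrap-around pair included) is at most
2; the riu2 map sends uniform patterns to their count of ones and all
others to a shared bin P+1, giving P+2 bins — 10, 18, 26 for the standard
geometries (8,1), (16,2), (24,3).  The code is invariant under circular
bit shifts, hence under image rotation.

Numerical choices:

* **(8,1) geometry**: the classic 3×3 lattice neighbourhood, diagonals at
  (±1,±1), no interpolation.  Larger circles sample at angle 2πp/P with
  bilinear interpolation (scikit-image interpolates the (8,1) diagonals at
  radius 1 instead; our unit tests therefore cross-check against
  scikit-image at (16,2), where the two geometries coincide, and verify the
  (8,1) case against a per-pixel reference loop).
* **Borders**: centres within ⌈R⌉ of an edge are excluded (their circles
  would leave the image).
* **Grey conversion**: ITU-R BT.601 luma (0.299, 0.587, 0.114),
  configurable.
* **Feature vector**: the grey patch is stretch-resized (bilinear) to
  `image_size`² (256/128/64; aspect-preserving zero-padding available), cut
  into non-overlapping `cell_size`² cells in raster order, and the per-cell
  riu2 histograms are L1-normalised and concatenated — length
  (image_size/cell_size)² × (P+2).  Whether normalisation in the original
  study was per cell or global is not stated; per-cell is this package's
  choice (configurable off) because it keeps every cell's block on a common
  scale regardless of cell size.

## SVM classifier

The shallow classifier is a soft-margin SVM trained in the dual:
maximise Σa_i − ½ΣΣ a_i a_j t_i t_j K(x_i,x_j) subject to 0 ≤ a_i ≤ C and
Σ a_i t_i = 0.  The box bound C is the only way the tuned penalty enters
the stated dual, so the soft-margin reading is adopted.  Defaults are the
tuned operating point: linear kernel, C = 5 (an RBF hook exists but is
untuned).  Features enter the SVM as the normalised histograms, with no
further scaling.

The solver is a deterministic sequential minimal optimisation (SMO):
pairwise multiplier updates preserve Σ a_i t_i = 0 exactly; convergence is
declared when no multiplier violates its KKT condition by more than `tol`
(default 1e-4); pairs with non-positive curvature (duplicate points) are
skipped.  The bias b is refined after convergence as the mean of
t_i − Σ_j a_j t_j K(x_j, x_i) over margin support vectors.  For the linear
kernel the explicit weight vector w = Σ a_i t_i x_i is stored, and tests
assert the identity y(x) = w·x + b as well as agreement with an
independent grid-search primal oracle and with scikit-learn's SVC (used
only as a cross-check, never as the solver).

Three classes are handled one-vs-one (three binary machines; the
decomposition used in the original study is unstated).  Prediction is by
majority vote; vote ties break to the class with the largest sum of
winning decision magnitudes, then to class order — fully deterministic.

## CNN classifier

The deep route is transfer learning: a convolutional backbone is kept
frozen and only a fully-connected head is trained —

    features (d) → Dense(512) → ReLU → Dropout(0.5) → Dense(3) → softmax,

categorical cross-entropy, Adam at learning rate 1e-4, batch 16, inputs
resized to `input_size`×`input_size`×3 (default 128), no data augmentation
and no early stopping; per-epoch train/validation loss and accuracy are
recorded.  The full-scale protocol runs 100 epochs; the separable synthetic
patch sets used in tests converge within 15.

Backbones are pluggable (`forward`/`backward`/`params`).  The bundled
`TinyBackbone` — two blocks of 3×3 convolution + ReLU + 2×2 max-pool with
seeded random filters, closed by a 2×2 spatial average — is the desk-scale
test surface.  The closing quadrant average matters: it turns the feature
map into near translation-invariant texture-energy statistics (4·64 = 256
features), which is what a plant patch carries; flattening the map instead
ties features to positions and generalises poorly.  Frozen-backbone
features are computed once and standardised to the training split's
mean/variance before entering the head.  Everything is NumPy with
hand-written backpropagation, so training is bit-reproducible given the
seed; unfreezing the backbone backpropagates through the convolutions too.
Large ImageNet-pretrained backbones were left out of the package: they are
not needed by any test, and the head/training protocol — the part specified
here — is backbone-agnostic.

## Evaluation

Per-class metrics come from one-vs-rest reductions of the 3×3 confusion
matrix (rows = true, columns = predicted; class order Crop, NLW, BLW):

    accuracy = (TP+TN)/N,  precision = TP/(TP+FP),
    recall = TP/(TP+FN),   F1 = 2PR/(P+R).

Macro averages are unweighted means; overall trace/N accuracy is also
reported (the two coincide in expectation on class-balanced data, and the
dataset design is balanced).  Division by zero yields 0 with a
`zero_division` flag rather than NaN, so degenerate runs still report.

Data splits are stratified 70/20/10 (train/validation/test): within each
class, items are shuffled by the seed and dealt out with largest-remainder
rounding — 5,080 items per class split as 3,556/1,016/508.

## Synthetic field scenes

The real field imagery behind the original study is not publicly deposited,
so the package ships a generator whose scenes stand in for it during
testing.  A scene is brownish soil (base RGB (112, 86, 58); achromatic
low-frequency brightness variation for clods and moisture; mild chromatic
per-pixel noise, σ = 8 grey levels) with well-separated plants — early
growth stage, no occlusion — and a scene-wide illumination gain drawn from
[0.85, 1.15] for sun/cloud variability.  Defaults: 768² px scenes, three
plants per class, plant diameters 72–110 px, bounding circles ≥ 30 px
apart (rejection-sampled; infeasible packings raise).

Plant archetypes:

* **Crop** — 3–4 wide blades (width 0.18·scale) from a central hub, about
  one sinusoidal vein band across the blade (0.9–1.3 cycles per blade
  width);
* **NLW** — 6–8 thin blades (0.11·scale), fine veining (2.2–2.8 cycles per
  blade width): the same monocot body plan as corn, so the Crop↔NLW
  confusion axis of real fields exists in the simulation, and a
  `stripe_overlap` parameter narrows the vein-density gap to emulate it
  (default 0: separable);
* **BLW** — 4–6 overlapping lobes with smooth blotchy shading (Gaussian
  low-pass noise).

Vein density is specified per blade width, not per pixel, because that is
the botanical invariant (a small grass is as finely veined as a large one);
it also keeps the texture cue stable under the descriptor's patch resize
across the plant-size range.  Shading is multiplicative (amplitude 0.32),
which preserves hue exactly, so every plant pixel stays inside the default
HSV band while soil hue (≈15 on the byte scale) stays below it.  All
randomness descends from the scene seed; identical seeds give bit-identical
scenes.

`scene_to_dataset` runs the real segmentation pipeline on generated scenes
and labels each extracted ROI by the ground-truth plant with the highest
mask overlap (accepted at IoU ≥ 0.5) — mirroring how the original field
dataset was built (segment, extract, then label), which is also why
classifier tests train on scene-extracted ROIs rather than on standalone
renders: it keeps the training and deployment domains identical.

**What the simulation does not show.**  The scenes are not photorealistic:
no perspective or camera geometry, no cast shadows or specular leaves, no
straw/stones, no occlusion or overlap (deliberately — the pipeline assumes
the early growth stage), and class textures far cleaner than nine real
species provide.  Passing tests demonstrate that the algorithms are
implemented correctly and that the pipeline recovers known structure under
its stated assumptions; they say nothing about accuracy on real field
imagery.

## Problem sizes used in tests

The test suite trains the SVM route on ~405 ROIs extracted from 45 seeded
scenes and evaluates on 20 held-out scenes (180 plants), at the smallest
study descriptor geometry LBP(8,1)/64²/32² (40 features); the CNN route
trains on 180 patches (60/class) at 64² input for 15 epochs.  These sizes
were chosen so the whole suite runs in minutes on one CPU core while still
exercising every stage at full fidelity.

## Known limitations

* Segmentation is colour-only: heavy shadow, specular soil, or non-green
  vegetation breaks the HSV band assumption; no illumination correction or
  vegetation-index alternatives are provided.
* Overlapping plants merge into one component (single-ROI, single-label
  assumption); the pipeline targets pre-canopy growth stages.
* The SMO solver targets the moderate problem sizes of this pipeline
  (hundreds to a few thousand training vectors); it builds the full kernel
  matrix in memory.
* The bundled backbone is random-initialised; it is a correctness and
  protocol test surface, not a competitive feature extractor for real
  imagery.
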