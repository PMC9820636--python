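# Methods

## The classification problem

A phase-contrast image of an hPSC colony is mapped to the probability that
the colony has the *good* morphological phenotype (pluripotency
maintained). The decision is learned end to end by a convolutional network
from labelled images; no segmentation or hand-crafted feature extraction
is involved. The positive label is good (y = 1) and training minimizes
mean binary cross-entropy between labels and the sigmoid output.

## Synthetic colony generator

The generator is a first-class, tested component: it renders a
pseudo-phase-contrast colony so that every downstream stage (preprocessing,
augmentation, training, evaluation, scale analysis) can be exercised with
known ground truth.

**Rendering model.** The colony boundary is a 32-vertex radial polygon
around a jittered centre; per-vertex radial noise with relative amplitude
`edge_spikiness` encodes the smooth-vs-spiky edge cue. Cells are
anti-aliased ellipses with random orientation; the ellipse eccentricity
encodes cell elongation, and per-cell radius jitter (`size_cv`) encodes
size variability. Cell centres are placed uniformly inside the colony;
because random placement overlaps, the number of cells is set through the
Boolean-model relation `n = -log(1 - packing_fraction) · A_colony /
A_cell`, so `packing_fraction` is the *expected covered fraction* of the
colony. Intensities: medium background 0.60, colony bed 0.48, cell bodies
≈ 0.34, a bright rim (phase halo) 0.95 at the colony edge; the inter-cell
background inside the colony is raised toward phase-bright (0.88) in
proportion to `gap_brightness`. The image is Gaussian-blurred (σ = 1 px),
Gaussian noise (`noise_sd`) is added, and values are clipped to [0, 1].
The ground-truth colony and cell masks are retrievable for oracle-style
checks.

**Class presets and `separation`.** The good preset is round cells
(eccentricity 0.30), dense packing (0.90), low size variability (CV 0.10),
a nearly smooth edge (spikiness 0.02) and no bright gaps. The full bad
preset is elongated cells (0.85), loose packing (0.50), high size
variability (0.35), a spiky edge (0.25) and phase-bright gaps (0.6). The
effective bad preset is the component-wise interpolation
`good + separation · (bad - good)`, so `separation = 0` makes the classes
identical (with a shared seed, pixel-identical) and `separation = 1` gives
the full contrast. These presets are declared morphological caricatures of
the two phenotypes, not fits to measured data: no quantitative
morphometrics of the real classes were available to fit against.

**Geometry defaults.** 256×256 px at 290/256 ≈ 1.13 µm/px, so the whole
~290 µm reference field of view fits in a small image and tests stay fast;
`GeneratorParams.real_geometry()` gives the reference camera geometry
(1280×960 px at 0.2266 µm/px). Cell diameter defaults to 15 µm, the upper
end of the typical 10–15 µm single-cell range.

**Seeding.** One master seed spawns per-image child seeds by counter
(`SeedSequence((master, i))`), so datasets are byte-reproducible and any
single image can be regenerated independently of insertion order.

**What the generator does not emulate.** Optics (no coherent phase-contrast
point-spread function, no shade-off or halo artefacts beyond the painted
rim), nuclei/nucleoli substructure, illumination gradients, debris, or
colony-to-colony correlation within a plating. Passing tests therefore
demonstrate that the pipeline recovers *the encoded morphological
contrasts* under controlled conditions; they do not certify accuracy on
real micrographs.

## Preprocessing

* Resize to the square network input uses local-mean (area)
  interpolation. The 4:3 source frame cannot be mapped to a square
  proportionally; the resize is deliberately anisotropic with per-axis
  µm/px bookkeeping, which is the simplest reading consistent with a fixed
  square network input. Pipeline order is resize → operator (configurable).
* Grayscale uses the Rec. 601 luma weights, which sum to exactly 1, so
  gray images are fixed points. Values stay float through the pipeline and
  are rounded only on PNG export.
* Min–max normalization maps a constant image to all-zeros (declared
  convention for the degenerate range).
* Binarization operates on the min–max-normalized scale with the inclusive
  convention pixel ≥ threshold → 1; the default threshold is Otsu's
  (parameter-free), overridable with any value in (0, 1).
* Histogram equalization is the global 256-bin CDF remap with output
  stretched to [0, 1] (not adaptive/CLAHE); it is monotone, so pixel order
  is preserved.

## Augmentation

Random cropping keeps a linear fraction of the side (default 0.875, the
common 224/256 convention) at a uniformly random offset and resizes back
to the input side; the dihedral step draws uniformly from the 8 symmetries
of the square, which preserve the pixel multiset exactly. The composed
transform applies crop then dihedral from one seeded stream; the two
commute distributionally, and fixing the order makes runs reproducible.
Augmentation is applied online, per epoch, to training items only —
validation images are never augmented.

## Architectures

All five variants are registry entries in one file, easy to edit if a
different layout is preferred. VGG13 is configuration B (2×64, 2×128,
2×256, 2×512, 2×512 convs, 3×3 kernels, 2×2 max-pools) with a reduced
two-layer head (hidden width 256 at full width) ending in one sigmoid
unit; "FirstPool4" sets the first pool's kernel/stride to 4; "VGG12" drops
the second conv of the last block; "Res+VGG13" adds a skip connection
around each block's conv stack, joined before the block's final ReLU and
pool. The skip is always a learnable 1×1 projection — including where
channel counts match, where an identity skip would be conventional —
because a uniform projection can be zero-initialized, in which limit the
residual network computes exactly the plain VGG13 forward pass; that
equivalence is asserted in the tests. Initialization is seeded He-uniform
(standard for ReLU stacks). A `width_multiplier` scales channel widths
(floor 4) and the head width (floor 8) for desk-scale variants.

The engine underneath is a small numpy implementation: im2col + BLAS
matmul convolutions with hand-written backward passes, non-overlapping max
pooling, and Adam. It is single-threaded-friendly and fully deterministic
given the seeds.

## Training

Defaults: Adam, learning rate 1e-4, batch size 16, 50 epochs with
patience-10 early stopping on validation loss, stratified 4:1 split — all
configurable. These hyper-parameters are robust small-dataset defaults;
none of them is prescribed by the classification problem itself. The
returned checkpoint is the best-validation-loss epoch. In the loss on
probabilities, p is clamped to [1e-7, 1 - 1e-7] to avoid log(0); the
training path itself uses the logit formulation, which is exact and
overflow-free. The stratified split apportions per-class validation counts
by largest remainder so they sum exactly to round(n/5) for a 4:1 ratio
(269 images → 54 validation). A non-finite loss aborts training with a
diagnostic rather than silently continuing.

## Evaluation

Accuracy, precision, recall and F1 follow the standard confusion-matrix
definitions; zero-denominator ratios are reported as 0 with a `degenerate`
flag instead of NaN. AUC is the rank-based Mann–Whitney statistic with
ties counted 1/2, identical to the trapezoidal area under the empirical
ROC (cross-checked against an independent pairwise oracle and
scikit-learn in the tests). Because precision and recall swap roles under
the opposite positive-class convention, reports carry **both** conventions
(good-positive headline, bad-positive alongside); the two agree on
accuracy, on AUC, and on F1 for tp/tn-symmetric matrices.

## Characteristic-scale experiment

Each image is cut into four exact quadrants (odd sides edge-padded first,
with a warning); level k holds n₀·4ᵏ images of linear physical scale
s₀/2ᵏ, where the reported "crop size" is the crop *width* in µm — the
reading under which level 1 of a 290 µm field is 145 µm. The 4:1 split is
made once at level 0 and propagated down the pyramid, so all crops of one
parent stay on one side (this is asserted at run time); crops are resized
to the network input side before training, and a fresh classifier is
trained per level per seed.

The constructed-signal dataset used to validate the scan
(`generate_scale_probe_dataset`) gives both classes the same colony
outline, edge and mean intensity; the bad class additionally carries a
1-px-period ±contrast lattice inside the colony, a caricature of thin
phase-bright gaps between rows of tightly packed cells. Because the
lattice has period 2 px and zero block mean, an exact 2× local-mean
downsample cancels it: whole 128 px images resized to the 64 px input
carry (almost) no class signal, while 64 px quarter crops at native
resolution retain it. The experiment therefore must select level k ≥ 1,
and does.

## Problem sizes

Everything is sized to run comfortably on one CPU: synthetic studies use
256 px images with reduced-width networks (×1/8 at input 64 for the
200-image signal-recovery and null runs; ×1/16 for the 80-image,
two-level, three-seed scale scan at 128 px), and unit tests use 32–64 px
images throughout. Full-width architectures at 256 px input are available
but are not exercised by the default test run.

## Known limitations

* The generator's presets are caricatures; effect sizes on real data will
  differ, and the classifier trained on synthetic images does not transfer
  to micrographs.
* The staged ablation protocol inherits greedy-selection bias (each stage
  fixes the previous winner); the full factorial mode is available.
* The numpy engine supports exactly the layer set these architectures
  need; there is no GPU path, and large inputs at full width train slowly.
* With very small validation sets the binomial noise on accuracy is large;
  the scale scan reports per-seed tables rather than a single argmax for
  this reason.
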