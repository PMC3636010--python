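# Methods

`phytoscope` implements an automated recognition chain for phytoplankton
micrographs: a synthetic scene generator with pixel-exact ground truth,
illumination correction against a blank reference, edge-seeded region-growing
segmentation, a battery of shape/texture/color/fluorescence features, and a
two-stage feed-forward neural-network classifier trained with resilient
propagation. This note documents the model choices, the tunable parameters,
the numerical conventions, and what the synthetic benchmark does and does
not demonstrate.

## Imaging model

A *frame set* is five co-registered 8-bit images of one microscope stage
position: a bright-field RGB image of the sedimented sample, a blank RGB
reference taken without sample, and three grayscale epifluorescence channels
targeting chlorophyll (a+b), phycoerythrin and phycocyanin autofluorescence.
The fluorescence channels are what make non-plankton exclusion reliable:
living phytoplankton autofluoresce, detritus does not, and the accessory
pigments (phycoerythrin in cryptophytes, phycocyanin in cyanobacteria)
separate major groups before any shape is considered.

All analysis assumes fully-in-focus particles (as produced by focal-plane
stacking on the acquisition side); out-of-focus organisms lack sharp edges
and deliberately merge into the background during segmentation, because
features measured on a blurred, partially segmented body would be worse than
no measurement.

## Illumination correction

Each bright-field channel is corrected as

    corrected = sample / blank * mean(blank)

computed in floating point, rounded once, clipped to [0, 255]; blank pixels
of value 0 are floored to 1 before the division. Correcting the blank by
itself yields a constant image at the blank's mean — the idempotence the
test suite asserts. The correction runs channel-wise on RGB; fluorescence
channels pass through untouched, since a transmitted-light blank says
nothing about epifluorescence background. Dividing out the blank removes
the illumination gradient that the sample and blank share, which also makes
the downstream background statistics tighter.

## Segmentation

Segmentation separates particles from background by region growing from
background seed points:

1. **Working image.** The brightness channel (max of R, G, B) of the
   corrected bright-field is edge-enhanced with the standard 3×3 Sobel
   operator (border replication, magnitude rescaled to 8 bits) and
   contrast-stretched saturating 0.4% of pixels (0.2% per tail). The
   working image is the stretched edge magnitude *alone*. An earlier design
   added the brightness channel 1:1 and rescaled the sum, but that halves
   the particle/background contrast and couples the growing criterion to
   the body's internal mottling; faint brown detritus was then absorbed
   into the background. With edges only, every sharply-outlined particle is
   enclosed by its own edge ring, and the ring — not the interior contrast —
   blocks the growth. The known, intended failure mode is that edge-free
   (out-of-focus) bodies merge with the background.
2. **Rough partition.** Catchment basins of the working image's local
   maxima (prominence above a noise tolerance, default 10 gray levels,
   exposed in the CLI) via marker-based watershed on the inverted image.
3. **Background seeds.** Per basin, the mode gray value on a 256-bin
   histogram; basins sharing a mode are grouped, and the mode whose group
   covers the largest summed area is the background value (ties break
   toward the lower gray value). Seeds are the pixels at that value inside
   those basins — in an edge-magnitude image this is the large, flat,
   near-zero area.
4. **Region growing.** Breadth-first sweeps over 4-neighbors; a frontier
   pixel joins when `|v − mean| ≤ 10 · max(std, 1)` where mean/std are the
   running statistics of all background pixels so far, refreshed once per
   sweep (per-pixel refreshing was the alternative; per-sweep is
   vectorizable and the equivalence suite pins its exact behavior against a
   brute-force implementation). The floor of 1 gray level keeps the
   criterion from collapsing to zero width on noise-free backgrounds.
5. **Halo reclaim.** The Sobel ring stops growth about one pixel outside
   the true boundary. Two bounded sweeps re-test frontier pixels against a
   3σ *brightness* criterion and reclaim the barrier's outer half for the
   background. The tight threshold (reclaim only what is statistically
   background) and the sweep bound keep transparent interiors intact.
6. **Particle extraction.** The complement of the background is labeled
   with 4-connectivity, holes are filled (transparent interiors count as
   particle), components smaller than 100 px are dropped (strictly: 99 px
   is excluded, 100 px survives), and components whose bounding box touches
   the frame border are excluded. Contours are closed 8-connected chains
   from Moore-neighbor tracing; the perimeter weights diagonal steps √2.

Coordinates are 0-based with half-open bounding boxes throughout.

## Features

Per particle, the feature battery comprises:

* **Basic shape** — area (pixel count), perimeter (chain length),
  circularity `4πA/P²` capped at 1, roundness `4A/(π·major²)` with ellipse
  axes from mask second moments, solidity (outline polygon area over its
  convex hull's area, both by the shoelace formula, so digitally convex
  shapes score ≈ 1), minimum Feret diameter (caliper width over pixel
  corners in 1° steps), aspect ratio.
* **Elliptic Fourier descriptors** — 29 harmonics of the closed contour,
  normalized for starting point and rotation via the first harmonic and
  scaled so harmonic 1 has amplitude 1. Amplitudes `sqrt(a²+b²+c²+d²)` are
  the features. Note that under arc-length parameterization even a perfect
  ellipse carries small odd harmonics that grow with eccentricity; the
  suite's "ellipse ⇒ no higher harmonics" check therefore uses a mild
  ellipse.
* **Hu invariant moments** of the binary mask; `hu_1` is the classifier
  feature ("image moment 1").
* **Local binary patterns** — riu2 coding with P = 8 circular neighbors at
  radius 1 (bilinear sampling, neighbor ≥ center, interpolation round-off
  below 1e-7 snapped to equality), summarized as a 10-bin histogram over
  interior masked pixels.
* **Gray-level co-occurrence statistics** — 32 levels, distance 1,
  symmetric, averaged over 0°/45°/90°/135°, only pairs fully inside the
  mask; contrast, correlation, energy (angular second moment), homogeneity
  (inverse difference moment), entropy (bits).
* **Directionality histogram** — Sobel gradient orientations in [0°, 180°),
  magnitude-weighted, 16 bins; uniform on zero gradient.
* **Symmetry** — Pearson correlation between the rotation-normalized crop
  and its mirror across the major (horizontal) and minor (vertical) axes,
  on the overlap of mask and mirrored mask; 1 by convention for constant
  crops.
* **Hue histogram** — 16 bins over HSB hue, each pixel weighted by its
  saturation so gray pixels contribute little; uniform when the particle is
  fully unsaturated.
* **Fluorescence means** — mean gray level of each fluorescence channel
  inside the mask.

Rotation normalization rotates the particle so the fitted-ellipse major
axis lies at 0° (bilinear for intensities, nearest for the mask; degenerate
circular particles are left alone). Only features that are *not* rotation
invariant by construction (LBP sampling grid, GLCM, directionality,
symmetry) are computed on the rotated crop; mask/contour descriptors are
invariant already and use the original geometry.

Two named sub-sets feed the classifiers:

* `stage1` (21 values): hue histogram + 3 fluorescence means + area +
  circularity — enough to gate plankton from non-plankton, since detritus
  is non-fluorescent and brown.
* `stage2` (48 values): LBP histogram + hu_1 + EFD harmonics 2–13 +
  circularity, roundness, solidity, min Feret, perimeter, area + hue
  histogram + fluorescence means.

The remaining features (GLCM statistics, directionality, EFD 14–29,
higher Hu moments, aspect ratio, symmetry) are computed and exported in the
`full` set for feature-selection experiments but are not fed to the default
classifiers: they are either sensitive to residual illumination/rotation
effects or dominated by shape variability within a class.

## Classifier

A fully-connected feed-forward network with the symmetric Elliott
activation `f(x) = x/(1+|x|)` on every hidden and output layer. Inputs are
min-max normalized to [−1, 1] with rules observed on the training data
(constant features map to 0; test-time values outside the training range
clip); the rules are persisted inside the model JSON so prediction always
normalizes exactly as training did. Targets are ±1 one-hot; prediction is
winner-take-all with ties broken toward the lower class index.

Training is full-batch RPROP without weight backtracking: per-weight step
sizes start at 0.1, grow ×1.2 while the gradient sign persists (cap 50),
shrink ×0.5 on a sign flip (floor 1e-6) with the stored gradient zeroed so
the flip is acted on once. Training stops at the first iteration whose
training-set misclassification fraction reaches the target error (default
0 — "error rate" is read as misclassification, not MSE, which bounded
activations can never drive to zero) or after 3000 iterations. Weight
initialization is uniform ±0.5 from the config seed; training is
bit-reproducible given the seed.

The default stage-2 architecture is two hidden layers of 50 and 30 neurons
with one output per class (12 in the full field setting: ten taxa plus
detritus plus unknown). An explicit candidate search with an 80/20
stratified validation split stands in for proprietary incremental pruning;
ties prefer fewer neurons. A permutation-importance ranking is provided as
a transparent substitute for black-box input-significance scores, without
claiming equivalence.

The two-stage pipeline first gates each particle with a small
plankton/non-plankton network (hidden layer of 10) on the `stage1`
features; gated particles are finalized as detritus. Survivors get the
`stage2` features and the taxon network's winner label. "Unknown" is a
trained output class for malformed/occluded particles, not an activation
threshold. The stage-2 network retains its own detritus output so it can
run stand-alone for confusion-matrix evaluation.

## Synthetic data

The generator renders frame sets with known masks and labels. Background:
RGB base level (default 230/228/225) plus a linear left-to-right
illumination gradient (default 12 gray levels); the blank reference carries
background and gradient but neither particles nor noise. Particles:
non-overlapping bodies (rejection placement with 6 px clearance so that
neighboring edge rings never fuse; bodies never touch the border) drawn
from six shape families — disk, ellipse, cell chain, star, colony plate,
spiny disk — emulating common freshwater morphotypes (centric diatoms,
cyanobacterial filaments, cryptophytes, desmids, coenobial colonies).
Bodies get a flat base color plus smoothed Gaussian mottling; fluorescence
channels carry each taxon's pigment profile as a constant level inside the
mask. Additive Gaussian noise (default σ = 2 gray levels) goes on the
bright-field and fluorescence images. Identical spec and seed render
bit-identical images.

The default detritus template is a brown ellipse (RGB 172/150/116, mottle
18) with zero pigment profile. An earlier, paler and more mottled draft
placed detritus brightness inside the 10σ background acceptance band, i.e.
it violated the generator's own contract of producing bodies distinct from
the background; the template was corrected accordingly.

Two crop pathways exist. `make_dataset` cuts crops with the ground-truth
masks — exact, fast, ideal for feature unit tests. `make_segmented_dataset`
renders mono-class scenes and runs the actual correction + segmentation to
harvest labeled crops, which is how training data is produced at a real
microscope (segment mono-cultures, then sort). Classifier training uses the
segmented pathway: masks from segmentation differ from ground truth by
about a pixel at the boundary, and a network trained to 0% error on
ground-truth crops is brittle exactly at that scale (smooth ellipses
drifted into the adjacent "unknown" class). "Unknown" training crops are
synthesized malformations: particles truncated along a chord near the
centroid (a wrongly segmented body) or two particles merged into one mask
(an aggregate).

**What the benchmark does not show.** Synthetic bodies have sharp edges,
constant pigment levels and no optics (no point-spread function, depth of
field, halos, or bleaching), and the class templates are well separated by
construction. Passing the synthetic end-to-end target therefore
demonstrates that the pipeline's stages compose correctly and that the
classifier generalizes across the segmentation pathway — not that the
published real-data accuracy would be reproduced on real micrographs,
which is impossible without the original image set.

## Evaluation conventions

Confusion matrices are row = true, column = predicted, class order
detritus, unknown, then taxa. Recognition rate of class c is
`100 · counts[c][c] / rowsum(c)`; the false-positive rate is
`100 · (colsum(c) − counts[c][c]) / counts[c][c]` — foreign particles
assigned to c relative to correctly recognized c, which differs from the
textbook FP/(FP+TN) but is the convention of the published reference table
this package reproduces (verified against its printed per-class values).
Rates are rounded half-up to 2 decimals; summary averages are unweighted
means over classes computed on the exact values before rounding.

The bundled reference counts contain one internal inconsistency: the
class-10 false-positive value printed in the original table (6.25) does not
follow from its own counts (16 foreign / 240 recognized = 6.67 under the
convention that reproduces the other 11 printed values), which also shifts
the printed average 5.45 to a recomputed 5.49 (both round to 5.5 at one
decimal). The package reports the recomputed values.

## Problem sizes and seeds

The synthetic benchmark trains on 200 crops per class (7 classes: 5 taxa +
detritus + unknown) and scores 12 independent 640×640 test scenes with 3
particles per template (≈ 216 particles, 36 detritus) — a scale chosen so
the full benchmark, including training, completes in about a minute while
every class contributes tens of test particles. The acceptance script
derives all randomness from its `--seed` argument; the test suite uses
fixed seeds throughout.

## Known limitations

* The segmentation assumes a light, even background occupying the largest
  area of the frame; dense samples where particles dominate would mislead
  the mode-based seed selection.
* Touching organisms are not split; they are expected to be routed to the
  unknown class by the classifier rather than declumped.
* The symmetry and directionality definitions are this package's own
  (mirror correlation after rotation normalization; magnitude-weighted
  orientation histogram); other systems' homonymous features may differ.
* Hue histograms are saturation-weighted but not illumination-normalized;
  strongly tinted illumination should be corrected by the blank first.
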