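# Methods

This note records the models, parameter choices and numerical decisions
behind `algascope`, and what the synthetic benchmark does and does not
demonstrate.

## Pipeline model

The system assumes bright-field micrographs in which organisms are
compact dark regions on a bright, slowly varying background. All images
are handled internally as float arrays in [0, 1] (rounded to 8 bits only
at file I/O) with 0-based, row-major coordinates, y increasing downward,
and half-open bounding boxes.

**Binarization.** The automatic threshold is Otsu's method on the
luminance channel. Two guards surround it. First, Otsu always returns a
threshold, including on images with no objects at all; the threshold is
therefore accepted only if the two resulting classes separate by at
least 4 within-class standard deviations. Splitting a single Gaussian
mode at its mean separates the halves by ≈ 1.6 σ ≈ 2.7 half-widths, so
object-free noise fields are rejected (all-background mask plus a
warning), while real scenes measure well above the criterion. Second,
the threshold is computed on the *unequalized* luminance: histogram
equalization is monotone, so it cannot change which pixels are dark, but
it spreads a near-constant bright background across the full intensity
range and destroys the bimodality Otsu relies on. `equalize_contrast`
remains a public pre-processing operation (classic 256-bin CDF remap,
applied to the intensity channel of RGB input so hue is untouched).

**Edge detection.** The Canny detector is assembled explicitly:
Gaussian smoothing (σ = 1.4 by default, truncated at 3σ, edge-replicated
borders), Sobel first derivatives (x rightward along columns, y downward
along rows), magnitude √(Gx² + Gy²), direction arctan2(Gy, Gx),
non-maximal suppression over four direction sectors, double threshold at
0.1/0.25 of the maximum magnitude, and hysteresis linking implemented as
connected-component labelling of weak pixels retained when their
component contains a strong pixel. A magnitude floor of 1e-9 treats
numerically constant images as edge-free. In the pipeline the detector
runs on the binarized image, so its role is boundary tracing; the
operator itself accepts any gray image.

**Morphological cleanup and overlap handling.** Edge maps become solid
regions by dilate (3×3, one pass) → fill holes → erode → clear
border-touching regions → drop components below 50 px (strict).
Components whose bounding rectangle is longer than 50 px and at least
50 px across are candidate overlaps and go through a marker-based
watershed on the distance transform. Markers are regional maxima with a
prominence of at least 0.15 × the maximum distance, computed by the HMAX
construction (grayscale reconstruction of *d* − *h* under *d*, then
regional maxima): maxima whose connecting saddle is shallower than the
tolerance merge into one marker. This matters because the rule flags
*every* large rotated organism, not just true overlaps — the flat medial
ridge of a single filament must yield exactly one marker, while two
overlapping cells (saddle depth > 15% of the half-width) still split.
The distance field is pre-smoothed (Gaussian, σ = 2) to remove
short-period boundary scalloping; the prominence is taken relative to
the raw maximum because smoothing lowers a thin ridge's absolute height.

## Feature measurement

Geometric features are measured on the auto-aligned mask. Alignment
finds the maximal-distance boundary pixel pair and rotates the object so
that chord is horizontal; the angle between two slopes is
θ = tan⁻¹((m₁ − m₂)/(1 + m₁ m₂)), normalized to (−90°, 90°]. The
reference line is horizontal (m₂ = 0) so θ is translation-invariant.

Pixel quantization dominates the error budget here, and several
decisions exist purely to control it:

* **Smoothing protocol.** Masks are median-smoothed (3×3) before
  measurement and again (5×5) after any lossy rotation.
  Nearest-neighbour rotation notches the boundary with ±1 px waviness,
  and the 8-connected chain perimeter (1 per axial step, √2 per
  diagonal) follows every notch: a disk's circularity 4πA/P² drops from
  0.91 to 0.62 at a 30° rotation without smoothing, which would break
  the shape-index rule (circular iff C ≥ 0.8, else elongated iff
  major/minor ≥ 2.5, else irregular).
* **Chord selection.** `inclination_angle` defaults to the strict
  exhaustive maximum (endpoints pruned to the convex hull above 400
  boundary pixels; exact ties broken by smallest |θ|, then
  lexicographically). For choosing the *pose*, chords within 2 px of the
  maximum are treated as indistinguishable and resolved by intrinsic
  criteria — smallest perpendicular extent of the boundary, then
  smallest second moment about the chord — so the chosen pose does not
  depend on how the object lies on the canvas. Exact quarter-turns use
  `np.rot90` (lossless); other alignments get one refinement pass when
  the residual inclination, measured with a 1-px-tolerant chord, exceeds
  1.5°.
* **Mirror convention.** Chord alignment fixes orientation only modulo
  180°; aligned objects are flipped so their heavier half lies left,
  otherwise the width-factor strips of an asymmetric organism would come
  out reversed for half of the input poses.
* **Width factors.** The horizontal span is cut into 5 equal strips and
  R_c = W_c/L uses the *mean* vertical extent over the columns of each
  strip. A per-strip maximum flips by a pixel whenever a wide column
  crosses a strip boundary under residual tilt; the mean is stable and
  agrees with the analytic mean-chord profile on reference shapes.

Rotation invariance of F1–F13 is verified at 5% for well-resolved
elongated objects at arbitrary angles and for the genus archetypes under
quarter-turns. It cannot hold universally at pixel resolution: a 1-px
change on a 14-px minor axis is already 7%, and a near-circular
irregular colony has no preferred chord, so its strip features retain
the boundary wobble (~10%) across poses. Classification does not depend
on strip stability for round genera — their separation comes from the
shape index, the axis ratio and texture.

**Texture block.** The masked grayscale crop, reduced to deviations from
its interior mean (a 2-px boundary rim is excluded — it carries
resampling gradients, not cell texture), is resampled to 64×64,
Hann-windowed and Fourier-transformed. The power spectrum (DC removed)
is accumulated on a 16-radius × 16-angle polar grid over φ ∈ [0, π); the
radial and angular marginals, each normalized to unit sum, concatenate
into the 32-dimensional descriptor. Crops whose total non-DC power is
below 1e-15 return an all-zero descriptor rather than normalized
round-off noise. PCA (mean-centred covariance eigendecomposition, top 8
components, largest-magnitude loading made positive) is fitted on the
training split only and frozen for testing.

## Classifier

The 21-8-5 network uses tanh on both layers; targets are +1/−1 coded.
Inputs are z-scored with training-split statistics stored in the model —
the raw features mix px, px² and dimensionless scales, which a tanh
network cannot absorb otherwise. Weights initialize uniformly in
±1/√fan_in from the seeded generator; biases start at zero. Training is
per-presentation backpropagation of squared error with momentum,
Δw(t) = −0.05 ∂E/∂w + 0.05 Δw(t−1), presentation order reshuffled each
epoch, at most 400 epochs. A stratified 10% split monitors validation
RMSE; training stops after 10 consecutive epochs of increase (a single
noisy uptick should not stop training) and the best-validation weights
are restored.

Prediction takes the argmax of the five outputs, ties to the lowest
index, and rejects to *Unidentified* when the winning activation is
below 0.5 — the upper half of the target range. This threshold is a
calibration choice: in-distribution organisms saturate (winning
activations ≥ 0.97 across held-out sets), while out-of-distribution
debris spreads widely (95th percentile ≈ 0.85), so 0.5 rejects about
70% of debris at zero measured cost to the genera. At a threshold of 0
almost no debris is rejected, because a trained tanh network assigns
confident outputs to arbitrary far-away inputs. The threshold is
configurable.

Evaluation builds a 6×6 confusion matrix (five genera + Unidentified);
rejections of true genera count as errors in the overall accuracy. When
a test image yields several detections, the largest object carries the
image's prediction.

## Synthetic data

The generator emulates what the pipeline needs from real micrographs:
bright background (mean 0.82 ≈ 210/255) with a smooth illumination
gradient (±0.05) and Gaussian noise (σ = 8/255), and dark organisms
(mean luminance ≤ 120/255) of five morphological archetypes —
*Navicula*: lens/boat, aspect 3.5–6, transverse striations (period
4–7 px, contrast 0.3); *Scenedesmus*: four overlapping ellipsoidal cells
in a plate; *Microcystis*: near-circular envelope (low-frequency radial
wobble ≤ 5%) filled with dark granules; *Oscillatoria*: stadium-shaped
filament, aspect 9–14, periodic transverse walls; *Chroococcus*: 2–4
tightly pressed circular cells; debris: irregular polygons without
periodic texture. Colony overlap fractions are chosen so that a colony's
internal distance-transform saddles stay above the watershed prominence
threshold: a colony is one organism, never four. All randomness flows
from one explicit seed through spawned `SeedSequence` streams; train and
test splits are disjoint streams, and identical seeds reproduce
byte-identical images.

Single-organism dataset scenes default to a 288×360 crop (a
single-organism field of view; multi-organism scenes default to
512×640). The crop keeps every archetype above ~0.6% of the frame, the
regime where Otsu's between-class criterion cleanly prefers the true
object/background split over a split of the background noise mode.

What passing the benchmark does **not** show: robustness to uneven
illumination beyond a linear gradient, to focus blur, halos or staining
variation; to morphological overlap between genera (the archetypes are
separated by ≥ 3 within-genus standard deviations in at least one
geometric feature by construction); or to the taxonomic subtlety of real
populations. The benchmark validates the pipeline's mechanics —
segmentation geometry, feature correctness, training dynamics — under
controlled, favourable imaging conditions.

## Benchmark protocol

The headline number is produced by `scripts/acceptance.py`: 40 training
and 50 test single-alga scenes per genus, extraction of the 13 geometric
features plus the 32-dim raw descriptor per object, PCA and network
trained on the training table only, and overall accuracy read off the
confusion matrix of the 250 test images (~35 s on one CPU). Smaller
configurations of the same protocol are used in the examples and in the
test suite where full size is not needed to exercise the property under
test.
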