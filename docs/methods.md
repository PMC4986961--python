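# Methods

This note records what `fruitpheno` computes, the assumptions behind each
step, and the numerical choices made where more than one defensible option
existed. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Photographic model

The package assumes the standard top-down phenotyping setup: specimens
arranged on a contrasting mat so that **no two objects touch**, with
circular reference markers of known physical diameter placed near the mat
borders, away from the produce. Touching specimens merge into one
connected component — this is a documented limitation, not a failure mode
the software tries to repair (no watershed splitting). Images must be
supplied upright; EXIF auto-rotation and RAW formats are out of scope.

Coordinates are 0-based and row-major with the origin at the top-left
corner. Optional down-scaling at load time uses box (area-average)
interpolation: it preserves mean intensity, and unlike nearest-neighbour
it does not alias object boundaries, which would bias perimeter estimates.
Calibrated outputs are insensitive to the resize factor (≤ 2% relative for
factors in [0.25, 1] while the smallest specimen still spans ≥ 50 px),
because the reference markers shrink with everything else.

## Segmentation

**Threshold mode.** A pixel is foreground iff it is below (dark objects on
a light mat) or above (the reverse) the cutoff in *every* selected RGB
channel. AND-combination across channels is chosen because the motivating
case — dark red fruit on white — is a conjunction of "dark in blue" style
conditions; polarity is an explicit flag rather than inferred. Thresholding
is deterministic, idempotent, and monotone in the cutoff.

**Neural mode.** For produce whose colour spans too wide a range for one
cutoff, a pixel classifier is trained on user-supplied swatch images (one
per colour class, exactly one labelled `background`). The network is fixed
at 3 inputs (R, G, B scaled to [0, 1]) → 10 sigmoid hidden units → softmax
over the classes. Pixels are shuffled with the run seed and split
70/15/15 into train/validation/test. Optimisation is full-batch L-BFGS on
the cross-entropy (a quasi-Newton equivalent of scaled conjugate
gradient), run in chunks of 25 iterations with early stopping once the
validation loss has not improved for 6 consecutive checks; the best
validation-loss weights are kept. Failure to trigger early stopping within
60 chunks is recorded as a note in the training report, not an error.
Foreground is the argmax over classes being any non-background class, with
ties resolved toward background; a probability cutoff was considered and
rejected as an extra parameter with no benefit on separable colours.
Swatch classes are capped at 10⁶ pixels (seeded subsample) — moderate
swatch resolution is sufficient for a 3-feature problem. Training with a
fixed seed is bit-reproducible, and classifiers serialise to a single
version-tagged JSON file.

## Mask cleanup

**Hole filling.** Specular reflections on glossy fruit segment as
background holes. Every 4-connected background region with no path to the
image border is converted to foreground. The operation is idempotent and
never removes foreground. Foreground components themselves use
8-connectivity (the standard dual pairing).

**Illumination stabilisation.** Lenses and lighting rigs darken image
borders; a vignette strong enough to cross the threshold creates spurious
components. The correction divides out a smooth multiplicative shading
field and rescales so the image median is preserved (clipped to [0, 255]).
The field is estimated on a ~64×-decimated gray image by a median filter
wider than any specimen — so dark objects cannot drag the estimate —
followed by a Gaussian blur at scale ≈ min(H, W)/4, then bilinear
upsampling. A plain heavy blur without the median step under-corrects by
several fold because the fruit themselves bias the field. Stabilisation
runs automatically before segmentation (a flag disables it); **colour
descriptors are always measured on the original pixels**, so the
correction never distorts colour phenotypes. A uniform image passes
through within ±1 intensity unit.

## Object extraction and calibration

Components below `min_area` pixels are marked discarded; components
touching the image border are measured but flagged (`W-BORDER`) because
the specimen may be truncated. Surviving objects are ordered in "reading
order": top-to-bottom in row bands one median object height tall,
left-to-right within a band — the order in which a person lays out a grid.

Reference markers are identified among the detected objects by a score =
circularity × border proximity, where circularity `4πA/P²` must exceed
0.85 and proximity is `1 − d/ (min(H, W)/2)` for the centroid's distance
`d` to the nearest edge. Circularity alone cannot work — many fruits are
round — but markers sit at the mat borders where the protocol keeps no
produce, so the product separates them. If fewer than the declared number
of sufficiently circular candidates exist, the error lists the candidate
scores.

The scale is `cm_per_px = known_diameter_cm / mean(equivalent-disk
diameters)`, with the equivalent-disk diameter `2√(A/π)` chosen over a
Feret diameter for robustness to boundary noise. **The declared reference
size is interpreted as the diameter.** The coefficient of variation of the
per-marker diameters is reported; above 0.05 it triggers a warning
(tilted camera or mis-detected marker). Lengths scale by `cm_per_px`,
areas by its square, volumes by its cube.

## Descriptors

* **Length** — maximum Feret diameter, computed as the largest pairwise
  distance between convex-hull vertices of the pixel-centre cloud. Pixel
  centres rather than pixel-corner footprints: on rasterized ellipses with
  semi-axes ≥ 20 px the centre hull tracks the analytic axes within
  ~0.7%, while the half-pixel footprint dilation added a systematic +1.3%.
* **Width** — maximum extent of the hull projected perpendicular to the
  length axis. When digitisation noise on a near-circular object makes the
  perpendicular extent exceed the Feret maximum, the two are swapped so
  `length ≥ width` always holds (highly circular objects can flip axes).
* **Perimeter** — Crofton estimate with 4 directions. A weighted
  boundary-chain length (1 per axial, √2 per diagonal step) was measured
  at +4.9% on a rasterized disk of radius 50 — outside the package's own
  ≤ 4% accuracy contract — whereas the Crofton estimator is +0.35% on the
  same disk, so the latter is used everywhere, including circularity.
* **Eccentricity** — from the second-central-moment equivalent ellipse
  (the standard definition), *not* from the Feret axes.
* **Solidity** — pixel area over convex hull area.
* **Volume / surface** — the silhouette revolved about its length axis,
  modelled as a prolate spheroid with `a = L/2`, `b = W/2`:
  `V = (4/3)πab²`, `S = 2πb²(1 + (a/(be))·arcsin e)` with
  `e = √(1 − b²/a²)`, continuously extended to the sphere `4πa²` as
  `b → a` (switch at `e < 10⁻⁶`).
* **Colour** — unweighted channel means; gray is `(R+G+B)/3` by default
  (`--gray-mode luminance` switches to Rec. 601 weights); colour variation
  is the population SD of per-pixel gray.
* Objects one pixel wide are degenerate: they are measured with a
  `W-DEGENERATE` warning, width floored at 1 px, and eccentricity pinned
  just below 1.

## Synthetic scenes

The generator renders the stated photographic world, not a tunable
benchmark: a 1200×1600 canvas (a 1000×1000-class image is sufficient for
segmentation work), near-white mat (252), four dark circular markers of
100 px diameter (2.54 cm declared size ⇒ 0.0254 cm/px) inset 90 px from
the corners, and by default 25 dark-red ellipses with major semi-axes
42–60 px (fruit spanning ~80–120 px, the scale at which small round fruit
are photographed in practice), aspect 0.62–0.95, random rotation, and a
radial colour gradient of amplitude 0.15. Placement is rejection sampling
with a ≥ 3 px enforced gap (the non-touching protocol) and produce kept
out of the border zone where the markers live. All randomness flows from
one seed; scenes are bit-reproducible.

Ground truth per specimen: analytic axes `2a`, `2b`, analytic
eccentricity `√(1 − (b/a)²)`, Ramanujan ellipse perimeter, the exact
rasterized pixel count, and the painted mean colour (for the radial
gradient `1 − gρ²` the analytic area-mean multiplier is `1 − g/2`). The
ground-truth mask is exactly the painted foreground — never anti-aliased —
so segmentation can be scored pixel-perfectly. Perturbations: exposure
scaling in [0.1, 4] with clipping (shutter-speed variation), a radial
vignette, specular holes covering a set fraction of each fruit, a
camera-height transform that shrinks all pixel dimensions about the canvas
centre, and a resolution rescale that grows canvas and objects together.
Superellipse exponents ≠ 2 create non-elliptical shapes for solidity
tests. The robustness harness adds Gaussian sensor noise of SD 2 so that
cross-condition correlations are not degenerate at exactly 1.

What a green synthetic test does **not** establish: performance under real
shadows, perspective and lens distortion, motion blur, JPEG artefacts, or
produce with textured/variegated skin. The generator draws smooth convex
shapes on a clean mat; real-world accuracy must be established against
manual measurements via the `validation` module.

## Bootstrap validation

Each of 1000 iterations draws `round(0.82·n)` of the `n` paired rows with
replacement (75 rows ⇒ 62 drawn; rounding is to-nearest), fits
`manual ~ 1 + digital` by OLS — plus fixed-effect indicator columns for an
optional session covariate, modelled no more elaborately than that — and
predicts the **out-of-bag** rows, i.e. those never drawn in the iteration
(with replacement, the out-of-bag fraction is `(1 − 1/n)^62 ≈ 43%`, not
18%). The Pearson correlation between predicted and observed manual
values is recorded; the summary is the mean and the 2.5th/97.5th
percentiles. Iterations with fewer than 3 out-of-bag rows or zero
variance are skipped and counted; more than 10% skips aborts. The
procedure is sometimes labelled "five-fold" in the field, but the 82%
with-replacement/out-of-bag scheme is the operational definition
implemented here; `train_fraction` is exposed as a parameter.

The cross-condition harness computes, for each trait, the K×K Pearson
matrix across acquisition conditions with specimens matched by
`object_index` (requiring identical order); an undefined correlation
(constant trait) is reported as missing, never as zero.

## Known limitations

* Touching specimens are merged; the protocol, not the software, must
  prevent contact.
* Reference detection assumes circular markers near the image border; a
  round fruit placed at the mat edge can be misclassified.
* JPEG inputs are accepted but lossy compression perturbs colour
  descriptors; use PNG/TIFF for colour work.
* The projected volume/surface model is a spheroid of revolution; for
  flat seeds it overstates thickness-dependent quantities, mirroring the
  lower cross-height correlations such traits show in practice.
* No colour calibration against a reference chart; colour comparisons are
  only valid within a standardised lighting session (or across sessions
  via the session covariate in the bootstrap model).
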