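# fruitpheno

High-throughput shape and colour phenotyping of fruits, seeds and
vegetables from conventional digital photographs.

Breeding programs and horticultural research need thousands of per-fruit
measurements (length, width, area, volume, colour, ...) that are slow and
error-prone to take by hand. `fruitpheno` extracts them automatically from
photographs of non-touching specimens laid on a contrasting mat, using
circular **reference markers** of known physical diameter placed in the
scene to convert pixels into centimetres. A batch of 25 fruits is measured
in under a second once photographed.

## What it computes

For every detected specimen:

* **size/shape** — length `L` (maximum Feret diameter), width `W` (maximum
  extent perpendicular to the length axis, with `L ≥ W` enforced), shape
  ratio `L/W`, 2-D area `A`, perimeter `P` (Crofton estimate),
  eccentricity `e = √(1 − (b/a)²)` of the moment-equivalent ellipse,
  solidity `A / A_hull`;
* **revolution solids** — projected volume `V = (4/3)π (L/2)(W/2)²` and
  projected skin surface of the prolate spheroid with semi-axes `L/2`,
  `W/2` (sphere `4π(L/2)²` in the circular limit);
* **colour** — mean R, G, B over the specimen, gray mean `(R+G+B)/3` and
  colour variation (population SD of the per-pixel gray), measured on the
  original image.

Segmentation is by per-channel RGB thresholding (e.g. "blue < 50" for dark
red fruit on a white mat) or, for variably coloured produce, a small neural
pixel classifier (3–10–K, sigmoid hidden layer, softmax) trained on colour
swatches with a 70/15/15 train/validation/test pixel split. Holes from
specular reflections are filled and smooth illumination gradients are
divided out automatically before thresholding.

The `validation` module implements an out-of-bag bootstrap
cross-validation of digital against manually taken measurements: each of
1000 iterations draws 82% of the paired rows with replacement, fits
`manual ~ digital (+ session)` by least squares, predicts the never-drawn
rows and records the Pearson correlation; the mean and 2.5/97.5 percentile
band are reported.

A fully seeded synthetic-scene generator (`synthetic_scenes`) renders
batches of rotated (super)ellipses with exact ground truth — every
quantitative claim in the test suite is checked against it.

## Worked example

```
$ fruitpheno simulate --out demo --n-scenes 1 --n-specimens 25 --seed 1
wrote 1 scene(s) to demo
$ fruitpheno run --images-dir demo --min-area 300 --csv demo/phenotypes.csv \
    --num-references 4 --reference-size 2.54
processed 1 image(s), 25 specimen record(s), 0 failure(s)
```

First rows of `demo/phenotypes.csv` (one row per fruit, in reading order):

```
 object_index  length_cm  width_cm  shape_ratio  area_cm2  volume_cm3  eccentricity  solidity  gray_mean
            1    2.48088   1.95029      1.27206   3.81274     4.94084      0.618310  0.988612    63.8293
            2    2.30307   2.03888      1.12957   3.71004     5.01291      0.465682  0.986942    61.6704
            3    2.46351   1.91606      1.28571   3.73846     4.73555      0.630322  0.986703    55.5149
```

Fruit 1 is 2.48 cm long and 1.95 cm wide (shape ratio 1.27 — clearly
oblong, eccentricity 0.62), covers 3.81 cm² in the image plane, and would
enclose 4.94 cm³ if revolved about its long axis; solidity ≈ 0.99 says the
outline is convex, and the gray mean of 64/255 a dark fruit. The four
corner markers (2.54 cm diameter) calibrated the pixel scale; their
per-image dispersion is reported in the run log as a tilt/mis-detection
check.

Validating digital measurements against a caliper table:

```
$ fruitpheno validate --table pairs.csv --manual-col manual --digital-col digital \
    --iterations 1000 --train-frac 0.82 --seed 1
mean r = 0.998 (95% CI 0.997 to 0.999; 1000/1000 iterations)
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates three seeded 25-fruit batches, measures them end to end with
the full pipeline, runs the bootstrap cross-validation of the measured
lengths against noisy "caliper" readings derived from the generator's
ground truth, and writes the JSON report to `--out`.

## Library layout

| module | contents |
| --- | --- |
| `core_io` | `Scene` container, PNG/JPEG/TIFF loading, area-average resizing |
| `segmentation` | threshold specs, swatch ingestion, neural pixel classifier |
| `morphology` | hole filling, illumination stabilisation, component labelling |
| `calibration` | reference-marker detection, pixel-to-cm scale |
| `descriptors` | per-object shape and colour phenotypes |
| `synthetic_scenes` | seeded scene generator with exact ground truth |
| `validation` | bootstrap cross-validation, cross-condition correlations |
| `pipeline` / `cli` | batch orchestration, CSV/figure output, `fruitpheno` command |

See `docs/methods.md` for the measurement definitions, model assumptions
and numerical choices.
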