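# Methods

## Scope and model

`seedscore` scores germination per seed image, not per plate: each tile is
assumed to contain exactly one seed position photographed repeatedly over
the course of a germination test, darker than its background, with the
target seed closer to the tile centre than any neighbouring object. The
classifier is a plain Euclidean *k*-NN majority vote over image features —
no distance weighting, no use of capture time as a feature (using time
would let the classifier exploit the germination curve itself and polarise
errors across time points rather than judge each image on its pixels).

Germination is treated as irreversible: within each seed's time series the
binary label is propagated as a running maximum, and the pre-test (time 0)
photographs are excluded from training and testing since they are
un-germinated by construction and only dilute the negative class.

## Feature set

The 25 object descriptors are the standard object-counter outputs: area,
perimeter, bounding box (origin, width, height), centroid and
intensity-weighted centre of mass, three derived distances (to tile centre
and between the two centres), grey statistics (mean, median, SD, min, max,
range, integrated density), and shape (extent, aspect ratio, equivalent
diameter, circularity, elongation). The named intensity/size/position
descriptors are the load-bearing ones; the shape descriptors complete a
fixed, declared 25-feature contract so the extractor's output width never
depends on configuration.

Histograms are computed over the **masked object pixels only** (a
`whole_tile_histograms` flag switches to the full tile): six channels × 256
levels = 1536 counts. HSB follows the ImageJ convention of quantising hue,
saturation and brightness to the same 0–255 integer range as RGB, so all
six histograms share one bin layout. Per-channel counts always sum to the
object's pixel count.

Numerical conventions: coordinates are 0-based, row-major, origin top-left;
grey = rounded mean of R, G, B; perimeter counts object pixels with a
4-neighbour outside the object (tile borders count as outside);
circularity = 4πA/P²; elongation is the major/minor axis ratio from second
central moments with both axes floored at 1 px so single-pixel and
collinear objects stay finite. Central-object selection breaks distance
ties (at 1e-9) by larger area, then lower label id, which makes it
invariant to the order components are supplied.

## Normalisation, PCA, splits

Traits span several orders of magnitude, so every feature is min-max scaled
to [0, 1]. Constant features map to 0; when training-derived ranges are
applied to test data, out-of-range values are clipped into [0, 1]. PCA (21
components by default) is computed on the covariance of the normalised
features — normalisation has already equalised scales, so a correlation
PCA would only re-weight near-constant features. Components are
sign-normalised (largest-magnitude loading positive) and computed by SVD of
the centred data, which keeps the 1561-feature case cheap.

Both normalisation and PCA are fitted on the training rows of each split
and applied to the test rows; fitting on all rows before splitting leaks
test information into the transform, but a `fit_on_all` flag provides that
behaviour for comparison. Splits are uniform over images with train size
round-half-up(n × fraction), reproducible from an integer seed.

## Classifier

Default *k* = 7 (odd, so votes are never tied). Distance ties at the k-th
rank are resolved by lowest training-row index via a stable sort —
deterministic and order-independent. For even *k* a tied vote is broken at
random from a stream keyed by (classifier seed, image identity), so batch
results do not depend on query order yet reproduce exactly; tied votes are
recorded with certainty 0.5. Squared distances are compared internally
(monotone-equivalent to Euclidean). The ROC sweeps the unfolded vote
fraction m/k; the folded certainty max(m, k−m)/k cannot order both classes.

## Label curation

The review loop scores the labelled set (leave-one-out by default,
holdout optional — which the original workflow used is not recorded, so
both are provided), queues the `batch_size` least-certain images (default
1% of images, minimum 10; ties ordered by image key), applies the
reviewer's corrections with provenance `amended`, re-propagates the
running-maximum rule so a corrected early germination updates later
frames, and repeats until an iteration changes nothing (or `max_iter`,
which sets a warning in the log rather than raising). Vote certainty flags
boundary regions, not individual mislabelled images — a confidently
misclassified label does not lower its own certainty — so curation
improves labels where classes overlap and cannot find isolated flips deep
inside a cluster; the exhaustive-batch case degenerates to full re-review
and recovers ground truth.

## ROC and confusion

The ROC uses the distinct score values as thresholds (germinated when
score ≥ threshold) with trapezoidal integration; tie handling gives ½
credit, so the area equals the Mann–Whitney rank estimator exactly (tested
to 1e-12 against exhaustive pair counting). Confusion counts use the k-NN
majority call itself (score ≥ ⌈k/2⌉/k); false-positive and false-negative
fractions are reported over all test images.

## Experiment modes

`objects_only` (25 features), `all_values` (1561), `pca` (21 components),
and `optimised_subset` — the curated-clear-image analogue, which applies
the same 21-component pipeline with a 1:2 train:test split (fraction 1/3).
The pipeline for the optimised mode follows the figure-legend description
(21 PCs) over the conflicting in-text mention of 25 raw variables, because
the legend describes all four curves in one consistent scheme. Default
experiment seed 1234.

## Synthetic data

The generator emulates what makes real germination imagery hard: a dark
brownish rotated ellipse on a light noisy background; axes inflating
2%/time point (water uptake); a tapered radicle of scheduled length from
one apex once the seed germinates; grey-green translucent mould speckle
clustered near and over the seed; broken seeds as two displaced
half-ellipses. Images are pure functions of (generator seed, seed id, time
index): per-seed phenotypes and per-time noise come from separately keyed
substreams, so appending seeds never changes existing images. The number
of germinators is deterministic (round-half-up of n × fraction, stable
under appending) so tests can assert exact class balance; germination
times are uniform over the post-imbibition time points.

Presets: `easy` models an optimised subset of distinctly scored seeds —
uniform plump seeds (semi-axes 32–38 × 16–20 px), long thick radicles
(25–45 px at emergence, +15 px/time point, base radius 0.4 × minor axis),
no mould, no breakage, noise SD 3. `hard` models a non-ideal set — wider
size range, short thin radicles (5–12 px, +4 px/time point, base radius
0.25 × minor axis) against a 2%/time-point swelling confound, mould
probability 0.35 with ~2 clusters/time point, 12% broken seeds, noise SD 8.
On the easy preset, object area alone separates the classes (AUC ≥ 0.9);
the full pipeline is near-perfect there and measurably worse on the hard
preset, reproducing the qualitative clear-vs-confounded contrast.

What the generator does **not** model: real mould morphology (hyphae
bridging seeds), illumination gradients and shadows, seed-coat texture
beyond white noise, husk/awn appendages, dead germinated seeds reverting
in appearance, and mis-tiled or multi-seed frames. Passing end-to-end
tests therefore demonstrates that the pipeline recovers a radicle-driven
signal under these stylised confounders, not field-grade accuracy on real
imagery — the hard-preset AUC here is higher than what heterogeneous real
seed lots yield.

## Problem sizes and runtime choices

End-to-end checks run 400 seeds × 4 time points per preset (1,200 scored
images each after time-zero exclusion) at the nominal 282 × 341 px tile;
the curation simulation uses 40 seeds × 3 time points with 5% of labels
flipped and an oracle reviewer. These sizes give stable AUC estimates
while keeping the full suite and the acceptance script to a few minutes.
Tiles are rendered lazily and reduced to features immediately, so the
image set never resides in memory at once.

## Known limitations

- One central object per tile: touching seeds or mould bridges that merge
  with the seed are measured as one object.
- Min-max normalisation is sensitive to single extreme training values.
- Certainty-ranked review cannot surface confidently wrong labels (see
  above); the convergence criterion bounds effort, not residual error.
- The Otsu default assumes a bimodal grey histogram; tiles with no seed
  raise a segmentation error rather than guessing.
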