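# Methods

`sectionfuse` solves two coupled problems in serial-section spatial biology:
(1) aligning stained images of consecutive fresh-frozen tissue sections with
a nonrigid, diffeomorphic transformation, and (2) using that alignment to
fuse molecular measurements acquired on different sections — circular
mRNA-capture spots (~55 µm, hexagonal lattice, ~100 µm pitch) and square
mass-spectrometry-imaging pixels (~30 µm) — into one spot-level dataset.
This note records the model, the parameter choices, and the limits of what
the synthetic validation shows.

## Registration model

**Similarity.** All image alignment maximizes local (windowed) normalized
cross-correlation: per pixel, the Pearson correlation of the two images over
a square window of radius 10 px at the 1024-px working resolution (1% of the
frame), averaged over the frame; zero-variance windows contribute 0. Local
NCC is invariant to locally linear intensity maps, which is what differently
stained sections require. The radius is held fixed across pyramid levels in
units of level pixels, matching the convention of greedy diffeomorphic
registration tools.

**Preprocessing.** Each image is segmented (640×640 grayscale resample →
total-variation denoising → Otsu threshold with tissue on the dark side →
morphological closing with a 5-px disk → removal of regions under
10,000 µm²), optionally mean-shift denoised for the affine stage (512×512
resample, joint (x, y, H, S, V) mean shift with spatial radius 20 and color
radius 15 on 8-bit-scaled HSV, max 10 iterations, termination shift < 1),
cropped to the tissue bounding box, padded to the common square of the pair,
Gaussian-smoothed (σ = 2) against aliasing, resampled to the working
resolution (default 1024), converted to 0.299/0.587/0.114 luminance, and
padded by 100 px (scaled with the working size) to leave room for
deformations. Every geometric step is stored as an exact affine, so the
original↔working mapping is invertible to machine precision. The nonrigid
stage repeats preprocessing without denoising: the local stage benefits from
fine image features that the affine stage treats as noise. Users can supply
their own masks anywhere; segmentation polarity (tissue darker than
background) is a flag.

**Affine stage.** A seeded random search over rigid transforms — rotation
uniform in ±180°, translation uniform within ±10% of the frame around the
center-of-mass initialization computed from the tissue masks — runs at the
coarsest pyramid level. The NCC basin around the true rotation is only a few
degrees wide, so the search uses 1000 trials and briefly L-BFGS-refines the
top 8 before picking the winner; evaluation at the coarsest level costs well
under a millisecond, keeping the whole search near a second. The six affine
parameters (translation, rotation, two log-scales, shear, about the frame
center) are then refined per pyramid level (factors 8, 4, 2, 1) by bounded
L-BFGS on local NCC, with the iteration budget halving at each finer level
(fine levels only polish). Bounds (|log-scale| ≤ 0.7, |shear| ≤ 0.6,
translation within half the frame) keep the optimizer inside invertible,
anatomically plausible maps.

**Nonrigid stage.** Greedy diffeomorphic refinement per pyramid level:
warp the moving image by the current total field composed with the affine
initialization; compute the per-pixel NCC ascent force (the analytic
derivative of windowed NCC with respect to the warped intensity, times the
warped image gradient); smooth the update with a Gaussian (pre-sigma 5);
scale it so the largest displacement is 1 px; compose it into the total
field; smooth the total field (post-sigma 4); accept only if similarity
improves, otherwise halve the step. Iterations stop at 100 per level, at a
relative similarity gain below 1e-5, or when the step underflows. Small
smoothed steps plus total-field smoothing keep the Jacobian of the
composite positive in practice; the Jacobian and the forward/backward
round-trip error are checked on every result and a warning is attached if
the round trip exceeds 2 px. The forward (pointset) direction is obtained
by fixed-point inversion of the final backward field (20 iterations,
tolerance 0.05 px); the field's post-smoothing makes incremental inverse
accumulation no more accurate, and the round-trip contract is verified
directly instead.

**Compositing.** Crop/pad/rescale bookkeeping, the stage affine, and the
stage displacement field are composed functionally and materialized once as
a single full-resolution displacement field (backward for image resampling,
forward for pointsets and polygons), so every data product is interpolated
exactly once. Images warp with linear interpolation, masks and label
rasters with nearest-neighbor, vertices through the forward map.

**Groupwise mode.** For an ordered series with a designated fixed section
(default: last), affine registrations run between neighbors and are
composed into each section's chain; the nonrigid stage then registers every
moving section directly against the fixed section starting from its chained
affine. Sections are independent after the affine chain, so the per-section
stage runs through a pluggable map function (default sequential); results
are bit-identical regardless of execution order. Caller-flagged damaged
sections are bridged over in the chain. In the groupwise path each section
is denoised once rather than once per neighbor pair; the result is the same
image the pairwise path would compute, at half the cost.

**Landmark fallback.** When intensity registration fails (e.g., severe
tissue damage), a least-squares affine or an exact thin-plate-spline
interpolant through manually placed landmark pairs can stand in for the
intensity stages; it returns the same chain type and is accepted everywhere
a registration result is.

## Evaluation

Accuracy is summarized by the target registration error: the Euclidean
distance between each warped landmark and its fixed partner. One
registration pair is summarized by its median TRE; a dataset of pairs by
the median of medians (MM-TRE, robust to failed registrations) and the mean
of medians (AM-TRE, which a single catastrophic failure dominates — the gap
between the two is itself diagnostic). Even-length medians take the
midpoint of the central order statistics. At the package's default export
resolution of 1 µm per pixel, pixel errors are micron errors.

## Omics integration model

**Grid projection.** Spot and pixel geometries are rasterized into integer
*reference matrices* at stained-image resolution: label k > 0 points at
data point k, 0 is background. A raster cell takes a spot's label iff its
center lies inside the spot circle (pixel-center rule; the fusion weights
recover sub-cell precision), and a pixel's label iff its center falls in
the half-open pitch×pitch square. Overlapping circles resolve to the lower
id with a warning; fully off-image geometry is reported, not dropped
silently. The default spot diameter is 55 µm on a 100 µm hexagonal pitch
(row pitch 100·√3/2, alternate rows offset 50 µm, so nearest-neighbor
center distance is exactly 100 µm) and the default pixel pitch is 30 µm.

**Pixel-omics-to-stain registration.** Pixel-based omics comes with no
intrinsic alignment to its own stained image, so a feature image is built
from the first principal component of the per-pixel spectra (mean-centered
SVD; scores min-max scaled to [0, 1]; sign fixed so interior grid pixels
score above border pixels, since eigenvector sign is arbitrary), upscaled
to stain resolution, and rigidly registered (rotation + translation only,
to avoid deforming the pixel grid) against the inverted stained grayscale
using the same NCC machinery restricted to three parameters. Masks can be
registered directly instead when available.

**Fusion.** After registration, the source reference matrix is warped
(nearest-neighbor) into target space and co-labeled cells are counted per
(target spot, source pixel) pair. Weights are each source pixel's fraction
of its spot's covered area (normalized per spot, summing to 1). Per spot
and measure the package reports the weighted mean Σwᵢvᵢ, the population
weighted standard deviation √Σwᵢ(vᵢ−mean)², the lower weighted median
(smallest value whose cumulative weight reaches 0.5, with a 1e-9 tie
epsilon against float cumsum error), and the unweighted extremes (extremes
have no canonical weighting), plus the overlap area and source count.
Spots without overlap are emitted flagged rather than dropped so joins stay
aligned.

**Filters.** Spots with tissue coverage below 80% are removed (coverage
exactly 0.80 survives). Tissue-type matching assigns each spot the majority
annotation label when its fraction reaches 0.5 (else unassigned) in both
the target and the warped source annotation, and keeps spots whose labels
agree. The sham control appends a 180° rotation about the fixed-image
center to an otherwise correct chain — deliberately wrong integration with
the correct marginal statistics.

## Synthetic data: what it emulates and what it does not

The generators produce, from one seed with named substreams (image,
deformation, omics, noise, landmarks, sections): a tissue blob with a
smoothly perturbed boundary; elliptical glands (dark rim, pale lumen) in
textured pink stroma on a white slide, H&E-like in palette; landmarks on
tissue; smooth invertible deformations (sums of Gaussian velocity bumps
exponentiated by scaling-and-squaring, 10 squarings, with forward and
backward fields exact inverses to < 0.1 px and a generator-side refusal
when the velocity gradient approaches folding; for frames over 800 px the
exponential is integrated at half resolution and upscaled, which is
indistinguishable at the smoothness scales used); serial sections with
accumulating drift, per-step rigid placement jitter (rotation ±10°,
translation 2% of frame), AR(1) stroma texture decorrelation (coefficient
0.75 per step), gland removal at the churn rate (default 0.15 per step),
and per-gland random walks in position and size — together these reproduce
the qualitative fact that registering distant sections is genuinely harder
than stepping through neighbors; and omics layers whose values are
baseline + effect·(gland area fraction) + optional smooth shared latent +
Gaussian noise, so true cross-layer correlation is known by construction.

Not emulated: realistic stain variability and scanner artifacts, real
spectra, tears and folds, cell-scale texture, partial-volume optics.
Passing tests therefore demonstrate the correctness and self-consistency of
the algorithms under controlled morphology and known deformations — not
clinical-grade accuracy on real slides, for which landmark-based evaluation
on real data remains necessary.

## Benchmark experiment design and problem sizes

The seeded experiments in `sectionfuse.experiments` (run by the test suite
and `scripts/acceptance.py`) use desk-scale problem sizes chosen so the
full battery completes on one CPU core in tens of minutes:

- *Affine recovery*: a 900-px section vs. a copy transformed by 25°
  rotation, (15, −10) px translation, 5% scale, registered at the full
  1024 working resolution.
- *Nonrigid recovery*: a known three-bump field (15 px amplitude, 80 px
  smoothness), registered at a 512 working resolution; reported as the
  median-TRE reduction relative to the affine-only chain and the fraction
  of positive Jacobian determinants.
- *Groupwise vs. pairwise*: ten replicates of a five-section, 600-px series
  with 6 px/step drift and deliberately strong axial heterogeneity (texture
  AR 0.6, gland churn 0.25/step, rigid placement jitter ±20°, gland
  random-walk 10 px/step), registered at a 160 working resolution with 30
  nonrigid iterations per level. These conditions were chosen so that the
  affine-only comparison already favors the chained affine on essentially
  every replicate — the mechanism the groupwise mode exists for — while
  neighbor registrations stay reliable; direct registration of the farthest
  pair then degrades and occasionally fails outright. The comparison counts
  replicates where the groupwise chain's median landmark TRE for the
  farthest pair does not exceed direct pairwise registration's. Both
  replicate experiments register the rendered images without mean-shift
  denoising: the synthetic noise is white, not stain speckle, so the
  denoiser adds cost but no signal there.
- *Integration ordering*: ten replicates of a 1200-px scene, spot layer on
  section 0, pixel layer on section 2 (two drift steps away), real
  registration at a 192 working resolution, then fusion under the true
  chain and its 180°-sham, each with and without tissue-type matching. The
  latent co-variation field (σ = 60 px, weight 0.35·effect) models
  within-tissue-type biology that only correct integration can align: it
  separates correct-but-unmatched integration from sham-with-matching, the
  ordering the real data shows.

## Known limitations

- The affine random search is global but sampled; a pathological section
  pair can defeat 1000 trials. The trial count and seed are options.
- The greedy nonrigid stage is a local optimizer; it refines, but cannot
  rescue, a wrong affine basin.
- Mean-shift denoising is O(pixels · window²) and is the single most
  expensive preprocessing step (~seconds per image at 512²).
- Weighted fusion assumes the source resolution is finer than the target's;
  mapping coarse data onto fine targets would need deconvolution, which is
  out of scope.
- Reference matrices assign each raster cell to at most one spot, so
  physically overlapping capture areas are tie-broken, not mixed.
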