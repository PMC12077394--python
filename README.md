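# sectionfuse

Nonrigid registration of stained serial tissue sections and area-weighted
fusion of spatial multi-omics data into a single spot-level dataset.

Spatially resolved omics assays — Visium-style spatial transcriptomics
(circular ~55 µm capture spots on a ~100 µm hexagonal lattice) and mass
spectrometry imaging (square ~30 µm pixels) — usually cannot share a tissue
section, so each modality lands on its own serial section. Integrating them
requires (1) registering the sections' stained images, which drift apart in
morphology with axial distance and deform nonrigidly during sectioning, and
(2) translating measurements between incompatible sampling geometries.
`sectionfuse` implements both halves for computational biologists working
with serial-section multi-omics:

- **Registration**: tissue segmentation → edge-preserving mean-shift
  denoising → grayscale downscaling to a padded 1024² working frame →
  multi-resolution affine registration (seeded rigid random search +
  quasi-Newton refinement) → greedy diffeomorphic nonrigid refinement, all
  under a local normalized-cross-correlation similarity (window radius
  10 px, pyramid 8/4/2/1, update smoothing σ=5, total-field smoothing σ=4).
  Every step is composited into a single full-resolution displacement
  field applicable to images, masks, label rasters, CSV pointsets, and
  GeoJSON polygons. A groupwise mode chains neighbor affines through an
  ordered series and nonrigid-refines each section directly against the
  fixed one.
- **Integration**: spot/pixel geometries are rasterized into integer
  *reference matrices* at stained-image resolution, warped like any other
  raster, and fused by area-fraction weights: per target spot, each source
  pixel contributes its fraction of the shared area, and the package
  reports weighted min/max/mean/std/median per measurement, plus tissue
  coverage and tissue-type-matching filters and a 180°-rotation sham
  control.
- **Evaluation**: landmark target registration error (TRE), per-pair median
  TRE, and the dataset summaries MM-TRE (median of medians) and AM-TRE
  (mean of medians), in µm at 1 µm/px.
- **Synthetic data**: seeded generators for histology-like sections, known
  invertible deformations, serial series with controllable heterogeneity,
  and omics layers with known cross-layer correlation — every test and
  benchmark runs against generated ground truth; no external data needed.

## Worked example

Simulate a two-section study, register, and evaluate:

```sh
sectionfuse simulate --seed 3 --size 700 --sections 2 --out sim
sectionfuse register sim/section_01.tiff sim/section_00.tiff \
    --moving-mask sim/section_01_mask.tiff \
    --fixed-mask sim/section_00_mask.tiff \
    --working-size 256 --seed 0 --out reg
sectionfuse transform --field reg/displacement_field.npz \
    --input sim/section_01_landmarks.csv --kind points --out warped
sectionfuse evaluate \
    --warped-landmarks warped/warped_points.csv \
    --fixed-landmarks sim/section_00_landmarks.csv --out eval
```

The `evaluate` step prints the landmark error report; one run of the above
printed:

```json
{
  "n_landmarks": 60,
  "median_tre_um": 2.7562761549028627,
  "mean_tre_um": 2.9576983134792814,
  "max_tre_um": 9.224311412127259
}
```

A median TRE of ~2.8 µm means half the landmarks of the registered moving
section landed within 2.8 µm of their true positions in the fixed section's
frame — sub-spot accuracy relative to the 55 µm capture areas the
integration step fills. The same pipeline is available as a library
(`sectionfuse.register_pair`, `sectionfuse.groupwise_register`,
`sectionfuse.overlap_weights`, `sectionfuse.fuse`, ...); the CLI is a thin
wrapper over it.

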