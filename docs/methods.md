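# Methods

This note documents the models, conventions and design choices behind
`fcdseg`, and what its synthetic validation does and does not establish.

## Scope and shape

The package implements the *evaluation side* of an FCD type II segmentation
study: preprocessing, lesion-focused slice selection, the pseudo-Dice metric
family, a 5-fold cross-validation harness, and fold-level statistics. The
segmentation model itself is deliberately a pluggable interface. A
full-scale encoder–decoder framework (e.g. nnU-Net) is *not* re-implemented;
an adapter can drive an installed nnU-Net v2 and parse its progress log,
while two desk-scale segmenters (a quantile-threshold baseline and an
SGD-trained logistic voxel classifier) make the harness executable and
testable in seconds.

Stage objects that are naturally transform- or fit/predict-shaped follow
scikit-learn estimator conventions (`Preprocessor`, `SliceSelector`,
`QuantileThresholdSegmenter`, `SGDLogisticSegmenter`: `fit`/`transform`/
`predict`, `get_params`, fitted attributes with trailing underscores);
metrics, statistics and the harness are plain functions, mirroring
`sklearn.metrics` / `sklearn.model_selection`.

## Geometry and I/O

A `Volume` is a 3D array plus a 4×4 NIfTI affine; voxel spacing is the
affine's column norms and must agree with any explicitly supplied spacing to
1e-3 mm. Array indices are 0-based; the third array axis is treated as the
axial (inferior–superior) slice axis by default and is configurable, since
stored array orientation varies between datasets. Masks are uint8 over
{0, 1} and must share their reference volume's grid exactly; cross-modality
registration is out of scope — callers supply voxel-aligned pairs.

## Preprocessing

Order: resample → skull strip → normalize → binarize, each stage loggable
and errors annotated with the stage name.

- **Resampling.** Target spacing defaults to 1 mm isotropic (a convention —
  nothing deeper; any standard spacing works). New shape per axis is
  `round(shape·spacing/target)` with a floor of 1; images use spline
  interpolation of configurable order (default 3), masks always
  nearest-neighbour so the label set {0, 1} is preserved exactly.
- **Skull stripping.** No external tool is assumed: Otsu threshold →
  morphological closing (radius 1) → largest face-connected component →
  hole filling. Deterministic and adequate for phantom-scale validation; a
  dedicated stripper can replace it behind `skullstrip_method`. A constant
  image has no separating threshold and is rejected.
- **Normalization.** Z-score within the brain mask (mean 0, sd 1 in-mask;
  0 outside). This removes scanner units entirely — it is idempotent and
  invariant under positive affine intensity maps, both tested. A global
  variant is kept behind configuration.
- **Binarization.** `raw > threshold` with threshold 0.5 by default.

## Slice selection

Only a few axial slices carry visible lesion. Slices are scored either by
per-slice lesion-voxel count (`lesion_area`, default when a mask exists;
an intensity-weighted variant is available) or by per-slice maximum
intensity (`peak_intensity`, usable without a mask, e.g. at inference —
whether selection may use the ground-truth mask at inference time is a
protocol question the package surfaces rather than resolves). The top k = 5
slices are kept, ties resolved toward the lower index for determinism, and
compiled in anatomical order into a slab. The slab keeps the nominal axial
spacing even for non-adjacent slices; true inter-slice gaps are in the
per-case selection report. With `lesion_area` and k at least the number of
lesion-bearing slices, slab extraction retains 100% of lesion voxels; for
any non-empty mask the slab's lesion fraction is at least the full volume's
(selection is enriching) — both are tested properties.

## Metrics

Dice and two pseudo-Dice variants are implemented (see README for
formulas). The default `as_printed` variant places ε as
2(|A∩B|+ε)/(|A|+|B|+ε): this is the form this evaluation protocol defines,
and it is *not* a conventional smoothed Dice — it equals 2 for two empty
masks, exceeds 1 at perfect overlap, and is bounded above by 2 (documented
and tested). The conventional `standard_smooth` form, bounded in [0, 1], is
provided alongside; the discrepancy is documented, not resolved. ε defaults
to 1e-5, small relative to any plausible lesion volume in voxels. The
moving-average window defaults to w = 10 epochs for reporting.

A score trace may index epochs or test samples; the harness records both
granularities (per-epoch trace; per-case scores at the final epoch).

## Cross-validation and statistics

Folds are a seeded random balanced partition (sizes differ by at most one);
no stratification is applied. Per-epoch trace values are the mean
validation-case pseudo-Dice. "Pseudo-Dice at the final epoch" is the raw
last trace value, not a moving average. Training defaults mirror a
full-scale schedule: 100 epochs, batch size 4, SGD with learning rate 0.01,
momentum 0.99, Nesterov; the deterministic quantile segmenter ignores the
epoch loop (its trace is constant), the SGD voxel classifier uses it.

Fold columns are compared with sample-sd (n−1) descriptives, t-based 95%
confidence intervals and a two-sided paired t-test (df = n−1) — the
t-based interval, not the normal approximation, is what reproduces the
reference study's printed intervals from its five fold scores, which was
verified by direct recomputation. Numerical guards: a sample sd below
1e-12 of the data scale is treated as exactly zero, so constant columns
(e.g. from a non-iterative segmenter) raise/flag degeneracy instead of
producing a spurious t from floating-point jitter. Report tables round
half-up to 2 decimals.

## Phantoms

`generate_phantom` builds a noisy ellipsoidal "brain" (tissue mean 100,
sd 5, arbitrary units — normalization removes scale) in a dark background,
with one or more hyperintense lesion blobs (contrast ×1.5) recorded exactly
in the mask. Lesions are ellipsoids with a 4–5 voxel in-plane radius
spanning 5 axial slices, placed at 40–70% of the brain's in-plane radius
("cortical"), with the anterior/posterior side drawn so that 62.4% of
centers fall in the anterior half — emulating the frontal-lobe prevalence
reported for FCD type II, as a marginal frequency only, not anatomy.
Placement is rejection-sampled inside the brain with bounded retries.

`generate_cohort` varies field of view and voxel spacing per case (shapes
44–60 in-plane and 32–40 axial mm; near-isotropic spacings 0.9–1.1 mm)
while keeping the physical brain size nearly constant (±≈4%), as across
adult subjects — so scans "vary in size" but lesion-to-brain fractions stay
in a realistic, moderately heterogeneous band. Cohorts used in tests and
the acceptance run are 10–20 cases of ≈50³ voxels: large enough to exercise
every stage and small enough that the whole suite runs in well under a
minute on one CPU.

What phantoms do **not** model: real anatomy and cortical geometry, MRI
physics (bias fields, partial volume, k-space artifacts), ambiguous lesion
borders, inter-rater annotation variability, or healthy controls. Phantom
scores (Dice ≈ 0.8–1.0 for the baselines) therefore say nothing about
clinical accuracy; they validate the *pipeline and metrics*, not a model.
Clinical FCD segmentation scores are far lower. Reproducing a clinical
study's absolute fold scores requires the original dataset and full-scale
GPU training, which is explicitly out of scope.

## Known limitations

- The quantile-threshold baseline assumes the lesion is the brightest
  structure; it is a validation device, not a competitive method.
- Slab geometry is deliberately approximate for non-adjacent slices.
- The skull stripper is tuned for bimodal phantom histograms; clinical
  scans should use a dedicated tool behind the pluggable interface.
- The external nnU-Net adapter only launches training and parses traces;
  dataset preparation for it is the caller's responsibility.
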