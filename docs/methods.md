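# Methods

`mrifuse` fuses heterogeneous observational brain-MRI studies into a
single relational catalog and prepares their T1-weighted images for
machine learning with a deliberately lightweight preprocessing and QC
chain.  This note documents the models, the parameters that matter, the
synthetic data the package is validated on, and the numerical choices
behind each stage.

## The relational catalog

The catalog is a ten-entity relational schema held in a single SQLite
file (any SQL URI can stand behind the same surface): *source dataset*,
*condition*, *source-condition map*, *subject*, *visit*, *scanner*,
*image*, *preprocess task*, *file type*, and *preprocess file*, plus two
auxiliary tables for per-visit clinical scores and QC results.  The image
is the fundamental entity; subjects carry time-invariant demographics,
visits carry everything longitudinal (diagnosis, BMI, clinical scores),
and scanners encode site/device differences.  Foreign keys are enforced
at all times, every insert pre-resolves its references so violations are
reported by entity name, and multi-row operations (study ingestion,
QC persistence) run in a single transaction.

Clinical scores live in a key-value side table rather than fixed columns
because visit-level instruments differ per study and per wave.  Summary
counts define "subjects" as *subjects with at least one image*; subjects
ingested with metadata only are reported separately by the ingest report
(`n_subjects_without_images`).

## Ingestion and harmonization

Each study is read by an adapter that owns the study's file dialect and
yields canonical rows; the core never sees study-specific column names or
calendars.  Loading runs strictly in the order subjects → visits →
images, because each phase references keys created by the previous one;
driving the phases out of order raises.  Ingestion of a study is
all-or-nothing.

**Image-to-visit matching.**  An image is attached to the *closest
clinical visit in the past* within `max_gap_days` (default 60).  A
same-day visit counts (gap 0); a future visit never matches, so no
post-acquisition clinical information can leak into an image's visit
context — the property that matters for prognostic modeling.  The
60-day default reflects the typical spacing between image acquisition
and clinical assessment in longitudinal cohorts while staying below the
timescale of neurodegeneration; it is a `MatchRule` parameter, not a
constant.

**Unmatched images.**  A longitudinal image with no qualifying past
visit is, by default, attached to a freshly synthesized visit flagged
`is_synthesized` and carrying no clinical payload (policy
`synthesize`); policy `skip` drops it and records it in the report.
Cross-sectional studies have no visit structure at all, so every image
gets a synthesized visit — the visit abstraction is imposed uniformly.

**Days since baseline.**  Day 0 is the subject's earliest visit (real
or synthesized); all visit and acquisition days are rebased to that
origin per subject, so the first visit is always day 0 and all stored
days are non-negative.

**Vocabulary mappings.**  Condition labels are mapped to a master list
through an explicit per-study table (`condition_map.csv`); the mapping
is declared data, never inferred, and an unmapped label is an error
recorded in the ingest report — no silent defaults.  Education given as
qualification codes is converted to years through a declared
`EducationMapping`; codes explicitly mapped to "unknown" propagate as
unknown.

## Preprocessing

All spatial operations use pull-resampling with trilinear interpolation:
for each target voxel, map its world position (mm) through the inverse
transform and sample the source; outside-volume samples are zero.
Transforms are world-space 4×4 matrices independent of either grid.

**Brain extraction** is classical: Otsu's threshold (maximizing
between-class variance), largest connected component, 2-iteration
morphological closing, hole filling, and a final largest-component pass
guaranteeing a single connected mask.  On the synthetic phantoms it
reaches Dice ≥ 0.95 against the generator's true mask; it is not
intended to compete with learned skull-stripping on clinical data.

**Bias-field correction** models the image as
`log I(x) = log µ_k(x) + log b(x)`, with `µ_k` a per-tissue-class mean
and `b` a polynomial of total degree ≤ `order` (default 3; the
acceptance experiments fit order 2, matching the simulated fields) on
world coordinates normalized to the mask bounding box.  A plain
least-squares polynomial fit to in-mask log-intensities is *not* enough:
grey/white contrast (~0.7 in log units) dwarfs realistic bias
amplitudes (~0.15), and the fit absorbs anatomy.  The estimator
therefore interleaves a k-means tissue classification (k = 3, seeded,
percentile-initialized) with the polynomial fit: each of 4 iterations
re-classifies the bias-corrected log-intensities, forms per-voxel
residuals against class means, trims outliers beyond 2.5 SD, smooths
the residual map with a 10 mm normalized Gaussian inside the
1-voxel-eroded mask (suppressing texture and partial-volume edges), and
refits.  The fitted log-field is clamped to its in-mask range before
exponentiation so polynomial extrapolation cannot explode outside the
brain, then normalized to mean 1 over the mask.  Non-positive in-mask
intensities are handled by a shifted log (or rejected, per
`on_nonpositive`).

**Affine registration** recovers 7 degrees of freedom — 3 Euler angles,
3 translations, one *isotropic* scale (`T·R·S`); no shear, no
anisotropic scaling — by maximizing normalized cross-correlation (NCC)
between the template and the resampled moving image inside the template
brain mask.  NCC is adequate and cheap for mono-modal T1-to-T1-template
alignment.  The search is Powell's derivative-free method over scaled
parameters (1 unit ≈ 0.02 rad, 2 mm, 0.02 log-scale) on a 3-level
pyramid (downsampling factors 4, 2, 1 with matched anti-alias
smoothing), initialized at the intensity center-of-mass alignment with
unit scale and zero rotation.  Only masked voxels are sampled during
optimization, which keeps a 64³ registration around one second on one
CPU.  The optimizer accepts a level's result only if it does not lower
the objective, and the final result never falls below the
initialization's similarity; non-convergence returns the best point
found with a `converged=False` flag.

**Nonlinear registration** is a small-deformation demons-style scheme on
the template grid, applied after the affine: per iteration, a
gradient-driven intensity-matching update (step clamp 1 mm), Gaussian
smoothing of the displacement field (σ = 3 mm) as regularization, and a
hard 12 mm displacement cap; 60 and 30 iterations on a 2-level pyramid.
The field is stored in mm, pull convention, as a 4-D NIfTI.  The
smoothing/iteration balance was chosen so that, on phantoms with ~4 mm
simulated deformations, the warp reliably raises masked template
correlation above the affine-only value while the finite-difference
Jacobian of `x + u(x)` stays positive everywhere (no folding).  This is
a convergence/regularity trade-off: smaller σ matches intensities better
but drives the Jacobian toward zero.

**Artifacts.**  Affine mode writes the brain mask, the registered image
and the 4×4 affine as a plain-text matrix (4 lines × 4 decimals);
nonlinear mode adds the warp.  Every artifact is registered in the
catalog keyed by (image, task, file type), so re-running a mode replaces
its artifacts without duplication, and `audit` verifies all referenced
files exist.  The full pipeline is deterministic: identical inputs give
byte-identical outputs.

## Quality control

The gate is the Pearson correlation of voxel intensities between a
registered image and the template, computed inside the template brain
mask, with a pass threshold of 0.4.  Raw (bias-corrected) intensities
are used, not ranks; the correlation is invariant to any positive affine
intensity rescaling of either input.  By default the affine-registered
image is scored (the stage is selectable).  Failures are flagged and
kept in the catalog — exclusion happens at query time through the
`qc_min_r` filter, so a different threshold never requires re-ingestion.
On the standard phantom fixture, correctly registered images score
r ≈ 0.95+ and 40 mm mis-registrations score r ≤ 0.3, so the 0.4 cutoff
separates the groups with a wide margin.  An alternative reading of the
metric — correlating against a *binarized* template rather than template
intensities — was considered and not used.  This is an integrity gate,
not a QA suite: motion or artifact-specific detectors are out of scope
by design (they cost orders of magnitude more than the preprocessing
itself).

## Synthetic data: what it emulates, and what it does not

The template phantom is a nested-ellipsoid "brain" with three tissue
intensity levels (CSF ≈ 0.12, grey ≈ 0.35, white ≈ 0.7), a tilted
off-center white-matter core, two asymmetric ventricles, a
posterior-inferior lobe, four ±0.08 intensity blobs, smooth random
texture (SD 0.03), and light smoothing.  The lobe and tilt matter: a
plain ellipsoid is nearly rotation-symmetric, and without a large-scale
shape asymmetry the coarsest pyramid level can lock onto a ~180°-flipped
optimum.  The phantom lives in a fixed 160 mm field of view at any grid
size (64³ → 2.5 mm voxels).

Subject images resample the template through the *inverse* of a sampled
7-DOF transform (rotations ≤ 10°/axis, translations ≤ 10 mm, scale
0.9–1.1 — so registration must recover the forward transform), multiply
an `exp(polynomial)` bias field (order 2, log-SD 0.15), and add Gaussian
noise (SD 0.02 against a white-matter intensity of 0.7); a smooth
random displacement bump (peak 4 mm) can be baked in ahead of the affine
perturbation for nonlinear tests.  Every image carries complete ground
truth: transform, bias field, brain mask, bump field.

Synthetic studies exercise metadata heterogeneity with two dialects.
The longitudinal study (default: 10 subjects × 3 visits × 1 image,
visit spacing 180 ± 15 days) ships `subjects.csv` + `visits.csv` + one
JSON sidecar per image, education as qualification codes with a separate
code→years table, and image acquisition days offset 0–90 days after
their visit — so with the 60-day rule roughly a third of images have no
qualifying visit, exercising the unmatched policies.  The
cross-sectional study (default: 5 subjects) is a single
`participants.csv` with different column names, education already in
years, and per-subject diagnosis labels from a different vocabulary
mapping into the same master list.  Study images default to 32³ grids;
the registration and QC experiments use 64³ phantoms directly.

What the phantoms do **not** emulate: real neuroanatomy and its
population variability, pathology, skull/neck tissue (brain extraction
sees a bright object on black), multi-modal contrast, scanner-specific
noise spectra, motion or susceptibility artifacts.  Passing tests
demonstrate that the machinery is correct and well-conditioned under
known ground truth — not that clinical-grade accuracy carries over to
real multi-site data.

## Validation sizes and determinism

The standard validation runs 20 phantoms (64³) for affine recovery, 20
for the nonlinear step, 10 + 5 for QC separation, 5 for bias recovery,
10,000 randomized instances for the matching rule, and one
longitudinal + one cross-sectional study for ingestion integrity —
sizes chosen to give stable medians and fractions at desk scale.  All
randomness flows through explicit seeds; regenerating a study with the
same spec yields a byte-identical directory tree.

## Known limitations

- The bias estimator recovers simulated fields at median r ≈ 0.94 but
  individual phantoms can fall to ~0.85 when the sampled field aligns
  with anatomy; a histogram-sharpening scheme (N4-style) would do
  better at higher cost.
- The affine metric is masked NCC only; multi-modal registration
  (mutual information) is explicitly out of scope.
- The demons warp is regularized by Gaussian smoothing with a positive
  observed Jacobian, but carries no diffeomorphic guarantee.
- Single-writer catalog semantics; no schema migration tooling.
- Condition mapping is flat; no ontology coding systems.
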