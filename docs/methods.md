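# Methods

This note documents the models implemented in `dbsmap`, the choices made
where the analysis family leaves the design open, what the synthetic cohort
generator does and does not emulate, and the package's known limitations.
Every number quoted here is computed by the test suite or the worked
example; none is asserted from outside the package.

## Coordinate conventions

All spatial data live in one world frame: RAS-oriented millimetres
("MNI-like"): +X right, +Y anterior, +Z superior, so *ventral* means
smaller Z. Images carry a 4×4 voxel→world affine; voxel indices are
0-based; masks are defined on voxel centers. TRK files are normalized to
this frame on read; streamlines are always handled in world mm.

## VTA model

The electric field of a monopolar contact is modelled as a quasi-static
homogeneous point source centered on the active contact:

|E|(r) = U·r_c / r² for r ≥ r_c, clamped to U/r_c inside the contact,

with U the amplitude in volts and r_c = 0.635 mm the contact radius.
Thresholding at E_th = 0.2 V/mm defines the binary VTA, analytically a ball
of radius r* = √(U·r_c/E_th); at the cohort-typical 2.5 V this is 2.82 mm,
and the voxelized volume at 0.5 mm voxels is within 10 % of the analytic
ball (tested). The point source replaces finite-element field solving
deliberately: it preserves the thresholding semantics all downstream stages
consume while keeping the field model a single isolated function
(`vta.field_magnitude`) that a finite-element or axon-model estimate could
replace without touching anything else. Pulse width and frequency are
carried through the data model but do not enter this field model. Only
voltage-controlled monopolar stimulation is supported; other modes raise.

Consequence to keep in mind: absolute VTA volumes from this model are not
comparable to finite-element volumes; only their relative geometry matters
to the analyses, which binarize immediately.

## Sweet-spot mapping

- N-image: per-voxel count of covering per-patient VTAs (bilateral union by
  default; a single hemisphere by config).
- Coverage filter: keep voxels covered by ≥ ceil(0.2·N) VTAs. The ceil
  makes "less than 20 % excluded" and "at least 20 % kept" coincide
  (N = 56 → 12).
- Mean-effect map: mean outcome change (pre − post, positive = improvement)
  over covering patients, per kept voxel.
- Voxel test: two-sided Wilcoxon signed-rank of the covering patients'
  changes against zero. Zeros are dropped; the exact null distribution is
  used for n ≤ 25 — computed by subset-sum convolution over doubled
  midranks, so ties are also exact (the implementation equals brute-force
  2ⁿ sign enumeration; tested with zero tolerance) — and a normal
  approximation with tie-corrected variance and no continuity correction
  beyond. All-zero voxels get p = 1 by convention.
- Multiplicity: Benjamini–Hochberg q-values over kept voxels only;
  sweet = (q ≤ α) ∧ (mean > 0), sour = (q ≤ α) ∧ (mean < 0), α = 0.05.
- Identical covering sets share one test: voxels are grouped by their
  patient-coverage pattern before testing, which is what makes per-fold CV
  refits cheap.

## Fiber filtering

Streamlines are resampled at half-voxel steps along their course (so thin
masks cannot be skipped between vertices); a fiber is connected to a
patient when any sampled point lies in the patient's bilateral-union VTA.
Fibers connected to < ceil(0.2·N) patients are discarded; the rest get a
pooled-variance Student t contrasting connected vs unconnected patients'
changes (Welch available by flag; pooled is the classical fiber-filtering
formulation). The top ceil(0.3·n_kept) by |T| are selected, ties broken
toward lower fiber id for determinism; degenerate scores (a group < 2, or
zero pooled variance) are flagged NaN and never selected.

## Out-of-fold prediction and cross-validation

Schemes: leave-one-out, or seeded k-fold (k = 10 default) partitions.
Everything data-dependent — coverage filter, voxel tests, FDR, prevalence
filter, T-scores, top-|T| selection — is recomputed on the training
patients of each fold; the spec of folds is deterministic given the seed.
Reported: Pearson R of predicted vs observed change with its two-sided p;
constant predictions yield NaN with a flag, fallback predictions are
counted.

Predictors:

- Sweet-spot: mean of the trained mean-effect map over the held-out VTA
  restricted to significant voxels, falling back to all kept voxels, then
  to 0 (flagged). Map values enter *relative to the training-cohort mean
  change*: the grand mean carries no spatial information, and leaving it in
  gives leave-one-out predictions a mechanical negative correlation with
  the observed outcomes (every training mean is missing exactly the
  held-out score). "sum" and "sweet-minus-sour overlap" variants are
  available by flag.
- Fiber: mean trained T-score over selected fibers connected to the
  held-out VTA; 0 (flagged) when none.

### Known limitation: residual null bias of the cross-validated R

Even with the centering above, the out-of-fold correlation is not
null-unbiased: over 100 null-scenario cohorts the mean LOOCV R is ≈ −0.15
for the sweet-spot model and ≈ −0.10 to −0.14 for the fiber model
(replicate SD ≈ 0.2; 10-fold is only slightly milder). The covariance of
predicted and observed is unbiased (mean ≈ 0); the bias lives in the
correlation's normalization — replicates whose predictions have small
spread are systematically the ones with negative covariance, and dividing
by the small spread amplifies them. The same ≈ −0.13 appears in a stripped
1-D simulation of exclude-self local means under a coverage filter, with no
imaging code involved, so it is a property of this class of
training-set-contrast predictors under heavily overlapping VTAs, not of the
implementation. Practical reading: a small negative out-of-fold R from
these estimators is compatible with no effect; positive R well above the
null spread is required to claim signal.

## Clinical statistics

- Improvement rate = (pre − post)/pre × 100 %, undefined (NaN) at pre = 0;
  reported to two decimals.
- Paired pre/post tests are gated by Shapiro–Wilk on the differences at
  α = 0.05: non-rejection → paired t with mean ± SD summaries; otherwise
  (including constant differences) → Wilcoxon signed-rank with
  median (Q1, Q3) summaries.
- Correlations are Spearman's rank: rank-then-Pearson rho; p by full
  permutation enumeration for n ≤ 10 and the Student-t approximation above.
  Coordinate–outcome correlations join each hemisphere's active-contact
  coordinates to the per-patient improvement rates (each patient appears
  once per hemisphere; an averaged-coordinates mode is available);
  overlap–outcome correlations use VTA∩region volumes in mm³. No
  multiplicity correction is applied across the correlation families by
  default (a Benjamini–Hochberg flag exists), matching common reporting
  practice in this literature.

## Synthetic cohort generator

The generator is the package's test bed: it emulates the *structure* of a
DBS outcome-mapping study with a recoverable planted answer, not realistic
anatomy.

Geometry (world mm): mirrored ellipsoidal STNs at (±10, 0, 0) with
semi-axes (1.75, 1.75, 4) — ≈ 3.5 mm wide, 8 mm long — split into equal
thirds along the long axis: sensorimotor (dorsal), associative, limbic
(ventral). The long axis is vertical, a deliberate simplification of the
oblique dorsolateral→ventromedial axis; it makes lead geometry exact
(offsets translate contacts purely in Z) at the cost of anatomical tilt.
Cortical targets are plain boxes: "PFC-like" anterior/superior and
"SMC-like" posterior/superior. Default grid 64³ at 0.5 mm; ≥ 3 voxels per
subregion third are required (coarser grids raise).

Electrodes: vertical 4-contact leads (2 mm center spacing), contact 0 at
the inferior STN border plus a dorsoventral offset, in-plane jitter
≤ 0.5 mm. Per patient one targeting depth ~ Uniform[0, 10] mm is drawn and
shared by both hemispheres with an N(0, 0.75) per-side deviation —
bilateral targeting errors are treated as correlated, and the wide span
gives the cohort genuine contrast between ventral and dorsal stimulation
(including patients whose VTA misses the planted sphere entirely, which the
voxel test needs for spatial specificity). Active contact is contact 0;
amplitude ~ N(2.5, 0.31) V, frequency ~ N(128.6, 18.7) Hz, pulse width
~ N(64.3, 6.6) µs, clipped to plausible ranges.

Tractogram: one shared bundle set (a normative-connectome stand-in):
quadratic Bézier streamlines from limbic-STN voxel centers curving
anteriorly into the PFC-like box, and from sensorimotor-STN voxels
posteriorly into the SMC-like box; 200 fibers per bundle by default, 24
points each. Bundle membership is recorded in the ground truth.

Outcomes: Δ_i = w_v·overlap_i + Σ_b w_b·cf_ib + ε_i, with overlap_i the
fraction of a planted sweet sphere (radius 2.5 mm, centered 2 mm above the
ventral border of the left STN — "ventrocentral left") covered by patient
i's VTA union, cf_ib the fraction of bundle b's fibers connected to the
VTA, and ε ~ N(0, noise_sd). Both mood scales carry the planted change
with independent noise draws; baselines are Uniform (anxiety 5–15,
depression 6–14); post = max(pre − Δ, 0), so very large effects can be
floor-clipped, as real bounded scales are. Motor score, quality-of-life and
medication dose get generic plausible improvements so cohort summaries look
sensible. Scenario weights: `ventral_effect` (w_v = 6 scale points, tract
weights 0, noise SD 1), `tract_only` (w_v = 0, PFC +4, SMC −4, noise SD
0.5), `null` (all zero, noise SD 1); `noise_sd` is overridable, and the
recovery analyses are run at low noise (0.1–0.5). Regeneration from
(n, scenario, seed) is bit-identical.

What the generator does not emulate — and hence what passing tests do not
show about real data: anatomical STN shape and obliquity, normalization
error, heterogeneous/anisotropic tissue, realistic tractography (crossing,
curving, whole-brain fiber counts), integer psychometric scores and their
item structure, comorbidity-driven outcome heterogeneity, and any
correlation between stimulation parameters and targeting quality.

## Numerical and scale choices

- Problem sizes: 56 patients (two electrodes each), 64³ grid at 0.5 mm,
  400 fibers, 200 null cohorts for the FDR check and 100 replicates for the
  null-CV check — sizes at which the full suite runs in minutes while every
  statistic is still computed exactly as defined.
- Exactness boundaries: signed-rank exact for n ≤ 25 (ties included),
  Spearman permutation-exact for n ≤ 10; both switch to standard
  approximations above.
- Ties in |T| selection and coverage patterns are resolved by id order, so
  every analysis is deterministic given its inputs.
- Degenerate inputs are flagged rather than raised wherever the analysis
  can continue (NaN fiber scores, degenerate correlations, fallback
  predictions); hard errors are reserved for structural problems (grid
  mismatches, invalid fractions, cohorts below n = 8).

## Other limitations

Only voltage-controlled monopolar stimulation and 4-contact leads;
no directional electrodes; no covariate adjustment or cluster-level
inference in the voxel statistics; the atlas legend must follow the
`STN_<hemi>_<subregion>` naming convention; the shared-tractogram design
means fiber results inherit every bias of a normative connectome.
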