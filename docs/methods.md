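# Methods

This note documents the models and numerical choices behind `morphorsa`:
what the pipeline computes, what the synthetic cohort generator does and
does not emulate, and where the design was genuinely open.

## Data model

The study design the package targets is: 30 stimuli, 6 in each of five
classes (BC, DC, OSN, SC, I); 16 participants performing two
multi-arrangement sessions on a 60 × 60 cm workbench with a rating task in
between; 8 rating dimensions probed once per stimulus, so 240 ratings per
participant. Six dimensions are continuous sliders in [0, 1]; two ("main
body parts", "number of limbs") are small non-negative integer counts.

Arrangements enter the analyses only through their pairwise distances:
every arrangement RDM is the matrix of Euclidean distances divided by the
largest pairwise distance, which makes all statistics invariant to where
and in what orientation a participant happened to work on the bench
(rotation, translation, reflection, and — through the max-normalization —
global scale). Rating RDMs are max-normalized absolute differences, the
same convention, so that regression coefficients across dimensions are
comparable.

## Agreement statistics

All agreement measures are Pearson correlations of strict upper triangles
(435 entries for 30 stimuli, 276 for the 24 labelled ones). The grand mean
RDM used in the between-participant agreement B_p *includes* the focal
participant — the defining formula is followed literally — which makes B_p
an optimistic consensus measure; the leave-one-out variant is exposed
separately as the lower noise-ceiling bound, the self-inclusive mean of
B_p as the upper bound. Degenerate inputs (zero-variance triangles) yield
a flagged NaN plus a `DegenerateInputWarning`, never a silent 0, so
simulation bugs that produce constant RDMs surface immediately.

The session comparison is a paired two-tailed t-test on the per-participant
single-session agreements, on the raw correlations (no Fisher-z transform)
so that the reported degrees of freedom are n − 1 = 15 for the default
cohort. Identical session vectors are reported as t = 0, p = 1 rather than
the NaN a generic implementation produces for zero-variance differences.
Group-mean confidence intervals use a percentile bootstrap (10,000
resamples of participants with replacement, 2.5/97.5 percentiles, seeded).

## Cell-class models

The simple class model is binary — same class 0, different class 1 — and is
evaluated on the 24 stimuli with a confirmed class, because the
indeterminate cells may belong to any class. The complex model grades the
between-class distances under three ordinal constraints motivated by the
biology (dividing cells are basal cells in mitosis, so BC is nearest DC;
dividing cells more often become supporting cells, so DC is nearer SC than
OSN; indeterminate cells are mostly immature sensory neurons, so I is
nearest OSN). The default table is same-class 0, BC–DC 0.5, DC–SC 0.75,
I–OSN 0.5, all other pairs 1.0; any table satisfying the constraints can be
supplied, and the constraints are asserted programmatically at
construction.

## Procrustes alignment

Arrangements are aligned rigidly: translation plus an orthogonal transform
(rotation or reflection), *without* rescaling, minimizing the summed
squared distance to the reference; the optimal orthogonal map is obtained
from the SVD of the cross-covariance. With no explicit reference a
generalized alignment iterates a mean shape: initialize at the first
configuration (centred), align all configurations to the mean, recompute
the mean, and stop when it moves less than 1e-10 in Frobenius norm (cap
100 iterations). Alignment affects only visualization and the averaged
coordinate features fed to the classifier — RDMs are alignment-invariant by
construction, so the agreement statistics do not depend on it.

## Rating regression and PCA

The cross-task model regresses the eight per-dimension rating RDMs of one
participant onto the cohort-average arrangement RDM by ordinary least
squares on upper triangles (8 coefficients + intercept, 435 observations).
It is fitted per participant and the per-participant fitted correlations
averaged for reporting; a pooled fit is available by passing concatenated
data. OLS rather than non-negative least squares is used deliberately: the
model is purely descriptive and sign constraints would hide anti-correlated
dimensions. Rank-deficient predictor sets are flagged and solved by the
minimum-norm solution. Transfer across cohorts applies the frozen
coefficients to a second cohort's rating RDMs with no refitting.

PCA operates on the cohort-mean 30 × 8 rating matrix. The two count
dimensions are first min–max rescaled to [0, 1] using the observed bounds
of the cohort-mean column (so a "number of limbs" column spanning 0..6 maps
onto the same range as the sliders); all columns are then centred and the
covariance matrix eigendecomposed. No variance standardization is applied
beyond that — the shared [0, 1] scale is the point. Components are sorted
by decreasing variance and each component's sign is fixed by making its
largest-magnitude loading positive, for determinism across platforms.
Per-participant data are projected into the *fitted* space (same scaling
bounds, same column means, same loadings) for the PCA-RDM regression onto
the class model. Ratings are used raw, not z-scored per participant; a
cohort whose participants use wildly different slider ranges would need
that extra step upstream.

## Classification

The classifier is a linear soft-margin SVM, C = 1, in a one-vs-rest
decomposition (liblinear; squared-hinge loss, primal solver — exactly
deterministic for fixed data). Features are standardized per fold on the
20-cell training split only, to avoid leakage; a constant feature's SD is
replaced by 1. Cross-validation enumerates all 6⁴ = 1296 ways of holding
out one exemplar per known class, so each labelled stimulus is tested in
exactly 6³ = 216 folds and the confusion matrix accumulates 5184 counts.
Every fold also predicts the six indeterminate cells; across folds this
yields a vote distribution per cell whose modal class (ties broken toward
the canonical order BC, DC, OSN, SC) summarizes what the cell most
resembles. "Best-achievable" accuracy is the resubstitution accuracy of
the same classifier trained and evaluated on all 24 labelled cells — an
optimistic ceiling used as a reference line, explicitly a stand-in and not
an estimate of attainable out-of-sample accuracy. Chance is 0.25 for the
balanced four-class problem, and a permutation helper re-runs the full CV
under label shuffling to calibrate it.

## The synthetic cohort generator

The generator produces data with the statistical structure the analyses
assume, not a behavioural model of how people actually place objects:

1. **Latent shape space.** Each stimulus is a point in an 8-D latent space.
   The four known class centroids sit at the corners of a square of side
   `class_separation` lying in a 2D plane of that space. The plane is
   rotated into all eight dimensions by a seeded random orthogonal matrix,
   so every rating dimension carries some class signal. A square — rather
   than a full simplex of equidistant centroids — is used because the
   arrangement task is inherently planar: four equidistant centroids cannot
   be embedded in 2D without distorting the between-class distances, which
   would cap the attainable class agreement for reasons that have nothing
   to do with noise. The square's cycle is BC → DC → SC → OSN, placing BC
   adjacent to DC and DC nearer SC than OSN, echoing the biological
   ordering. The I centroid lies on the OSN→SC segment at 0.35 of the way
   from OSN. Class members scatter around their centroid with isotropic SD
   `within_class_sd`.

2. **Arrangements.** The latent pairwise distances are embedded into 2D by
   classical (Torgerson) metric MDS; participant-level jitter (drawn once
   per participant, shared across their sessions — stable idiosyncrasies)
   and session-level jitter are added; a random rigid transform (uniform
   rotation, translation, reflection with probability 0.5) places the
   configuration, which is then isotropically rescaled into the workbench
   square with a 5% margin. Reflections are applied half the time
   deliberately, to stress the reflection-permitting Procrustes step.

3. **Ratings.** Dimension d is a monotone min–max readout of latent
   feature d onto [0, 1] (bounds from the noise-free column), with
   participant noise added in latent space before the readout and the
   result clipped; count dimensions are then quantized ("main body parts"
   to 0..4, "number of limbs" to 0..8).

All randomness derives from one seed through fixed per-(purpose,
participant, session) substreams, so any slice of a cohort can be
regenerated in isolation, bit-identically.

**Defaults.** `class_separation=5.0`, `within_class_sd=1.25`,
`participant_noise_sd=1.0`, `session_noise_sd=1.0` (all in latent units),
chosen once to land the default cohort in the qualitative regime of real
naive-observer data: near-ceiling within-participant agreement (~0.93),
clearly lower between-participant agreement (~0.8), weak-to-moderate class
agreement (~0.4–0.6), and above-chance but imperfect classification with
the characteristic DC/SC confusions. The generator does *not* emulate:
sequential placement strategies, slider anchoring effects, attention
lapses, or any image-computable shape features. Passing tests therefore
demonstrate that the *analysis machinery* is correct and well calibrated,
not that these effect sizes will be observed in a real cohort.

## Problem sizes and numerical choices

The validation suite runs everything at the study's native scale (16 × 2 ×
30 cohorts, 1296-fold CV); the heavier calibrations use 100 simulated
cohorts for the null class-agreement distribution and 100 label
permutations for the classifier null, sizes at which the Monte-Carlo error
of the checked means is comfortably below the asserted bounds. Oracle
comparisons use tolerance 1e-9 (closed-form identities), RDM rigid
invariance 1e-9, serialization round trips 1e-12. Generalized Procrustes
convergence: 1e-10, cap 100 iterations. Degenerate cases are errors or
flagged NaNs as described above; an RDM whose points all coincide is an
error (`DegenerateInputError`), not an all-zero matrix.

## Known limitations

* The rating-noise model shares `participant_noise_sd` with the
  arrangement pathway; rating and placement reliability cannot be varied
  independently except through `session_noise_sd`.
* The complex class model's numeric table is one admissible choice under
  the ordinal constraints; conclusions based on its exact CC value should
  be checked against other admissible tables.
* B_p with two participants whose RDMs are exact complements is undefined
  (the grand mean is constant); the package flags rather than resolves
  this.
* The classifier comparison between arrangement- and rating-derived
  features depends on the number of PCA components retained; with all 8
  components the SVM can overfit idiosyncratic stimulus scatter on a
  20-sample training split, so the 2-component variant is the more robust
  summary of class separability in the rating data.
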