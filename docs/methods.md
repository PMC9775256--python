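# Methods

`morphorec` quantifies how well multiple linear regression (the "RM"
method) reconstructs missing 3D landmarks on a damaged bone, using the
human zygomatic as the motivating system: 30 landmarks per specimen, of
which 1–7 are fixed anatomical points and 8–30 are surface
semilandmarks.  This note records the models, the numerical choices, and
what the synthetic experiments do and do not demonstrate.

## Shape-space machinery

**GPA.** All configurations are centered, scaled to unit centroid size,
and iteratively rotated onto a running consensus (initialized as the
first specimen after normalization; with the default tolerance 1e-10 and
max 100 iterations the initialization is irrelevant).  Convergence is
declared when the consensus moves by less than the tolerance in
root-sum-of-squares.  Rotations are constrained to determinant +1;
mirror-image (antimere) specimens must be reflected explicitly at the
I/O stage, because silently allowing reflections inside the alignment
would hide a digitization or curation problem.

**Distance.** All reported distances are *partial* Procrustes distances:
both configurations at unit centroid size, optimally rotated, residual
root-sum-of-squares.  This is the chordal metric on shape space (it
satisfies the triangle inequality, which the test suite verifies
empirically) and matches what mainstream morphometrics packages report.
Study distances are computed pairwise, independently of any common
alignment; a `common_space` mode exists for diagnostics of already
aligned samples.  Whether the original analyses used pairwise or
common-space distances is not documented in the source material; the
pairwise choice is recorded here as ours.

**Sliding.** Surface semilandmarks are slid to minimize thin-plate-spline
bending energy relative to the consensus, using the 3D kernel U(r) = r.
The bending-energy matrix is the upper k×k block of the inverted
bordered TPS system; its sign is fixed so the quadratic form is PSD
(verified by eigenvalue check; affine fields span its null space).
Because the package ingests landmark clouds rather than meshes, tangent
planes are estimated per semilandmark by total-least-squares plane fits
to the 8 nearest landmarks (falling back to a doubled neighborhood when
degenerate), and sliding is tangent-plane only, with no re-projection
onto a surface — a documented deviation from mesh-based workflows.  Each
sliding iteration solves, per specimen, the exactly-minimizing tangent
offsets t = −(UᵀB̃U)⁻¹UᵀB̃y (ridge 1e-10 only if singular, with a
warning), then re-runs GPA.  Fixed landmarks are never displaced by the
slide step itself; the closing GPA applies only common similarity
transforms.  Because the consensus — and with it the energy form — is
recomputed between iterations, monotonicity of total energy is not
automatic; a safeguard reverts and stops if an iteration would raise it,
so the recorded energy trace is non-increasing by construction.  Default:
3 iterations, early stop at relative energy change below 1e-6.

## The RM model

The regression is trained on the GPA-aligned, slid reference sample: the
flattened coordinates of the missing landmarks are regressed by ordinary
least squares (with intercept) on the flattened coordinates of all
present landmarks, one multivariate fit for all missing coordinates
jointly.  A damaged specimen is completed by (1) superimposing its
present landmarks onto the matching subset of the reference consensus
with a full similarity fit — the specimen's size is nuisance — (2)
feeding the aligned present coordinates to the regression, (3) inserting
the predictions.  The returned transform lets the completion be mapped
back to original specimen space.  Predictions are the endpoint; no
re-sliding is applied to imputed semilandmarks.

**Predictor reduction.** Procrustes alignment concentrates all shape
variation in the tangent space of the consensus: the linearized
centering, rotation and scale constraints leave the predictor block
nearly rank-deficient (when exactly two landmarks are missing, one
dependency is exact — eliminating the six missing coordinates from the
six alignment constraints leaves one relation, because the skew matrix
of the difference of two consensus landmarks is singular).  Sliding
further removes tangent-plane noise at every semilandmark.  OLS
coefficients along such near-null directions are arbitrarily large, and
a damaged specimen — aligned on its present subset only — does not obey
the full-configuration constraints, so those coefficients convert a
small alignment discrepancy into a large prediction error (measured ~3×
inflation of mean reconstruction error on the default synthetic sample).
The model therefore reduces predictors to principal-component scores,
retaining min(n−2, numerical rank, components explaining 99% of
predictor variance), whenever the design is wide (3·k_present+1 ≥ n) or
its condition number exceeds 100.  Well-conditioned designs are fitted
by plain OLS, and ridge regularization is never used, keeping the method
a linear regression throughout.  A reference sample with (numerically)
zero variance yields an intercept-only model, i.e. regression through
the mean.  The reduction applied is recorded on the fitted results as
`predictor_reduction`.

The documented floor on the reference sample is n ≥ 10.

## The damage-simulation study

Damage cases name 1-based landmark sets to delete; the defaults are
Case 1 = {1, 2} (incomplete temporal process), Case 2 = {4, 5, 7}
(damaged orbit), Case 3 = {16–21} (incomplete zygomatic body).  For each
of 30 seeded targets per case, the remaining specimens are re-aligned
and re-slid from scratch (strict leave-one-out — the target never
touches its own reference consensus or regression, which a poisoning
test verifies), the model is fitted, the target's *raw* configuration is
damaged and imputed, and two distances are recorded: d(true, predicted)
and d(true, reference consensus).  The second is the accuracy of using
the mean shape as a reconstruction template, the baseline RM must beat.
Missingness is applied to raw coordinates (realistic damage), with
alignment happening inside the imputation via the present subset.

Per-case seeds derive from the master seed via
`numpy.random.SeedSequence(seed).spawn`, so each case is independently
reproducible; `shared_targets` forces one common target sample.  Targets
are sampled independently per case by default since the original design
does not state whether they were shared.

Statistics: per case, a two-sample t-test (Welch by default — the
original analysis does not state the variant; pooled is available, and
the paired version of the same comparison is emitted as a supplementary
column since the two distances are in fact paired per target); across
cases, one-way ANOVA on d(true, predicted) with df (g−1, N−g) and Tukey
HSD (Tukey–Kramer for unbalanced groups), with the studentized-range
distribution evaluated by `scipy.stats.studentized_range`.  All of these
are implemented as explicit formulas so every number in a report can be
recomputed from the exported records CSV; the test suite checks that
round trip to 1e-12 and checks the formulas against independent
implementations.

Outlier screening computes each specimen's distance to the consensus and
flags those above Q3 + 1.5·IQR; review is a human step and nothing is
excluded automatically.

## The synthetic generator

The generator exists so that every downstream stage is testable without
any external data.  It emulates, per specimen of population p:

    shape = mean + offset_p + L (s ∘ z) + ε,   then similarity nuisance

with a deterministic 30-point template on a smooth curved patch (50 mm
across, 12 mm dome height; fixed landmarks at suture corners, the
{1,2}, {4,5,7} and {16–21} index blocks spatially clustered to mirror
the damage cases), unit-norm factor loadings L, iid digitization noise
ε, and optional per-specimen uniform rotation, translation, and
lognormal scale exp(N(0, 0.05²)).

Default covariance (scales relative to template centroid size CS ≈ 89.6
in template units; noise σ = 0.5% CS per coordinate):

* six **global modes** — leading eigenvectors of the kernel
  exp(−d²/ℓ²) on the template with ℓ = 0.3 × template diameter,
  assigned cyclically to the x/y/z axes, with geometrically declining
  sds 5.5% CS × 0.75^j.  These give nearby landmarks correlated
  displacements, i.e. the redundancy the regression exploits, and set
  the inter-individual distance scale (mean d to consensus ≈ 0.06).
* three **process-tip modes** displacing landmarks {1, 2} rigidly along
  each axis, sd 1.0 σ, emulating population-variable projection of the
  temporal process.
* three **body modes** displacing landmarks {16–21} rigidly along each
  axis, sd 3.0 σ, emulating the variable muscle-attachment surface of
  the zygomatic body.

The local modes are what make reconstruction error depend on damage
*location*, not just landmark count.  The sds follow a variance
calculus fixed at design time: with global factors recoverable from any
large present subset, the unexplained variance at the missing landmarks
is 3·k_miss·σ² (noise) plus the local-mode variance of any fully
deleted region.  Case 1 then carries 6σ² + 3σ² = 9σ², matching Case 2's
9σ² (no local modes in the orbit) — so the 2- and 3-landmark cases are
comparable, as in the regime the study design targets — while Case 3
carries 18σ² + 27σ² = 45σ², which separates it sharply.  Population
offsets (norm ≈ 2% CS, along the two leading global modes; validated to
stay below 20% of CS) make the mixed sample mildly heterogeneous
without dominating.  The default sample composition is 119 Italian + 20
African-American + 11 Spanish = 150 specimens, so the subsample analysis
can restrict to the 119-specimen Italian group.

**What passing tests show — and don't.**  The generator produces
Gaussian, low-rank, stationary variation on a single smooth patch.  Real
cranial samples have non-Gaussian variation, sexual dimorphism,
measurement error that correlates along digitization order, curved
sutures, and meshes on which slid semilandmarks should be re-projected.
Passing the synthetic study demonstrates that the pipeline's machinery
is correct and that the qualitative conclusions (regression beats the
mean-shape template; error grows with contiguous damage extent; a
homogeneous subsample behaves like the full sample) hold under the
assumed covariance structure — not that the same effect sizes would be
observed on any particular osteological collection.

## Problem sizes and determinism

The default study (150 specimens, 3 cases × 30 strict leave-one-out
targets, GPA tolerance 1e-8 inside the study loop, 3 sliding
iterations) runs in well under a minute on one CPU; the replicate
analysis in the test suite repeats it ten times.  Every random choice —
generator draws, nuisance transforms, target sampling — flows from
explicit integer seeds, and equal seeds reproduce results bit-for-bit.

## Known limitations

* Tangent-plane sliding without surface re-projection can move
  semilandmarks slightly off any true surface; with the default small
  slides this is second-order, but large slides on strongly curved
  regions would need meshes.
* The imputation aligns the damaged specimen on present landmarks only;
  with very few or nearly collinear present landmarks the
  superimposition (and hence the completion) degrades, and the code
  refuses outright below 3 non-collinear present landmarks.
* Welch vs pooled t, pairwise vs common-space distances, and
  shared vs per-case target samples are configuration choices, not
  facts recovered from the original analysis environment.
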