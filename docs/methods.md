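# Methods

## Coordinate frame and sign conventions

All landmarks live in a right-knee frontal-plane frame in millimetres:
x increases medially, y superiorly.  Angles are degrees everywhere.  The
hip–knee–ankle angle is defined as minus the counter-clockwise angle from
the distally-pointing femoral mechanical axis to the distally-pointing
tibial shaft axis, so varus (tibia adducted, talus medial to the knee) is
negative — matching the epidemiological convention in which male cohorts,
more varus on average, have more negative HKA means.  One constant
(`kneessm.conventions.ALIGNMENT_SIGN`) defines this; the generator, the
alignment module and the tests all share it.

## The 129-point template

The knee outline is an idealised but anatomically plausible 129-point
polyline: distal femur (55 points, with the distolateral corner at index 17,
the intercondylar notch apex at 30), proximal tibia (40 points, plateau
centre at 76), fibular head (14) and superior patella (20).  The medial
femoral condyle is flat at y = 0 for x ≤ 22.5 mm and the medial tibial
plateau flat at y = −5 mm on the same x grid, so the template's medial
minimum joint-space width is exactly 5.0 mm — a convenient exact fixture for
the grading geometry.  Osteophyte sites are short runs of outline points at
the four joint margins; the two medial-compartment indices they can displace
(41, 42, 64) are excluded from the mJSW search.

## Shape model

Generalized Procrustes alignment centres every configuration, scales it to
unit centroid size and iteratively rotates it to the evolving mean
(reflections are impossible by construction of the 2-D rotation estimate);
the mean is re-normalised each iteration and iteration stops when its RMS
change is below 1e-10 (max 100 iterations, failure raises with the last
residual).  Two post-processing steps make downstream contracts exact:

* the output frame is **canonicalised** from the consensus geometry alone
  (major principal axis along +y, sign fixed by the largest-|value| mean
  coordinate), so GPA is idempotent and invariant to arbitrary similarity
  transforms of any input;
* each aligned shape is **tangent-projected** (rescaled so its dot product
  with the consensus is 1).  Residuals are then exactly orthogonal to the
  rotation and scale directions, which makes `reconstruct -> score` round
  trips exact to machine precision rather than merely first-order accurate.

PCA of the tangent-projected coordinates (SVD; min(n−1, 258) modes;
deterministic sign: largest-|loading| coordinate positive) gives orthonormal
modes, per-mode variances and unstandardised SDs.  A mode score divides the
projection by the training SD, so scores are in SD units with training
columns mean-0/SD-1 by construction.  Whether the original size
normalisation used centroid size is not knowable from the outline data
alone; centroid size is the standard choice and is recorded here as an
assumption.

## rKOA grading

Site osteophyte grades count the area cut-offs at or below the measured
area, capped at 3.  The cut-offs (defaults 1, 3, 6 mm² per site) and the
score→grade bins (0 → 0, (0,1] → 1, (1,2.5] → 2, (2.5,4.5] → 3, >4.5 → 4)
are **configuration values, not published constants**: the grading scheme
this reimplements published its thresholds separately, so the defaults are
labelled assumptions and every consumer can override them.  JSN thresholds
are inclusive on the lower bound of each grade's interval (3.0 mm → grade
0).  Scores are held as doubled integers internally, so the 0.5 weighting
never touches floating-point equality.

## Alignment angles

The femoral head centre comes from an algebraic (Kåsa) least-squares circle
fit — linear in the parameters, exact for noise-free rings, and within 1e-6
of a grid-search minimiser of the same loss at the 7-point/0.5 mm-noise
scale, so a geometric refinement would add nothing here.  The anatomical
femoral axis is the first principal axis of the shaft points, oriented
distally.  Non-finite inputs or angles at or beyond ±45° produce a flagged
NaN rather than an exception, mirroring how failed automatic searches are
handled in practice.

## Association analysis

Each (KSM, grade contrast, covariate model, stratum) cell is a separate
binary maximum-likelihood logistic fit (statsmodels) restricted to grade 0
plus the contrast grade; grades 3 and 4 are merged into one "3–4" band
before modelling.  ORs are per SD by the scoring contract; CIs and p-values
are Wald (the symmetric default on the log-OR scale).  Ethnicity enters as
indicators against the largest category; within a fit subset, levels with
fewer than 10 observations are collapsed into the reference so the adjusted
models stay estimable at simulation sample sizes.  Rows missing HKA are kept
for Models 1–2 and dropped from Model 3 only; attrition counts are attached
to the frame and the manifest.  Separation or non-convergence flags the row
(NaN estimates) and never aborts the sweep.  Sex-by-KSM interactions add a
product term to the adjusted combined-sex models; the reported p-value is
the Wald p of that term.  No small-sample (Firth-type) correction is
applied: synthetic sample sizes are controllable, and flagged rows are
visible.  The confidence level is 95% throughout.

## Composite shapes

`mean + scale · Σₖ βₖ · sdₖ · modeₖ` over the first 10 modes with the
arbitrary visual scale defaulting to 5.  All ten coefficients enter
regardless of significance.  Demographics-adjusted (Model 2) and
HKA-adjusted (Model 3) coefficient sets are both supported; overlays
translate the composite so point 17 coincides with the reference — no
re-rotation, so varus differences stay visible.  Flagged (NaN) coefficients
contribute no displacement in pipeline rendering.

## Synthetic cohort generator

The generator defines the study conditions for every test.  Defaults:

| parameter | default | basis |
|---|---|---|
| age | N(63.72, 7.53²) yr | cohort marginals |
| sex | 48% male | cohort marginals |
| height, weight | sex-specific normals (163.59/6.45, 177.29/6.61 cm; 67.89/12.78, 83.02/13.27 kg) | cohort marginals |
| ethnicity | 7 categories, 96.8% largest | cohort marginals |
| latent varus | N(+1.51, sd) male, N(−0.21, sd) female, sd 2.0° | means chosen so HKA = −varus reproduces the cohort's sex-specific HKA means; the SD is an assumption consistent with the published HKA range |
| anatomic offset | 5.5° | FTA − HKA difference implied by the cohort's FTA/HKA means |
| jsn_varus_coupling | 0.18 mm/° | calibrated once (with the osteophyte hazard) so the realised grade distribution approximates the published 80.7/14.6/3.6/1.2% split, then frozen |
| osteophyte hazard | 0.045/site, ×e^0.25·varus⁺ medial, Gamma(1.1, 1.3) areas | same calibration |
| landmark noise | 0.25 mm iid | assumption: sub-pixel placement error |
| hka_noise_deg | 0 | optional independent angular error of the total-body derivation |

Deformation chain: planted smooth modes → tibia+fibula rotation by the
latent varus about the knee centre (midpoint of notch and plateau centre) →
tapered medial-plateau lift (`coupling · max(0, varus)`) → osteophyte
protrusion (parallel outward displacement sized so the shoelace area between
displaced and original outline equals the drawn area exactly) → iid jitter.
The nine planted fields are fixed low-frequency Fourier fields,
orthonormalised after projecting out the template's translation/rotation/
scale directions, with strictly decreasing SDs (0.9·0.85ᵏ mm), so PCA
recovers them in order and their latent coefficients are recorded in the
truth table.  Geometry whose medial joint surfaces interpenetrate is
regenerated with fresh randomness up to 10 times, then errors loudly.

Outcomes come in two regimes.  The **naturalistic** default draws osteophyte
presence/size from the varus-linked hazard and lets the grading module
determine the grade from the generated geometry.  When `mode_effects` (or
`hka_effect`) is set, the **embedded-effect** regime draws the grade from a
baseline-category logit on the standardized latent mode scores (intercepts
anchored to the cohort grade marginals; mode index 1 is the varus rotation)
plus optionally the measured HKA, then constructs osteophyte areas that make
the grading module reproduce exactly the drawn grade.  Conditional on a
{0, g} pair this is exactly the logistic model the association module fits,
so per-SD log-OR recovery is well-posed.  Two caveats are deliberate: an
active `jsn_varus_coupling` can add geometric JSN on top of the drawn grade
(embedded-effect simulations therefore set it to 0), and drawing osteophyte
protrusions into the outline leaks outcome information into the scored
shape.  The `osteophytes_in_outline=False` switch removes that leak,
mirroring annotation protocols that mark bone shape excluding osteophytes;
clean recovery experiments use it.

### What the generator does and does not emulate

It emulates the *structure* of the data (landmark sets, covariates, areas,
paired total-body geometry) and first-order epidemiological features (varus
dominance, varus–JSN coupling, grade marginals, sex differences in
alignment).  It does not emulate image-level noise correlations between
neighbouring landmarks, osteophyte shape detail, population substructure
beyond sex, or any longitudinal process.  Passing recovery tests therefore
demonstrates correctness of the *pipeline* under a known generative model —
not that real-cohort effect estimates would be reproduced.

## Simulation design and problem sizes

Monte-Carlo checks use fixed seeds and sizes chosen to keep their binomial
error well inside the asserted bands: type-I error over 1000 (unit suite) or
400 (acceptance suite) replicates at n = 2000; Wald coverage over 2000
replicates at n = 5000 (asserting the 94–96% band) and 400 replicates at
n = 2000; full-pipeline OR recovery over 200 cohorts of n = 500; HKA
mediation/attenuation over 30 cohorts of n = 1000.  The mediation experiment
gives both measures realistic independent error (landmark noise 1.0 mm, HKA
placement error 1.0°) — with error-free measures KSM1 and HKA are collinear
beyond anything seen in practice and the Model-3 fit is unstable rather
than informative.

## Known limitations

* The osteophyte area cut-offs and score→grade bins are assumptions
  (configurable); absolute grade distributions shift if they change.
* mJSW is a minimum over a finite point set; with landmark jitter it is
  biased slightly downward (extreme-value effect).  The truth table records
  the pre-noise value.
* The 2-D similarity alignment discards size; analyses of allometry would
  need the centroid sizes, which are not retained.
* Embedded-effect cohorts realise the drawn grade exactly only when the
  geometric JSN channel is quiet; the combination of both channels is
  naturalistic but no longer exactly logistic.
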