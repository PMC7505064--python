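# Methods

This note documents the models, the synthetic-data generators and the
numerical choices behind `bearcondition`.

## Allometric body condition index

Body mass and length are modelled on the natural-log scale,
ln W = b ln L + a + ε with ε ~ N(0, σ²), fitted by ordinary least squares
(statsmodels). σ is the residual standard deviation with n − 2 denominator
(the root of `mse_resid`). BCI is the *raw residual divided by σ* — not an
externally studentized residual — because that is the form practitioners
apply in the field with the frozen reference coefficients
(3.04, −10.41, 0.19 for the Shiretoko sample; available as
`SHIRETOKO_REFERENCE_MODEL`). Consequences tested in the suite:

* in-sample BCI has mean exactly 0 and SD √((n−2)/n) ≈ 0.998 at n = 476
  (within 2 % of 1 for n ≥ 100);
* BCI is exactly orthogonal to ln L in the fitted sample, so its
  correlation with raw body length is near zero (the small nonzero value
  comes only from the curvature of the log transform) — matching the
  "condition is independent of body size" design requirement;
* BCI is strictly increasing in mass and decreasing in length.

Fits require ≥ 3 records with positive mass and length and non-constant
length; BCI evaluation rejects nonpositive inputs.

## von Bertalanffy growth

A(t) = A∞(1 − e^(−K(t−T))), fitted by Levenberg–Marquardt nonlinear least
squares (`scipy.optimize.curve_fit`, xtol/ftol 1e−12) with standard errors
from the Jacobian-based covariance. Default initialization is
A∞ = max observed length, K = 0.3/y, T = −1 y, which converges on monotone
growth data of this shape; an explicit start can be supplied. At least four
distinct ages are required. The closed-form inverse
t(p) = T − ln(1 − p)/K is used for the age at a fraction p of asymptotic
length; predictions below T are a domain error (negative size).

Sexes are compared with a nested extra-sum-of-squares F test: reduced =
one pooled 3-parameter curve, full = one curve per sex (6 parameters),
F = ((RSS_r − RSS_f)/3)/(RSS_f/(n−6)) on (3, n−6) df. This construction
reproduces the df bookkeeping of the published comparison (3, 426 at
n = 432). Tiny negative numerators from optimizer noise are clamped to 0.

## Photograph filtering and posture categories

Nine attributes are scored 1/2/3; any 3 rejects the photograph. Posture
categories: Good (all attributes 1), BS / NF / NB (a 2 on exactly one of
body straightness, neck flexing, neck lateral bending, all else 1), and
unusable otherwise (including body-arch 2s and multiple 2s). The strict
reading — a photography attribute scored 2 also blocks category
assignment — is the default; `strict_photography=False` keys categories on
the posture attributes only. Method eligibility encodes which categories'
ratio means are statistically indistinguishable from Good: nose-inclusive
lengths (HBL, EBL) tolerate only Good, PBL additionally NF, and HTL
additionally NF and NB — which is why TH:HTL is the adopted indicator.

## Landmark geometry

Image convention: origin top-left, y downward, angles counterclockwise
positive on screen. Ground alignment rotates all coordinates about the
origin by −ground_angle (an isometry; |angle| < 45° enforced). After
alignment, "horizontal" lengths are absolute x-differences (projections
onto the ground): HBL and HTL; EBL is the Euclidean nose–tail distance;
PBL = HTL + Euclidean(shoulder→ear) + Euclidean(ear→nose); TH is the
absolute y-difference between the lowest abdomen point and the highest
waist point, regardless of their x offset. EBL ≥ HBL and PBL ≥ HTL hold by
construction and are enforced as container invariants. Fur exclusion is
the annotator's responsibility: the geometry trusts the coordinates given.
Missing landmarks drop only the measures that need them.

Replicate tracings of one photograph are combined as the *ratio of means*
(mean TH over mean length), not the mean of per-replicate ratios; with ≥ 3
replicates the measurement SE of the ratio stays below 0.0025, i.e. cannot
move the second decimal place.

## Precision framework and tests

CV = 100·SD/mean with the n−1 sample SD. The SD of a long (50-tracing)
replicate series is treated as the population SD, giving SE(n) = SD/√n and
the minimum replicate rule n_min = smallest n with SD/√n strictly below
0.0025 (`SE_THRESHOLD`).

CV equality across k methods uses the Feltz–Miller asymptotic chi-square
statistic with weights nᵢ − 1 (implemented in-package; no installed
library provides it), normalized internally so percent and fraction inputs
give identical statistics. Its type-I error at nominal 5 % is verified by
simulation in the suite (2000 replicates, within ±2 %). Pearson
correlations use scipy with the two-sided t test. One-way ANOVA uses scipy
with Tukey–Kramer pairwise comparisons from statsmodels (valid for
unbalanced groups).

The two-way ANOVA (BCI ~ season × age-sex class) uses sequential (Type I)
sums of squares computed from rank-detecting least squares on successively
augmented design blocks (intercept, factor A, factor B, cell indicators).
Term df are rank increments, so an empty factor cell reduces the
interaction df exactly as R's `lm` does by dropping aliased coefficients:
on the 476-record 3 × 6 layout with its one empty cell (female cubs in
spring) the table reproduces df (2, 459), (5, 459) and (9, 459). The
implementation is cross-checked against `statsmodels.anova_lm(typ=1)` on
full-rank layouts. A term whose df collapses to zero raises.

## Condition pipeline

Calibration pairs use photographs of the captured bear within ±3 days of
capture that pass the filter and are TH:HTL-eligible; fewer than two
usable photographs raises a warning and the pair should be skipped. BCI is
regressed on the median photographic ratio (OLS); predictions outside the
calibrated ratio range are flagged as extrapolation.

Half-month evaluation: photographs are grouped by (year, month,
days 1–15 / 16–end), ranked by total attribute score (ties broken by photo
id; "best" is operationalized as lowest total score since no formal
definition exists), and the median ratio of the best ≥ 2 is the evaluation
value. The seasonal test is a one-way ANOVA over half-month levels with
yearly evaluation values as replicates — eight half-months over three
years give the (7, 16) df layout — with Tukey pairwise comparisons.

## Synthetic-data generators

All generators are pure functions of (spec, seed) built on
`numpy.random.default_rng`.

**Population** (`generate_population`). The season × age-sex composition
is the published 476-bear table, including its empty female-cub-spring
cell. Ages: cubs 0; subadults uniform over 1–4 (F) / 1–7 (M); adults
uniform from 5 (F) / 8 (M) to `adult_max_age` = 20 (a plausible upper age
for this population; no age distribution is published).
Lengths are the sex-specific growth curve at the drawn age plus Gaussian
noise (SD 8 cm, the residual scale of the growth fits), floored at 30 cm.
Masses are log-normal around the reference allometry, with the published
seasonal BCI means (−0.20 / −0.03 / +0.36) and season-pooled class means
(e.g. +0.65 for adult males) added to the ln-residual in σ units. Torso
height is attached to 23 randomly chosen adult females as
TH:BL = 0.45 + 0.018·(c·BCI + √(1−c²)·z) with coupling c = 0.81; the mean
level 0.45 is an anatomically plausible choice (only the correlation is
published). Optional duplicate records at strictly younger ages exercise
de-duplication.

**Replicate photo measurements** (`generate_replicate_measurements`). Per
photo, one standard-normal posture draw scales every method's ratio by its
published category CV (a shared draw keeps EBL ≥ HBL and PBL ≥ HTL, since
real method ratios co-move with posture); category means/SDs are the
published posture table; replicate tracings multiply each measure by
independent Gaussian noise at the published within-photo CVs (TH 0.29 %,
HBL 0.27 %, EBL 0.29 %, PBL 0.26 %, HTL 0.45 %), so the 50-replicate
TH:HTL ratio CV comes out near √(0.29² + 0.45²) ≈ 0.53 %.

**Landmarks** (`generate_landmarks`). Coordinates realizing a target
measurement set exactly: tail base anchored, nose placed from HBL/EBL, the
ear on the ellipse with foci shoulder/nose and segment-sum PBL − HTL
(infeasible targets raise), the torso column from TH; then rotation to the
requested ground angle and optional i.i.d. pixel jitter.

**Seasonal series and calibration studies.** The half-month trajectory
defaults to the published pattern (late-August minimum 0.567, early-October
maximum 0.714) with a yearly level effect (SD 0.015) and per-photo noise
(SD 0.018), three photographs per half-month over 2016–2018. Calibration
studies draw adult females with latent condition z ~ N(0,1), capture mass
realizing BCI = z, and a photographic ratio coupled to z at c = 0.77.

What the generators do *not* emulate: measurement-protocol drift between
observers, within-year growth (ages are integer years), non-Gaussian
posture effects, fur-boundary ambiguity, and any dependence of photo
availability on condition. Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes, not that the assumptions hold
for new field data.

## Problem sizes and determinism

The test suite and the acceptance script keep simulations at moderate
sizes chosen to estimate each quantity well: 30–60 replicate populations
of 476 records for the regression targets, 200 replicate 7-bear
calibration studies, 200 seeds for parameter-recovery bias, 2000
replicates for the CV-test size, and 40 seeds for the seasonal and
posture-pattern checks. Correlations from replicate small-n studies are
aggregated on the Fisher z scale (tanh of the mean atanh r), since the
plain mean of sample correlations is noticeably attenuated at n = 7. All
randomness flows from explicit seeds; the acceptance script derives
per-replicate child seeds from its `--seed` via `numpy.random.SeedSequence`.

## Known limitations

* The reject/categorize rules are deterministic encodings of a human
  scoring protocol; inter-observer variability is out of scope.
* The calibration is fitted on few bears (seven in the reference study);
  prediction intervals are not provided, only an extrapolation flag.
* The Feltz–Miller test is asymptotic and can be mis-sized for very small
  replicate groups (n ≲ 10).
* `min_measurements` treats the long-series SD as the population SD; with
  short series the rule understates the needed replicates.
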