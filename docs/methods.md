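# Methods

This note documents the models, default parameters and design choices
behind `diabkit`, in the order the pipeline runs: photo geometry, nutrient
accounting, weight regression, cohort labelling, the stacked classifier,
and attribution — together with what the two synthetic-data generators do
and do not emulate.

## Photo geometry

The measurement scenario is a phone leaning against a table at tilt
`alpha` (gyroscope, radians), photographing food on the table. In the
vertical plane through the phone, the phone–table contact point is the
origin, x runs along the table, y is vertical. With `p` the
bottom-of-phone-to-camera length (metres) and `beta` the phone-model
constant field-offset angle, the camera sits at `A = (p cos a, p sin a)`
and the near field-of-view boundary ray meets the table at
`l_OB = p sin b / sin(a + b)`.

The mapping from an in-image food position `k = a/b` (fraction of image
height, 0 at the bottom edge) to the table distance `l_OC` is the standard
pinhole construction: the optical axis is perpendicular to the phone body,
the image plane sits at unit focal length with vertical half-extent
`cot(beta)` so that the bottom image edge ray is exactly the boundary ray
through B. The viewing ray direction is `n + (2k-1) cot(beta) u` (n the
axis, u the phone-body direction) and `l_OC` is its table intersection.
Rays with `k` beyond `max_valid_k(alpha, beta)` point above the horizon
and raise a `ParallelRayError` rather than returning a value.

A published closed form for this mapping exists whose printed final step
is dimensionally inconsistent (its denominator subtracts a length from an
x-coordinate) and whose intermediate point D lies on the phone axis, which
would make the line-through-A-and-D construction degenerate. The package
therefore validates the pinhole mode against an *independent* numerical
ray caster (rotation-matrix frame construction plus a bracketing root
finder, no shared formula) and keeps the printed form available as
`mode="literal"` purely for audit; its disagreement is reported, never
silently corrected.

`projected_area` converts a binary segmentation mask to physical area as
`S = (set pixels) x pitch^2` and measures `a` to the mask centroid — the
centroid is stable under mask noise, whereas the lowest set pixel is not.

## Scene simulator

Foods are disks of radius 3–12 cm lying on the table, rendered through the
same pinhole camera (3-D: a lateral axis is added) at 120x120 px by
default. Mass follows `density_coefficient x footprint area x shape
factor` with type-specific coefficients of 5–20 kg/m² — a plated 200 g
portion scale — and recorded weights carry multiplicative log-normal noise
with sigma = 0.05 (a 5 % kitchen-scale error). Shot tilts are uniform on
[30°, 80°]. Per-sample footprint radii jitter ±20 % around the type base
radius so the weight regression sees within-type area variation.

Because perspective scale varies across the mask, each rendered scene
reports an effective pixel pitch: the square root of the mean ground area
covered by one mask pixel, from the projection Jacobian. With that pitch,
`count x pitch^2` recovers the true footprint area up to pixelation error,
which shrinks roughly inversely with resolution (measured: ~15 % at 120
px, ~3 % at 240 px, <1 % at 480 px for a 6 cm disk at 0.45 m).

What the simulator does *not* emulate: segmentation errors (masks are
exact), occlusion, non-flat foods, lens distortion, lighting. Passing
round-trip tests therefore demonstrates the geometry and the estimator
plumbing, not robustness to real segmentation noise.

## Weight regression

Weight is regressed on (food type, alpha, l_OC, S) with an L1 penalty:
numeric features are standardised before penalisation, food type enters as
an indicator block, and by default an S x type interaction block lets the
model express per-type area-to-mass densities (the generative law in the
simulator). The intercept is unpenalised. `lambda` defaults to internal
5-fold cross-validation; `lambda = 0` falls back to ordinary least squares
(minimum-norm for collinear designs). Predictions are clamped at zero
grams. Constant design columns are dropped with a warning.

The irreducible error under the noise model is
`E|w e^eps - w| = w e^{s^2/2} (2 Phi(s) - 1)` (about `0.04 w` at s = 0.05);
the held-out MAE of the fitted model is judged against this analytic
floor, not against any fixed gram value, because absolute MAE scales with
the portion sizes a dataset happens to contain.

## Cohort schema and labelling

The cohort layout is 127 features over four categories: 6 personal, 16
medical indicators at each of two examinations, 10 lifestyle answers, 79
nutrient intakes (14-day daily means). The three-class target compares the
exams' HbA1c: class 0 no change, 1 increased, 2 decreased. The no-change
band `epsilon` defaults to 0 — class 0 then requires an exact tie — since
any nonzero band would be an invented clinical threshold; a band can be
passed where assay repeatability warrants one.

The predictor matrix drops the entire second-exam block (111 columns:
personal, lifestyle, nutrient, first-exam medical, selected by category
tags, never by column position) because the target is derived from it.
Categorical answers are integer-encoded against declared codebooks.

## Cohort simulator

Class labels are constructed exactly: no-change participants keep their
baseline HbA1c at the second exam; increased/decreased participants drift
by `|N(0.7, 0.25)|` percentage points (clipped at 0.2) up or down. Other
medical indicators get 15 %-of-SD retest noise. Nutrient intakes are
log-normal (log-SD 0.3) with a rank-5 factor structure so nutrients
co-vary within food groups — independent columns would make univariate
screening unrealistically easy. Lifestyle categoricals come from
latent-Gaussian discretisation of their codebooks, with weekly drinking
predominantly "Never or rarely" as in the study population.

Risk structure is injected as planted effects: a feature is shifted by a
stated number of its SDs within the class it drives. The default plant
list follows the directions the attribution analysis reports on real
data (older age and lower WHR stabilise; lower Se, higher HDL and lower
baseline HbA1c precede an increase; higher baseline TG and abstinent
drinking precede a decrease), at 1.0 SD by default. The power experiments
use five numeric plants at 1.5 SD — the "strong effect" level — under
which an oracle given the five true features reaches ~85 % accuracy, so
measured pipeline accuracy should be read against that ceiling, not
against 100 %.

The simulator matches the deposited cohort's schema and class mix
(21:15:52 of 88), not its marginal distributions; results on it bound what
the pipeline can do when its assumptions hold, and say nothing about
distribution shift or measurement artefacts in real data.

## Stacked classifier

Bases are XGBoost (100 trees, depth 3, learning rate 0.15, subsample and
column subsample 0.9), an RBF SVC (C = 1, scaled gamma) with
pairwise-coupling Platt calibration, and 150 extremely randomised trees
(max_features 0.5); the meta learner is distance-weighted 9-NN over the
3 bases x 3 classes probability block. Each base runs behind univariate
ANOVA-F screening fitted inside its training data — 6 features for the
SVC, 10 for the extra trees, 40 for XGBoost. Screening sized to the
expected count of active risk factors (order ten in a cohort of this
kind) is what makes distance- and variance-based learners workable at
n = 88, p = 111; the tree booster tolerates, and uses, a wider screen.

Meta training uses out-of-fold base probabilities from an internal
stratified 5-fold, averaged over two fold draws (`oof_repeats = 2`) to
damp fold noise, after which the bases are refit on the full training
data. SMOTE (k = 5, capped below the smallest class) balances every
*training* partition to the majority count; validation rows never enter
the oversampler, and every cross-validation report carries an index-level
audit of that. The oversample-then-split shortcut is available only
behind `protocol="oversample_then_split"` because it leaks interpolated
copies of validation points into training and inflates scores.

Outer evaluation is stratified 5-fold (the fold builder deals shuffled
class members round-robin, guaranteeing per-fold class counts within one
of proportional allocation), reporting accuracy and macro
precision/recall/F1 both pooled and as fold mean ± SD, a pooled 3x3
confusion matrix, and a macro one-vs-rest ROC averaged on a 101-point FPR
grid with trapezoid AUC. Metrics raise on a class absent from the truth
rather than returning NaN.

A note on the null behaviour: because training folds are SMOTE-balanced,
the fitted stack carries no majority-class prior. On signal-free cohorts
its accuracy therefore sits *between* 3-class chance and the majority
rate (empirically ~0.53 against a 0.59 majority rate), and the no-signal
control checks that it does not exceed the majority rate — exceeding it
would indicate leakage.

## Attribution

Feature contributions use a model-agnostic permutation-sampling Shapley
estimator on the stack's class probabilities (probability is the one
output scale all four learners share). Each sampled (feature ordering,
background row) pair contributes a telescoping walk from the background
row to the explained point, so additivity — base value plus contributions
equals the model output — holds exactly for the estimate; Monte-Carlo
error affects only the split among features, and the per-contribution
sampling SE is reported. With at most 8 features the estimator enumerates
all orderings and is exact for the empirical background. The default
background is 50 training rows; 20 orderings per explained row is enough
for rankings (the power study recovers >= 4 of 5 planted features in the
global top-5 with 8 orderings over 32 explained rows).

Global importance is the mean |contribution| over samples and classes;
per-class rankings restrict to one output. The sign summary reports, per
feature, the fraction of above-median-value samples whose contribution is
positive — a tabular stand-in for a beeswarm plot, and the tested surface
(plots are serialised alongside but never asserted on).

## Problem sizes and numerical choices

Validation experiments run at: 100-point geometry grids (agreement
asserted at 1e-6 relative; the ray caster itself solves to ~1e-14), 50
random confusion matrices (exact equality), weight recovery at n = 1000
training / 500 held-out scenes, and 20-seed power/null cohort studies at
n = 88 each — sizes chosen so the full suite re-runs in minutes on one
core while keeping Monte-Carlo error well below every asserted margin.
Ties in fuzzy food matching break lexicographically; degenerate inputs
(vertical phone, above-horizon rays, empty masks, singular `alpha + beta`)
raise typed errors rather than returning sentinel values.

## Known limitations

* The geometry model assumes the food lies in the vertical plane through
  the phone; lateral offsets change the effective distance slightly.
* The weight model is linear in its features by construction; foods whose
  mass scales nonlinearly with projected area (tall or hollow items) are
  outside its family.
* The classifier's hyperparameters are sized for n ~ 100, p ~ 100 tabular
  cohorts; they are config values, not constants.
* Attribution explains the model, not biology: a highly ranked feature is
  a model dependence, and only the planted-effect experiments — where
  ground truth is known — license a causal reading.
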