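# Methods

`compoct` re-creates, end to end, the measurement chain used in CT
body-composition research on lymphoma cohorts: a single axial slice at
the third lumbar vertebra (L3) is segmented into skeletal muscle and
adipose tissue, scalar indices are derived from the masks, patients are
classified, and the classifications enter a survival analysis.  Because
the clinical images and outcomes of such trials are not redistributable,
every stage is also provided with a synthetic counterpart whose ground
truth is known exactly; all quantitative claims made by the test suite
and the acceptance script are statements about those synthetic
conditions, not about patient data.

## 1. Tissue model and ground truth

Tissue identity on CT is inferred from attenuation: skeletal muscle
occupies −29 to +150 HU and adipose tissue −190 to −30 HU.  Ground
truth follows the two-step procedure used in practice: an operator
outlines twelve regions of interest (ten muscle groups, visceral fat
VAT, subcutaneous fat SAT), then pixels inside each contour are kept
only if their HU falls in the tissue window.  Both window bounds are
treated as inclusive; since the source thresholds are quoted without
bracket semantics and HU is effectively continuous, the boundary
convention is immaterial in practice but documented and fixed.  The two
windows are disjoint, so muscle and fat masks derived from one contour
can never overlap.

## 2. Synthetic phantoms

The phantom generator (`compoct.phantom`) renders an elliptical torso:
a subcutaneous fat ring, a muscle band split into eight
abdominal-wall/paraspinal sectors plus two psoas discs beside a
vertebral body (> +150 HU), and a visceral compartment of fat with
bowel-gas pockets (< −190 HU) wrapped in thin soft-tissue walls.  Two
quantities are controlled exactly because the downstream indices depend
on them:

* **muscle area** — the band thickness is solved by bisection so the
  realized labelled area matches `target_muscle_area_cm2` (within 5 %,
  in practice within a few pixels);
* **mean muscle attenuation** — muscle HU is drawn as
  Normal(target, 5 HU), truncated to the window, and recentred so the
  pre-noise mean equals `target_muscle_mean_hu` exactly.

Fat is Normal(`fat_mean_hu`, 8 HU) truncated inside the fat window.
Additive Gaussian acquisition noise (default 3 HU) is applied last; with
the default means the in-window guarantee degrades by well under 1 %.
The guarantee does erode if a tissue mean is placed within ~3 noise
standard deviations of a window edge — the defaults keep 60+ HU of
margin.  Geometry that cannot host the requested muscle area (too large
for the torso, or smaller than the psoas discs plus a minimal band)
raises a `GeometryInfeasibleError` rather than silently clamping.

Dataset generation draws spec fields uniformly from configurable ranges
(default: muscle area 110–200 cm², muscle mean 22–48 HU, fat mean −110
to −90 HU, noise 2–4 HU, both sexes).  These ranges define the study
conditions under which the segmentation results below hold.  What the
phantoms deliberately do not model: anatomical shape variation beyond an
ellipse, contrast enhancement, beam hardening, metal or motion
artefacts, or 3-D context.  Segmentation performance on phantoms
therefore demonstrates that the training/prediction machinery works, not
that the trained weights transfer to patients.

## 3. Segmentation ensemble

Twelve independent U-Nets are trained, one per ROI, each against only
its own binary mask — per-ROI specialisation is the defining feature of
the approach.  The architecture is a standard six-resolution-level
encoder/decoder (five 2×2 max-poolings, so the input side must be
divisible by 32) with two 3×3 convolutions per level, group
normalization, ReLU, nearest-neighbour upsampling with a following
convolution, skip concatenations, and a 1×1 sigmoid head.  The network
is implemented directly on numpy (im2col convolutions lowered to BLAS
matrix products, explicit backward passes, Adam) so training runs on a
single CPU core in minutes at the 128×128 desk scale.

Two architectural choices deserve justification:

* **Coordinate feature planes.**  Two constant input planes holding the
  normalized row/column coordinate are appended inside the network.
  Several target ROIs (the angular muscle-band sectors, the psoas
  bellies) are defined by absolute position rather than local texture; a
  purely translation-equivariant network can only recover position from
  boundary padding, which measurably slows convergence.  The network
  interface remains a single-channel HU grid.
* **Loss and initialization.**  Soft Dice alone collapses to the empty
  prediction on small-foreground ROIs (a sector is ~1.5 % of pixels):
  once the sigmoid saturates toward zero the Dice gradient vanishes.
  The training loss is therefore soft Dice plus binary cross-entropy
  taken at the logit, the standard pairing, with the foreground term of
  the cross-entropy up-weighted (default 5) to counter the class
  imbalance.  The output head's bias starts at −2 so the initial
  prediction sits near the background prior rather than at 0.5; without
  this, the first-epoch cross-entropy shock intermittently drives a
  small network into a saturated all-background state it never leaves
  (a seed-dependent failure we observed directly).

Inputs are clipped to [−200, 250] HU (bracketing both tissue windows)
and min-max scaled.  Networks carry 6 base channels doubling per level
and capped at 32.  Training uses Adam at the published initial
learning rate 10⁻³, batch size 4, a held-out validation fifth of the
training slices, and early stopping on the validation loss defined as
1 − Dice of the *thresholded, HU-gated* prediction — exactly the
quantity the ensemble is judged on; the soft loss is a poor proxy for
it once probabilities are merely well-ranked, and gating matters
because spill-over from a small muscle ROI into surrounding fat is
removed downstream.  The epoch budget is configurable; the published
cap of 300 epochs is retained as the config default, while the test
suite and the acceptance script train for up to 10 epochs at 128×128 —
a budget sized for a single CPU core at which the phantom task has
converged (the fastest networks stop after 3–6 epochs via early
stopping; sector networks use the full budget).

Prediction thresholds each probability map at 0.5 (ties to foreground),
pools the ten muscle masks by pixelwise union into the muscle ROI, and
finally gates every mask with its tissue HU window.  Whether the
original pipeline gated its network outputs is not documented; gating
makes predicted and manual masks definitionally comparable (the manual
masks are HU-gated by construction) and is applied symmetrically here.
Evaluation reports per-class Dice (2|A∩M|/(|A|+|M|), defined as 1 for
two empty masks), absolute differences of the four body-composition
indices, and the Pearson correlation of pixel counts.

Per-sector Dice of individual muscle networks plateaus around 0.85–0.9:
the exact angular cut between adjacent sectors is ambiguous from the
image, and boundary pixels are traded between neighbours.  The pooled
muscle mask is insensitive to this trade, which is why pooled Dice is
substantially higher than any single sector's — one reason the pooling
design works well.

## 4. Body composition

From the pooled muscle mask and the fat masks: area in cm² (pixel count
× pixel area), skeletal muscle index SMI = area/height², muscle
attenuation MA = mean HU over muscle pixels, and VAT/SAT indices =
area/height².  Classification uses strict inequalities, following the
wording the thresholds are defined with: sarcopenia SMI < 55 (men) / 39
(women) cm²/m²; muscular hypodensity MA below the sex-specific 10th
percentile of the cohort (the reference cohort's percentiles, 26.7 HU
male / 23.1 HU female, are the fixed defaults and remain overridable);
obesity BMI > 30, underweight BMI < 18.5 kg/m².  Percentiles use the
linear-interpolation definition (numpy's default), which is documented
because re-derived cutoffs depend on it.  An empty muscle mask yields
MA = NaN, SMI = 0, a warning, and an explicitly undetermined
hypodensity flag.

## 5. Cohort simulator

`compoct.cohortsim` generates tabular cohorts for testing the survival
battery by parameter recovery.  Anthropometrics are drawn per sex from
log-normal (BMI, SMI) or normal (age, MA) marginals matched to the
reference medians and interquartile ranges, tied by a Gaussian copula
with correlations MA–age = MA–BMI = −0.4 and SMI–BMI = +0.4 (the source
reports only the signs; the magnitudes are package defaults).  Group
assignment is by quantile: hypodensity = lowest `hypodense_fraction` of
MA per sex (mirroring the percentile definition), obesity = highest
`obese_fraction` of BMI.

Endpoints are exponential proportional-hazards models with configurable
hazard ratios (hypodensity, obesity, aaIPI per ordinal level, age per
year, centred at 48).  The baseline rate is calibrated by root-finding
so that the *non-hypodense population's* marginal 36-month survival
equals the configured target (0.899 for OS, 0.809 for PFS) under the
realized covariate mix — calibrating the all-covariates-zero patient
instead would make the simulated cohort far more lethal than the
reference cohort.

Joint endpoint construction: OS has its own exponential clock; PFS is
the minimum of an independent progression clock (rate = PFS − OS rate,
floored at zero for the rare covariate patterns where the embedded
ratios would invert the ordering) and the OS clock.  Both marginals are
then *exactly* proportional hazards, which is what makes ±5 %
hazard-ratio recovery tests meaningful.  The cause of the first event
(relapse vs non-relapse mortality) is a Bernoulli label whose
per-patient weight is calibrated as target-NRM / P(event by 36 m), so
each group's true 36-month NRM cumulative incidence equals its target
exactly.  The price of keeping all three calibrations exact is a known
artefact: a record whose first event is labelled NRM (death without
relapse) may still carry a later OS time.  A fully coherent
relapse→post-relapse-death chain was considered and rejected: it cannot
keep the OS marginal exactly proportional-hazards, and a label-patching
variant (forcing OS = PFS time on NRM labels) measurably distorts the
embedded OS hazard ratio.  The competing-risk analysis consumes
(pfs_time, cause); the Cox/KM analyses consume the OS clock; neither
mixes the two.

Censoring is administrative: per-patient uniform on
`admin_censor_months` ± 15.2 months, reproducing the reference median
follow-up and its interquartile spread.  PET response statuses are
categorical (neg/pos/missing) with group-specific missingness;
"missing" is an explicit value, never a dropped row.

## 6. Survival statistics

Kaplan–Meier, log-rank, and Cox models delegate to `lifelines`; Cox
uses Efron tie handling with Wald intervals on the log-hazard scale
(matching log-symmetric published intervals).  Non-convergence and
separation raise errors rather than returning clipped estimates.
Competing risks use the Aalen–Johansen estimator per group and cause.
Gray's test for equality of cumulative incidence functions is
implemented in `survstats.gray_test`: the rho = 0 score compares
cause-specific subdistribution hazards on Gray's modified risk sets
(subjects failing from competing causes remain at risk with weight
(1 − F̂_cause(t⁻))/Ŝ(t⁻) estimated within their own group); the
variance uses the log-rank-type hypergeometric form on those modified
risk sets rather than Gray's full estimator.  Against the reference R
implementation (`cmprsk::cuminc`) the statistic agrees to within ~0.3 %
on untied data and ~3 % under heavy ties — adequate for screening-level
p-values, and the approximation is documented here precisely because it
is one.  Group comparisons use the chi-square test (Yates-corrected for
2×2 tables) and Student's t; ROC screening uses the rank-based AUC with
the 0.7 retention threshold.

36-month survival and incidence values are read from the fitted step
functions by right-continuous evaluation.

## 7. Problem sizes and numerical choices

The acceptance script trains on 60 phantoms at 128×128 and evaluates on
20 (the published study trained on 190 patients and tested on 49; the
desk scale keeps the train:test ratio and runs on one CPU core), and
uses 200 simulated cohorts of n = 656 for effect-size recovery.
Reported hazard-ratio recoveries are geometric means over replicates;
Cox maximum-likelihood estimates carry a small positive finite-sample
bias (~1–2 % at ~75 events), visible in the recovered values.  The
Aalen–Johansen 36-month NRM mean over replicates sits slightly above
the calibrated truth for the hypodense group (≈ +1 point at n_group
≈ 65) — tail-time estimates from 65 subjects under ~50 % censoring are
right-skewed; the deviation is within the tolerance the recovery test
states, and is a property of the estimator at this group size, not of
the calibration.

Probability threshold 0.5 with ties to foreground; Dice of two empty
masks defined as 1; Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸); group norm
ε = 10⁻⁵; float32 throughout the network.  All randomness flows from
explicit integer seeds (`numpy.random.default_rng`); phantom, training,
and cohort stages consume independent sub-seeds so changing one stage's
seed leaves the others' outputs untouched.

## 8. Known limitations

* Phantom realism is deliberately minimal (Section 2); Dice values on
  phantoms should not be quoted as expected clinical performance.
* The ten muscle-group names `m01..m10` are synthetic; the reference
  grouping for human anatomy is not reproduced.
* The cohort simulator's copula magnitudes and post-baseline structure
  (PET positivity rates, fat-index marginals) are plausibility
  defaults, configurable but not fitted to data.
* Gray's test variance is an approximation (Section 6).
* Automatic L3-slice selection, 3-D volumes, and contrast-enhanced
  imaging are out of scope.
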