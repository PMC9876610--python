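# Methods

## Scope and model of the experiment

`traitgaze` analyses a free-viewing emotional-face paradigm: participants
fixate a peripheral attention-getter, a 20°×20° central face appears for
10 s while binocular gaze is recorded at 300 Hz (1920×1080 screen, 60 cm
viewing distance), and an emotion judgment follows. Each participant
completes 4 blocks × 20 trials spanning five emotions (angry, fearful,
happy, sad, neutral). Two self-report scales index the traits of interest:
the 50-item Autism-spectrum Quotient (AQ; 4-point scoring 50–200 and
dichotomous scoring 0–50) and the 17-item Social Phobia Inventory (SPIN,
0–68). The analysis asks how autistic traits and social anxiety — alone and
in interaction — shape attention to the eyes across the trial: overall
proportional eye-looking, the first on-face fixation (probability of
landing on the eyes, its duration, its latency), and the 250 ms
moving-average eye-looking time course.

## Preprocessing

1. **Gap interpolation.** Tracking losses are filled per eye by linear
   interpolation when the bridged gap between bounding valid samples is at
   most 75 ms; longer runs and runs touching the trial edges stay invalid.
   Valid samples are never altered.
2. **Binocular merging.** Cyclopean gaze is the mean of both eyes; when
   only one eye is valid its coordinates are used rather than dropping the
   sample (maximizes retention; the averaging rule alone does not dictate
   the one-eye case).
3. **Fixation detection.** Dispersion-threshold I-DT by default: a fixation
   is a maximal run of valid samples whose dispersion (x-range + y-range)
   stays within 1° of visual angle and whose inclusive duration (one sample
   period per member sample) reaches 60 ms. Scanning is greedy left to
   right; invalid samples break windows. The algorithm is deterministic and
   is verified against an exhaustive window-growing oracle. A
   velocity-threshold I-VT mode (default 30°/s) is available.
   Degree→pixel conversion assumes a 531×299 mm panel at 60 cm
   (≈37.9 px/° at centre); all constants are configurable because the
   physical set-up is a property of the lab, not the method.
4. **AOIs.** The face is a centred 20°×20° square; the eyes region is a
   single band spanning the full face width from 25% to 45% of face height
   (both eyes jointly). Membership is half-open, `[x0,x1)×[y0,y1)`, so a
   centroid exactly on a lower/right edge falls outside. Real-data use
   should supply measured AOI geometry through the config.
5. **Trial validity.** A trial is excluded when (a) more than 30% of
   samples remain invalid after interpolation, (b) less than 50% of the
   trial duration is spent on the face, or (c) the emotion judgment was
   wrong. Thresholds are strict (exactly 30%/50% keeps the trial, with a
   1e-9 float guard). Face time is computed from fixation durations by
   default (sample-based counting is available); reasons are recorded
   non-exclusively so either accounting of exclusion totals can be
   reproduced.

## Dependent variables

* `prop_eyes_overall` — eyes fixation time / (eyes + face) fixation time
  over the whole trial; undefined without face time.
* first on-face fixation — the earliest fixation labelled eyes or face.
  Only when it lands on the eyes are `first_fix_duration` (ms) and
  `latency_to_eyes` (onset from face appearance, ms) defined; both are
  natural-log transformed for modelling because their distributions are
  right-skewed. The per-participant proportion of eyes-first trials divides
  eyes-first trials by that participant's valid correct trials.
* epoch curve — proportional eye-looking inside a 250 ms window sliding in
  50 ms steps (configurable down to per-sample), computed from exact
  fixation-interval overlap; windows without face time are NaN. The step
  is a design choice — the protocol specifies the 250 ms window but not
  the overlap.

Trait scores are z-standardized over the post-exclusion analysis sample
(ddof = 1). Group splits use the published screening cutoffs: dichotomous
AQ ≥ 26, SPIN ≥ 19, both inclusive. The AQ reverse-key ships with the
standard published 24 agree-scored items and is configurable.

## Inference

**Linear mixed models.** Each gaze measure is modelled with fixed effects
sex + z-AQ × z-SPIN × emotion (sum-to-zero factor coding), a random
intercept per participant, and REML estimation (`statsmodels MixedLM`;
a closed-form profiled-REML line search takes over if the general
optimizer fails at the τ²=0 boundary — for a random-intercept model the
REML criterion depends only on the variance ratio, so the profiled search
cannot fail). Type III F tests use the Wald statistic of each term's
coefficient block, valid under sum coding. Denominator degrees of freedom
use the Satterthwaite approximation: the covariance of (τ², σ²) comes from
the numerically differentiated curvature of the restricted log-likelihood,
each 1-df contrast gets df = 2f²/Var(f) with f = l′C(θ)l, and multi-df
terms combine per-eigencontrast df through the harmonic aggregate
2E/(E−q), E = Σνᵢ/(νᵢ−2). This matches `lmerTest` to the reported
precision (cross-checked in the test suite). A residual-df mode exists;
Kenward-Roger is not implemented and requesting it raises rather than
silently approximating.

**Simple slopes.** The conditional SPIN slope at z-AQ ∈ {−1, 0, +1}
(labelled low/medium/high; moderator levels map back to original-scale AQ
scores by mean + level·SD) is b_spin + level·b_interaction, marginal over
emotion by sum coding. Standard errors come from the coefficient
covariance; the standardized slope is β = B·SD(z_spin)/SD(response) on the
analysis sample. The identity "slope at level a equals the z-SPIN
coefficient after recentring z-AQ at a" is enforced exactly by refitting
the recentred design at the fitted variance components (a pure linear
reparameterization); an independently re-optimized refit would agree only
to optimizer tolerance. Slope comparisons across levels are pairwise Wald
tests on slope differences (all proportional to the interaction
coefficient); no specific published procedure is being reproduced there
and the output labels them as such.

**Cluster-based permutation test.** Participant-mean epoch curves are
compared between groups with a Welch t per epoch (robust to the unequal
group sizes the cutoffs produce); NaN epochs are dropped pairwise. The
cluster-forming threshold is the two-sided t critical value at α = 0.05
with the per-epoch Welch df. Clusters are maximal contiguous same-sign
supra-threshold runs; the cluster statistic is the summed t mass. The null
distribution is the maximum |mass| over relabellings of participants:
exhaustive enumeration when C(n, n₁) ≤ 10⁵ (p = share of relabellings,
identity included, reaching the observed mass), otherwise Monte-Carlo with
p = (1 + exceedances)/(1 + n_perm), default 1000 seeded permutations.

## Synthetic-data generator

The generator is a forward model of the experiment with recorded ground
truth. Cohort: latent bivariate-normal AQ/SPIN with correlation 0.44 and
the observed full-sample moments (4-point AQ 120.35 ± 14.28, SPIN
24.37 ± 12.47), rounded and clipped to scale ranges; the dichotomous AQ
derives from the 4-point total by the calibrated monotone map
round((aq4−50)/3) (matching the observed binary mean of ~23); 35% male;
age 22 ± 2.45.

Each trial is a semi-Markov AOI sequence: an initial off-face latency
(log-normal; trait effects linear on the log scale), a first on-face
fixation landing on the eyes with Bernoulli probability (trait effects
linear on the logit scale, base rate 0.29), then alternating
gamma-distributed fixations (shape 4, floored at 100 ms so dwells stay
detectable) over eyes / rest-of-face / off-face with an off-excursion
probability of 0.06 and an eyes-transition probability of 0.45. Trait
effects on eye dwell are linear on the log-mean. After 5 s, simulants in
the high-AQ group transition to the eyes at a rate reduced by the
avoidance factor (default 0.30). Right-skewed families (log-normal
latencies, gamma dwells) are the package's choice — the measured data
motivate a skewed generator but fix no family — and the log-linear /
logit-linear trait structure with an AQ × SPIN product mirrors the models
fitted downstream, which makes parameter-recovery studies well-posed.
Default effect sizes take the reported conditional slopes at face value
(log-dwell SPIN slope 0.095 with interaction 0.124; log-latency 0.05 with
0.06; eyes-first logit −0.07 with −0.21); emotion-specific gaze
differences are not modelled. Judgment accuracy is Bernoulli(0.885).

Rendering places one target point per fixation inside its AOI (consecutive
fixation targets at least 60 px apart so distinct fixations stay separable
at the 1° dispersion threshold), adds isotropic cyclopean jitter (5 px)
and independent per-eye noise (2.5 px), and overwrites Poisson-burst
windows (0.12 bursts/s × 180 ms) with invalid samples. All draws descend
from one integer seed through per-participant/per-trial child streams, so
datasets are byte-reproducible and order-independent.

What the generator does **not** emulate: saccade kinematics (transitions
are instantaneous), smooth pursuit, drift, pupil dynamics, emotion-specific
scanning, or calibration error. Passing tests therefore validate the
pipeline's arithmetic and statistical behaviour, not robustness to every
artefact of real recordings.

## Validation protocol and problem sizes

`traitgaze.studies` fixes the standing validation studies, shared by the
test suite and `scripts/acceptance.py`:

* **Null calibration** — 500 replicates (tests; 250 in the acceptance
  script) of 20 participants × 20 trials with every trait effect zeroed;
  the z-AQ × z-SPIN Type III test and the AQ-group cluster test (250 ms
  non-overlapping epochs, 199 permutations) must reject at ~5%. Cohorts
  leaving a trait group with <2 members are redrawn; membership is
  independent of gaze under the null, so this conditioning is harmless.
* **Direction recovery** — 100 replicates (60 in the script). (i) Log-dwell
  slopes 0.15 + 0.15·z-AQ give a SPIN effect on log first-fixation duration
  of +0.30 at z-AQ = +1 and 0 at −1; success requires a significant
  positive simple slope at +1 and a null slope at −1 (30 participants ×
  40 trials). (ii) Avoidance factor 0.5 after 5 s; success requires a
  significant negative late cluster in the AQ-group comparison
  (30 × 20). Effect sizes were fixed a priori from the power arithmetic in
  the docstrings.
* **Round-trip fidelity** — 3 participants × 80 trials rendered without
  noise or missingness; preprocessing must recover the first on-face
  fixation's AOI and, for truth intervals above the 60 ms detectability
  floor, match the sequence AOI-for-AOI with onset/offset errors within
  one sample period (3.33 ms).

These sizes are the package's chosen defaults for a laptop-scale check;
every study takes replicate counts and cohort sizes as parameters.

## Numerical and degenerate-input choices

* Fixation offsets extend one sample period past the last member sample so
  a 60-sample stationary burst at 300 Hz reads as 200 ms, not 196.7 ms.
* Exactly-at-threshold validity fractions keep the trial (strict
  inequalities with a 1e-9 guard against float representation).
* Satterthwaite finite-difference steps scale with the variance components;
  at the τ² = 0 boundary one-sided differences are used and non-positive
  contrast variances fall back to residual df (capped at 10⁷).
* Epoch values with no face time are NaN, excluded pairwise by the cluster
  test; Welch t needs ≥2 observations per group per epoch.
* LMM non-convergence is flagged on the results object, never hidden;
  rank-deficient designs raise with the aliased column names.
* Random slopes of emotion are available only implicitly (the full model is
  out of scope: with one observation per trial-emotion cell it is known to
  be convergence-fragile, and no acceptance guarantee is attached).

## Known limitations

* The Satterthwaite multi-df combination can differ from lmerTest in the
  second decimal of the denominator df (different eigencontrast handling);
  F statistics and single-df tests agree to reported precision.
* The proportion responses (overall and eyes-first) are modelled as
  Gaussian LMMs, as in the original analysis; calibration holds at the
  simulated scales but bounded responses remain an approximation.
* The analysis of the eyes-first proportion aggregates to participant ×
  emotion cells before fitting (the trial-level variable is binary); the
  protocol did not state the aggregation level.
* Real exported tracker data must match the documented TSV/CSV layouts;
  no vendor-proprietary formats are parsed.
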