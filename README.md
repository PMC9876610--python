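# traitgaze

Eye-tracking analysis of how autistic traits and social anxiety — separately
and in interaction — modulate attention to the eyes during face viewing.

People high in social anxiety and people high in autistic traits both show
atypical eye contact, but the temporal signatures differ: vigilance (fast
orienting to the eyes), maintenance (difficulty disengaging once fixated),
and avoidance (reduced looking) predict different effects on the *first*
fixation on the eyes versus eye-looking *later* in the trial, and the two
traits are correlated enough that their interaction matters. `traitgaze`
implements the full analysis pipeline for a 10 s free-viewing paradigm
recorded at 300 Hz:

* **preprocess** — linear interpolation of tracking gaps ≤ 75 ms, binocular
  averaging, dispersion-based (I-DT) fixation detection, eyes/face AOI
  labelling, and trial exclusion (>30% missing, <50% face time, incorrect
  response);
* **metrics** — AQ (4-point and dichotomous) and SPIN questionnaire scoring,
  trait z-standardization and group splits (AQ ≥ 26, SPIN ≥ 19), overall
  proportional eye-looking time, first-fixation measures (eyes-first flag,
  log duration, log latency), and 250 ms moving-average eye-looking curves;
* **inference** — random-intercept linear mixed models with Type III
  F tests (Satterthwaite df), simple slopes of social anxiety at z-AQ ∈
  {−1, 0, +1}, and cluster-based permutation tests comparing trait groups'
  eye-looking time courses;
* **simulate** — a seeded forward model of the whole experiment (correlated
  traits, trait-dependent semi-Markov fixation sequences, missingness
  bursts) with recorded ground truth, used for calibration and recovery
  studies.

The statistical model, for a gaze measure $y_{ij}$ of participant $i$ on
trial $j$:

$$y_{ij} = \beta_0 + \mathbf{x}_{ij}^\top\beta + u_i + \varepsilon_{ij},
\qquad u_i \sim \mathcal N(0, \tau^2),\ \varepsilon_{ij} \sim \mathcal N(0, \sigma^2)$$

with fixed effects sex + z-AQ × z-SPIN × emotion (sum-coded) and the simple
slope of z-SPIN at moderator level $a$ given by
$B(a) = \beta_{\text{spin}} + a\,\beta_{\text{aq}\times\text{spin}}$.
Time courses are compared by epoch-wise Welch $t$, clustering contiguous
same-sign supra-threshold epochs and testing the summed cluster mass against
the permutation distribution of the maximum mass under participant
relabelling.

## Worked example

```python
from traitgaze import (EyeLMM, LMMSpec, SimulationParams,
                       simulate_design_level, cluster_permutation)

# generator defaults encode the expected trait-effect directions
params = SimulationParams(n_participants=30, seed=11)
traits, trials, curves = simulate_design_level(params, n_trials=40)

eyes_first = trials[trials["first_face_fix_on_eyes"] == True]
res = EyeLMM(eyes_first, LMMSpec("log_duration")).fit()
print(res.summary())

labels = traits.set_index("participant_id").loc[curves.index, "aq_group"]
print(cluster_permutation(curves, labels, n_perm=1000, seed=11).summary())
```

Output (abridged):

```
Linear mixed model (REML): log_duration ~ C(sex, Sum) + z_aq4 * z_spin * C(emotion, Sum)
groups: participant_id (n_groups=30, n_obs=336)
random-intercept var tau2=0.035665, residual var sigma2=0.25505, converged=True

Type III tests (satterthwaite denominator df):
                                  F  num_df  den_df       p
z_spin                        4.646       1   25.23 0.04085
z_aq4:z_spin                  1.765       1   33.11  0.1931
...

Simple slopes of z_spin by autistic-trait level:
     low (z_aq=-1): B=+0.0021 SE=0.0907 t(32.8)=+0.024 beta=+0.004 p=0.9813
  medium (z_aq=+0): B=+0.1037 SE=0.0481 t(25.2)=+2.156 beta=+0.178 p=0.0408
    high (z_aq=+1): B=+0.2053 SE=0.0900 t(28.5)=+2.282 beta=+0.353 p=0.0302

Cluster permutation test: 6 cluster(s), 1000 permutations
  5575-7475 ms: mass=-137.48, p=0.0020
  8325-9875 ms: mass=-110.61, p=0.0060
  ...
```

Read: with the default generator (which injects a social-anxiety effect on
first-fixation duration that grows with autistic traits, and late eye
avoidance in the high-AQ group), social anxiety lengthens the first fixation
on the eyes at medium and high — but not low — autistic traits
(B = +0.21 per SD of SPIN at +1 SD of AQ, t(28.5) = 2.28), and the high-AQ
group shows significantly reduced eye-looking in late clusters around
5.6–7.5 s and 8.3–9.9 s.

The same pipeline runs from the shell on on-disk artifacts:

```bash
traitgaze all --seed 1 --out run1          # simulate → … → report
traitgaze analyze --config cfg.yaml --out run1
```

`run1/report.txt` lists the exclusion summary, the four mixed-model term
tables with simple slopes, and the two group time-course comparisons with
significant clusters shaded in the accompanying figures.

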