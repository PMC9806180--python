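# Methods

This note records the models, estimators, numerical choices and known
limitations behind `idiobias`.  It is written for users who want to know
exactly what the pipeline computes and what passing its validation suite
does and does not establish.

## Error scoring

**Matching design.** The stimulus space is a closed loop of
`n_prototypes × (n_morphs_per_pair + 1)` steps (default 3 × 49 = 147).
The trial error is the signed shortest circular distance from target to
response in morph units: magnitude `min((j−i) mod n, (i−j) mod n)` ≤
⌊n/2⌋, sign positive when the shorter arc runs in the increasing-index
direction.  The sign convention is a package choice — any fixed convention
leaves every correlation downstream unchanged; an exact half-loop tie
(even `n` only) is returned as `+n/2`.  For profile-level analyses,
stimuli are binned in threes anchored at index 0 (147 → 49 bins), which
trades stimulus resolution for ~5 trials per bin at the default 255 trials
per observer.

**Rating design.** Raw 0–10 ratings are min–max rescaled per observer to
[0, 10] (`10·(X−Xmin)/(Xmax−Xmin)`), which removes any positive-gain
affine response propensity exactly and is idempotent; a constant rater is
rejected as non-normalizable.  The error is the absolute difference from
ground truth (real = 10, generated = 0).  Normalization uses all of an
observer's trials so the initial and retest phases share one scale.

## Sensitivity summaries

**JND.** A Gaussian is least-squares fitted to the error frequency
histogram (bin width 1 morph unit) and the JND is half the 25th–75th
percentile span of the implied cumulative Gaussian, i.e. 0.67449 σ̂.  The
fit goes through the Gaussian's *bin integrals* rather than its density at
bin centers: a density fit picks up ≈1/12 of extra variance from the
unit-width discretization, which visibly breaks the 0.67449 σ identity for
narrow error distributions (σ ≈ 1).  Degenerate inputs (zero spread)
return JND 0 with a warning; a non-converging fit falls back to the sample
SD, also with a warning.  A minimum of 20 error values is required.

**d′.** The procedure behind published d′ values for rating tasks is
often under-specified; here normalized ratings are binarized at the scale
midpoint ("real" call iff rating > 5 — the only symmetric criterion on the
normalized scale), hit and false-alarm rates use the 1/(2N) correction for
0/1 rates, and d′ = probit(H) − probit(F).  Only initial-phase trials
enter, so repeated images are never counted twice.  A constant rater
bypasses normalization (binarizing a constant is propensity-free) and
yields d′ = 0.

## Consistency estimation

Per-observer profiles are mean errors per binned stimulus (matching) or
per repeated image and phase (rating).  Correlations are Pearson over keys
present on both sides (pairwise-complete; ≥ 3 shared keys required — with
255 trials over 49 bins, occasionally empty half-bins are unavoidable).
All averaging of correlations happens on the Fisher z scale,
`tanh(mean(atanh r))`; inside resampling loops |r| = 1 (noise-free
degenerate cases) saturates instead of raising, and undefined correlations
are dropped from the pool.

**Split-half bootstrap (matching).** Per iteration every observer's
trials are re-split per bin into halves of ⌈k/2⌉/⌊k/2⌋ (the extra trial
assigned to a random half); within mode correlates an observer's two
halves, between mode correlates one half of each observer with one half of
every other (one correlation per unordered pair per iteration — which
halves pair is immaterial since splits are random).  The bootstrap
distribution over 1000 iterations gives the mean and 2.5/97.5 percentile
CI; no BCa correction is applied.

**Test–retest (rating).** Within mode is the correlation of initial- vs
retest-phase errors over the repeated images; the observer-level bootstrap
resamples observers with replacement (within) or resamples, from all
ordered observer pairs, as many pairs as exist (between: initial errors of
one observer vs retest errors of another, used symmetrically in both
directions).

## Permutation nulls

The chance level for profile correlations must respect the similarity of
neighbouring stimuli: smooth error profiles make naive i.i.d. shuffles
understate the null variance.  The matching-design null therefore
circularly shifts one half's binned labels by an observer-specific uniform
shift in [1, n_bins − 1] before correlating (shift 0 is excluded — it
would reproduce the true alignment; shifts act on binned indices because
the correlations do).  The rating-design null independently permutes the
image labels of the initial and retest error vectors; iterations in which
every correlation in the pool is degenerate are redrawn with a counter,
and an all-degenerate group raises.  Nulls use 10,000 iterations by
default; p-values are one-sided with the plus-one correction.

### Calibration

With **equal per-bin trial counts**, the aligned split-half statistic and
the shifted null draws are exchangeable under the no-bias hypothesis when
the observed statistic is a single split (the trial-error distribution is
then invariant under per-observer circular relabeling), so the test is
exactly calibrated; the validation suite confirms the 5% nominal rate on
balanced bias-free cohorts (294 trials = 2 per stimulus, 6 observers, 400
cohorts, 999-draw nulls).

Two deliberate deviations from that idealized setting, both properties of
the procedure rather than of this implementation, are quantified by
`scripts/acceptance.py` and should be kept in mind when interpreting
p-values on real designs:

* under uniform random target sampling, per-bin counts are unequal and
  that inequality is *aligned* between the two halves of the observed
  statistic but *misaligned* under shifting; the aligned statistic is
  slightly heavier-tailed than the null and the test mildly
  anticonservative (`null_rejection_rate_uniform_sampling`, ≈ 0.07 at
  α = 0.05 under the default conditions);
* the pipeline's headline statistic is the bootstrap *mean* over re-splits,
  which has less spread than the single-split null draws, making the
  reported p-values conservative in the opposite direction.

## Synthetic observers

The generator exists to make the chain testable, not to model any
published cohort; its parameters are artifact constructs.

* **Bias profiles** are truncated random Fourier series on the circle:
  harmonics with wavelength ≥ `smoothness` (in stimulus units) receive
  i.i.d. standard-normal coefficients, scaled so the expected per-point
  variance is `bias_sd²`; the mean over the loop is exactly 0.  Smoothness
  is essential: it is what makes the shift null genuinely different from
  an i.i.d. shuffle.
* **Matching response:** response = target + round(bias[target] +
  shared_weight·shared[target] + N(0, noise_sd)), wrapped to the loop;
  with probability `lapse_rate` the response is uniform instead.  Targets
  are uniform by default; a balanced scheme (every stimulus equally often)
  is available for calibration studies.
* **Rating response:** latent = 5 + discriminability·(truth − 5) +
  bias[image] + shared_weight·shared[image] + N(0, noise_sd); observed =
  clip(gain·latent + offset, 0, 10).  The image bias is identical across
  phases, which is exactly what the test–retest correlation measures.  One
  balanced retest set (20 real + 20 generated of the 100 images) is drawn
  per cohort and shared by all observers, as a test–retest design
  requires; the within-group between-observer correlation would otherwise
  collapse for want of shared repeated images.
* **Default conditions** mirror the analyzed designs: 13 + 11 matching
  observers × 255 trials on the 147-step loop; 7 + 5 rating observers,
  100 images + 40 repeats (the pipeline drops one repeated image by
  default, analyzing 39, as in the design it emulates).  Bias magnitudes
  (matching: idiosyncratic SD 5, shared SD 4, noise SD 12, lapse 0.02;
  rating: bias SD 2, shared SD 1, noise SD 1.5, discriminability 0.08,
  per-observer gain U(0.8, 1.2) and offset U(−1, 1)) were chosen once as a
  realistic regime — consistency and d′ values in the range reported for
  comparable tasks — and are not fitted to any dataset.

What the simulator does *not* emulate: perceptual nonlinearity along the
morph continuum, sequential effects, learning or fatigue, criterion
drift, heavy-tailed lapse behaviour, or any image-computable basis for
the biases.  Passing parameter recovery on these cohorts validates the
estimators' arithmetic and calibration, not any claim about real
observers.

## Parameter recovery

For matching cohorts with idiosyncratic bias variance σ_b², shared
variance σ_c², trial noise σ_e² and m trials per bin, the split-half
expectations are

    r_within  ≈ (σ_b² + σ_c²) / (σ_b² + σ_c² + 2σ_e²/m)
    r_between ≈ σ_c² / (σ_b² + σ_c² + 2σ_e²/m)

The validation suite checks pooled estimates against these within ±0.05
on 50 replicate cohorts of the full 24 × 255 design at σ_b = 5, σ_c = 4,
σ_e = 4, smoothness 30, lapse 0.  The formula idealizes equal per-bin
counts and exact profile variances; under uniform target sampling,
convexity of 1/n across Poisson-like bin counts and Jensen losses from
realized-profile variance spread attenuate the measured correlations below
it, by an amount that grows with σ_e (≈0.036 at σ_e = 4, ≈0.055 at
σ_e = 8 for r_within).  The recovery experiment therefore runs in the
low-noise regime where the stated approximation is accurate; the ordering
r_within > r_between whenever σ_b² > 0 is additionally checked across
distinct regimes.

## Reliability and meta-statistics

For the 3AFC view of the matching data, targets and responses are recoded
to their nearest prototype (ties, impossible at odd spacing, would go to
the lower category) and Cronbach's α is computed with observers as items
and stimuli as cases — the orientation that yields one α per group.  Cells
hold each observer's modal response category per target (ties to the lower
code); targets not seen by every observer are dropped so the matrix is
complete.  For the rating design, α is computed on the initial-phase error
matrix (images × observers).  Fisher's combined probability test uses
χ² = −2 Σ ln pᵢ on 2k df; the p-values entering it in the pipeline are the
paired-bootstrap p-values for "radiologists more consistent within
themselves than untrained observers", one per design.

## Determinism and problem sizes

All randomness flows from seeded `numpy` generators; the pipeline derives
independent child seeds per stage from the run seed, and identical
config + seed gives a byte-identical JSON report.  Default problem sizes
(1000 bootstrap, 10,000 permutation iterations at the full cohort sizes)
complete in well under two minutes on one CPU; the validation suite's
Monte-Carlo studies use 50 recovery cohorts and 400 calibration cohorts
with 999-draw nulls, sizes at which the binomial/sampling error is
comfortably below the tolerances they assert.

## Known limitations

* Pairwise-complete correlation over binned profiles makes no small-sample
  correction; with very sparse designs (≪ 2 trials per bin) within-half
  means become noisy and the minimum-3-shared-keys rule can reject
  observers.
* The mild anticonservatism of the shift-permutation test under unequal
  per-bin counts (above) is inherent to the published construction; users
  analyzing designs with strongly unbalanced stimulus presentation should
  prefer balanced presentation or interpret borderline p-values
  cautiously.
* Cronbach's α on modal 3AFC categories treats codes 0/1/2 as numeric, as
  the dummy-coding construction prescribes; it is not an ordinal α.
* The between-observer bootstrap resamples pairs, not observers; its CI
  does not propagate uncertainty in the observer sample itself.
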