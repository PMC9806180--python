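# idiobias

Analysis pipeline for quantifying **idiosyncratic perceptual biases** —
stable, observer-specific patterns of error in perceptual judgments — from
trial-level behavioral data, together with a synthetic-observer simulator
that makes every stage of the chain verifiable by parameter recovery.

The package targets two task designs from observer-performance research on
medical-image perception:

* **matching** — continuous report on a circular morph continuum: a target
  shape drawn from a 147-step loop (3 prototypes × 48 interpolated morphs
  per adjacent pair) is briefly shown, and the observer adjusts a probe
  along the loop to match it.  The trial error is the signed shortest
  circular distance between target and response, in morph units.
* **rating** — realness ratings of real versus GAN-generated lesion images
  on a 0–10 scale, with a repeated-presentation phase for test–retest
  analysis.  Ratings are min–max normalized per observer (removing affine
  response propensity) and the trial error is |normalized rating − ground
  truth| with ground truth 10 for real and 0 for generated images.

## The statistics at the core

For observer *i* with per-stimulus mean-error profile split into random
halves (or into initial/retest phases), consistency is measured by Pearson
correlation pooled on the Fisher *z* scale:

    r_within  = tanh( mean_i atanh r(half1_i, half2_i) )
    r_between = tanh( mean_{i<j} atanh r(half_i, half_j) )

with 95% percentile bootstrap confidence intervals.  A significant
`r_within` is the signature of an idiosyncratic bias; `r_between` measures
bias shared across observers.  Chance levels come from custom permutation
nulls that respect the data's structure:

* **circular-shift null** (matching): one half's binned stimulus labels are
  circularly shifted by a random non-zero offset before correlating,
  destroying alignment while preserving each profile's autocorrelation;
* **label-shuffle null** (rating): image labels of the initial and retest
  error vectors are independently permuted.

One-sided p-values use the plus-one rule `(#{null ≥ observed}+1)/(N+1)`.
Sensitivity is summarized per observer by the JND (0.67449 σ of a Gaussian
fitted to the error histogram) or by d′ = probit(H) − probit(F) after
binarizing normalized ratings at the scale midpoint.  Agreement across
observers is summarized by Cronbach's α (observers as items), and evidence
from the two designs is combined with Fisher's combined probability test,
χ² = −2 Σ ln pᵢ on 2k df.

Because the underlying behavioral datasets are not public, the
`observers` module simulates cohorts whose generative parameters
(stimulus-specific bias profiles, shared group bias, trial noise, lapses,
rating propensities) are known exactly, so recovery of every statistic can
be tested against closed-form variance-components expectations.

## Worked example

```python
import idiobias as ib

config = ib.RunConfig(
    experiment="matching",
    matching_cohort=ib.MatchingCohortConfig(n_radiologists=6, n_untrained=5),
    n_bootstrap=500,
    n_permutation=2000,
    seed=7,
)
report = ib.run_pipeline(config)
for group, g in report["matching"]["groups"].items():
    print(
        f"{group:12s} within r={g['within']['mean_r']:.3f} "
        f"[{g['within']['ci_low']:.3f}, {g['within']['ci_high']:.3f}] "
        f"null<= {g['null_within']['upper_97_5']:.3f} p={g['p_within']:.4f} | "
        f"between r={g['between']['mean_r']:.3f} | "
        f"JND={g['jnd_mean']:.1f} | alpha={g['cronbach_alpha']:.2f}"
    )
```

prints

```
radiologist  within r=0.326 [0.274, 0.379] null<= 0.131 p=0.0005 | between r=0.170 | JND=9.3 | alpha=0.87
untrained    within r=0.237 [0.171, 0.308] null<= 0.150 p=0.0005 | between r=0.045 | JND=9.2 | alpha=0.91
```

Read: both simulated groups show split-half within-observer consistency
(0.326 and 0.237) far above the 97.5% bound of the shift-permutation null
(≈0.13–0.15; p ≈ 5·10⁻⁴ is the plus-one floor at 2000 iterations), i.e.
stable observer-specific biases; the lower between-observer correlations
quantify the bias component shared within a group.  The JND (~9 morph
units) says observers resolve the continuum to about a tenth of its span,
and α summarizes inter-observer agreement of the coarse 3-category
(nearest-prototype) recoding of the same trials.

The same entry point runs the rating design (`experiment="rating"`, with
test–retest consistency, label-shuffle nulls and d′) or both, in which case
the report also carries Fisher's combined test of the group difference in
within-observer consistency across the two designs.  A thin CLI wraps the
library: `idiobias simulate|analyze|all --config cfg.yaml --seed 1 --out dir`
(see `idiobias --help`); `simulate` writes trial CSVs plus a ground-truth
JSON sidecar, `analyze` ingests and validates trial CSVs of either schema.

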