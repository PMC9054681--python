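# Methods

## Proportional-odds model of diagnosis severity

The ordered diagnosis Y (NCI < MCI < AD) is modeled by the cumulative-logit
regression P(Y ≤ k | x) = logistic(α_k − xβ) with strictly increasing
cutpoints α and a single slope vector β shared across cut levels.  The sign
convention (η = xβ entering negatively inside the logistic) makes a positive
coefficient shift mass toward AD; the synthetic-data generator uses the
identical convention, so recovered coefficients compare directly with
generating ones.

Maximum likelihood is computed through statsmodels' `OrderedModel`
(logit link), which parameterizes the thresholds internally as the first
cutpoint plus log-gaps, guaranteeing monotone cutpoints without
constraints.  The primary optimizer is BFGS with gradient tolerance 1e-8
and an L-BFGS retry; non-convergence (typical cause: complete separation)
raises a `FitError` naming the term set rather than returning a dubious
fit.  The intercept-only model is fitted the same way with an empty design;
its fitted probabilities equal the observed level frequencies (a property
of the cumulative-logit MLE used as a test oracle).

Continuous miRNA levels enter on the natural-log scale by default (levels
are positive and span orders of magnitude; the analysis axis is
logarithmic), written `log(mir20b)` in the term syntax; the raw scale is
available by omitting the wrapper.  Categorical predictors are
dummy-encoded against their first level; the reference level is absorbed by
the cutpoints.  A rank check on the design (with implicit constant) rejects
collinear term sets at fit time.

Drop-one analysis of deviance refits the model without each term and
reports χ² = 2(ℓ_full − ℓ_reduced) on df equal to the parameter-count
difference.  The scheme respects marginality (a Type-II-like ordering):
dropping a main effect also removes every interaction involving it, while
interactions are removed alone.  A reduced model that fails to converge
produces a per-term error entry without aborting the other terms.

## Ordinal coefficient of discrimination D

With p_c,i the fitted probability of subject i's observed category,
D = mean(p_c) − (1 − mean(p_c)) = 2·mean(p_c) − 1.  The defining
subtraction is of the *remaining* predicted probability mass from the mass
credited to the truth; the reduction to 2·mean(p_c) − 1 is algebraic.  For
binary outcomes with balanced classes this equals Tjur's coefficient of
discrimination exactly (asserted to 1e-12 against a direct two-group-means
oracle in the tests).  The statistic is bounded in [−1, 1]; an
uninformative K-level model scores 2/K − 1, so three-level models below
mean(p_c) = ½ produce negative D even when clearly better than chance.
D is not the likelihood: the full model's D can fall below a reduced
model's on the same data, which is documented rather than asserted.

Partial D per effect: compute D for the full model and for each drop-one
reduced model (each on its own fitted probabilities — the reduced model is
refitted, not the full model with a zeroed term), Fisher-z transform
(atanh) the square roots, difference, back-transform, square.  Numerical
policy: negative D clamps to 0 before the square root (the transform is
undefined otherwise; worse-than-chance discrimination is treated as zero
explanatory contribution); √D is capped at 1 − 1e-12 to keep atanh finite;
a negative z-difference floors the partial at 0, so partials are reported
on a nonnegative scale.  A consequence worth noting when reading results:
whenever the full-model D is ≤ 0, every partial is 0 by the clamping rule;
partials are informative for strongly discriminating models
(mean(p_c) > ½).

## X-linked Hardy–Weinberg test

Variant used: the pooled-frequency Pearson χ² over all five cells (female
AA/AG/GG, male A/G) with df = (3−1) + (2−1) − 1 = 2, the one estimated
quantity being the pooled allele frequency
q̂ = (n_AG + 2·n_GG + n_G) / (2·n_female + n_male).  This jointly tests
female-genotype HWE and male–female allele-frequency homogeneity, and on
the packaged worked-example counts (229/24/1; 312/14) gives χ² = 0.510 and
p = 0.775, confirming the variant against an independent expected-count
computation.  No continuity correction is applied.  Expected cells below 5
are flagged; an exactly zero expected cell (monomorphic sample) is an error
since the test is then undefined and an exact test (not provided) would be
needed.  The single GG female in the worked example is included: small
counts weaken the approximation but do not invalidate the statistic.

Calibration behavior at rare alleles: at q ≈ 0.048 with 254 females the
expected GG cell is ≈ 0.58, and the simulated null distribution of the
statistic is visibly lumpy (Kolmogorov distance ≈ 0.09 from χ²₂ over
10,000 replicates) while the α = 0.05 rejection rate remains calibrated
(≈ 4.9%).  The distribution-level Q–Q property is therefore tested at
q = 0.3, where all expected cells exceed 5 and the measured Kolmogorov
distance is ≈ 0.008.  This is a property of Pearson's statistic under
sparse cells, not of the implementation.

## Fura-2 segmentation and measures

Phase detection is deterministic given the trace and parameters.

* **Onset I** — first cycle whose ratio exceeds (baseline mean +
  `onset_k`·baseline SD) for `onset_run` consecutive cycles, the baseline
  being every cycle before the candidate (at least `min_baseline` = 5).
  Defaults `onset_k` = 3, `onset_run` = 3, the standard sustained-threshold
  convention for event onset in noisy physiological signals.
* **Peak P** — argmax of the raw ratio at or after I, first occurrence on
  ties.
* **Discharge end II** — the active-to-passive elbow: backward differences
  of the trace are compared with the mean decay rate of the first fully
  post-peak differences, and II is the first cycle where the rate magnitude
  drops below `discharge_frac` (default 0.2) of that reference.  On noisy
  traces the differences are taken on a centered moving average
  (`smooth_window` = 7 cycles) and the half-window lag is subtracted;
  per-cycle raw differences at realistic noise (≈ 1% of amplitude) are
  noise-dominated, and the smoothed rule recovers II within ±3 cycles in
  ≥ 95% of traces at that noise level.  When the pre-onset baseline shows
  zero noise the smoothing is skipped, and the raw rule recovers the
  generating indices exactly on idealized traces for any tail rate.

A trace with no detectable onset is a non-responder — an annotation, not an
error — and is excluded from batch tables with a count of exclusions, since
non-responding cells in a KCl-depolarization experiment are likely not
neurons.  Responder status additionally honors an optional `min_amplitude`
threshold (ratio units, default 0: the stimulus-response threshold is a
user decision, not a packaged constant).

Measures: pre-flow length and baseline amplitude are computed on the raw
ratio; b, b′ and the peak amplitude *a* are onset-aligned and
baseline-subtracted (baseline = mean raw ratio over [0, I), i.e. the
segment mean, not the value at I); *a′* is the P→II height of the min–max
scaled trace (min = 0, max = 1), hence invariant under affine transforms of
the raw signal.  Durations are in cycles (the recording's native unit); an
optional seconds-per-cycle factor adds converted columns but is never
assumed.  The F380 division guard defaults to 1e-6 of the channel median.

## Synthetic-data generators

All generators draw from `numpy.random.default_rng(seed)`; per-trace
streams in batches are spawned from one `SeedSequence`, so identical seeds
give bit-identical output.

* **Cohorts** — miRNA levels are log-normal per region (levels are positive
  and analyzed on a log axis); defaults use illustrative region log-means
  (TL 0.0, CB −0.5, PCC 0.5; SD 1.0) since region-specific distribution
  parameters are not pinned down by published summaries.  APOE ε4 presence
  is Bernoulli(0.30), a typical carrier fraction for an elderly
  memory-clinic mix.  Diagnosis is drawn from the latent cumulative-logit
  model with default cutpoints (−0.5, 1.0) and effects
  η = β_miR·log(mir) + β_ε4·e4 + β_int·log(mir)·e4.  Age and sex are filler
  demographics completing the cohort schema; they do not enter the latent
  model.  What this emulates: the marginal design of a three-region
  autopsy-cohort analysis.  What it does not: measurement error in qPCR
  quantitation, region-correlated repeated measures from the same donors,
  or diagnosis misclassification — so passing recovery tests show the
  estimator is correct under its own assumptions, not that those
  assumptions hold in any particular tissue archive.
* **X genotypes** — female genotypes multinomial((1−q)², 2q(1−q), q²), male
  hemizygotes binomial(q); allele totals are conserved by construction.
* **Fura traces** — piecewise idealized curve: constant baseline; linear
  rise from one increment above baseline at I (so influx is first
  detectable exactly at I) to baseline + a at P; linear fall by a′ at II;
  exponential tail decaying toward baseline at `tail_rate` per cycle;
  additive Gaussian noise.  Linear rise/discharge is the simplest shape
  preserving all six measures.  Defaults (500 cycles, I/P/II at
  100/140/220, baseline 1.0, a = 1.2, a′ = 1.0, tail_rate = 0.005,
  noise 0.012 = 1% of a) keep the tail's initial slope below
  `discharge_frac` × the discharge rate, which is the regime where the
  elbow rule is well-posed.  Real recordings additionally show baseline
  drift, photobleaching and multi-peaked responses, which the generator
  does not emulate.

## Problem sizes used in the checks

Simulation-based tests run at the sizes that make their guarantees sharp
but cheap: null-frequency convergence at n = 30,000 (3 SE), Wald coverage
with 100 replicates at n = 5,000, likelihood-ratio type-I error with 1,000
replicates at n = 500, HWE calibration with 10,000 replicates at the
worked example's sample sizes, and Fura recovery over 200 seeded traces.
The acceptance script reports the same quantities at moderately reduced
replicate counts (100 / 400 / 100) chosen so a full run completes in about
a minute on one CPU.

## Known limitations

* No proportional-odds assumption diagnostics, survey weights or Bayesian
  alternatives; duplicate rows are allowed and unweighted.
* Partial D is reported nonnegative by construction; it cannot distinguish
  "no contribution" from "harmful-to-discrimination" terms.
* The HWE test is asymptotic; with rare alleles the flagged small cells
  mean p-values in the body of the distribution are approximate (tails are
  calibrated at the worked example's scale).
* Trace segmentation assumes a single transient per recording; traces with
  repeated stimulations should be windowed upstream.
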