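# Methods

`socddm` implements an analysis pipeline for social-influence bias in
two-alternative perceptual decisions: observers judge the rotation
direction of a structure-from-motion cylinder whose binocular disparity
controls the available sensory evidence, after receiving trial-by-trial
"left"/"right" advice from a social partner.  The package has three layers:
psychometric (choice-proportion) analysis, a full drift-diffusion account of
choices and reaction times, and a synthetic-cohort generator that makes the
whole pipeline testable end to end without any behavioral data release.

## The decision model

A decision variable performs Brownian motion with drift `v` (evidence
units/s) and diffusion coefficient `s` between absorbing boundaries at 0 and
`a`; absorption at the upper boundary is read out as a "left" response (and
positive drift points leftward), absorption at the lower boundary as
"right".  The start is parameterized relatively, `z_rel` in (0, 1) with 0.5
the unbiased midpoint.  Observed RT = first-passage time + non-decision time
`Ter`.  Across trials, drift is Normal(`v`, `eta`), the starting point is
uniform over a range `sz` (absolute evidence units) and the non-decision
time uniform over a range `st` seconds.

`s` is not jointly identifiable with (`v`, `a`, `z`, `eta`, `sz`) and is
fixed by convention at `s = 0.1` (the dominant convention in the
diffusion-fitting literature); it is configurable and recorded in all
outputs.  All reported parameter magnitudes are therefore scale-qualified
by this convention.

### Numerics

First-passage densities and CDFs use two exact expansions selected by the
scaled time `tau = (t - Ter) / (a/s)^2`:

* small `tau`: method-of-images sums — Gaussian images for the density,
  and an inverse-Gaussian/erfc image sum for the CDF, evaluated in log
  space so extreme drifts cannot overflow;
* large `tau`: the spectral sine series and its closed-form time integral.

Truncation is adaptive with an absolute error of 1e-7 per evaluation.  The
scalar switch point is `tau = 0.12`; the vectorized CDF kernel used in
fitting switches at `tau = 0.035`, where the spectral branch's worst-case
cancellation error `exp(w^2/2 tau) * 1e-16` still sits well below the series
tolerance.  Across-trial variability is handled by quadrature: 10-node
Gauss–Hermite over `eta` and 10-node Gauss–Legendre over each of `sz` and
`st`; a parameter at zero collapses its dimension.  Quadrature error is
dominated by the series tolerance for the smooth integrands involved.

The brute-force oracle is an Euler–Maruyama path simulator (default
`dt = 1e-4` s, absorption cap 30 s; non-absorbed paths are flagged, never
dropped).  A Brownian-bridge crossing test at every step detects boundary
excursions between grid points, removing the O(sqrt(dt)) first-passage bias
of naive Euler stepping; this is what makes a 1e6-trial simulation a usable
2%-level check of the analytic series.  Path noise comes from an inlined
xoshiro256+ generator with polar-method Gaussians (seeded via splitmix64);
per-trial variability draws use numpy's PCG64.  All randomness descends
from explicit seeds through `numpy.random.SeedSequence`.

## Psychometrics

Choice proportions are modelled as `P(left | d) = Phi((d - mu)/sigma)` over
signed disparity `d`; `sigma` is the discrimination threshold, and
disparities are normalized per observer to [-1, 1] before pooling.
Estimation is binomial maximum likelihood with a probit link (a compact
Newton/Fisher-scoring routine on aggregated counts; an unweighted
least-squares mode is retained behind a flag).  No lapse-rate parameter is
included — a known limitation: real children's asymptotic errors inflate
fitted thresholds slightly, which the synthetic data do not emulate.

The social-influence bias of an observer is the *shift*: the signed
horizontal offset between the curves fitted to advice-left and advice-right
trials under a common slope, positive toward the advised direction.  Whether
splitting by advice is warranted is tested by comparing a single pooled
curve against the paired shared-slope model, with two p-values: an
extra-sum-of-squares F-style test on proportions, and (the default) a
permutation test that re-draws the advice split of responses within each
disparity (2,000 permutations by default).  Both adjusted R² values are
computed on the advice-split proportions with the two-curve parameter
count, so identical advice conditions score identically.  Per-disparity
advice effects across participants use two-sided Wilcoxon rank-sum tests
with Bonferroni correction.

## Synthetic cohorts

Each simulated participant completes the study design: 210 trials in 10
blocks of 21, seven signed disparities (three magnitudes, both signs, zero)
with 3 trials per level per block, advice correct on exactly 2/3 of trials
at every nonzero disparity (the stricter per-level reading; a global-2/3
mode is switchable) and balanced 50:50 at zero disparity, pseudorandomly
interleaved.  Disparity ranges follow the pre-measured threshold bands
(high ±0.06/0.04/0.02°, mid ±0.03/0.02/0.01°, low ±0.015/0.01/0.005°; mid
is the default).

Advice acts through two dissociable mechanisms, per trial:

* drift bias: `v = k_v * d_norm + sign(advice) * dv_advice`
* starting-point bias: `z_rel = 0.5 + sign(advice) * z_advice`

Base parameters for all presets: `a = 0.14`, `Ter = 0.35 s`, `eta = 0.08`,
`sz = 0.02`, `st = 0.2 s` — chosen to give child-plausible RTs (median
≈ 0.7 s) and ceiling accuracy near 95%.  Two constants are *calibrated*, not
chosen: `k_v` is root-found so accuracy at the largest disparity is 0.95,
and the adolescent preset's `dv_advice` is root-found so the population
psychometric shift equals 0.419 normalized disparity.  Both calibrations
run on analytic choice probabilities (no simulation noise) at import time;
`scripts/calibrate.py` prints them.  The younger-neurotypical and autistic
presets carry starting-point biases (`z_advice` = 0.02/0.03 rising with age
for NT 6–11, 0.06 for the autistic groups, 0 for NT 12–14), reproducing the
qualitative pattern of a prior-expectation effect in the younger and
autistic groups versus an evidence-level effect in neurotypical
adolescents.  An optional anticonformity term (a reversed starting-point
displacement at zero disparity only) is provided but off by default: no
mechanism is asserted for the zero-disparity opposition effect seen in the
youngest children.  Group sizes default to the study's cells (e.g. NT 12–14
adult-advice n = 26).

What the generator does *not* emulate: learning or fatigue across blocks,
advisor-identity effects, participant heterogeneity within a group (all
members share the profile parameters), lapses, and any violation of the
diffusion model itself.  Passing recovery tests therefore demonstrates that
the pipeline is correct and well-calibrated under its own assumptions, not
that those assumptions hold for real children.

Exclusion rules: trials with RT strictly greater than 8 s are removed;
participants below 85% correct at the largest disparity (exactly 85%
passes) or with strictly more than 80% of zero-disparity responses toward
one side are removed entirely.  Participant statistics are computed on
RT-surviving trials, making the operation idempotent and order-independent;
flagged rows are preserved on disk.

## Model fitting and comparison

Group-level trials are pooled into disparity × advice cells.  Within each
cell, each response boundary's RTs are binned at their observed
{.1,.3,.5,.7,.9} quantiles (6 bins; boundaries with fewer than 10 responses
collapse to 3 bins, fewer than 2 to a single bin), and parameters maximize
the multinomial log-likelihood of the bin counts under the model's
predicted bin probabilities.

Five variants differ in which parameters may vary with advice direction:
none (1), `z` only (2), `v` only (3), `v` and `z` (4), all (5).  Drift is
always free per disparity; under the default nuisance tying `a, Ter, eta,
sz, st` are shared across disparities (with 7 disparities, k = 13, 14, 20,
21, 26 — freeing every parameter per disparity, as a literal reading of the
protocol would have it, is unidentifiable at ~30 trials per cell; a
`strict_disparity_tying` flag provides it anyway).  Comparison uses
BIC = k ln(n) − 2 lnL; ties are reported, not broken.

Optimization is bounded Powell from a choice-fraction heuristic start plus
seeded random restarts (default 5; the spread of restart log-likelihoods is
reported).  `fit_all_models` warm-starts each richer model from its best
fitted sub-model, which guarantees the fitted log-likelihoods respect the
nesting partial order to within optimizer tolerance (1e-3 log-likelihood
units).

Uncertainty for the advice effects — the per-disparity drift
advice-differences and the starting-point displacement toward advice —
comes from a *profile bootstrap*: trials are resampled with replacement
within cells, and each replicate re-estimates drift and starting-point
parameters by warm-started coordinate descent with the nuisance parameters
held at the point estimate (a full re-fit per replicate is computationally
out of reach; holding the nuisance fixed narrows the intervals slightly,
which is acceptable for effect-detection at the effect sizes of interest
but should not be read as exact coverage for the nuisance-correlated
components).  Percentile 95% intervals are reported with
Bonferroni-corrected significance flags (drift differences flagged against
0, starting point against the 0.5 midpoint).  The conformity split
(advice × conformed cells) is provided for descriptive re-fits with an
explicit caveat that conditioning on the response biases parameter
interpretation.

## Problem sizes used in the shipped checks

The acceptance checks run at sizes chosen for desk-class hardware while
keeping every stated tolerance: density conservation over a 50-point random
parameter sweep; oracle equivalence at 1e6 Euler trials (histogram bins of
0.2 s on [0.3, 2.5] s, so Monte-Carlo noise sits well inside the 2% band)
plus a 5e4-trial KS check; null and dual-mechanism recovery at ~1e4 trials;
model-selection recovery over 3 replicate cohorts of 17 participants
(~3,500 trials each, every replicate must select the dual-mechanism model);
shift calibration over 40 cohorts of 26 participants; type-I error over 500
six-participant null cohorts (400 permutations each); mechanism
dissociation over 3 replicates per mechanism (200 bootstrap replicates
each).  The trial simulator and fits are deterministic given the seeds
fixed in the tests.

At ~1e4 trials the advice-difference in drift is recovered with a
relative sampling SD of roughly 10% (the starting point trades off against
drift, and quantile binning discards some information relative to full
likelihood), so single-cohort recovery errors of 15-20% occur for some
seeds; the starting points themselves are recovered within ~0.015.

## Known limitations

* The probit psychometric curve is a (deliberately conventional)
  misspecification of the diffusion choice function; combined with the 2/3
  advice-validity design weights it leaves a residual population "shift" of
  ~0.002 under the null — two orders of magnitude below cohort noise, and
  absorbed consistently by the calibration.
* Group-level pooling assumes participant homogeneity; no hierarchical
  estimation is offered.
* The BIC selection-uncertainty procedure (paired comparison across
  bootstrap replicates) and the profile bootstrap are labelled
  interpretations; the field reports group-level CIs from single fits
  without a canonical recipe.
* Collapsing bounds, urgency signals, lapse rates and non-Normal/Uniform
  variability forms are out of scope.
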