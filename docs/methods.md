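# Methods

## Overview

`rapsig` implements an in-silico drug-response signature pipeline of the
kind used to ask whether tumors will respond to a pathway inhibitor from
expression data alone, together with the downstream analyses that validate
such a signature: dose-response (EC50) fitting on cell-line viability
screens and tumor-growth-inhibition (TGI) analysis of xenograft trials.
The motivating application is rapamycin (an mTOR inhibitor) in breast
cancer, where the signature is trained on a small panel of drug-treated
versus untreated cell-line profiles and then applied to large
subtype-annotated tumor cohorts.

The guiding biological premise: a tumor whose expression over the
signature genes resembles *untreated* cells still has the drug's target
pathway running and is predicted **sensitive**; a tumor resembling
*treated* cells (pathway already down) is predicted **resistant**.
Sensitivity is therefore defined as 1 − P(treated).

## Signature construction

Given a linear-scale probe × sample training matrix with treated/control
labels, `build_signature` runs:

1. **Quantile normalization** across samples: every column's sorted values
   are replaced by the across-column mean of sorted values.  Ties share
   the mean of the reference values at their rank positions (average
   ranks, linearly interpolated), which makes the operation deterministic
   and idempotent for tie-free data.
2. **log2 transform** with a floor (default 1.0 intensity unit, matching
   MAS5-style intensities that are bounded away from zero).
3. **Probe ranking** by the absolute pooled-variance two-sample
   t-statistic between classes; ties break by probe id.  The top *k*
   probes (default *k* = 200) form the signature.  Constant probes get
   t = 0 and sort last.
4. **Reference statistics.**  The sorted across-sample mean of the
   selected submatrix is stored as the signature's reference quantiles;
   after mapping the training samples through those quantiles, per-probe
   means and SDs are stored.  These frozen statistics are what every
   future sample is standardized against.
5. **Metagene.**  The standardized submatrix is row-centered and
   decomposed by SVD; the unit-norm first left singular vector gives the
   per-probe weights and each sample's projection is its metagene score.
   The sign is fixed so treated samples score higher than controls.
6. **Bayesian probit regression** of the class label on the metagene
   score, fitted with the Albert–Chib latent-variable Gibbs sampler under
   independent Normal(0, prior_sd²) priors on intercept and slope
   (defaults: 5,000 iterations, 1,000 burn-in, prior_sd = 10, fixed seed).
   Prediction averages the probit probability over the post-burn-in
   draws.  A maximum-likelihood logistic fit is available behind
   `SignatureConfig(method="logistic")` for users who prefer a
   point-estimate classifier.

### Scoring new samples

`standardize_to_reference` restricts a cohort to the signature probes,
rank-maps **each sample independently** onto the stored reference
quantiles, and z-scores per probe with the frozen training statistics.
Because the mapping is rank-based, predictions are invariant to any
monotone transform applied uniformly to a cohort (affine rescaling
included), and because it is per-sample, a sample's prediction never
depends on which other samples happen to be in the file.  A
`cohort_quantile` flag reproduces joint whole-cohort quantile
normalization for parity experiments; that mode is explicitly
cohort-dependent.

### Cross-validation

`loocv` rebuilds the entire signature — probe re-selection included — for
each held-out sample, then scores the sample through the frozen-reference
path above.  An instrumentation counter on the ranking step lets the test
suite assert that selection really does happen inside every fold, so the
reported accuracy carries no selection leakage.  Folds that would leave a
class with fewer than two samples are marked undefined.

### Sampler behavior and its limits

When the two classes are linearly separable in metagene score — the usual
situation for a training set with a real treatment effect — the probit
likelihood is flat over a long ridge of slopes and the posterior is held
proper only by the prior.  The Albert–Chib chain then mixes slowly *in the
coefficients*, while the predictive probabilities at and beyond the class
centers are saturated and stable (they change by < 0.01 when the chain
length is doubled).  Probabilities in the middle of a wide empty margin
are genuinely posterior-uncertain and the sampler can misplace them by
~0.1 relative to a dense 2-D grid integration of the same posterior; for
overlapping classes the sampler agrees with the grid oracle to better
than 0.01 everywhere.  The convergence warning therefore monitors
split-half *predictive* drift at the training scores with a tolerance of
0.1 — chosen because routine separable fits show drift up to ~0.09 at the
gap edges — and flags only gross instability.  It warns, never raises.

## Dose-response (EC50)

The viability model is the constrained sigmoid

    v(d) = bottom + (top − bottom) / (1 + (d/EC50)^hill)

with hill fixed at 1 (configurable), following the "constrained
sigmoidal" preset of standard curve-fitting software.  Plates follow the
screen design: a vehicle well plus nine doses from 0.1 pM to 1 nM.

Fitting choices, made for statistical rather than cosmetic reasons:

* residuals are taken on **log viability** (geometric mean per dose),
  because fluorescence noise is multiplicative — unweighted linear
  residuals let the noisy high-viability wells swamp the informative
  low-viability tail and inflate EC50 error by ~4× in simulation;
* **top is a free parameter** bounded within a factor *e* of the vehicle
  geometric mean, with the vehicle entering the fit as the d = 0
  observation.  Hard-fixing top to the (noisy) vehicle mean propagates
  that noise directly into EC50 and roughly doubles its error;
* **bottom** is constrained to (0, vehicle mean];
* a deterministic multistart over 25 log-spaced EC50 values, bounded one
  decade beyond the dose range, avoids local minima; fits landing on the
  EC50 bound or with < 10% dynamic range are flagged `converged=False`
  (no resolvable inhibition reports EC50 at the upper bound).

Measured on the default generator (10% multiplicative noise, 3
replicates, 100 seeds): median |relative EC50 error| ≈ 4%, bias < 1%.
The fit is exactly scale-equivariant: doses × c gives EC50 × c.

The association between predicted sensitivity and potency is ordinary
least squares of **log10 EC50** on sensitivity (doses span four orders of
magnitude, so raw EC50 would be lever-dominated); slope, Pearson r and
the two-sided p-value for zero slope are returned, using converged fits
only.  A raw-EC50 variant is available via `use_log10=False`.

## Xenograft efficacy

Volumes come from two-dimensional caliper readings via the ellipsoid
approximation V = l·w²/2 (mm³).  Group growth curves are per-(group, day)
means with SEM = SD/√n (a single-animal point reports SEM 0 and is
identifiable by its n).  Percent tumor-growth inhibition is the
endpoint-based, baseline-subtracted definition

    TGI = 100 × (1 − ΔV_treated / ΔV_control),   ΔV = V(final) − V(day 0)

evaluated at the last day measured in both arms; a non-growing control
arm makes the quantity undefined and raises.  Group comparisons use the
two-sided Student's t-test with pooled variance (Welch behind a flag),
with P < 0.05 called significant.  Stratified randomization sorts animals
by baseline volume into consecutive blocks of one animal per arm and
permutes each block under a seed.

## The synthetic-data generator

Every generator is a pure function of its `SimulationConfig` (seed
included).  The probe-space "biology" — per-probe baselines uniform on
[6, 12] log2, the planted responsive gene set and its per-gene effect
signs — derives from `structure_seed` (default: `seed`), so replicate
cohorts or re-noised training sets can share one biology while varying
sampling noise.

* **Training sets** default to 5 treated vs 18 control samples on a
  22,283-probe array.  The treatment effect is planted **gene-wise**:
  whole genes respond, all of a gene's probes shifting together by
  `effect_sd` within-class SDs (default 2 × noise_sd = 1.0 log2 unit,
  with noise_sd = 0.5), for a total of `n_planted` = 200 responsive
  probes.  Gene-wise planting is why fitted signatures contain multi-probe
  genes and their unique-gene count falls below the probe count, as in
  real array signatures.
* **Cohorts** draw a per-sample pathway activation from
  Normal(subtype mean, 0.35) and set treatment-likeness τ = 0.5 −
  activation, so strongly pathway-driven tumors sit on the untreated-like
  (sensitive) side of the decision midpoint.  Default subtype means
  (basal-like 0.55 > HER2 0.16 > luminal B 0.07 > normal-like −0.12 >
  luminal A −0.32) were chosen so that the normal-quantile share of each
  stratum falling on the sensitive side matches the frequencies reported
  for large breast-cancer cohorts; the ordering is a generator convention
  mirroring the published qualitative ranking, not a claim about biology.
  Default stratum sizes total 1,401 samples.
* **Viability plates** apply multiplicative lognormal noise (CV 10%) to
  the hill-1 sigmoid on the screen's 10-dose ladder, 3 replicates.
* **Xenograft trials** enroll baselines uniform on [50, 100] mm³,
  randomize by baseline, and grow each animal exponentially with a
  lognormal individual rate (control doubling time ~1 week, rate CV 10%)
  plus 5% lognormal measurement noise, reported as caliper pairs with
  aspect ratio uniform on [0.5, 1].  In a drug arm the rate is deflected
  so the animal's *expected endpoint volume gain* is (1 − tgi_true) times
  its control-trajectory gain.  Deflecting the gain rather than the raw
  rate is deliberate: scaling an exponential rate by (1 − TGI) compounds
  over the trial and drives endpoint TGI estimates to ~100% regardless of
  the programmed value, whereas the gain-based construction makes the
  endpoint estimator converge to `tgi_true` as group size grows.

What the generator does *not* emulate: probe-level array chemistry,
batch/study effects across cohorts (each synthetic cohort is internally
homogeneous), censoring or dropout in animal studies, and any real
correlation structure between genes beyond the planted program.  Passing
recovery tests therefore demonstrates that the estimators are correct and
calibrated under the stated noise models, not that the biological signal
in any real dataset is as clean.

## Problem sizes used in validation

The automated checks run the full default training size (22,283 probes,
23 samples, LOOCV with per-fold refits), 100 replicate cohorts of 125
samples for the subtype-ranking stability check, 100 seeded plates for
EC50 recovery, 50 seeded trials per arm for TGI recovery, and 10,000
simulated null trials for t-test calibration.  The seven-model efficacy
summary programs per-model suppressions spanning 0.77–0.99 (mean 0.94)
for the mTOR-inhibitor arm and 0.02–0.52 (mean 0.36) for doxorubicin and
recomputes the realized percentages from simulated trials.

## Known limitations

* Mid-margin probabilities under complete class separation inherit the
  sampler's slow coefficient mixing (see above); classifications at 0.5
  are unaffected in practice because scored samples rarely sit in the
  empty margin, but per-sample probabilities between roughly 0.2 and 0.8
  should be read as having ±0.1 Monte Carlo uncertainty in that regime.
* The probe-selection statistic (pooled t) and the LOOCV-with-reselection
  protocol are reasonable defaults, not the only defensible choices; both
  are isolated behind `SignatureConfig` and `loocv`.
* EC50 is only identified within about a decade of the dose range; true
  values above the top dose are flagged unconverged rather than
  extrapolated.
* Only the endpoint TGI definition is implemented; window-averaged
  variants would need the full curves, which `growth_curves` exposes.
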