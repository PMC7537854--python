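# Methods

## Estimand and estimator

The target is the age-specific risk of female genital mutilation summarized
by the survival function S(t) = P(T > t), the probability of not being cut
by completed age t, for t = 0..49.  Ages are a discrete grid of completed
years: an event "at age 7" occurs in the interval [7, 8), and S(t) is
survival *through* age t.  No continuous-time interpolation is attempted —
survey respondents report whole years of age, and the estimator operates on
single years of age.

The estimator is the weighted Kaplan–Meier product limit
Ŝ(t) = ∏_{a=0..t} (1 − d_a/n_a) with weighted event counts d_a and weighted
risk sets n_a.  Conventions:

* **Ties.** A person censored at age a remains in the risk set for events at
  a (the standard convention; self reports censor at the interview age, so
  the person was observably uncut through that whole year).
* **Exhausted risk sets.** A factor with n_a = 0 is defined as 1, so curves
  extend flat past the last observed age.  This matters for young cohorts
  (proxy-reported daughters are at most 14): their curves are informative
  only up to the oldest observed age and flat beyond it.
* **Weights.** Any positive rescaling of the weights leaves Ŝ unchanged;
  this scale invariance is what makes de-normalization safe within surveys
  and meaningful across them.

## Design-based variance

Var(log Ŝ(t)) is estimated by influence-function linearization with the
ultimate-cluster approximation.  The influence of record i (time t_i, event
e_i, weight w_i) on log Ŝ(t) is

    z_i(t) = Σ_{a ≤ min(t, t_i)} [1/(n_a − d_a) − 1/n_a]  −  e_i·1(t_i ≤ t)/(n_{t_i} − d_{t_i})

PSU totals of w_i·z_i(t) are formed per primary sampling unit, and the
variance is the stratified with-replacement between-PSU variance of those
totals, Σ_h n_h/(n_h−1) Σ_j (z_hj − z̄_h)²; finally SE(Ŝ) = Ŝ·SE(log Ŝ).
With every record its own PSU in one stratum this reduces to (approximately)
the binomial SE, which the tests confirm.

Choices and edge cases:

* Strata with a single PSU cannot contribute a between-PSU variance; the
  default is a hard error naming the stratum, with `lonely_psu="collapse"`
  merging lonely strata into a neighbouring stratum as an opt-in.
* Ages where Ŝ = 0 get SE = 0 (the log-scale variance is undefined there;
  the estimate is degenerate anyway).
* A Rao–Wu rescaling PSU bootstrap (resample n_h−1 PSUs with replacement per
  stratum, rescale weights by count·n_h/(n_h−1)) is shipped as the
  *validation oracle*: slower, but free of linearization error.  The
  linearized SE is required to track it within 10% on a clustered fixture.
* Pooled analyses treat each survey's strata as distinct strata of one
  super-design (identifiers are namespaced `survey:stratum`, `survey:psu`).

Confidence intervals are symmetric normal intervals on log Ŝ, exponentiated
and truncated to [0, 1] (default), with log(−log) intervals as an option.
Curve comparisons (urban vs rural) are per-age z-tests on Ŝ_a − Ŝ_b with
independent variances; any design covariance between the groups is ignored,
which is exact when the groups partition clusters.

## Event-history reconstruction

Raw survey rows become event records as follows: a cut person with a valid
event age a ≤ current age → (time=a, event); an uncut person →
(time=current age, censored); anything else is excluded and *counted*, never
imputed — cut with missing or "don't know" age, event age exceeding current
age, interview age outside the instrument's range, birth year before 1960.
The exclusion log satisfies input = retained + excluded per survey, and the
pipeline asserts this conservation end to end.

Specific decisions:

* **"During infancy"** replies map to age 0 and set `infancy_flag`, so
  sensitivity re-runs can drop or remap them.  Mapping to 0 is conservative
  (keeps the event, assigns the earliest consistent age).
* **Birth year** = interview year − current age.  Century-month codes are
  deliberately out of scope; cohorts are whole-year constructs.
* **Cohorts** are 1-, 5- or 10-year classes anchored at 1960 with an open
  terminal class "After 2009"; birth years before 1960 are excluded to match
  the earliest cohort analysed.
* Proxy records (daughters) are structurally capped at time ≤ 14.

## Synthetic data generator

The generator emulates what the pipeline consumes, with known truth:

* **Hazard model.** A baseline per-age hazard h0(a) (default concentrated at
  ages 0–15, zero from 20, lifetime risk ≈ 48%) shifted on the log-odds
  scale: logit h = logit h0 + δ·(birth year − 1990) + β·rural.  Defaults
  δ = −0.03 (a steady secular decline) and β = 0.6 (rural excess) are
  realistic magnitudes for practising countries; the logistic form is a
  testing device, chosen as the simplest monotone cohort decline, not a
  claim about any real data-generating process.  The logistic link keeps
  every shifted hazard inside [0, 1] by construction (structural 0/1 hazards
  are preserved), so no clipping step is needed.
* **Design.** Strata × clusters × households, one eligible woman (15–49 at
  interview) per household, daughters ~ Poisson(1.2) aged 0–14.  Residence
  is assigned at *cluster* level, mirroring residence-homogeneous census
  enumeration areas.  Two-stage sampling (clusters within strata, households
  within clusters) with per-stratum sample sizes; unequal fractions produce
  unequal weights.  Weights are inverse inclusion probabilities normalized
  to mean 1 over sampled women (the DHS convention), daughters inherit their
  mother's weight.
* **Misreporting.** Event-age heaping rounds to the nearest multiple of 5
  (ties toward zero, applied to event ages only, capped at the reported
  current age so records stay internally consistent), with probability 0.2;
  events at ages 0–1 are recorded as "during infancy" with probability
  0.25.  Current-age heaping, non-response, and status misreporting are not
  modelled — so passing tests say nothing about those real-data problems.
* Identical specs (including seed) produce byte-identical CSV output.

What the generator does *not* emulate: household rosters beyond
mother–daughter pairs, orphan daughters, migration between residences,
survey non-response, or social-desirability bias in reported status.
Validation against it therefore demonstrates correctness of the estimation
machinery under the declared design, not robustness to those field problems.

## Pipeline

`run_analysis` performs region exclusion (to keep pooled surveys
geographically comparable), event reconstruction, de-normalization
(weight × population total / sampled women), pooling, and per-cell weighted
KM with CIs, where cells are cohort × {nothing | residence | country}.
Grouping splits the pooled table once rather than re-running ingestion per
cell.  Outputs (curves, unweighted cohort counts, exclusion log, JSON run
report) are written with fixed float formatting and sorted keys; a config
hash excludes the output directory, so identical configs give byte-identical
outputs wherever they are written.  Plots are optional artifacts; plotting
failures never fail a run.

## Validation study sizes

The shipped validation uses problem sizes that keep the full suite to a few
minutes on one CPU while leaving Monte-Carlo error well below the margins
tested: 200 random fixtures (n ≤ 50) for oracle equivalence at 1e-12; a
2-stratum × 20-PSU × 25-women clustered design with a 500-replicate
bootstrap for SE validation (10% tolerance); 1000 replicates of n = 2000
simple random samples for CI coverage (target 92–97% at ages 5/10/15);
two pooled surveys with ≈ 5000 records per 10-year cohort, 3 replicates, for
curve recovery (mean max error ≤ 0.03 over ages 0–15, where those cohorts
are fully observed); and 1000 null replicates (zero residence effect) for
test calibration (rejection within 3 Monte-Carlo SEs of 5%).

## Known limitations

* Left truncation, competing risks, covariate-adjusted (Cox-type) models and
  whole-curve log-rank tests are out of scope.
* The variance treats first-stage sampling as with-replacement (no finite
  population correction) — standard for DHS-style designs, conservative for
  high sampling fractions.
* Recall error in self-reported event ages decades after the fact is handled
  only as far as heaping/infancy categories go; systematic age displacement
  would bias the age profile and is not corrected.
* Cohort cells pool records whose censoring ages differ by birth year;
  within wide cohorts under a steep trend this mixes slightly different
  hazards, a small bias that the recovery test bounds empirically.
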