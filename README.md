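# fgmrisk

Design-based estimation of age-specific female genital mutilation (FGM) risk
from pooled household surveys.

## The problem

Nationally representative household surveys (DHS/MICS) record FGM in two
modules: each woman aged 15–49 reports her own status and the age at which
she was cut, and reports status, current age and age-at-cutting for each of
her daughters aged 0–14.  A daughter (or woman) not yet cut at interview may
still be cut later, so these are *right-censored* time-to-event data.  The
quantity of interest is the survival function

&nbsp;&nbsp;&nbsp;&nbsp;*S(t) = P(T > t)*,

the probability that a girl has not experienced FGM by completed age *t*,
estimated per single year of age 0–49 with the Kaplan–Meier product limit

&nbsp;&nbsp;&nbsp;&nbsp;*Ŝ(t) = ∏<sub>a≤t</sub> (1 − d<sub>a</sub>/n<sub>a</sub>)*,

where *d<sub>a</sub>* and *n<sub>a</sub>* are weighted numbers of FGM events
and of girls/women at risk at age *a*.  Comparing *Ŝ(t)* across birth
cohorts (1-, 5- or 10-year, from 1960 on) measures whether and where the
practice is declining; stratifying by rural/urban residence or country
localizes the decline.

Surveys use stratified multi-stage cluster sampling, so the package weights
every observation by its sampling weight (daughters inherit their mother's
weight — all daughters 0–14 of sampled women are enumerated, so no further
adjustment is needed), de-normalizes weights by population totals before
pooling surveys, and computes Horvitz–Thompson-style linearized variances
from between-cluster variation within strata.

The package is aimed at biostatisticians and survey analysts: the actual
survey microdata are restricted-access, so everything ships with a
first-class synthetic-data generator that emulates the survey design
(stratified two-stage cluster samples, normalized weights, proxy reports,
right-censoring, age heaping, "during infancy" coding) with fully known
hazards, giving every pipeline stage a ground truth.

## Worked example

`examples/04_cohort_trends.py` generates two synthetic surveys (interviewed
in 2009 and 2015) whose hazard of cutting declines by 0.04 log-odds per
birth year, pools them with de-normalized weights, and estimates 10-year
cohort curves:

```
probability of remaining uncut through age 15, by birth cohort:
   1960–1969: S(15) = 0.150  [0.072, 0.314]
   1970–1979: S(15) = 0.264  [0.183, 0.381]
   1980–1989: S(15) = 0.307  [0.215, 0.436]
   1990–1999: S(15) = 0.523  [0.443, 0.617]
   2000–2009: S(15) = 0.562  [0.465, 0.681]
  After 2009: S(15) = 0.882  [0.776, 1.000]
```

Each successive cohort's curve sits above the last — the "stacked" pattern
that signals a genuine decline in cutting risk — and the 95% intervals are
design-based (between-cluster variance within strata).  The other examples
cover the weighted product-limit core on a hand-checkable fixture (`01`),
the survey generator (`02`), event-history reconstruction with exclusion
accounting (`03`), and rural/urban contrasts with z-tests (`05`).

A thin CLI wraps the same pipeline:

```sh
fgmrisk simulate --seed 7 --out demo_survey
fgmrisk estimate config.yaml        # full run from a YAML run config
fgmrisk compare  <output_dir>       # rural/urban table from saved curves
```

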