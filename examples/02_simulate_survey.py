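"""Generate a synthetic DHS-like survey and inspect its structure.

A population of women 15-49 (one per household, two strata of clusters) with
a known per-age hazard of being cut, declining across birth cohorts; a
two-stage cluster sample with normalized weights; daughters 0-14 reported by
their mothers and right-censored at their current age.
"""

import fgmrisk as fr

spec = fr.SyntheticSpec(
    seed=7,
    cohort_trend=-0.03,        # log-odds of cutting falls 0.03 per birth year
    residence_effect=0.6,      # rural excess on the log-odds scale
    clusters_sampled_per_stratum=(5, 15),   # unequal fractions -> unequal weights
    households_sampled_per_cluster=10,
)
tables = fr.simulate_survey(spec, survey_id="DEMO")

print(f"{len(tables.women)} women, {len(tables.daughters)} daughters sampled")
print("weights are normalized to mean 1 over women:",
      round(tables.women["weight"].mean(), 6))
print("distinct weight values (unequal sampling fractions):",
      sorted(tables.women["weight"].round(4).unique()))
print()
print(tables.women.head(5).to_string(index=False))
print()
truth = fr.true_survival(spec, birth_year=1990, residence="rural")
print("true probability a rural girl born 1990 is uncut at 15:",
      round(truth.s[15], 4))
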