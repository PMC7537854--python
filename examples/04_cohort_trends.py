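"""Pooled multi-survey cohort analysis: the full pipeline on synthetic data.

Two surveys (interviewed 2009 and 2015) are generated with a declining
hazard across birth cohorts, de-normalized against population totals, pooled,
and estimated per 10-year birth cohort.  Because risk declines, the cohort
survival curves stack: each younger cohort lies above the last.
"""

import tempfile
from pathlib import Path

import fgmrisk as fr

with tempfile.TemporaryDirectory() as tmp:
    surveys = []
    for sid, iy, seed, total in [("A2009", 2009, 31, 2e6), ("B2015", 2015, 32, 3e6)]:
        spec = fr.SyntheticSpec(
            seed=seed, interview_year=iy, cohort_trend=-0.04,
            clusters_sampled_per_stratum=8, households_sampled_per_cluster=10,
            heaping_prob=0.0, infancy_code_prob=0.0)
        tables = fr.simulate_survey(spec, survey_id=sid)
        wp, dp = fr.write_survey(tables, Path(tmp) / "data")
        surveys.append(fr.SurveyInput(survey_id=sid, women_file=str(wp),
                                      daughters_file=str(dp), population_total=total))

    config = fr.RunConfig(surveys=surveys, cohort_width=10,
                          output_dir=str(Path(tmp) / "out"), lonely_psu="collapse")
    result = fr.run_analysis(config)

print("unweighted counts per cohort:")
print(result.counts.to_string(index=False))
print()
print("probability of remaining uncut through age 15, by birth cohort:")
for key, curve in sorted(result.curves.items()):
    cohort = dict(key)["cohort"]
    lo = curve.ci_low[15] if curve.ci_low is not None else float("nan")
    hi = curve.ci_high[15] if curve.ci_high is not None else float("nan")
    print(f"  {cohort:>10}: S(15) = {curve.s[15]:.3f}  [{lo:.3f}, {hi:.3f}]")
print()
print("younger cohorts sit higher: the generated decline in cutting risk is")
print("recovered as stacked survival curves.")
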