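"""Rural/urban contrast of cutting risk with design-based z-tests.

The generator gives rural clusters a higher hazard (log-odds +0.8).  The
pipeline estimates residence-stratified cohort curves and compares them at
chosen ages; the difference urban - rural in S(t) should be positive and the
z-statistics large.
"""

import tempfile
from pathlib import Path

import fgmrisk as fr

with tempfile.TemporaryDirectory() as tmp:
    spec = fr.SyntheticSpec(
        seed=55, residence_effect=0.8, p_rural=0.5,
        clusters_per_stratum=25, households_per_cluster=20,
        clusters_sampled_per_stratum=25, households_sampled_per_cluster=20,
        heaping_prob=0.0, infancy_code_prob=0.0)
    tables = fr.simulate_survey(spec, survey_id="RU")
    wp, dp = fr.write_survey(tables, Path(tmp) / "data")
    config = fr.RunConfig(
        surveys=[fr.SurveyInput(survey_id="RU", women_file=str(wp),
                                daughters_file=str(dp), population_total=1e6)],
        cohort_width=10, group_by=("residence",),
        output_dir=str(Path(tmp) / "out"), lonely_psu="collapse")
    result = fr.run_analysis(config)
    report = fr.rural_urban_report(result, ages=[10, 15])

cols = ["cohort", "age", "s_urban", "s_rural", "diff", "se", "z", "p"]
print(report[[c for c in cols if c in report.columns]].round(4).to_string(index=False))
print()
print("diff = S_urban - S_rural > 0: urban girls face lower cutting risk, as generated;")
print("z and p are design-based (between-cluster variance within strata).")
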