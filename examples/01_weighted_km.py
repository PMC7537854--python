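"""Weighted Kaplan-Meier on a tiny hand-checkable event table.

Five people: cut at ages 4 and 6, interviewed (censored) at ages 5, 7 and 8.
The product-limit estimate drops to 4/5 at age 4 and to 4/5 * 2/3 = 8/15 at
age 6, then stays flat.
"""

import pandas as pd

import fgmrisk as fr

records = pd.DataFrame(
    {
        "time": [4, 5, 6, 7, 8],
        "event": [True, False, True, False, False],
        "weight": 1.0,
        "stratum_id": "s1",
        "psu_id": ["a", "b", "c", "d", "e"],
    }
)

rt = fr.risk_table(records)
curve = fr.km_variance(records)
fr.confidence_interval(curve)

print(rt.to_frame().loc[3:9, ["age", "n_at_risk", "events", "censored"]].to_string(index=False))
print()
print(curve.to_frame().loc[3:9, ["age", "s_hat", "se", "ci_low", "ci_high"]].round(4).to_string(index=False))
print()
print("S(6) =", curve.s[6], "= 4/5 * 2/3; the curve is the probability of")
print("remaining uncut through each completed year of age.")
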