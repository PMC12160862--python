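"""Clinical statistics layer: IHC scores, contingency tests, survival.

Scores example staining measurements, tests a published-style
contingency table, simulates a cohort whose hazard doubles with a binary
marker, and fits Kaplan-Meier/log-rank and Cox models.  Printed: each
composite score and category, the chi-square p-value, the log-rank p and
the fitted hazard ratio with its confidence interval.
"""

import numpy as np

import stromascape as ss

print("composite IHC scores:")
for area, grade in [(80, 3), (30, 1), (55, 2), (4, 3)]:
    s = ss.ihc_composite_score(area, grade)
    print(f"  area {area:5.1f}% x intensity {grade}: "
          f"area score {s.area_score}, composite {s.composite:2d} -> {s.category}")

table = [[53, 44], [58, 18]]  # marker-high/low vs vascular invasion -/+
stat, dof, p = ss.pearson_chi_square(table)
print(f"\nchi-square on {table}: stat {stat:.2f}, df {dof}, p {p:.3f}")

marker = np.repeat([0.0, 1.0], 150)  # marker-negative vs marker-positive
records = ss.generate_survival(marker, beta=np.log(2.0), censor_rate=0.25, seed=9)
records["marker"] = marker

import pandas as pd

groups = pd.Series(np.where(marker == 1, "marker+", "marker-"))
km = ss.km_logrank(records, groups)
print(f"\nlog-rank: statistic {km.statistic:.2f}, p {km.p_value:.2e}")

fit = ss.cox_ph(records, ["marker"])
row = fit.loc["marker"]
print(f"Cox HR {row['HR']:.2f} (95% CI {row['ci_low']:.2f}-{row['ci_high']:.2f}), "
      f"p {row['p_value']:.2e}  [true HR = 2]")

print(f"\ntumor volume (L=10, W=4 mm): {ss.assay_metrics('volume', length=10, width=4):.0f} mm^3")
print(f"wound healing (100 -> 25): {ss.assay_metrics('wound', initial_area=100, current_area=25):.0f}%")
print(f"colony rate (60 / 600): {ss.assay_metrics('colony', colonies=60, seeded_cells=600):.0f}%")
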