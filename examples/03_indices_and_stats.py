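"""The six behavioural indices and their statistics on a small cohort.

Generates a 6-fish cohort (3 with an alarm-pheromone-style fear session,
3 with an ethanol-style appetitive session), standardises each fish against
its own baseline, and runs Welch tests plus a correlation-matrix PCA.
"""

import numpy as np

import ventrack as vt
from ventrack.stats import pca_fit, welch_t

cfg = vt.CohortConfig(fish=[
    vt.FishPlan("f1", ("normal", "fear"), 120.0, seed=11),
    vt.FishPlan("f2", ("normal", "fear"), 120.0, seed=12),
    vt.FishPlan("f3", ("normal", "fear"), 120.0, seed=13),
    vt.FishPlan("f4", ("normal", "appetitive"), 120.0, seed=14),
    vt.FishPlan("f5", ("normal", "appetitive"), 120.0, seed=15),
    vt.FishPlan("f6", ("normal", "appetitive"), 120.0, seed=16),
])
table = vt.generate_cohort(cfg)
print(f"{len(table)} index windows "
      f"({len(table) // len(cfg.fish) // 2} per fish and state)\n")

print("standardised index means per state (baseline normal = 0):")
print(table.groupby("state")[vt.INDEX_COLUMNS].mean().round(2), "\n")

for treated in ("fear", "appetitive"):
    sub = table[table["fish_id"].isin(
        table.loc[table["state"] == treated, "fish_id"].unique())]
    print(f"{treated} vs normal (Welch t):")
    for col in vt.INDEX_COLUMNS:
        r = welch_t(sub.loc[sub["state"] == treated, col],
                    sub.loc[sub["state"] == "normal", col])
        mark = "*" if r.pvalue < 1e-3 else " "
        print(f"  {col:>10}: t = {r.statistic:+6.1f}  p = {r.pvalue:8.2e} {mark}")
    print()
# fear raises stopping and ventilation rate and quietens their variability;
# the appetitive state mostly raises variability while stabilising the rhythm

model = pca_fit(table)
print("PC explained-variance fractions:",
      np.round(model.explained_variance, 3))
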