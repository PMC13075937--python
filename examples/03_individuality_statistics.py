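"""Quantify individuality across environmental contexts on a synthetic cohort.

Generates a 200-fly cohort measured in four contexts with known variance
structure (between-fly variance 1, within-fly variance 1, i.e. true
repeatability ICC = 0.5, plus a temperature fixed effect), then runs the
full statistics layer: cross-context Pearson correlation, percentile-rank
changes, the rank-difference ridge GLM, and the random-intercept mixed
model with bootstrap ICC confidence interval.
"""

import numpy as np

from idiofly import simulate, stats
from idiofly.simulate import ContextModifier, VarianceComponents

components = VarianceComponents(
    sigma2_between=1.0, sigma2_within=1.0, fixed_effects={"temperature": 0.5}
)
contexts = [
    ContextModifier(context_id="day1_23C", day=1, temperature=23.0),
    ContextModifier(context_id="day2_23C", day=2, temperature=23.0),
    ContextModifier(context_id="day2_32C", day=2, temperature=32.0),
    ContextModifier(context_id="dark", day=2, temperature=23.0, light=0),
    ContextModifier(context_id="flight", day=2, temperature=23.0,
                    modality="flight", rank_disruption=0.5),
    ContextModifier(context_id="disrupted", day=3, temperature=23.0,
                    rank_disruption=1.0),
]
table = simulate.simulate_cohort(200, contexts, components, seed=7)

# individual consistency: same flies, different contexts
r_temp = stats.pearson_across_contexts(table, "trait", "day2_23C", "day2_32C")
r_disr = stats.pearson_across_contexts(table, "trait", "day1_23C", "disrupted")
print(f"r across a 9 C temperature change: {r_temp.r:.3f} (p={r_temp.p:.2e})")
print(f"r against a rank-disrupted context: {r_disr.r:.3f} (p={r_disr.p:.2f})")

# rank changes feed the ridge GLM: which kind of change costs consistency?
pairs = [
    dict(changed=("time",),
         rank_changes=stats.rank_change(table, "trait", "day1_23C", "day2_23C")),
    dict(changed=("temperature",),
         rank_changes=stats.rank_change(table, "trait", "day2_23C", "day2_32C")),
    dict(changed=("vision",),
         rank_changes=stats.rank_change(table, "trait", "day2_23C", "dark")),
    dict(changed=("behavioral_state",),
         rank_changes=stats.rank_change(table, "trait", "day2_23C", "flight")),
    dict(changed=("time", "arena"),  # the rank-disrupting assay switch
         rank_changes=stats.rank_change(table, "trait", "day1_23C", "disrupted")),
]
X, y = stats.build_change_design(pairs)
fit = stats.fit_ridge_cv(X, y, seed=1)
fit = stats.bootstrap_ridge(X, y, fit, n_boot=1000, seed=2)
print("\nridge GLM on |rank change| (z-scored coefficients):")
for name in fit.predictor_names:
    print(f"  {name:>16}: {fit.coefficients[name]:+6.2f}"
          f"  (SE {fit.bootstrap_se[name]:.2f}, p={fit.p_values[name]:.3g})")

# repeatability: mixed model with fly random intercept
stable = table[~table.context.isin(["disrupted", "flight"])]
lmm, ci = stats.bootstrap_icc(stable, "trait", n_boot=200, seed=3)
print(f"\nICC (repeatability) = {lmm.icc:.3f}, 95% CI [{ci[0]:.3f}, {ci[1]:.3f}]"
      f"  (generating value 0.5)")
est, lo, hi = lmm.fixed_effects["temperature"]
print(f"temperature fixed effect = {est:.3f} [{lo:.3f}, {hi:.3f}] per deg C"
      f"  (generating value 0.5)")
print(
    "\nA large temperature effect moves the whole group, yet r and ICC stay\n"
    "near 0.5: individuality survives the context change.  Only the\n"
    "rank-disrupting context destroys consistency (r near 0)."
)
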