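"""End-to-end treatment comparison: simulate, build responses, fit the rank
regression, and run pairwise Mann-Whitney tests.

A scaled-down follow-up experiment (T2-first sequential vs cocktail at mid
and late dosing, 6 replicates each, plus controls) is simulated; per
population the response is the mean OD600 across the experiment.  The
regression runs on the rank-transformed response with AIC model selection,
and the arms are compared pairwise with Holm correction.
"""

import phagesteer as ps
from phagesteer.io import trajectories_to_od_table
from phagesteer.stats import mean_density_response, pairwise_family, select_model

arms = [
    ps.TreatmentSpec("sequential", "T2", "mid", "LAMBDA", 6),
    ps.TreatmentSpec("sequential", "T2", "late", "LAMBDA", 6),
    ps.TreatmentSpec("cocktail", "BOTH", "mid", "BOTH", 6),
    ps.TreatmentSpec("cocktail", "BOTH", "late", "BOTH", 6),
    ps.TreatmentSpec("control", n_replicates=3),
]
params = ps.SimParams()
design = ps.enumerate_design(arms)
trajectories = ps.run_design(arms, params, seed=11)
od_table = trajectories_to_od_table(trajectories)
response = mean_density_response(od_table, design)

treated = response[response["strategy"] != "control"]
best, comparison = select_model(
    treated, [["strategy"], ["strategy", "timing"], ["strategy", "timing", "strategy:timing"]]
)
print("model comparison (rank-transformed response):")
print(comparison.to_string(index=False))
print(f"\nselected terms: {best.terms}; AIC = {best.aic:.1f}; "
      f"adj R^2 = {best.adj_r_squared:.2f}")
strategy_p = [p for name, p in best.pvalues.items() if "strategy" in name][0]
print(f"strategy coefficient p = {strategy_p:.3g}")

groups = {
    label: sub["response"].to_numpy()
    for label, sub in treated.groupby(
        treated["population_id"].str.rsplit("_r", n=1).str[0]
    )
}
print("\npairwise Mann-Whitney (Holm-adjusted):")
for result in pairwise_family(
    groups,
    [
        ("seq-T2first-mid", "cocktail-mid"),
        ("seq-T2first-late", "cocktail-late"),
    ],
):
    a, b = result.comparison
    print(f"  {a} vs {b}: U = {result.statistic:.0f}, "
          f"p = {result.p_value:.3f}, Holm p = {result.adjusted_p:.3f}")

print(
    "\nA lower mean rank for the T2-first sequential arms indicates stronger"
    "\nsuppression than the matched cocktails; significance varies run to run"
    "\nbecause each population's fate is a resistance-mutation lottery."
)
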