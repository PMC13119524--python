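"""Estimate maximum growth rates from 24 h microplate curves and compare
isolates against the ancestor.

Simulates noisy growth curves (5-min grid, 2% multiplicative noise) for the
wild type, a cost-free cross-resistant mutant and a costly mucoid mutant,
fits the sliding-window log-linear estimator, and runs the one-way ANOVA
with Welch tests against WT (Holm-adjusted).
"""

import numpy as np

import phagesteer as ps
from phagesteer.growth import GrowthCurve, compare_growth_rates, estimate_max_growth_rate

params = ps.SimParams()
rng = np.random.default_rng(5)

genotypes = {
    "WT": ps.Genotype("WT", {"T2": 1, "LAMBDA": 1}),
    "cross_resistant": ps.Genotype("xr", {"T2": 0, "LAMBDA": 0}),
    "mucoid": ps.Genotype("mucoid", {"T2": 0, "LAMBDA": 0}, growth_cost=0.15),
}

rates: dict[str, list[float]] = {}
for label, genotype in genotypes.items():
    for _ in range(6):
        times, od = ps.simulate_growth_curve(genotype, params, noise_sd=0.02, seed=rng)
        est = estimate_max_growth_rate(GrowthCurve(label, times, od))
        rates.setdefault(label, []).append(est.mumax)
    mean = np.mean(rates[label])
    print(f"{label:16s} mumax = {mean:.3f} /h over 6 replicate curves")

result = compare_growth_rates(rates, wt_label="WT")
print(f"\none-way ANOVA: F = {result.f_statistic:.1f}, p = {result.p_value:.2e}")
print(result.table.to_string(index=False))
print(
    "\nThe cost-free cross-resistant mutant is indistinguishable from WT;"
    "\nthe mucoid mutant's ~15% growth cost is detected against WT."
)
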