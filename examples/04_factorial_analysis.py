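"""Which factors drive the category rates: disease, phase, or target class?

Runs the balanced three-way ANOVA on the rate table under both supported
denominators. Under the drugs-on-any-network denominator the percentages
sum to 100 within each (disease, phase) cell, so the DISEASE and PHASE main
effects are identically zero by construction; the all-drugs denominator
with only in-network categories frees those effects.
"""

from netdrugmap import (
    SelectionRule,
    SynthConfig,
    generate_universe,
    rate_table,
    select_diseases,
    significance_stars,
    three_way_anova,
    tukey_hsd,
)

universe, _ = generate_universe(SynthConfig(approval_odds_multiplier=4.0, seed=1))
selected = select_diseases(universe, SelectionRule(n_top=9))

for denom, kw in (("dna", {}), ("all_drugs", {"include_no_network": False})):
    table = rate_table(universe, selected, denominator=denom, **kw)
    arr, factors, levels = table.to_anova_array()
    res = three_way_anova(arr, factors=factors)
    print(f"denominator = {denom}:")
    for eff in ("DISEASE", "PHASE", "TARGET", "PHASExTARGET"):
        f, p = res.f_stats[eff], res.p_values[eff]
        print(f"  {eff:>14}: F={f:10.3f}  p={p:.3g} {significance_stars(p)}")
    print()

# post-hoc contrast of the three phase means (all / clinical / approved)
table = rate_table(universe, selected, denominator="all_drugs",
                   include_no_network=False)
arr, factors, levels = table.to_anova_array()
res = three_way_anova(arr, factors=factors)
phase_means = {lvl: float(arr[:, i, :].mean()) for i, lvl in enumerate(levels[1])}
n_per_phase = arr.shape[0] * arr.shape[2]
print("Tukey HSD over phase means:")
for row in tukey_hsd(phase_means, res.ms_error, res.residual_df, n_per_phase):
    print(f"  {row['level_a']} vs {row['level_b']}: "
          f"diff={row['difference']:+.2f}  p={row['p_adjusted']:.3g}")
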