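"""Simulate and analyse a genotype x osmoticum rolling experiment.

Generates low-roller and high-roller genotype groups across three osmotic
potentials, measures every strip, and prints the group summary plus the
two-way ANOVA. The low-roller group starts revolute (negative curvature at
full turgor) and flattens with dehydration; the high-roller group rolls
adaxially and tightens sharply.
"""

from leafroll import (
    HIGH_ROLLER,
    LOW_ROLLER,
    anova_two_way,
    group_summary,
    measure_batch,
    simulate_experiment,
)

manifest, sections = simulate_experiment(
    [LOW_ROLLER, HIGH_ROLLER],
    psi_levels=[-0.06, -1.38, -2.82],
    reps=10,
    seed=42,
)
records, failures = measure_batch(manifest, sections=sections)
print(f"measured {len(records)} strips ({len(failures)} failures)\n")

summary = group_summary(records)
print(summary.round(4).to_string(index=False))
print()
print("Each row is one group x potential cell: cell mean, standard error")
print("and replicate count for mean curvature (mm^-1) and the log index.")
print()

table = anova_two_way(records, response="mean_curvature_mm")
print(table.to_string())
print()
print("The group:psi interaction tests whether the rolling response to")
print("dehydration differs between the genotype groups.")
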