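"""Beta diversity: distances, ordination and permutation tests.

Computes Bray-Curtis and weighted UniFrac distances on relative
abundances, ordinates them (PCoA and non-metric MDS), and tests the
grouping with ANOSIM and one-way PERMANOVA at 999 permutations.
"""

from ecoassembly import (
    ScenarioConfig,
    anosim,
    bray_curtis,
    nmds,
    pcoa,
    permanova,
    simulate_scenario,
    weighted_unifrac,
)

truth = simulate_scenario(
    ScenarioConfig(n_taxa=100, depth=5000, regime="filtering_divergent", seed=42)
)
groups = truth.metadata.groups_for(truth.table.sample_ids)

bc = bray_curtis(truth.table)
wu = weighted_unifrac(truth.table, truth.tree)

ord_bc = pcoa(bc)
p1, p2 = 100 * ord_bc.proportion_explained[:2]
print(f"PCoA (Bray-Curtis): axis1 {p1:.2f}%, axis2 {p2:.2f}% of variation")

nm = nmds(bc, k=2, n_starts=20, seed=0)
print(f"NMDS stress = {nm.stress:.3f}  (< 0.1 indicates a good 2-D fit)")

for name, dm in (("Bray-Curtis", bc), ("weighted UniFrac", wu)):
    a = anosim(dm, groups, n_permutations=999, seed=1)
    p = permanova(dm, groups, n_permutations=999, seed=1)
    print(
        f"{name}: ANOSIM R = {a.statistic:.3f} (p = {a.p_value:.3f}); "
        f"PERMANOVA R2 = {p.effect_size:.2f} (p = {p.p_value:.3f})"
    )
# R near 1 means between-source distances dominate within-source ones;
# R2 is the fraction of squared distance explained by the grouping.
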