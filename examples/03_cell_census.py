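"""From microscope census tables to abundance, biomass and growth rates.

Methanotrophs (MOB) are rare in counts but large in size, so their
biomass share exceeds their count share; dividing carbon consumption by
biomass gives specific activity, and a 30% growth efficiency converts
that to a growth rate.
"""

from lakemox import (
    CensusSpec,
    Group,
    gen_cell_census,
    implied_growth_rate,
    relative_contributions,
    specific_activity,
)

spec = CensusSpec(
    dapi_abundance=2.5e6,  # cells per mL
    mob_fraction_alpha=0.004,
    mob_fraction_gamma=0.009,
    seed=8,
)
census = gen_cell_census(spec)
metrics = relative_contributions(census)

print(f"{'group':>10} {'cells/mL':>10} {'vol um3':>8} {'ugC/L':>7} {'count%':>7} {'biomass%':>8}")
for g in Group:
    m = metrics[g.value]
    print(
        f"{g.value:>10} {m.abundance:10.2e} {m.mean_volume:8.2f} {m.biomass:7.1f} "
        f"{100 * m.relative_abundance:7.2f} {100 * m.relative_biomass:8.2f}"
    )

gamma = metrics[Group.GAMMA_MOB.value]
print(
    f"\nGamma-MOB biomass enrichment: {gamma.relative_biomass / gamma.relative_abundance:.1f}x "
    "(biomass share over count share, ~ their cell-volume ratio to the community)"
)

mob_biomass = metrics[Group.ALPHA_MOB.value].biomass + metrics[Group.GAMMA_MOB.value].biomass
sa = specific_activity(c_consumption=3.5 * mob_biomass, biomass_ugc_l=mob_biomass)
print(f"MOB specific activity {sa:.2f} 1/d -> growth rate {implied_growth_rate(sa):.2f} 1/d at 30% efficiency")
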