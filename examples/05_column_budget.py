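"""Upscale per-depth rates to a whole-column carbon budget for one lake.

Stratified layers come from the density profile; the kinetics model is
applied at every oxic meter; layer-wise heterotrophic rates and slab
volumes from the hypsographic curve close the budget.
"""

from lakemox import budget, gen_hypsography, gen_profile, layer_boundaries
from lakemox.column import EPILIMNION, HYPOLIMNION, METALIMNION

from conftest_scenario import stratified_scenario  # shared demo scenario

scenario = stratified_scenario()
profile = gen_profile(scenario)
hypso = gen_hypsography(scenario)
partition = layer_boundaries(profile)
print(
    f"stratified: {partition.stratified}; epilimnion to {partition.epi_bottom:.1f} m, "
    f"metalimnion to {partition.meta_bottom:.1f} m"
)

layer_hcc = {EPILIMNION: 95.0, METALIMNION: 70.0, HYPOLIMNION: 45.0}  # ugC/L/d
b = budget(profile, hypso, partition, layer_hcc)
print(f"total MCC {b.total_mcc:.1f} gC/d, total HCC {b.total_hcc:.1f} gC/d")
print(
    f"methanotrophy consumes {b.fraction_methanotrophy:.1f}% of whole-column "
    f"microbial C consumption"
)
print(
    f"anoxic volume fraction {b.anoxic_volume_fraction:.2f}; volume with "
    f"CH4:O2 > 0.6: {b.volume_fraction_ratio_above:.2f}"
)
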