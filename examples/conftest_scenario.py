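"""Shared demo scenario for the example scripts."""

from lakemox import LakeScenario


def stratified_scenario() -> LakeScenario:
    """A humic, strongly stratified 20-m lake with a large CH4 stock."""
    return LakeScenario(
        lake_id="demo",
        max_depth=20.0,
        surface_area=1e6,
        hypso_shape_exponent=1.5,
        doc=8.5,
        kd_par=0.8,
        stratified=True,
        epi_temp=22.0,
        hypo_temp=5.5,
        thermocline_depth=5.0,
        thermocline_width=3.0,
        surface_o2=260.0,
        bottom_o2=18.0,
        surface_ch4=0.05,
        bottom_ch4=180.0,
        ch4_buildup_rate=0.06,
        seed=11,
    )
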