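import numpy as np
import pytest

from lakemox import KineticsParams, LakeScenario, O2Calibration


@pytest.fixture
def default_params() -> KineticsParams:
    return KineticsParams()


@pytest.fixture
def default_cal() -> O2Calibration:
    return O2Calibration()


@pytest.fixture
def stratified_scenario() -> LakeScenario:
    return LakeScenario(
        lake_id="toy",
        max_depth=20.0,
        surface_area=1e6,
        hypso_shape_exponent=2.0,
        doc=6.0,
        kd_par=0.5,
        stratified=True,
        epi_temp=22.0,
        hypo_temp=5.0,
        thermocline_depth=6.0,
        thermocline_width=3.0,
        surface_o2=260.0,
        bottom_o2=5.0,
        surface_ch4=0.02,
        bottom_ch4=455.0,
        ch4_buildup_rate=0.25,
        seed=7,
    )


@pytest.fixture
def kinetics_grid():
    """Factorial grid spanning the model's calibration envelope."""
    ch4 = np.geomspace(0.1, 400.0, 10)
    o2 = np.linspace(1.0, 250.0, 10)
    temp = np.linspace(277.0, 298.0, 8)
    c, o, t = np.meshgrid(ch4, o2, temp, indexing="ij")
    return c.ravel(), o.ravel(), t.ravel()
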