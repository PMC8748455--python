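"""Gas solubility and unit conversions for dissolved CH4 and O2.

This layer does three jobs for the rest of the pipeline:

* a temperature-dependent Henry's-law constant for CH4 in fresh water,
  via the Wiesenburg & Guinasso (1979) Bunsen-coefficient fit evaluated
  at salinity zero (the coefficient set is named and swappable through
  :class:`GasConstants`);
* the two-compartment mole balance that back-calculates the dissolved
  CH4 concentration of a water sample from the headspace partial
  pressure after syringe equilibration with CH4-free gas;
* the small family of exact linear unit conversions (mg O2 <-> umol,
  umol CH4 -> ug C) and the CH4:O2 molar ratio.

All conversions are linear, positivity-preserving, and exact inverse
pairs. Ideal-gas behaviour is assumed in the headspace (uatm scale;
non-ideality is negligible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidDataError, OutOfDomainError, UndefinedRatioError

#: Molar CH4:O2 ratio of balanced aerobic methane oxidation,
#: CH4 + 2 O2 -> CO2 + 2 H2O. Waters with ambient CH4:O2 above this value
#: cannot be fully oxidized aerobically.
AEROBIC_OXIDATION_CH4_O2 = 0.5

MOLAR_MASS_C = 12.011  # g mol-1
MOLAR_MASS_O2 = 31.998  # g mol-1
GAS_CONSTANT_L_ATM = 0.0820573  # L atm mol-1 K-1
MOLAR_VOLUME_STP = 22.414  # L mol-1, ideal gas at 0 degC / 1 atm

#: Wiesenburg & Guinasso (1979) coefficients for the CH4 Bunsen solubility
#: coefficient, ln(beta) = a1 + a2*(100/T) + a3*ln(T/100) at salinity 0.
_WG79_CH4_BUNSEN = (-67.1962, 99.1624, 27.9015)


@dataclass(frozen=True)
class GasConstants:
    """Physical constants and the named CH4 solubility coefficient set.

    The default solubility set is the Wiesenburg & Guinasso (1979)
    freshwater (zero-salinity) Bunsen fit; supply different ``bunsen_a``
    coefficients to swap parameterizations.
    """

    solubility_set: str = "wiesenburg-guinasso-1979-S0"
    bunsen_a: tuple[float, float, float] = field(default=_WG79_CH4_BUNSEN)
    molar_mass_c: float = MOLAR_MASS_C
    molar_mass_o2: float = MOLAR_MASS_O2
    gas_constant: float = GAS_CONSTANT_L_ATM


DEFAULT_GAS_CONSTANTS = GasConstants()


@dataclass(frozen=True)
class HeadspaceMeasurement:
    """One syringe headspace-equilibration measurement.

    Parameters
    ----------
    p_ch4_headspace
        CH4 partial pressure in the headspace after equilibration (uatm).
    v_water, v_gas
        Water sample and (initially CH4-free) gas volumes in the syringe (mL).
    t_equil
        Water temperature during syringe equilibration (degC).
    t_incub
        Incubation temperature (degC); carried for provenance and for
        converting back to an in-situ partial pressure.
    """

    p_ch4_headspace: float
    v_water: float
    v_gas: float
    t_equil: float
    t_incub: float

    def __post_init__(self) -> None:
        if self.v_water <= 0 or self.v_gas <= 0:
            raise InvalidDataError("headspace volumes must be positive")
        if self.p_ch4_headspace < 0:
            raise InvalidDataError("partial pressure must be >= 0")


def henry_constant(temp_c: float, constants: GasConstants = DEFAULT_GAS_CONSTANTS) -> float:
    """CH4 Henry's-law solubility at ``temp_c`` in mol L-1 atm-1.

    Strictly decreasing over 0-40 degC (warmer water holds less gas).
    """
    if not 0.0 <= temp_c <= 40.0:
        raise OutOfDomainError(
            f"temperature {temp_c} degC outside the supported 0-40 degC range"
        )
    a1, a2, a3 = constants.bunsen_a
    t_k = temp_c + 273.15
    bunsen = math.exp(a1 + a2 * (100.0 / t_k) + a3 * math.log(t_k / 100.0))
    return bunsen / MOLAR_VOLUME_STP


def headspace_to_dissolved(
    m: HeadspaceMeasurement, constants: GasConstants = DEFAULT_GAS_CONSTANTS
) -> float:
    """Dissolved CH4 in the original water sample, umol L-1.

    Mass balance at equilibrium: all CH4 initially dissolved in the water
    is split between the aqueous phase (Henry's law at the equilibration
    temperature) and the gas phase (ideal gas at the equilibration
    temperature); the zero-air headspace contributes no CH4.
    """
    p_atm = m.p_ch4_headspace * 1e-6
    v_water_l = m.v_water / 1000.0
    v_gas_l = m.v_gas / 1000.0
    t_k = m.t_equil + 273.15
    aq_mol = p_atm * henry_constant(m.t_equil, constants) * v_water_l
    gas_mol = p_atm * v_gas_l / (constants.gas_constant * t_k)
    return (aq_mol + gas_mol) / v_water_l * 1e6


def o2_mg_to_umol(x: float) -> float:
    """mg O2 L-1 -> umol O2 L-1."""
    if x < 0:
        raise InvalidDataError("O2 concentration must be >= 0")
    return x * 1000.0 / MOLAR_MASS_O2


def o2_umol_to_mg(x: float) -> float:
    """umol O2 L-1 -> mg O2 L-1 (exact inverse of :func:`o2_mg_to_umol`)."""
    if x < 0:
        raise InvalidDataError("O2 concentration must be >= 0")
    return x * MOLAR_MASS_O2 / 1000.0


def ch4_umol_to_ugc(x: float) -> float:
    """umol CH4 L-1 -> ug C L-1 (one carbon per CH4 molecule)."""
    if x < 0:
        raise InvalidDataError("CH4 quantity must be >= 0")
    return x * MOLAR_MASS_C


def ch4_o2_ratio(ch4: float, o2: float) -> float:
    """Molar CH4:O2 ratio; raises :class:`UndefinedRatioError` at zero O2.

    Zero O2 means the depth is anoxic — callers must branch on the
    exception rather than receive an arbitrary number.
    """
    if ch4 < 0 or o2 < 0:
        raise InvalidDataError("concentrations must be >= 0")
    if o2 == 0:
        raise UndefinedRatioError("CH4:O2 undefined at zero O2 (anoxic water)")
    return ch4 / o2
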