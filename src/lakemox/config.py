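"""YAML pipeline configuration.

A config file holds optional sections, each mapping onto one of the
parameter dataclasses; omitted sections and fields fall back to the
package defaults::

    kinetics:
      ch4_exponent: 0.79
    o2_calibration:
      anoxia_threshold_mg_l: 0.2
    heterotrophy:
      respiratory_quotient: 1.0
      leucine_to_carbon: 1.55
      isotope_dilution: 2.0
    census:
      carbon_content: 63.0
    stratification:
      min_density_slope: 0.1
    gas_constants:
      solubility_set: wiesenburg-guinasso-1979-S0
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .census import CensusConfig
from .column import StratificationConfig
from .errors import ConfigurationError
from .gas_chem import GasConstants
from .incubations import HeterotrophyConfig
from .kinetics import KineticsParams, O2Calibration


@dataclass(frozen=True)
class PipelineConfig:
    gas_constants: GasConstants = field(default_factory=GasConstants)
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    o2_calibration: O2Calibration = field(default_factory=O2Calibration)
    heterotrophy: HeterotrophyConfig = field(default_factory=HeterotrophyConfig)
    census: CensusConfig = field(default_factory=CensusConfig)
    stratification: StratificationConfig = field(default_factory=StratificationConfig)


_SECTIONS = {
    "gas_constants": GasConstants,
    "kinetics": KineticsParams,
    "o2_calibration": O2Calibration,
    "heterotrophy": HeterotrophyConfig,
    "census": CensusConfig,
    "stratification": StratificationConfig,
}


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig`; ``None`` gives all defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigurationError(f"unknown config section(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        if not isinstance(section, dict):
            raise ConfigurationError(f"section '{name}' must be a mapping")
        valid = {f.name for f in fields(cls)}
        bad = set(section) - valid
        if bad:
            raise ConfigurationError(f"unknown field(s) in '{name}': {sorted(bad)}")
        kwargs[name] = cls(**section)
    return PipelineConfig(**kwargs)
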