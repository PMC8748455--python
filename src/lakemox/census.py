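"""Microscopy cell-census processing: abundance, biovolume, biomass.

Epifluorescence censuses record per-cell areas (um2) by group — DAPI for
all prokaryotes, plus CARD-FISH-labelled Alpha- and Gamma-class
methanotrophs (MOB). This module converts those tables into cell
abundances (field-of-view scale-up), spherical-equivalent biovolumes,
carbon biomass (63 fg C um-3 by default), relative contributions,
filtration factors, specific activity, and implied growth rates.

DAPI counts include archaea and are reported as *prokaryotic*, not
bacterial. DAPI totals include the MOB cells; MOB are subtracted from
DAPI only where a non-MOB quantity is explicitly requested (the
filtration factor).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import InvalidDataError


class Group(str, Enum):
    DAPI = "DAPI"
    ALPHA_MOB = "ALPHA_MOB"
    GAMMA_MOB = "GAMMA_MOB"


@dataclass(frozen=True)
class CensusConfig:
    """Microscope scale and conversion constants.

    ``pixel_area`` x ``min_area_px`` gives the minimum-area screen
    (default 22 px = 0.22 um2) that removes viruses and eukaryotic
    nuclei from DAPI counts. ``carbon_content`` is the per-biovolume
    carbon factor (fg C um-3); ``growth_efficiency`` converts specific
    activity to growth rate.
    """

    pixel_area: float = 0.01  # um2 per pixel
    min_area_px: int = 22
    carbon_content: float = 63.0  # fg C um-3
    growth_efficiency: float = 0.30

    def __post_init__(self) -> None:
        if min(self.pixel_area, self.min_area_px, self.carbon_content, self.growth_efficiency) <= 0:
            raise InvalidDataError("all census config values must be > 0")

    @property
    def min_area_um2(self) -> float:
        return self.min_area_px * self.pixel_area


DEFAULT_CENSUS_CONFIG = CensusConfig()


@dataclass(frozen=True)
class CellCensus:
    """Per-cell areas by group for one sample, plus the scale-up metadata.

    ``cells`` has columns ``group``, ``field_id``, ``cell_area_um2``.
    ``field_area_fraction`` is the area of one counted field of view as a
    fraction of the effective filtration area of the membrane.
    """

    sample_id: str
    cells: pd.DataFrame
    n_fields: int
    filtered_volume_ml: float
    field_area_fraction: float

    def __post_init__(self) -> None:
        if self.n_fields < 1:
            raise InvalidDataError("n_fields must be >= 1")
        if self.filtered_volume_ml <= 0:
            raise InvalidDataError("filtered_volume_ml must be > 0")
        missing = {"group", "field_id", "cell_area_um2"} - set(self.cells.columns)
        if missing:
            raise InvalidDataError(f"census table missing columns {sorted(missing)}")

    def areas(self, group: Group | str) -> np.ndarray:
        g = Group(group).value
        return self.cells.loc[self.cells["group"] == g, "cell_area_um2"].to_numpy(float)


@dataclass(frozen=True)
class CensusMetrics:
    """Derived quantities for one group of one sample."""

    group: str
    abundance: float  # cells mL-1
    mean_volume: float  # um3
    biomass: float  # ug C L-1
    relative_abundance: float  # fraction of DAPI counts
    relative_biomass: float  # fraction of total DAPI biomass


def filter_min_area(areas, config: CensusConfig = DEFAULT_CENSUS_CONFIG) -> np.ndarray:
    """Drop cells below the minimum-area threshold, preserving order."""
    areas = np.asarray(areas, dtype=float)
    if np.any(areas < 0):
        raise InvalidDataError("areas must be >= 0")
    return areas[areas >= config.min_area_um2]


def volume_from_area(area):
    """Spherical-equivalent biovolume (um3) from projected cell area (um2).

    Equivalent-circle diameter d = 2 sqrt(area / pi); volume = (pi/6) d^3.
    """
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise InvalidDataError("area must be > 0")
    d = 2.0 * np.sqrt(area / math.pi)
    vol = math.pi / 6.0 * d**3
    return float(vol) if vol.ndim == 0 else vol


def area_from_volume(volume):
    """Inverse of :func:`volume_from_area` (used by the synthetic generator)."""
    volume = np.asarray(volume, dtype=float)
    if np.any(volume <= 0):
        raise InvalidDataError("volume must be > 0")
    d = (6.0 * volume / math.pi) ** (1.0 / 3.0)
    area = math.pi * d**2 / 4.0
    return float(area) if area.ndim == 0 else area


def abundance_from_counts(
    counts_per_field,
    n_fields: int,
    filtered_volume_ml: float,
    field_area_fraction: float,
) -> float:
    """Cells per mL from field-of-view counts.

    Mean count per field x (effective filter area / field area) /
    filtered volume. 2-6 mL is the expected filtration volume; values
    outside that band are accepted with a warning.
    """
    if filtered_volume_ml <= 0:
        raise InvalidDataError("filtered_volume_ml must be > 0")
    if field_area_fraction <= 0:
        raise InvalidDataError("field_area_fraction must be > 0")
    if not 2.0 <= filtered_volume_ml <= 6.0:
        warnings.warn(
            f"filtered volume {filtered_volume_ml} mL outside the expected 2-6 mL",
            stacklevel=2,
        )
    counts = np.asarray(counts_per_field, dtype=float)
    mean_count = counts.mean() if counts.ndim else float(counts)
    return mean_count / field_area_fraction / filtered_volume_ml


def biomass(
    abundance_per_ml: float,
    mean_volume_um3: float,
    config: CensusConfig = DEFAULT_CENSUS_CONFIG,
) -> float:
    """Carbon biomass, ug C L-1: abundance x biovolume x carbon content."""
    if abundance_per_ml < 0 or mean_volume_um3 < 0:
        raise InvalidDataError("abundance and volume must be >= 0")
    # cells mL-1 -> cells L-1 (x1000); x um3 x fg C um-3 -> fg C L-1; -> ug (x1e-9)
    return abundance_per_ml * 1000.0 * mean_volume_um3 * config.carbon_content * 1e-9


def relative_contributions(
    census: CellCensus, config: CensusConfig = DEFAULT_CENSUS_CONFIG
) -> dict[str, CensusMetrics]:
    """Per-group abundance, biovolume, biomass and relative shares.

    Relative quantities are fractions of the DAPI (total prokaryote)
    count and biomass. The biomass-vs-abundance enrichment of a small
    group approaches its mean-volume ratio to the community: a group
    three times larger than the average cell contributes three times
    more to biomass than to counts.
    """
    dapi_areas = census.areas(Group.DAPI)
    dapi_areas = filter_min_area(dapi_areas, config)
    if dapi_areas.size == 0:
        raise InvalidDataError("census has no DAPI cells above the area threshold")

    out: dict[str, CensusMetrics] = {}
    per_group: dict[str, tuple[float, float, float]] = {}
    for group in Group:
        areas = filter_min_area(census.areas(group), config)
        if areas.size == 0:
            per_group[group.value] = (0.0, 0.0, 0.0)
            continue
        mean_vol = float(volume_from_area(areas).mean())
        counts_per_field = areas.size / census.n_fields
        abund = abundance_from_counts(
            counts_per_field,
            census.n_fields,
            census.filtered_volume_ml,
            census.field_area_fraction,
        )
        per_group[group.value] = (abund, mean_vol, biomass(abund, mean_vol, config))

    dapi_abund, _, dapi_biomass = per_group[Group.DAPI.value]
    for group in Group:
        abund, mean_vol, bm = per_group[group.value]
        out[group.value] = CensusMetrics(
            group=group.value,
            abundance=abund,
            mean_volume=mean_vol,
            biomass=bm,
            relative_abundance=abund / dapi_abund if dapi_abund else 0.0,
            relative_biomass=bm / dapi_biomass if dapi_biomass else 0.0,
        )
    return out


def filtration_factor(
    unfiltered_nonmob_biomass: float, filtered_nonmob_biomass: float
) -> float:
    """Non-MOB DAPI biomass reduction factor of the 1.2-um filtration step."""
    if filtered_nonmob_biomass <= 0:
        raise InvalidDataError("filtered biomass must be > 0")
    if unfiltered_nonmob_biomass <= 0:
        raise InvalidDataError("unfiltered biomass must be > 0")
    factor = unfiltered_nonmob_biomass / filtered_nonmob_biomass
    if factor < 1:
        warnings.warn(
            f"filtration factor {factor:.3g} < 1 (filtration should not add biomass)",
            stacklevel=2,
        )
    return factor


def nonmob_biomass(metrics: dict[str, CensusMetrics]) -> float:
    """DAPI biomass minus the MOB groups' biomass (ug C L-1)."""
    return max(
        metrics[Group.DAPI.value].biomass
        - metrics[Group.ALPHA_MOB.value].biomass
        - metrics[Group.GAMMA_MOB.value].biomass,
        0.0,
    )


def specific_activity(c_consumption: float, biomass_ugc_l: float) -> float:
    """Carbon consumed per unit consumer biomass per day (d-1)."""
    if biomass_ugc_l <= 0:
        raise InvalidDataError("biomass must be > 0")
    if c_consumption < 0:
        raise InvalidDataError("consumption must be >= 0")
    return c_consumption / biomass_ugc_l


def implied_growth_rate(
    specific_activity_d: float, config: CensusConfig = DEFAULT_CENSUS_CONFIG
) -> float:
    """Growth rate (d-1) implied by a specific activity and growth efficiency."""
    if specific_activity_d < 0:
        raise InvalidDataError("specific activity must be >= 0")
    return specific_activity_d * config.growth_efficiency
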