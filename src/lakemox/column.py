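"""Whole water-column upscaling: stratification, volumes, carbon budget.

Per-depth MOX rates (kinetics model on calibrated O2 and in-situ CH4 and
temperature) and layer-wise heterotrophic rates are weighted by the
volume of each 1- or 2-m slab from the lake's hypsographic curve and
summed into a whole-column carbon budget, from which the percent of
microbial carbon consumption routed through methanotrophy follows.

Stratified layers (epilimnion / metalimnion / hypolimnion) are detected
from the density profile with a metalimnion-bounds algorithm equivalent
to rLakeAnalyzer's ``meta.depths`` (minimum density slope 0.1 kg m-3
m-1; profiles whose temperature range is below 1 degC are unstratified).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import gas_chem
from .errors import (
    ConfigurationError,
    ExtrapolationError,
    InvalidDataError,
    OutOfDomainError,
    UndefinedRatioError,
)
from .kinetics import (
    DEFAULT_O2_CALIBRATION,
    DEFAULT_PARAMS,
    KineticsParams,
    O2Calibration,
    calibrate_o2,
    predict_mox,
)

log = logging.getLogger(__name__)

EPILIMNION = "epilimnion"
METALIMNION = "metalimnion"
HYPOLIMNION = "hypolimnion"


@dataclass(frozen=True)
class DepthProfile:
    """Per-depth temperature, O2 and CH4 on a uniform positive-down grid."""

    lake_id: str
    date: str
    depth: np.ndarray  # m, surface = 0, step 1 or 2
    temp: np.ndarray  # degC
    o2: np.ndarray  # umol L-1
    ch4: np.ndarray  # umol L-1
    par: np.ndarray | None = None  # umol photons m-2 s-1

    def __post_init__(self) -> None:
        for name in ("depth", "temp", "o2", "ch4"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.par is not None:
            object.__setattr__(self, "par", np.asarray(self.par, dtype=float))
        z = self.depth
        if z.size < 2:
            raise InvalidDataError("profile needs >= 2 depths")
        steps = np.diff(z)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise InvalidDataError("depth grid must be strictly increasing and uniform")
        if not {self.temp.size, self.o2.size, self.ch4.size} == {z.size}:
            raise InvalidDataError("profile columns must share the depth grid length")
        if np.any(self.o2 < 0) or np.any(self.ch4 < 0):
            raise InvalidDataError("concentrations must be >= 0")

    @property
    def grid_step(self) -> float:
        return float(self.depth[1] - self.depth[0])


@dataclass(frozen=True)
class Hypsography:
    """Planar lake area (m2) as a function of depth (m)."""

    lake_id: str
    depth: np.ndarray
    area: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "depth", np.asarray(self.depth, dtype=float))
        object.__setattr__(self, "area", np.asarray(self.area, dtype=float))
        if self.depth.size != self.area.size:
            raise InvalidDataError("depth and area must share one length")
        if np.any(np.diff(self.depth) <= 0):
            raise InvalidDataError("hypsography depths must be strictly increasing")
        if np.any(np.diff(self.area) > 1e-9):
            raise InvalidDataError("area must be nonincreasing with depth")
        if self.area[0] <= 0:
            raise InvalidDataError("surface area must be > 0")

    def area_at(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if np.any(z > self.depth[-1] + 1e-9) or np.any(z < self.depth[0] - 1e-9):
            raise ExtrapolationError("grid extends beyond the tabulated hypsography")
        return np.interp(z, self.depth, self.area)


@dataclass(frozen=True)
class LayerPartition:
    """Epilimnion / metalimnion bounds (m); both absent when unstratified."""

    stratified: bool
    epi_bottom: float | None = None
    meta_bottom: float | None = None

    def __post_init__(self) -> None:
        if self.stratified:
            if self.epi_bottom is None or self.meta_bottom is None:
                raise InvalidDataError("stratified partition needs both boundaries")
            if not 0 < self.epi_bottom <= self.meta_bottom:
                raise InvalidDataError("need 0 < epi_bottom <= meta_bottom")


@dataclass(frozen=True)
class StratificationConfig:
    min_density_slope: float = 0.1  # kg m-3 m-1
    mixed_cutoff: float = 1.0  # degC

    def __post_init__(self) -> None:
        if self.min_density_slope <= 0 or self.mixed_cutoff <= 0:
            raise InvalidDataError("stratification thresholds must be > 0")


DEFAULT_STRATIFICATION = StratificationConfig()


def water_density(temp_c) -> np.ndarray:
    """Fresh-water density (kg m-3) from temperature (degC).

    Martin & McCutcheon (1999) polynomial; maximum near 4 degC,
    decreasing above it. Valid 0-40 degC.
    """
    t = np.asarray(temp_c, dtype=float)
    if np.any((t < 0) | (t > 40)):
        raise OutOfDomainError("temperature outside the 0-40 degC density range")
    rho = 1000.0 * (
        1.0 - (t + 288.9414) / (508929.2 * (t + 68.12963)) * (t - 3.9863) ** 2
    )
    return float(rho) if rho.ndim == 0 else rho


def _interp_crossing(mid: np.ndarray, slope: np.ndarray, i_from: int, i_to: int, thresh: float) -> float:
    """Depth where the slope crosses ``thresh`` between two midpoints."""
    s0, s1 = slope[i_from], slope[i_to]
    if s0 == s1:
        return float(mid[i_to])
    frac = (s0 - thresh) / (s0 - s1)
    return float(mid[i_from] + frac * (mid[i_to] - mid[i_from]))


def layer_boundaries(
    profile: DepthProfile, config: StratificationConfig = DEFAULT_STRATIFICATION
) -> LayerPartition:
    """Metalimnion bounds from the density profile (meta.depths-equivalent).

    Density slopes are evaluated between successive depths (at segment
    midpoints); the maximum-slope segment anchors the metalimnion, and
    the bounds are found by walking outward to the first segment whose
    slope drops below ``min_density_slope``, linearly interpolating the
    crossing depth. A temperature range below ``mixed_cutoff`` — or no
    segment exceeding the slope threshold — means unstratified.
    """
    z = profile.depth
    if z.size < 3:
        raise InvalidDataError("stratification detection needs >= 3 depths")
    if np.ptp(profile.temp) < config.mixed_cutoff:
        return LayerPartition(stratified=False)

    rho = water_density(profile.temp)
    dz = np.diff(z)
    slope = np.diff(rho) / dz
    mid = z[:-1] + dz / 2.0
    peak = int(np.argmax(slope))
    if slope[peak] < config.min_density_slope:
        return LayerPartition(stratified=False)

    thresh = config.min_density_slope
    # walk up from the peak toward the surface; the boundary never leaves the
    # steep region, so clamp the interpolated crossing at the grid point
    # separating the last sub-threshold segment from the first steep one
    epi_bottom = float(mid[0])
    for i in range(peak - 1, -1, -1):
        if slope[i] < thresh:
            epi_bottom = max(_interp_crossing(mid, slope, i + 1, i, thresh), float(z[i + 1]))
            break
    # walk down from the peak toward the bottom (mirror-image clamp)
    meta_bottom = float(z[-1])
    for i in range(peak + 1, slope.size):
        if slope[i] < thresh:
            meta_bottom = min(_interp_crossing(mid, slope, i - 1, i, thresh), float(z[i]))
            break
    return LayerPartition(stratified=True, epi_bottom=epi_bottom, meta_bottom=meta_bottom)


def layer_volumes(hypso: Hypsography, grid) -> np.ndarray:
    """Trapezoidal slab volumes (m3) between successive grid depths.

    Slab i spans [z_i, z_{i+1}] with volume dz * (A_i + A_{i+1}) / 2;
    the returned array has ``len(grid) - 1`` entries and sums exactly to
    the trapezoidal whole-lake volume over the grid.
    """
    z = np.asarray(grid, dtype=float)
    if z.size < 2:
        raise InvalidDataError("grid needs >= 2 depths")
    a = hypso.area_at(z)
    dz = np.diff(z)
    return dz * (a[:-1] + a[1:]) / 2.0


def assign_layers(depths, partition: LayerPartition) -> np.ndarray:
    """Layer label per depth; a boundary depth belongs to the upper layer."""
    z = np.asarray(depths, dtype=float)
    labels = np.full(z.shape, EPILIMNION, dtype=object)
    if partition.stratified:
        labels[z > partition.epi_bottom] = METALIMNION
        labels[z > partition.meta_bottom] = HYPOLIMNION
    elif partition.epi_bottom is not None:
        # two-layer convention for lakes without a persistent metalimnion
        labels[z > partition.epi_bottom] = HYPOLIMNION
    return labels


def column_mox(
    profile: DepthProfile,
    params: KineticsParams = DEFAULT_PARAMS,
    cal: O2Calibration = DEFAULT_O2_CALIBRATION,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-depth MOX rates (umol L-1 d-1) and the anoxic mask.

    O2 is offset-calibrated first; anoxic depths (calibrated O2 below
    the 0.2 mg L-1 threshold) get rate zero — the model covers aerobic
    oxidation only. Depths with missing or zero CH4 contribute no MOX
    and are logged.
    """
    o2_cal, anoxic = calibrate_o2(profile.o2, cal)
    rates = np.zeros_like(profile.depth)
    usable = (~anoxic) & np.isfinite(profile.ch4) & (profile.ch4 > 0)
    dropped = (~np.isfinite(profile.ch4)) | (profile.ch4 <= 0)
    if np.any(dropped & ~anoxic):
        log.warning(
            "%s %s: %d oxic depth(s) without usable CH4 excluded from MOX",
            profile.lake_id,
            profile.date,
            int(np.sum(dropped & ~anoxic)),
        )
    if np.any(usable):
        rates[usable] = predict_mox(
            profile.ch4[usable], o2_cal[usable], profile.temp[usable] + 273.15, params
        )
    return rates, anoxic


def column_hcc(
    depths, partition: LayerPartition, layer_rates: dict[str, float]
) -> np.ndarray:
    """Per-depth HCC (ug C L-1 d-1): each depth inherits its layer's rate."""
    labels = assign_layers(depths, partition)
    needed = set(labels.tolist())
    missing = needed - set(layer_rates)
    if missing:
        raise ConfigurationError(f"no HCC rate for layer(s): {sorted(missing)}")
    return np.array([layer_rates[lbl] for lbl in labels], dtype=float)


@dataclass(frozen=True)
class ColumnBudget:
    """Whole-column carbon budget for one profile of one lake."""

    lake_id: str
    date: str
    mox: np.ndarray  # umol L-1 d-1 per depth
    hcc: np.ndarray  # ug C L-1 d-1 per depth
    layers: np.ndarray  # label per depth
    depth_volumes: np.ndarray  # m3 per depth (half-slabs either side of the point)
    total_mcc: float  # g C d-1
    total_hcc: float  # g C d-1
    fraction_methanotrophy: float  # percent; nan when total consumption is 0
    anoxic_volume_fraction: float
    volume_fraction_ratio_above: float  # volume share with CH4:O2 > ratio threshold
    ratio_threshold: float = 0.6
    provenance: dict = field(default_factory=dict)

    @property
    def fraction_defined(self) -> bool:
        return np.isfinite(self.fraction_methanotrophy)

    @property
    def fraction_heterotrophy(self) -> float:
        return 100.0 - self.fraction_methanotrophy


def budget(
    profile: DepthProfile,
    hypso: Hypsography,
    partition: LayerPartition,
    layer_hcc: dict[str, float],
    params: KineticsParams = DEFAULT_PARAMS,
    cal: O2Calibration = DEFAULT_O2_CALIBRATION,
    ratio_threshold: float = 0.6,
) -> ColumnBudget:
    """Volume-weighted whole-column budget of MCC and HCC.

    Each grid depth's rate is weighted by half the trapezoidal slab
    volume on either side of it (the trapezoid rule in depth). Totals
    are in g C d-1; the headline number is the percent of total
    microbial C consumption routed through methanotrophy.
    """
    mox, anoxic = column_mox(profile, params, cal)
    hcc = column_hcc(profile.depth, partition, layer_hcc)
    slabs = layer_volumes(hypso, profile.depth)
    # centered per-depth volumes: half of each adjacent slab, so the weighted
    # rate sum is the trapezoid rule in depth and Σ vols equals the lake volume
    vols = np.zeros(profile.depth.size)
    vols[:-1] += slabs / 2.0
    vols[1:] += slabs / 2.0

    # ug C L-1 d-1 x m3 x 1000 L m-3 x 1e-6 g ug-1 = 1e-3 g d-1
    mcc_per_depth = mox * gas_chem.MOLAR_MASS_C  # ug C L-1 d-1
    total_mcc = float(np.sum(mcc_per_depth * vols) * 1e-3)
    total_hcc_g = float(np.sum(hcc * vols) * 1e-3)
    total = total_mcc + total_hcc_g
    fraction = 100.0 * total_mcc / total if total > 0 else float("nan")

    total_vol = float(vols.sum())
    anoxic_frac = float(vols[anoxic].sum() / total_vol) if total_vol > 0 else 0.0

    o2_cal, _ = calibrate_o2(profile.o2, cal)
    above = np.zeros(profile.depth.size, dtype=bool)
    for i in range(profile.depth.size):
        try:
            above[i] = gas_chem.ch4_o2_ratio(profile.ch4[i], o2_cal[i]) > ratio_threshold
        except UndefinedRatioError:
            above[i] = profile.ch4[i] > 0  # anoxic with CH4 present: ratio -> inf
    ratio_frac = float(vols[above].sum() / total_vol) if total_vol > 0 else 0.0

    return ColumnBudget(
        lake_id=profile.lake_id,
        date=profile.date,
        mox=mox,
        hcc=hcc,
        layers=assign_layers(profile.depth, partition),
        depth_volumes=vols,
        total_mcc=total_mcc,
        total_hcc=total_hcc_g,
        fraction_methanotrophy=fraction,
        anoxic_volume_fraction=anoxic_frac,
        volume_fraction_ratio_above=ratio_frac,
        ratio_threshold=ratio_threshold,
        provenance={"layer_hcc": dict(layer_hcc)},
    )
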