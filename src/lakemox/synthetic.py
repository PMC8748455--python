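"""Seeded synthetic lakes: profiles, hypsographies, incubations, censuses.

The generator emulates the statistical structure of a set of temperate
oligo- to mesotrophic lakes spanning a DOC gradient of roughly 2-11 mg
L-1: thermally stratified and unstratified water columns, CH4 rising
from trace surface values to hundreds of uM in the hypolimnion
(0.02-455 uM envelope), O2 declining from air-saturated surface waters
to hypoxia or anoxia at depth (3-265 uM envelope), MOB at 0.1-5% of
DAPI counts with group mean biovolumes near 0.9 (Gamma-MOB), 0.5
(Alpha-MOB) and 0.3 um3 (DAPI), and log-linear first-order CH4 decay in
incubations.

Profiles themselves are deterministic smooth shapes (normalized logistic
temperature and O2, normalized exponential CH4) so monotonicity and the
exact concentration envelopes hold by construction; randomness enters
through incubation noise, census draws, and the suite-level sampling of
lake characteristics. All randomness flows from one root seed through
named ``numpy`` SeedSequence streams, so identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .census import DEFAULT_CENSUS_CONFIG, CellCensus, CensusConfig, Group, area_from_volume
from .column import DepthProfile, Hypsography
from .errors import DegenerateLakeError, InvalidDataError
from .incubations import IncubationSeries


@dataclass(frozen=True)
class LakeScenario:
    """Static description of one synthetic lake."""

    lake_id: str
    max_depth: float  # m
    surface_area: float  # m2
    hypso_shape_exponent: float  # area(z) = A0 (1 - z/zmax)^exponent
    doc: float  # mg C L-1
    kd_par: float  # m-1
    stratified: bool
    epi_temp: float  # degC
    hypo_temp: float  # degC
    thermocline_depth: float  # m
    thermocline_width: float  # m
    surface_o2: float  # umol L-1
    bottom_o2: float  # umol L-1
    surface_ch4: float  # umol L-1
    bottom_ch4: float  # umol L-1
    ch4_buildup_rate: float  # m-1, exponential shape parameter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth <= 0 or self.surface_area <= 0:
            raise InvalidDataError("max_depth and surface_area must be > 0")
        if self.hypso_shape_exponent < 0:
            raise InvalidDataError("hypso_shape_exponent must be >= 0")
        if not 0 <= self.surface_ch4 <= self.bottom_ch4:
            raise InvalidDataError("need bottom_ch4 >= surface_ch4 >= 0")
        if min(self.surface_o2, self.bottom_o2) < 0:
            raise InvalidDataError("O2 concentrations must be >= 0")
        if self.stratified and not 0 < self.thermocline_depth < self.max_depth:
            raise InvalidDataError("thermocline must lie inside the water column")


@dataclass(frozen=True)
class CensusSpec:
    """Target composition and cell-size structure of a synthetic census."""

    dapi_abundance: float  # cells mL-1
    mob_fraction_alpha: float
    mob_fraction_gamma: float
    mean_volume_dapi: float = 0.3  # um3
    mean_volume_alpha: float = 0.5
    mean_volume_gamma: float = 0.9
    volume_cv: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mob_fraction_alpha < 0 or self.mob_fraction_gamma < 0:
            raise InvalidDataError("MOB fractions must be >= 0")
        if self.mob_fraction_alpha + self.mob_fraction_gamma > 1:
            raise InvalidDataError("MOB fractions must sum to <= 1")
        if min(self.mean_volume_dapi, self.mean_volume_alpha, self.mean_volume_gamma) <= 0:
            raise InvalidDataError("mean volumes must be > 0")


@dataclass(frozen=True)
class LakeSeason:
    """One synthetic lake with its sequence of dated profiles."""

    scenario: LakeScenario
    profiles: list[DepthProfile] = field(default_factory=list)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _grid(scenario: LakeScenario, grid_step: float) -> np.ndarray:
    if grid_step not in (1, 2):
        raise InvalidDataError("grid_step must be 1 or 2 m")
    if scenario.max_depth < grid_step:
        raise DegenerateLakeError(
            f"lake of depth {scenario.max_depth} m cannot carry a {grid_step}-m grid"
        )
    n = int(round(scenario.max_depth / grid_step))
    if abs(n * grid_step - scenario.max_depth) > 1e-9:
        raise DegenerateLakeError("max_depth must be a multiple of the grid step")
    return np.arange(n + 1, dtype=float) * grid_step


def _normalized_logistic(z: np.ndarray, center: float, width: float) -> np.ndarray:
    """Monotone 0 -> 1 transition over z, exactly 0 at z[0] and 1 at z[-1]."""
    w = max(width, 1e-6) / 4.0  # logistic scale: transition mostly within `width`
    raw = 1.0 / (1.0 + np.exp(-(z - center) / w))
    lo, hi = raw[0], raw[-1]
    return (raw - lo) / (hi - lo) if hi > lo else np.zeros_like(z)


def gen_profile(scenario: LakeScenario, grid_step: float = 1.0) -> DepthProfile:
    """Depth profile of temperature, O2, CH4 (and PAR) for one scenario.

    Temperature follows a logistic transition between ``epi_temp`` and
    ``hypo_temp`` centered at the thermocline (isothermal when
    unstratified); O2 declines monotonically from ``surface_o2`` to
    ``bottom_o2`` along an oxycline tied to the thermocline; CH4 rises
    monotonically with an exponential shape hitting ``surface_ch4`` and
    ``bottom_ch4`` exactly at the end points. PAR decays as
    ``1500 exp(-kd_par z)``. Deterministic for a fixed scenario.
    """
    z = _grid(scenario, grid_step)
    zmax = scenario.max_depth

    if scenario.stratified:
        s_t = _normalized_logistic(z, scenario.thermocline_depth, scenario.thermocline_width)
        temp = scenario.epi_temp + (scenario.hypo_temp - scenario.epi_temp) * s_t
        # oxycline slightly below and wider than the thermocline
        s_o = _normalized_logistic(
            z, scenario.thermocline_depth + 0.5, scenario.thermocline_width * 1.5
        )
        o2 = scenario.surface_o2 + (scenario.bottom_o2 - scenario.surface_o2) * s_o
    else:
        temp = np.full_like(z, scenario.epi_temp)
        frac = z / zmax
        o2 = scenario.surface_o2 + (scenario.bottom_o2 - scenario.surface_o2) * frac

    r = scenario.ch4_buildup_rate
    if abs(r) < 1e-9:
        shape = z / zmax
    else:
        shape = np.expm1(r * z) / np.expm1(r * zmax)
    ch4 = scenario.surface_ch4 + (scenario.bottom_ch4 - scenario.surface_ch4) * shape

    par = 1500.0 * np.exp(-scenario.kd_par * z)
    return DepthProfile(
        lake_id=scenario.lake_id,
        date="2015-07-15",
        depth=z,
        temp=temp,
        o2=o2,
        ch4=ch4,
        par=par,
    )


def gen_hypsography(scenario: LakeScenario, grid_step: float = 1.0) -> Hypsography:
    """Hypsographic curve area(z) = A0 (1 - z/zmax)^exponent on the grid.

    Exponent 0 is the exact cylinder (constant area, including at
    ``max_depth``); any positive exponent tapers strictly to zero area
    at the bottom.
    """
    z = _grid(scenario, grid_step)
    e = scenario.hypso_shape_exponent
    if e == 0:
        area = np.full_like(z, scenario.surface_area)
    else:
        area = scenario.surface_area * (1.0 - z / scenario.max_depth) ** e
    return Hypsography(lake_id=scenario.lake_id, depth=z, area=area)


def gen_incubation(
    k_true: float,
    c0: float,
    times,
    noise_cv: float = 0.05,
    replicates: int = 2,
    seed: int = 0,
    sample_id: str = "synthetic",
) -> IncubationSeries:
    """First-order CH4 decay series with multiplicative lognormal noise.

    Concentrations are ``c0 exp(-k_true t)`` perturbed by mean-one
    lognormal noise of coefficient of variation ``noise_cv``
    (concentrations stay positive and measurement error scales with
    signal); replicate flasks share the sampling times and differ only
    in noise draws. ``noise_cv = 0`` returns the exact series.
    """
    if k_true < 0:
        raise InvalidDataError("k_true must be >= 0")
    if c0 <= 0:
        raise InvalidDataError("c0 must be > 0")
    if noise_cv < 0:
        raise InvalidDataError("noise_cv must be >= 0")
    times = np.asarray(times, dtype=float)
    if times.size < 3:
        raise InvalidDataError("need >= 3 time points")
    rng = _rng(seed, 1)
    t_all, c_all, f_all = [], [], []
    for rep in range(replicates):
        clean = c0 * np.exp(-k_true * times)
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv**2))
            noise = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=times.size)
            clean = clean * noise
        t_all.append(times)
        c_all.append(clean)
        f_all.append(np.full(times.size, f"flask{rep + 1}"))
    return IncubationSeries(
        sample_id=sample_id,
        analyte="ch4",
        time=np.concatenate(t_all),
        conc=np.concatenate(c_all),
        flask_id=np.concatenate(f_all),
        time_unit="d",
    )


def gen_incubation_o2(
    slope_true: float,
    o2_0: float,
    times_h,
    noise_sd: float = 0.02,
    replicates: int = 2,
    seed: int = 0,
    sample_id: str = "synthetic",
) -> IncubationSeries:
    """Linear O2 drawdown series (mg L-1 vs hours) with Gaussian noise."""
    if slope_true < 0:
        raise InvalidDataError("slope_true must be >= 0 (drawdown magnitude)")
    times_h = np.asarray(times_h, dtype=float)
    if times_h.size < 3:
        raise InvalidDataError("need >= 3 time points")
    rng = _rng(seed, 2)
    t_all, c_all, f_all = [], [], []
    for rep in range(replicates):
        conc = o2_0 - slope_true * times_h
        if noise_sd > 0:
            conc = conc + rng.normal(0.0, noise_sd, size=times_h.size)
        t_all.append(times_h)
        c_all.append(np.maximum(conc, 0.0))
        f_all.append(np.full(times_h.size, f"flask{rep + 1}"))
    return IncubationSeries(
        sample_id=sample_id,
        analyte="o2",
        time=np.concatenate(t_all),
        conc=np.concatenate(c_all),
        flask_id=np.concatenate(f_all),
        time_unit="h",
    )


def _draw_areas(
    rng: np.random.Generator,
    n: int,
    mean_volume: float,
    cv: float,
    min_area: float,
) -> np.ndarray:
    """Lognormal biovolumes with the given mean and CV, areas >= min_area."""
    if n == 0:
        return np.array([])
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    mu = np.log(mean_volume) - sigma**2 / 2.0
    areas = np.empty(0)
    while areas.size < n:  # redraw sub-threshold cells (truncation)
        draw = rng.lognormal(mu, sigma, size=2 * (n - areas.size) + 8)
        a = area_from_volume(draw)
        areas = np.concatenate([areas, a[a >= min_area]])
    return areas[:n]


def gen_cell_census(
    spec: CensusSpec,
    n_fields: int = 46,
    filtered_volume_ml: float = 4.0,
    field_area_fraction: float = 2e-5,
    config: CensusConfig = DEFAULT_CENSUS_CONFIG,
    allow_any_fields: bool = False,
    sample_id: str = "synthetic",
) -> CellCensus:
    """Synthetic per-cell census table with the specified group structure.

    Counts per field are Poisson around the expectation implied by the
    DAPI abundance and the field-of-view scale-up; MOB counts are
    binomial subsets of the DAPI count at the spec fractions. Per-cell
    areas are drawn so the spherical-equivalent volumes have the group
    means and CV, truncated at the 0.22 um2 minimum-area threshold.
    """
    if not allow_any_fields and not 24 <= n_fields <= 55:
        raise InvalidDataError(
            "n_fields outside the emulated 24-55 range (set allow_any_fields=True to override)"
        )
    rng = _rng(spec.seed, 3)
    mean_per_field = spec.dapi_abundance * filtered_volume_ml * field_area_fraction
    rows: list[pd.DataFrame] = []
    group_fracs = {
        Group.DAPI: 1.0,
        Group.ALPHA_MOB: spec.mob_fraction_alpha,
        Group.GAMMA_MOB: spec.mob_fraction_gamma,
    }
    group_vols = {
        Group.DAPI: spec.mean_volume_dapi,
        Group.ALPHA_MOB: spec.mean_volume_alpha,
        Group.GAMMA_MOB: spec.mean_volume_gamma,
    }
    dapi_counts = rng.poisson(mean_per_field, size=n_fields)
    for group in Group:
        if group is Group.DAPI:
            counts = dapi_counts
        else:
            counts = rng.binomial(dapi_counts, group_fracs[group])
        areas = _draw_areas(
            rng, int(counts.sum()), group_vols[group], spec.volume_cv, config.min_area_um2
        )
        rows.append(
            pd.DataFrame(
                {
                    "group": group.value,
                    "field_id": np.repeat(np.arange(1, n_fields + 1), counts),
                    "cell_area_um2": areas,
                }
            )
        )
    return CellCensus(
        sample_id=sample_id,
        cells=pd.concat(rows, ignore_index=True),
        n_fields=n_fields,
        filtered_volume_ml=filtered_volume_ml,
        field_area_fraction=field_area_fraction,
    )


_MONTHS = ["2015-05", "2015-06", "2015-07", "2015-08", "2015-09", "2015-10", "2015-11"]


def gen_lake_suite(n_lakes: int = 6, seed: int = 0) -> list[LakeSeason]:
    """A suite of lake scenarios with seasonal profile sequences.

    Lakes span a DOC gradient of ~2.6-10.9 mg L-1 with light attenuation
    (kd_par) and hypolimnetic CH4 accumulation both rising with DOC
    (browner, more humic lakes stratify shallower and store more CH4).
    At least one lake — exactly two when ``n_lakes`` is 6, mirroring the
    emulated six-lake set — is shallow and unstratified. Each lake gets
    4-16 dated profiles across the open-water season with a deepening
    oxycline and a growing hypolimnetic CH4 stock.
    """
    if n_lakes < 2:
        raise InvalidDataError("need >= 2 lakes")
    rng = _rng(seed, 4)
    n_unstrat = 2 if n_lakes == 6 else max(1, n_lakes // 3)
    docs = np.linspace(2.6, 10.9, n_lakes)
    seasons: list[LakeSeason] = []
    for i in range(n_lakes):
        doc = float(docs[i])
        kd = 0.12 + 0.075 * doc + float(rng.uniform(-0.03, 0.03))
        unstratified = i < n_unstrat
        if unstratified:
            max_depth = float(rng.integers(4, 9))
            scenario = LakeScenario(
                lake_id=f"L{i + 1:02d}",
                max_depth=max_depth,
                surface_area=float(rng.uniform(5e4, 5e5)),
                hypso_shape_exponent=float(rng.uniform(0.8, 1.5)),
                doc=doc,
                kd_par=kd,
                stratified=False,
                epi_temp=float(rng.uniform(18, 24)),
                hypo_temp=float(rng.uniform(18, 24)),
                thermocline_depth=max_depth / 2.0,
                thermocline_width=1.0,
                surface_o2=float(rng.uniform(250, 265)),
                bottom_o2=float(rng.uniform(150, 240)),
                surface_ch4=float(rng.uniform(0.02, 0.3)),
                bottom_ch4=float(rng.uniform(0.5, 4.0)),
                ch4_buildup_rate=0.2,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        else:
            max_depth = float(rng.integers(12, 31))
            # deeper CH4 stock in higher-DOC lakes
            bottom_ch4 = float(doc * rng.uniform(15.0, 19.0))
            scenario = LakeScenario(
                lake_id=f"L{i + 1:02d}",
                max_depth=max_depth,
                surface_area=float(rng.uniform(1e5, 2e6)),
                hypso_shape_exponent=float(rng.uniform(1.0, 2.5)),
                doc=doc,
                kd_par=kd,
                stratified=True,
                epi_temp=float(rng.uniform(20, 25)),
                hypo_temp=float(rng.uniform(4, 8)),
                thermocline_depth=float(np.clip(8.0 - 0.45 * doc, 2.0, max_depth - 3.0)),
                thermocline_width=float(rng.uniform(2.0, 4.0)),
                surface_o2=float(rng.uniform(250, 265)),
                bottom_o2=float(rng.uniform(10.0, 30.0)),
                surface_ch4=float(rng.uniform(0.02, 0.3)),
                bottom_ch4=min(bottom_ch4, 455.0),
                ch4_buildup_rate=0.06,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        n_prof = int(rng.integers(4, 17))
        profiles = []
        for j in range(n_prof):
            frac = j / max(n_prof - 1, 1)
            if scenario.stratified:
                # season: thermocline deepens, CH4 stock grows, bottom O2 erodes
                snap = replace(
                    scenario,
                    thermocline_depth=float(
                        np.clip(
                            scenario.thermocline_depth + 2.0 * frac,
                            1.0,
                            scenario.max_depth - 2.0,
                        )
                    ),
                    bottom_ch4=scenario.bottom_ch4 * (0.35 + 0.65 * frac),
                    bottom_o2=scenario.bottom_o2 * (1.0 - 0.85 * frac),
                )
            else:
                snap = scenario
            prof = gen_profile(snap, grid_step=2.0 if scenario.max_depth > 25 else 1.0)
            month = _MONTHS[int(round(frac * (len(_MONTHS) - 1)))]
            prof = DepthProfile(
                lake_id=prof.lake_id,
                date=f"{month}-{15 + (j % 10):02d}",
                depth=prof.depth,
                temp=prof.temp,
                o2=prof.o2,
                ch4=prof.ch4,
                par=prof.par,
            )
            profiles.append(prof)
        seasons.append(LakeSeason(scenario=scenario, profiles=profiles))
    return seasons
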