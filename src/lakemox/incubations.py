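"""Rate estimation from bottle incubations.

Methanotrophic carbon consumption (MCC) comes from the first-order decay
of CH4 in unamended dark incubations: the rate constant ``k`` (d-1) is
the absolute OLS slope of ln(CH4) on time, and the oxidation rate at
each time point is ``k`` times the observed concentration. Heterotrophic
carbon consumption (HCC) is the sum of leucine-derived bacterial
production (HBP) and O2-drawdown respiration (HBR, respiratory quotient
1 by default), with the respiration rate of filtered incubations scaled
back up by the microscopically measured biomass reduction factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidDataError
from .gas_chem import MOLAR_MASS_C, MOLAR_MASS_O2, ch4_umol_to_ugc


@dataclass(frozen=True)
class IncubationSeries:
    """Timed concentrations from one incubation (replicate flasks pooled).

    ``time`` is in days for CH4 decay series and in hours for O2
    drawdown series (``time_unit`` records which); ``conc`` holds the
    matching concentrations (umol L-1 for CH4, mg L-1 for O2);
    ``flask_id`` labels the replicate flask of each observation.
    """

    sample_id: str
    analyte: str  # "ch4" or "o2"
    time: np.ndarray
    conc: np.ndarray
    flask_id: np.ndarray
    time_unit: str = "d"

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "conc", np.asarray(self.conc, dtype=float))
        object.__setattr__(self, "flask_id", np.asarray(self.flask_id))
        if self.time.size != self.conc.size or self.time.size != self.flask_id.size:
            raise InvalidDataError("time, conc and flask_id must share one length")

    @property
    def n_timepoints(self) -> int:
        return np.unique(self.time).size


@dataclass(frozen=True)
class DecayFit:
    """First-order decay fit: k = |slope| of ln(conc) vs time (d-1)."""

    k: float
    intercept_ln_c0: float
    r_squared: float
    n_points: int
    qc_pass: bool


@dataclass(frozen=True)
class O2SlopeFit:
    """Linear O2 drawdown fit (mg O2 L-1 h-1, absolute slope)."""

    slope: float
    r_squared: float
    n_points: int
    duration_h: float
    duration_ok: bool  # incubation ran >= 48 h
    increasing: bool  # O2 rose over time (biologically unexpected)


@dataclass(frozen=True)
class HeterotrophyConfig:
    """Conversion factors for the heterotrophy rate chain.

    ``leucine_to_carbon`` (kg C per mol leucine) and ``isotope_dilution``
    are package defaults for the standard leucine protocol and are meant
    to be tuned to the local protocol; ``qc_threshold`` is the minimum
    r-squared of an acceptable decay fit.
    """

    respiratory_quotient: float = 1.0
    leucine_to_carbon: float = 1.55  # kg C mol-1
    isotope_dilution: float = 2.0
    qc_threshold: float = 0.92

    def __post_init__(self) -> None:
        for name in ("respiratory_quotient", "leucine_to_carbon", "isotope_dilution", "qc_threshold"):
            if getattr(self, name) <= 0:
                raise InvalidDataError(f"{name} must be > 0")


DEFAULT_HETEROTROPHY = HeterotrophyConfig()


@dataclass(frozen=True)
class RateResult:
    """Per-incubation carbon consumption rates (ug C L-1 d-1)."""

    mcc: float
    hbp: float
    hbr: float
    hcc: float
    mox_umol: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.mcc, self.hbp, self.hbr, self.mox_umol) < 0:
            raise InvalidDataError("rates must be >= 0")
        if not np.isclose(self.hcc, self.hbp + self.hbr, rtol=0, atol=1e-9):
            raise InvalidDataError("hcc must equal hbp + hbr exactly")


def _ols(x: np.ndarray, y: np.ndarray):
    if np.ptp(y) == 0:  # flat series: zero slope, r2 degenerate -> perfect fit
        return 0.0, float(y[0]), 1.0
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.rvalue**2


def fit_first_order_decay(
    series: IncubationSeries,
    qc_threshold: float = DEFAULT_HETEROTROPHY.qc_threshold,
    pooled: bool = True,
):
    """OLS of ln(concentration) on time; k is the absolute slope.

    Replicate flasks are pooled into one regression by default (more
    points per fit); ``pooled=False`` instead returns one
    :class:`DecayFit` per flask. A fit passes QC when its r-squared
    exceeds ``qc_threshold``.
    """
    if not pooled:
        return [
            fit_first_order_decay(
                IncubationSeries(
                    series.sample_id,
                    series.analyte,
                    series.time[series.flask_id == f],
                    series.conc[series.flask_id == f],
                    series.flask_id[series.flask_id == f],
                    series.time_unit,
                ),
                qc_threshold,
            )
            for f in np.unique(series.flask_id)
        ]
    if series.n_timepoints < 3:
        raise InsufficientDataError("decay fit needs >= 3 time points")
    if np.any(series.conc <= 0):
        raise InvalidDataError("nonpositive concentration: log-linear fit undefined")
    slope, intercept, r2 = _ols(series.time, np.log(series.conc))
    return DecayFit(
        k=abs(slope),
        intercept_ln_c0=intercept,
        r_squared=r2,
        n_points=series.time.size,
        qc_pass=bool(r2 > qc_threshold),
    )


def mox_timepoint_rates(fit: DecayFit, concentrations) -> np.ndarray:
    """Oxidation rate at each time point: k x observed CH4 (umol L-1 d-1)."""
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise InvalidDataError("concentrations must be >= 0")
    return fit.k * conc


def mcc_from_mox(mox_umol_l_d: float) -> float:
    """Methanotrophic C consumption, ug C L-1 d-1, from a MOX rate in uM d-1.

    CH4 is the sole carbon source of obligate methanotrophs, so every
    oxidized mole of CH4 is one mole of consumed carbon.
    """
    return ch4_umol_to_ugc(mox_umol_l_d)


def fit_o2_consumption(series: IncubationSeries) -> O2SlopeFit:
    """Absolute OLS slope of O2 (mg L-1) on time (h).

    Flags incubations shorter than 48 h and series where O2 increased.
    """
    if series.n_timepoints < 3:
        raise InsufficientDataError("O2 fit needs >= 3 time points")
    slope, _, r2 = _ols(series.time, series.conc)
    duration = float(np.ptp(series.time))
    increasing = slope > 0
    if increasing:
        warnings.warn(
            f"O2 increased over time in {series.sample_id}; returning |slope|",
            stacklevel=2,
        )
    return O2SlopeFit(
        slope=abs(slope),
        r_squared=r2,
        n_points=series.time.size,
        duration_h=duration,
        duration_ok=duration >= 48.0,
        increasing=bool(increasing),
    )


def hbr_from_o2_slope(
    slope_mg_l_h: float, config: HeterotrophyConfig = DEFAULT_HETEROTROPHY
) -> float:
    """Heterotrophic respiration, ug C L-1 d-1, from an O2 slope.

    Unit chain: mg O2 L-1 h-1 x 24 -> mg O2 L-1 d-1; / 31.998 x 1000 ->
    umol O2 L-1 d-1; x RQ -> umol C; x 12.011 -> ug C L-1 d-1.
    """
    if slope_mg_l_h < 0:
        raise InvalidDataError("O2 slope must be >= 0 (pass the absolute slope)")
    umol_o2 = slope_mg_l_h * 24.0 / MOLAR_MASS_O2 * 1000.0
    return umol_o2 * config.respiratory_quotient * MOLAR_MASS_C


def hbp_from_leucine(
    incorporation_pmol_l_h: float, config: HeterotrophyConfig = DEFAULT_HETEROTROPHY
) -> float:
    """Heterotrophic production, ug C L-1 d-1, from leucine incorporation.

    pmol leu L-1 h-1 x 24 -> pmol L-1 d-1; x leucine_to_carbon
    (kg C mol-1 = 1e-3 ug C pmol-1) x isotope_dilution -> ug C L-1 d-1.
    """
    if incorporation_pmol_l_h < 0:
        raise InvalidDataError("incorporation must be >= 0")
    return (
        incorporation_pmol_l_h
        * 24.0
        * config.leucine_to_carbon
        * 1e-3
        * config.isotope_dilution
    )


def apply_filtration_factor(
    filtered_rate: float,
    unfiltered_nonmob_biomass: float,
    filtered_nonmob_biomass: float,
) -> float:
    """Scale a filtered-incubation rate back to the whole community.

    The factor is the ratio of unfiltered to filtered non-MOB biomass;
    filtration removes biomass so the factor is normally >= 1, and a
    factor < 1 triggers a warning but is honoured.
    """
    if unfiltered_nonmob_biomass <= 0 or filtered_nonmob_biomass <= 0:
        raise InvalidDataError("biomasses must be > 0")
    factor = unfiltered_nonmob_biomass / filtered_nonmob_biomass
    if factor < 1:
        warnings.warn(
            f"filtration factor {factor:.3g} < 1: filtration appears to have added biomass",
            stacklevel=2,
        )
    return filtered_rate * factor


def total_hcc(hbp: float, hbr: float) -> float:
    """Total heterotrophic C consumption: exact sum of HBP and HBR."""
    if hbp < 0 or hbr < 0:
        raise InvalidDataError("rates must be >= 0")
    return hbp + hbr
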