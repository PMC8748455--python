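"""Season-level synthesis: light attenuation, loess crossing, regressions.

Summaries across the season and across lakes: the loess-smoothed
relationship of methanotrophic and heterotrophic C consumption along the
CH4:O2 gradient and the substrate ratio at which methanotrophy overtakes
heterotrophy; per-lake distributions of the whole-column methanotrophy
fraction; linear regressions of the summer-mean fraction against lake
DOC and light attenuation (Kd PAR), including the covariate value at
which methanotrophy becomes the majority (>50%) pathway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess

from .column import ColumnBudget
from .errors import InsufficientDataError, InvalidDataError


@dataclass(frozen=True)
class KdFit:
    """PAR attenuation coefficient: |slope| of ln(PAR) on depth (m-1)."""

    kd: float
    r_squared: float
    n_points: int


def kd_from_par(depth, par) -> KdFit:
    """Kd PAR from a light profile: absolute log-linear slope vs depth."""
    depth = np.asarray(depth, dtype=float)
    par = np.asarray(par, dtype=float)
    if depth.size != par.size:
        raise InvalidDataError("depth and PAR must share one length")
    if depth.size < 3:
        raise InsufficientDataError("Kd fit needs >= 3 points")
    if np.any(par <= 0):
        raise InvalidDataError("PAR values must be > 0 for the log fit")
    x = np.column_stack([np.ones(depth.size), depth])
    beta, *_ = np.linalg.lstsq(x, np.log(par), rcond=None)
    fitted = x @ beta
    y = np.log(par)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return KdFit(kd=abs(float(beta[1])), r_squared=r2, n_points=depth.size)


@dataclass(frozen=True)
class CrossingEstimate:
    """CH4:O2 ratio at which loess-smoothed MCC overtakes HCC."""

    ratio_at_crossing: float
    uncertainty_halfwidth: float
    defined: bool


def _loess_crossing(
    log_ratio: np.ndarray,
    log_mcc: np.ndarray,
    log_hcc: np.ndarray,
    span: float,
    grid: np.ndarray,
) -> float | None:
    """Ratio where the smoothed log-MCC curve first crosses log-HCC upward."""
    mcc_fit = lowess(log_mcc, log_ratio, frac=span, xvals=grid)
    hcc_fit = lowess(log_hcc, log_ratio, frac=span, xvals=grid)
    diff = mcc_fit - hcc_fit
    sign = np.sign(diff)
    for i in range(diff.size - 1):
        if sign[i] < 0 <= sign[i + 1]:
            d0, d1 = diff[i], diff[i + 1]
            frac = d0 / (d0 - d1) if d0 != d1 else 0.0
            return float(np.exp(grid[i] + frac * (grid[i + 1] - grid[i])))
    return None


def crossing_ratio(
    ratio,
    mcc,
    hcc,
    span: float = 0.75,
    n_boot: int = 200,
    seed: int = 0,
    n_grid: int = 200,
) -> CrossingEstimate:
    """Loess-based estimate of the MCC = HCC crossing ratio.

    MCC, HCC and the CH4:O2 ratio are smoothed on log scales; the
    crossing is the ratio where the predicted MCC curve first rises
    above the predicted HCC curve (linear root-finding on a dense log
    grid). The uncertainty halfwidth is half the central 95% spread of
    the crossing over ``n_boot`` bootstrap resamples of the points.
    ``defined`` is False when the curves never cross.
    """
    ratio = np.asarray(ratio, dtype=float)
    mcc = np.asarray(mcc, dtype=float)
    hcc = np.asarray(hcc, dtype=float)
    if not ratio.size == mcc.size == hcc.size:
        raise InvalidDataError("ratio, mcc and hcc must share one length")
    if ratio.size < 10:
        raise InsufficientDataError("crossing estimate needs >= 10 points")
    if np.any(ratio <= 0) or np.any(mcc <= 0) or np.any(hcc <= 0):
        raise InvalidDataError("ratio, MCC and HCC must be > 0 (log scales)")

    order = np.argsort(ratio)  # permutation invariance
    lr, lm, lh = np.log(ratio[order]), np.log(mcc[order]), np.log(hcc[order])
    grid = np.linspace(lr.min(), lr.max(), n_grid)

    point = _loess_crossing(lr, lm, lh, span, grid)
    if point is None:
        return CrossingEstimate(float("nan"), float("nan"), defined=False)

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, lr.size, size=lr.size)
        idx.sort()
        est = _loess_crossing(lr[idx], lm[idx], lh[idx], span, grid)
        if est is not None:
            boots.append(est)
    if boots:
        # larger one-sided deviation of the central-95% bootstrap interval from
        # the point estimate: robust to the skew of the crossing's distribution
        lo, hi = np.percentile(boots, [2.5, 97.5])
        halfwidth = float(max(point - lo, hi - point, 0.0))
    else:
        halfwidth = float("nan")
    return CrossingEstimate(point, halfwidth, defined=True)


@dataclass(frozen=True)
class SeasonSummary:
    """Distribution of the methanotrophy fraction across one lake's season."""

    lake_id: str
    n_profiles: int
    mean_fraction: float
    median_fraction: float
    q1_fraction: float
    q3_fraction: float
    whisker_low: float
    whisker_high: float
    mean_ratio_volume_fraction: float
    doc: float | None = None
    kd_par: float | None = None


def season_summary(
    budgets: list[ColumnBudget],
    doc: float | None = None,
    kd_par: float | None = None,
) -> SeasonSummary:
    """Boxplot-style summary of per-profile methanotrophy fractions.

    Quartiles use linear interpolation between order statistics;
    whiskers extend to the most extreme data point within 1.5 IQR of
    the hinges. Undefined fractions (zero total consumption) are
    excluded.
    """
    if not budgets:
        raise InsufficientDataError("need >= 1 budget")
    fractions = np.array(
        [b.fraction_methanotrophy for b in budgets if b.fraction_defined], dtype=float
    )
    if fractions.size == 0:
        raise InvalidDataError("no defined methanotrophy fractions in this season")
    q1, med, q3 = np.percentile(fractions, [25, 50, 75])
    iqr = q3 - q1
    lo_bound, hi_bound = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = fractions[(fractions >= lo_bound) & (fractions <= hi_bound)]
    return SeasonSummary(
        lake_id=budgets[0].lake_id,
        n_profiles=int(fractions.size),
        mean_fraction=float(fractions.mean()),
        median_fraction=float(med),
        q1_fraction=float(q1),
        q3_fraction=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        mean_ratio_volume_fraction=float(
            np.mean([b.volume_fraction_ratio_above for b in budgets])
        ),
        doc=doc,
        kd_par=kd_par,
    )


def lake_plot_order(summaries: list[SeasonSummary]) -> list[str]:
    """Lake ids sorted by increasing mean volume share with CH4:O2 > 0.6."""
    ranked = sorted(summaries, key=lambda s: s.mean_ratio_volume_fraction)
    return [s.lake_id for s in ranked]


@dataclass(frozen=True)
class CovariateFit:
    """OLS of the summer-mean methanotrophy fraction on a lake covariate."""

    covariate: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_lakes: int
    x_at_50pct: float  # covariate value where the fit predicts 50%
    threshold_defined: bool


def fraction_vs_covariate(
    summaries: list[SeasonSummary],
    covariate: str,
    include: list[str] | None = None,
) -> CovariateFit:
    """Linear regression of mean fraction on ``doc`` or ``kd_par``.

    ``include`` restricts the fit to the named lakes (the headline
    regressions use the stratified, hypolimnion-forming lakes only).
    Also reports the covariate value where the fitted line predicts a
    50% methanotrophy share — the majority-methanotrophy threshold —
    flagged undefined when the slope is (numerically) zero.
    """
    if covariate not in ("doc", "kd_par"):
        raise InvalidDataError("covariate must be 'doc' or 'kd_par'")
    subset = [s for s in summaries if include is None or s.lake_id in include]
    if len(subset) < 3:
        raise InsufficientDataError("regression needs >= 3 included lakes")
    x = np.array([getattr(s, covariate) for s in subset], dtype=float)
    if np.any(~np.isfinite(x)):
        raise InvalidDataError(f"missing {covariate} for an included lake")
    y = np.array([s.mean_fraction for s in subset], dtype=float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    defined = abs(slope) > 1e-12
    x50 = (50.0 - intercept) / slope if defined else float("nan")
    return CovariateFit(
        covariate=covariate,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n_lakes=len(subset),
        x_at_50pct=float(x50),
        threshold_defined=bool(defined),
    )
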