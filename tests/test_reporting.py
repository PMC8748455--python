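"""Season statistics: Kd, loess crossing, summaries, covariate fits."""

import numpy as np
import pytest

from lakemox import (
    ColumnBudget,
    crossing_ratio,
    fraction_vs_covariate,
    kd_from_par,
    lake_plot_order,
    season_summary,
)
from lakemox.reporting import SeasonSummary
from lakemox.errors import InsufficientDataError, InvalidDataError


class TestKd:
    def test_exact_exponential_profile(self):
        z = np.arange(0.0, 11.0)
        fit = kd_from_par(z, 1000.0 * np.exp(-0.5 * z))
        assert fit.kd == pytest.approx(0.5, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_light_zero_attenuation(self):
        z = np.arange(0.0, 6.0)
        assert kd_from_par(z, np.full(6, 800.0)).kd == pytest.approx(0.0, abs=1e-12)

    def test_noisy_profile_recovers_generating_kd(self):
        rng = np.random.default_rng(17)
        z = np.arange(0.0, 16.0)
        estimates = []
        for _ in range(200):
            par = 1200.0 * np.exp(-0.7 * z) * rng.lognormal(0.0, 0.1, z.size)
            estimates.append(kd_from_par(z, par).kd)
        assert np.mean(estimates) == pytest.approx(0.7, rel=0.02)

    def test_nonpositive_par_rejected(self):
        with pytest.raises(InvalidDataError):
            kd_from_par([0, 1, 2], [100.0, 0.0, 1.0])


def _crossing_points(cross_at=0.6, n=60, noise=0.0, seed=0):
    """MCC/HCC point cloud constructed to cross exactly at `cross_at`."""
    rng = np.random.default_rng(seed)
    ratio = np.geomspace(0.01, 100.0, n)
    hcc = np.full(n, 80.0)
    mcc = hcc * (ratio / cross_at) ** 1.2
    if noise > 0:
        mcc = mcc * rng.lognormal(0.0, noise, n)
        hcc = hcc * rng.lognormal(0.0, noise, n)
    return ratio, mcc, hcc


class TestCrossingRatio:
    def test_recovers_constructed_crossing(self):
        ratio, mcc, hcc = _crossing_points()
        est = crossing_ratio(ratio, mcc, hcc, seed=1)
        assert est.defined
        assert abs(est.ratio_at_crossing - 0.6) <= max(est.uncertainty_halfwidth, 0.1)

    def test_never_crossing_curves_flagged_undefined(self):
        ratio = np.geomspace(0.01, 100.0, 40)
        hcc = np.full(40, 80.0)
        est = crossing_ratio(ratio, hcc / 10.0, hcc, seed=1)
        assert not est.defined

    def test_permutation_invariance(self):
        ratio, mcc, hcc = _crossing_points(noise=0.2, seed=4)
        est1 = crossing_ratio(ratio, mcc, hcc, seed=9)
        perm = np.random.default_rng(0).permutation(ratio.size)
        est2 = crossing_ratio(ratio[perm], mcc[perm], hcc[perm], seed=9)
        assert est1.ratio_at_crossing == pytest.approx(est2.ratio_at_crossing, rel=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            crossing_ratio([1.0] * 5, [1.0] * 5, [2.0] * 5)


def _summary(lake_id, mean_fraction, doc, kd, ratio_frac=0.0):
    return SeasonSummary(
        lake_id=lake_id,
        n_profiles=5,
        mean_fraction=mean_fraction,
        median_fraction=mean_fraction,
        q1_fraction=mean_fraction,
        q3_fraction=mean_fraction,
        whisker_low=mean_fraction,
        whisker_high=mean_fraction,
        mean_ratio_volume_fraction=ratio_frac,
        doc=doc,
        kd_par=kd,
    )


class TestFractionVsCovariate:
    def test_exact_linear_relation_recovered(self):
        """Fractions placed on fraction = 50 + 5 (DOC - 6.5) recover the line."""
        summaries = [
            _summary(f"L{i}", 50.0 + 5.0 * (doc - 6.5), doc, 0.1 * doc)
            for i, doc in enumerate([3.0, 5.0, 7.0, 9.0, 11.0])
        ]
        fit = fraction_vs_covariate(summaries, "doc")
        assert fit.slope == pytest.approx(5.0, rel=1e-9)
        assert fit.intercept == pytest.approx(50.0 - 5.0 * 6.5, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.x_at_50pct == pytest.approx(6.5, rel=1e-9)

    def test_zero_slope_threshold_undefined(self):
        summaries = [
            _summary(f"L{i}", 20.0, doc, 0.1) for i, doc in enumerate([3.0, 6.0, 9.0, 12.0])
        ]
        fit = fraction_vs_covariate(summaries, "doc")
        assert not fit.threshold_defined

    def test_lake_filter_changes_set_size_by_two(self):
        summaries = [
            _summary(f"L{i}", 10.0 + 2 * i, 2.0 + i, 0.2 + 0.1 * i) for i in range(6)
        ]
        stratified = [s.lake_id for s in summaries[2:]]  # exclude the two shallow lakes
        full = fraction_vs_covariate(summaries, "doc")
        subset = fraction_vs_covariate(summaries, "doc", include=stratified)
        assert full.n_lakes - subset.n_lakes == 2

    def test_too_few_lakes_rejected(self):
        with pytest.raises(InsufficientDataError):
            fraction_vs_covariate([_summary("a", 10, 3, 0.3), _summary("b", 20, 5, 0.5)], "doc")


def _budget(lake, fraction, ratio_frac=0.0):
    return ColumnBudget(
        lake_id=lake,
        date="2015-07-01",
        mox=np.zeros(3),
        hcc=np.zeros(3),
        layers=np.array(["epilimnion"] * 3, dtype=object),
        depth_volumes=np.array([1.0, 1.0, 0.0]),
        total_mcc=fraction,
        total_hcc=100.0 - fraction,
        fraction_methanotrophy=fraction,
        anoxic_volume_fraction=0.0,
        volume_fraction_ratio_above=ratio_frac,
    )


class TestSeasonSummary:
    def test_single_profile_degenerate_summary(self):
        s = season_summary([_budget("L1", 42.0)])
        assert s.mean_fraction == s.median_fraction == 42.0
        assert s.n_profiles == 1

    def test_hand_computed_quartiles(self):
        """Fractions {10,20,30,40}: median 25, hinges 17.5/32.5 (linear interp)."""
        budgets = [_budget("L1", f) for f in (10.0, 20.0, 30.0, 40.0)]
        s = season_summary(budgets)
        assert s.median_fraction == pytest.approx(25.0)
        assert s.q1_fraction == pytest.approx(17.5)
        assert s.q3_fraction == pytest.approx(32.5)
        assert s.whisker_low == 10.0 and s.whisker_high == 40.0

    def test_permutation_invariance(self):
        fr = [5.0, 60.0, 22.0, 13.0]
        a = season_summary([_budget("L1", f) for f in fr])
        b = season_summary([_budget("L1", f) for f in reversed(fr)])
        assert a.median_fraction == b.median_fraction
        assert a.q1_fraction == b.q1_fraction

    def test_plot_order_follows_ratio_volume_fraction(self):
        summaries = [
            _summary("high", 50.0, 9.0, 0.9, ratio_frac=0.8),
            _summary("low", 5.0, 3.0, 0.3, ratio_frac=0.01),
            _summary("mid", 20.0, 6.0, 0.6, ratio_frac=0.3),
        ]
        assert lake_plot_order(summaries) == ["low", "mid", "high"]
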