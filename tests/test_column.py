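"""Stratification detection, slab volumes, and the whole-column budget."""

import math

import numpy as np
import pytest

from lakemox import (
    DepthProfile,
    Hypsography,
    LayerPartition,
    StratificationConfig,
    budget,
    column_hcc,
    column_mox,
    layer_boundaries,
    layer_volumes,
    water_density,
)
from lakemox.column import EPILIMNION, HYPOLIMNION, METALIMNION, assign_layers
from lakemox.errors import ConfigurationError, ExtrapolationError, OutOfDomainError


def _profile(depth, temp, o2, ch4):
    return DepthProfile("toy", "2015-07-01", depth, temp, o2, ch4)


class TestWaterDensity:
    def test_maximum_near_four_degrees(self):
        grid = np.linspace(0.0, 40.0, 401)
        rho = water_density(grid)
        assert abs(grid[np.argmax(rho)] - 4.0) < 0.1
        assert water_density(4.0) > water_density(25.0)

    def test_hand_evaluated_polynomial_at_20c(self):
        expected = 1000.0 * (
            1.0 - (20.0 + 288.9414) / (508929.2 * (20.0 + 68.12963)) * (20.0 - 3.9863) ** 2
        )
        assert water_density(20.0) == pytest.approx(expected, rel=1e-12)
        assert water_density(20.0) == pytest.approx(998.234, abs=1e-3)

    def test_out_of_range_rejected(self):
        with pytest.raises(OutOfDomainError):
            water_density(45.0)


class TestLayerBoundaries:
    def test_isothermal_profile_unstratified(self):
        z = np.arange(0.0, 11.0)
        part = layer_boundaries(_profile(z, np.full(z.size, 15.0), z * 0 + 100, z * 0 + 1))
        assert not part.stratified

    def test_sub_cutoff_range_unstratified(self):
        z = np.arange(0.0, 11.0)
        temp = 15.0 - 0.05 * z  # total range 0.5 degC < 1 degC cutoff
        part = layer_boundaries(_profile(z, temp, z * 0 + 100, z * 0 + 1))
        assert not part.stratified

    def test_step_profile_boundaries_bracket_the_jump(self):
        z = np.arange(0.0, 11.0)
        temp = np.where(z <= 5, 25.0, np.where(z >= 7, 10.0, 17.5))
        part = layer_boundaries(_profile(z, temp, z * 0 + 100, z * 0 + 1))
        assert part.stratified
        assert 5.0 <= part.epi_bottom <= 7.0
        assert 5.0 <= part.meta_bottom <= 7.0
        assert part.epi_bottom <= part.meta_bottom

    def test_single_steep_segment_bracketed(self):
        """With exactly one super-threshold segment both bounds straddle it."""
        z = np.arange(0.0, 9.0)
        temp = np.where(z <= 4, 22.0, 8.0)  # single jump between 4 and 5 m
        part = layer_boundaries(_profile(z, temp, z * 0 + 100, z * 0 + 1))
        # brute force: density slope exceeds threshold only on segment [4, 5]
        rho = water_density(temp)
        slopes = np.diff(rho)
        over = np.flatnonzero(slopes >= 0.1)
        assert over.tolist() == [4]
        assert 4.0 <= part.epi_bottom <= 5.0
        assert 4.0 <= part.meta_bottom <= 5.0


class TestLayerVolumes:
    def test_cylinder_slabs(self):
        z = np.arange(0.0, 11.0)
        hypso = Hypsography("cyl", z, np.full(z.size, 500.0))
        vols = layer_volumes(hypso, z)
        assert np.allclose(vols, 500.0)

    def test_quadratic_taper_matches_closed_form(self):
        """area = A0 (1 - z/20)^2 integrates to A0 * 20 / 3 exactly."""
        z = np.arange(0.0, 21.0)
        a0 = 1e6
        hypso = Hypsography("cone", z, a0 * (1 - z / 20.0) ** 2)
        total = layer_volumes(hypso, z).sum()
        assert total == pytest.approx(a0 * 20.0 / 3.0, rel=0.01)

    def test_coarser_grid_still_within_two_percent(self):
        z_fine = np.arange(0.0, 21.0)
        a0 = 1e6
        hypso = Hypsography("cone", z_fine, a0 * (1 - z_fine / 20.0) ** 2)
        total = layer_volumes(hypso, np.arange(0.0, 21.0, 2.0)).sum()
        assert total == pytest.approx(a0 * 20.0 / 3.0, rel=0.02)

    def test_volume_conservation_against_trapezoid(self):
        rng = np.random.default_rng(9)
        z = np.arange(0.0, 31.0)
        area = np.sort(rng.uniform(0, 1e6, z.size))[::-1].copy()
        hypso = Hypsography("rand", z, area)
        assert layer_volumes(hypso, z).sum() == pytest.approx(
            np.trapezoid(area, z), rel=1e-9
        )

    def test_grid_beyond_hypsography_rejected(self):
        hypso = Hypsography("shallow", np.arange(0.0, 6.0), np.linspace(100, 0, 6))
        with pytest.raises(ExtrapolationError):
            layer_volumes(hypso, np.arange(0.0, 11.0))


class TestColumnRates:
    def test_fully_anoxic_column_zero_mox(self):
        z = np.arange(0.0, 6.0)
        prof = _profile(z, np.full(6, 10.0), np.full(6, 2.0), np.full(6, 50.0))
        rates, anoxic = column_mox(prof)
        assert np.all(rates == 0)
        assert np.all(anoxic)

    def test_uniform_oxic_column_constant_rate(self):
        z = np.arange(0.0, 6.0)
        prof = _profile(z, np.full(6, 15.0), np.full(6, 100.0), np.full(6, 10.0))
        rates, anoxic = column_mox(prof)
        assert not np.any(anoxic)
        assert np.allclose(rates, rates[0])
        assert rates[0] > 0

    def test_mixed_profile_nonzero_only_where_oxic(self):
        z = np.arange(0.0, 6.0)
        o2 = np.array([150.0, 120.0, 80.0, 30.0, 4.0, 1.0])
        prof = _profile(z, np.full(6, 15.0), o2, np.full(6, 10.0))
        rates, anoxic = column_mox(prof)
        assert np.all(rates[~anoxic] > 0)
        assert np.all(rates[anoxic] == 0)

    def test_layer_assignment_with_boundary_tiebreak(self):
        z = np.arange(0.0, 10.0)
        part = LayerPartition(stratified=True, epi_bottom=3.0, meta_bottom=6.0)
        hcc = column_hcc(z, part, {EPILIMNION: 100.0, METALIMNION: 60.0, HYPOLIMNION: 30.0})
        assert hcc[3] == 100.0  # boundary depth belongs to the upper layer
        assert hcc[4] == 60.0
        assert hcc[6] == 60.0
        assert hcc[7] == 30.0
        assert set(np.unique(hcc)) == {100.0, 60.0, 30.0}

    def test_single_layer_lake_constant_hcc(self):
        z = np.arange(0.0, 5.0)
        part = LayerPartition(stratified=False)
        hcc = column_hcc(z, part, {EPILIMNION: 80.0})
        assert np.all(hcc == 80.0)

    def test_missing_layer_rate_named_in_error(self):
        z = np.arange(0.0, 10.0)
        part = LayerPartition(stratified=True, epi_bottom=3.0, meta_bottom=6.0)
        with pytest.raises(ConfigurationError, match="hypolimnion"):
            column_hcc(z, part, {EPILIMNION: 100.0, METALIMNION: 60.0})


class TestBudget:
    def _toy(self, ch4):
        z = np.array([0.0, 1.0, 2.0])
        prof = _profile(z, np.full(3, 20.0), np.full(3, 100.0), np.asarray(ch4, float))
        hypso = Hypsography("toy", z, np.array([1000.0, 600.0, 200.0]))
        part = LayerPartition(stratified=False)
        return prof, hypso, part

    def test_hand_computed_three_depth_budget(self):
        """Budget equals an explicit per-slab spreadsheet-style sum."""
        prof, hypso, part = self._toy([1.0, 2.0, 4.0])
        b = budget(prof, hypso, part, {EPILIMNION: 50.0})
        o2_cal = 1.0228 * 100.0 - 6.392
        # slabs 800 and 400 m3, split half-and-half onto their bounding depths
        vols = [800 / 2, 800 / 2 + 400 / 2, 400 / 2]

        def rate(ch4):
            return math.exp(
                20.08 + 0.79 * math.log(ch4) - 5669.61 / 293.15
            ) * (math.exp(-0.01 * o2_cal) - math.exp(-0.19 * o2_cal))

        mcc_g = sum(rate(c) * 12.011 * v for c, v in zip([1.0, 2.0, 4.0], vols)) * 1e-3
        hcc_g = sum(50.0 * v for v in vols) * 1e-3
        assert b.total_mcc == pytest.approx(mcc_g, rel=1e-9)
        assert b.total_hcc == pytest.approx(hcc_g, rel=1e-9)
        assert b.fraction_methanotrophy == pytest.approx(
            100.0 * mcc_g / (mcc_g + hcc_g), rel=1e-9
        )

    def test_fraction_shares_sum_to_hundred(self):
        prof, hypso, part = self._toy([1.0, 2.0, 4.0])
        b = budget(prof, hypso, part, {EPILIMNION: 50.0})
        assert b.fraction_methanotrophy + b.fraction_heterotrophy == pytest.approx(100.0)

    def test_zero_ch4_zero_methanotrophy_fraction(self):
        prof, hypso, part = self._toy([0.0, 0.0, 0.0])
        b = budget(prof, hypso, part, {EPILIMNION: 50.0})
        assert b.fraction_methanotrophy == 0.0

    def test_undefined_fraction_when_no_consumption(self):
        prof, hypso, part = self._toy([0.0, 0.0, 0.0])
        b = budget(prof, hypso, part, {EPILIMNION: 0.0})
        assert not b.fraction_defined

    def test_anoxic_column_zero_fraction(self):
        z = np.array([0.0, 1.0, 2.0])
        prof = _profile(z, np.full(3, 10.0), np.full(3, 2.0), np.array([10.0, 50.0, 200.0]))
        hypso = Hypsography("toy", z, np.array([1000.0, 600.0, 200.0]))
        b = budget(prof, hypso, LayerPartition(stratified=False), {EPILIMNION: 50.0})
        assert b.fraction_methanotrophy == 0.0
        assert b.anoxic_volume_fraction == pytest.approx(1.0)
        assert b.volume_fraction_ratio_above == pytest.approx(1.0)

    def test_fraction_monotone_in_hypolimnetic_ch4(self):
        fractions = []
        for bottom in [5.0, 20.0, 80.0, 300.0]:
            prof, hypso, part = self._toy([0.5, bottom / 4.0, bottom])
            b = budget(prof, hypso, part, {EPILIMNION: 50.0})
            fractions.append(b.fraction_methanotrophy)
        assert np.all(np.diff(fractions) > 0)

    def test_grid_refinement_invariance_within_two_percent(self):
        """Halving the grid step of a piecewise-linear lake moves totals < 2%."""
        z1 = np.arange(0.0, 11.0)
        temp = np.full(z1.size, 18.0)
        o2 = np.linspace(250.0, 50.0, z1.size)
        ch4 = np.linspace(0.5, 80.0, z1.size)
        hypso = Hypsography("g", z1, 1e5 * (1 - z1 / 10.0) ** 1.5)
        b1 = budget(
            DepthProfile("g", "d", z1, temp, o2, ch4),
            hypso,
            LayerPartition(stratified=False),
            {EPILIMNION: 50.0},
        )
        z2 = np.arange(0.0, 10.01, 0.5)
        interp = lambda v: np.interp(z2, z1, v)  # noqa: E731
        b2 = budget(
            DepthProfile("g", "d", z2, interp(temp), interp(o2), interp(ch4)),
            hypso,
            LayerPartition(stratified=False),
            {EPILIMNION: 50.0},
        )
        assert b2.fraction_methanotrophy == pytest.approx(
            b1.fraction_methanotrophy, rel=0.02
        )

    def test_layer_labels_follow_partition(self):
        z = np.arange(0.0, 10.0)
        labels = assign_layers(z, LayerPartition(True, 3.0, 6.0))
        assert labels[0] == EPILIMNION and labels[5] == METALIMNION and labels[9] == HYPOLIMNION
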