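"""Synthetic lake generator: determinism, physical sanity, envelopes."""

import dataclasses

import numpy as np
import pytest

from lakemox import (
    CensusSpec,
    Group,
    fit_first_order_decay,
    gen_cell_census,
    gen_hypsography,
    gen_incubation,
    gen_lake_suite,
    gen_profile,
    kd_from_par,
    relative_contributions,
)
from lakemox.errors import DegenerateLakeError, InvalidDataError
from lakemox.io import frame_bytes, profiles_to_frame


class TestGenProfile:
    def test_unstratified_is_isothermal(self, stratified_scenario):
        scn = dataclasses.replace(
            stratified_scenario, stratified=False, hypo_temp=stratified_scenario.epi_temp
        )
        prof = gen_profile(scn)
        assert np.ptp(prof.temp) < 1.0

    def test_ch4_envelope_hit_exactly(self, stratified_scenario):
        prof = gen_profile(stratified_scenario)
        assert prof.ch4.min() == pytest.approx(0.02)
        assert prof.ch4.max() == pytest.approx(455.0)

    def test_o2_envelope_and_monotonicity(self, stratified_scenario):
        prof = gen_profile(stratified_scenario)
        assert np.all(np.diff(prof.o2) <= 1e-9)
        assert np.all(np.diff(prof.ch4) >= -1e-9)
        assert prof.o2[0] == pytest.approx(260.0)
        assert prof.o2[-1] == pytest.approx(5.0)

    def test_seeded_determinism(self, stratified_scenario):
        a = gen_profile(stratified_scenario)
        b = gen_profile(stratified_scenario)
        assert frame_bytes(profiles_to_frame([a])) == frame_bytes(profiles_to_frame([b]))

    def test_temperature_within_physical_bounds(self, stratified_scenario):
        prof = gen_profile(stratified_scenario)
        assert prof.temp.min() >= 0.0 and prof.temp.max() <= 30.0

    def test_par_decay_matches_kd(self, stratified_scenario):
        prof = gen_profile(stratified_scenario)
        fit = kd_from_par(prof.depth, prof.par)
        assert fit.kd == pytest.approx(stratified_scenario.kd_par, rel=1e-9)

    def test_invalid_grid_step_rejected(self, stratified_scenario):
        with pytest.raises(InvalidDataError):
            gen_profile(stratified_scenario, grid_step=0.5)

    def test_too_shallow_lake_rejected(self, stratified_scenario):
        scn = dataclasses.replace(
            stratified_scenario, max_depth=1.0, stratified=False, thermocline_depth=0.5
        )
        with pytest.raises(DegenerateLakeError):
            gen_profile(scn, grid_step=2.0)


class TestGenHypsography:
    def test_zero_exponent_is_cylinder(self, stratified_scenario):
        scn = dataclasses.replace(stratified_scenario, hypso_shape_exponent=0.0)
        hypso = gen_hypsography(scn)
        assert np.all(hypso.area == stratified_scenario.surface_area)

    def test_quadratic_volume_against_closed_form(self, stratified_scenario):
        hypso = gen_hypsography(stratified_scenario)  # exponent 2, A0 1e6, zmax 20
        dz = np.diff(hypso.depth)
        total = (dz * (hypso.area[:-1] + hypso.area[1:]) / 2).sum()
        assert total == pytest.approx(1e6 * 20.0 / 3.0, rel=0.01)

    def test_bottom_area_is_zero(self, stratified_scenario):
        hypso = gen_hypsography(stratified_scenario)
        assert hypso.area[-1] == 0.0


class TestGenIncubation:
    def test_noise_free_exact_series(self):
        series = gen_incubation(0.5, 10.0, [0, 1, 2, 3], noise_cv=0.0, replicates=1)
        expected = 10.0 * np.exp(-0.5 * np.arange(4.0))
        assert np.allclose(series.conc, expected, rtol=1e-12)

    def test_zero_k_constant_series(self):
        series = gen_incubation(0.0, 7.5, [0, 1, 2, 3], noise_cv=0.0, replicates=1)
        assert np.all(series.conc == 7.5)

    def test_noise_free_round_trip_to_machine_precision(self):
        series = gen_incubation(0.31, 25.0, [0, 0.5, 1, 2, 4], noise_cv=0.0)
        assert fit_first_order_decay(series).k == pytest.approx(0.31, rel=1e-9)

    def test_replicates_share_times_but_not_noise(self):
        series = gen_incubation(0.5, 10.0, [0, 1, 2], noise_cv=0.1, replicates=2, seed=3)
        f1 = series.flask_id == "flask1"
        assert np.array_equal(series.time[f1], series.time[~f1])
        assert not np.allclose(series.conc[f1], series.conc[~f1])

    def test_negative_k_rejected(self):
        with pytest.raises(InvalidDataError):
            gen_incubation(-0.1, 10.0, [0, 1, 2])

    def test_seeded_determinism(self):
        a = gen_incubation(0.5, 10.0, [0, 1, 2], noise_cv=0.05, seed=12)
        b = gen_incubation(0.5, 10.0, [0, 1, 2], noise_cv=0.05, seed=12)
        assert np.array_equal(a.conc, b.conc)


class TestGenCellCensus:
    def test_group_mean_volumes_within_ten_percent(self):
        spec = CensusSpec(
            dapi_abundance=1e7,
            mob_fraction_alpha=0.02,
            mob_fraction_gamma=0.03,
            seed=21,
        )
        census = gen_cell_census(spec)
        metrics = relative_contributions(census)
        assert census.cells.groupby("group").size()[Group.DAPI.value] >= 1e4
        assert metrics[Group.DAPI.value].mean_volume == pytest.approx(0.3, rel=0.1)
        assert metrics[Group.ALPHA_MOB.value].mean_volume == pytest.approx(0.5, rel=0.1)
        assert metrics[Group.GAMMA_MOB.value].mean_volume == pytest.approx(0.9, rel=0.1)

    def test_zero_mob_fractions_give_dapi_only(self):
        spec = CensusSpec(dapi_abundance=1e6, mob_fraction_alpha=0.0, mob_fraction_gamma=0.0)
        census = gen_cell_census(spec)
        assert set(census.cells["group"]) == {Group.DAPI.value}

    def test_mob_count_share_within_observed_envelope(self):
        spec = CensusSpec(
            dapi_abundance=3e6, mob_fraction_alpha=0.004, mob_fraction_gamma=0.009, seed=2
        )
        census = gen_cell_census(spec)
        metrics = relative_contributions(census)
        mob_share = (
            metrics[Group.ALPHA_MOB.value].relative_abundance
            + metrics[Group.GAMMA_MOB.value].relative_abundance
        )
        assert 0.001 <= mob_share <= 0.05

    def test_all_areas_above_threshold(self):
        spec = CensusSpec(dapi_abundance=2e6, mob_fraction_alpha=0.01, mob_fraction_gamma=0.01)
        census = gen_cell_census(spec)
        assert census.cells["cell_area_um2"].min() >= 0.22

    def test_overfull_fractions_rejected(self):
        with pytest.raises(InvalidDataError):
            CensusSpec(dapi_abundance=1e6, mob_fraction_alpha=0.6, mob_fraction_gamma=0.5)

    def test_field_count_outside_protocol_needs_override(self):
        spec = CensusSpec(dapi_abundance=1e6, mob_fraction_alpha=0.0, mob_fraction_gamma=0.0)
        with pytest.raises(InvalidDataError):
            gen_cell_census(spec, n_fields=10)
        gen_cell_census(spec, n_fields=10, allow_any_fields=True)


class TestGenLakeSuite:
    def test_reproducible_six_lake_suite(self):
        a = gen_lake_suite(6, seed=42)
        b = gen_lake_suite(6, seed=42)
        assert [s.scenario for s in a] == [s.scenario for s in b]
        pa = profiles_to_frame([p for s in a for p in s.profiles])
        pb = profiles_to_frame([p for s in b for p in s.profiles])
        assert frame_bytes(pa) == frame_bytes(pb)

    def test_doc_gradient_coupled_to_light_attenuation(self):
        suite = gen_lake_suite(6, seed=1)
        doc = np.array([s.scenario.doc for s in suite])
        kd = np.array([s.scenario.kd_par for s in suite])
        assert doc.min() < 3.0 and doc.max() > 10.0
        assert np.corrcoef(doc, kd)[0, 1] > 0.9

    def test_doc_coupled_to_hypolimnetic_ch4(self):
        suite = gen_lake_suite(6, seed=1)
        strat = [s.scenario for s in suite if s.scenario.stratified]
        doc = np.array([s.doc for s in strat])
        ch4 = np.array([s.bottom_ch4 for s in strat])
        assert np.corrcoef(doc, ch4)[0, 1] > 0.5

    def test_exactly_two_unstratified_in_six(self):
        suite = gen_lake_suite(6, seed=5)
        assert sum(not s.scenario.stratified for s in suite) == 2

    def test_profile_counts_in_range(self):
        suite = gen_lake_suite(4, seed=3)
        for s in suite:
            assert 4 <= len(s.profiles) <= 16

    def test_concentration_envelopes_respected(self):
        suite = gen_lake_suite(6, seed=7)
        for s in suite:
            for p in s.profiles:
                assert p.ch4.min() >= 0.0 and p.ch4.max() <= 455.0
                assert p.o2.min() >= 0.0 and p.o2.max() <= 265.0
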