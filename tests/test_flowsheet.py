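import copy

import numpy as np
import pytest

from tal_biorefinery.flowsheet import (
    FacilitySpec,
    FeedstockSpec,
    FermentationSpec,
    InfeasibleTiterError,
    SeparationSpec,
    Stream,
    ferment,
    prepare_juice,
    run_facilities,
    separate,
    simulate,
)
from tal_biorefinery.solubility import DecarbModel


@pytest.fixture
def feed():
    return FeedstockSpec(feed_rate_wet_t_per_h=143.64)


class TestPrepareJuice:
    def test_perfect_extraction_leaves_no_sugar_in_bagasse(self, feed):
        perfect = FeedstockSpec(
            feed_rate_wet_t_per_h=feed.feed_rate_wet_t_per_h, extraction_efficiency=1.0
        )
        juice, bagasse, *_ = prepare_juice(perfect, 150.0)
        assert bagasse.get("sucrose") == 0.0
        assert bagasse.get("glucose") == 0.0

    def test_unit_mass_balance_closes(self, feed):
        juice, bagasse, _, evaporated, dilution = prepare_juice(feed, 150.0)
        mass_in = feed.feed_rate_wet_t_per_h * 1000.0 + dilution
        mass_out = juice.total_mass + bagasse.total_mass + evaporated
        assert mass_out == pytest.approx(mass_in, rel=1e-9)

    def test_juice_sugars_equal_feed_sugars_times_efficiency(self, feed):
        juice, _, *_ = prepare_juice(feed, 150.0)
        total = feed.feed_rate_wet_t_per_h * 1000.0
        assert juice.get("sucrose") == pytest.approx(
            total * feed.sucrose * feed.extraction_efficiency, rel=1e-12
        )
        assert juice.get("glucose") == pytest.approx(
            total * feed.glucose * feed.extraction_efficiency, rel=1e-12
        )

    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            FeedstockSpec(feed_rate_wet_t_per_h=100.0, water=0.5)


class TestFerment:
    def juice(self, sugar_conc=160.0):
        # 10 t/h sucrose + 1 t/h glucose in enough water for the target conc
        sugars = {"sucrose": 10000.0, "glucose": 1000.0}
        sugar_eq = sugars["sucrose"] * 1.052687 + sugars["glucose"]
        return Stream({**sugars, "h2o": 1000.0 * sugar_eq / sugar_conc})

    def test_batch_time_is_titer_over_productivity(self):
        from tal_biorefinery.flowsheet import _required_juice_sugar_conc

        spec = FermentationSpec(acetate_cofeed_ratio=0.2)
        res = ferment(self.juice(_required_juice_sugar_conc(spec)), spec)
        assert res.batch_time_h == pytest.approx(35.9 / 0.12, rel=1e-12)
        assert res.batch_time_h == pytest.approx(299.2, abs=0.05)

    def test_carbon_closes_exactly(self):
        from tal_biorefinery.flowsheet import _required_juice_sugar_conc

        spec = FermentationSpec(acetate_cofeed_ratio=0.2)
        juice = self.juice(_required_juice_sugar_conc(spec) * 1.05)
        res = ferment(juice, spec)
        c_in = (
            juice.get("sucrose") * (12 * 12.011 / 342.297)
            + juice.get("glucose") * (6 * 12.011 / 180.156)
            + res.sodium_acetate_purchase * (2 * 12.011 / 82.034)
        )
        c_out = res.broth.carbon_kg_per_h() + res.vent.carbon_kg_per_h()
        assert abs(c_in - c_out) / c_in < 1e-6

    def test_infeasible_titer_names_required_concentration(self):
        spec = FermentationSpec(titer_g_per_L=150.0, yield_fraction_of_theoretical=0.1)
        with pytest.raises(InfeasibleTiterError, match="g/L substrate"):
            ferment(self.juice(), spec)

    def test_dilute_juice_rejected_with_required_concentration(self):
        spec = FermentationSpec(acetate_cofeed_ratio=0.2)
        with pytest.raises(InfeasibleTiterError, match="required substrate"):
            ferment(self.juice(40.0), spec)

    def test_zero_yield_rejected(self):
        with pytest.raises(ValueError):
            FermentationSpec(yield_fraction_of_theoretical=0.0)

    def test_joint_yields_cannot_exceed_carbon(self):
        spec = FermentationSpec(
            yield_fraction_of_theoretical=1.0, cell_mass_yield_g_per_g=0.5
        )
        with pytest.raises(ValueError, match="carbon"):
            ferment(self.juice(), spec)


class TestSeparate:
    def broth(self, tal=4700.0, titer=35.9):
        water = 1000.0 * tal / titer
        return Stream(
            {"tal": tal, "citric_acid": 1900.0, "cell_mass": 2500.0, "h2o": water,
             "csl": 1300.0, "sodium_salts": 1500.0, "phosphate_salts": 40.0},
            temperature_C=30.0,
        )

    def test_overall_recovery_is_product_of_three_factors(self, tal_thermo):
        spec = SeparationSpec()
        res = separate(self.broth(), spec, tal_thermo)
        expected = (
            (1.0 - res.decarb_conversion)
            * res.crystallization_fraction
            * spec.crystal_retention_efficiency
        )
        assert res.overall_recovery == pytest.approx(expected, rel=1e-12)
        # and the factors are what the sub-models say independently
        assert res.product.get("tal") / self.broth().get("tal") == pytest.approx(
            expected, rel=1e-9
        )

    def test_baseline_ph_gives_decarb_factor_0791(self, tal_thermo):
        res = separate(self.broth(), SeparationSpec(), tal_thermo)
        assert 1.0 - res.decarb_conversion == pytest.approx(0.791, abs=1e-12)

    def test_no_decarb_limit_recovery_is_cryst_times_retention(self, tal_thermo):
        spec = SeparationSpec(maintained_pH=11.0)
        model = DecarbModel(((2.10, 0.0), (11.0, 0.0)))
        res = separate(self.broth(), spec, tal_thermo, decarb=model)
        assert res.overall_recovery == pytest.approx(
            res.crystallization_fraction * spec.crystal_retention_efficiency
        )

    def test_undersaturated_broth_warns_not_silent(self, tal_thermo):
        with pytest.warns(RuntimeWarning, match="no product"):
            separate(self.broth(tal=100.0, titer=3.0), SeparationSpec(), tal_thermo)

    def test_separation_mass_balance_closes(self, tal_thermo):
        broth = self.broth()
        res = separate(broth, SeparationSpec(maintained_pH=9.0), tal_thermo)
        mass_in = broth.total_mass + res.naoh_dose_kg_per_h
        mass_out = (
            res.product.total_mass + res.supernatant.total_mass
            + res.wet_solids.total_mass + res.vent.total_mass
            + res.water_evaporated_kg_per_h
        )
        assert mass_out == pytest.approx(mass_in, rel=1e-9)


class TestFacilities:
    def test_zero_combustibles_zero_electricity(self):
        res = run_facilities(Stream({}), [Stream({})], 0.0, 0.0, 100.0, FacilitySpec())
        assert res.electricity_produced_kwh_per_h == 0.0
        assert res.electricity_exported_kwh_per_h == 0.0
        assert res.electricity_purchased_kwh_per_h > 0.0  # parasitic load remains

    def test_produced_power_bounded_by_fuel_energy(self):
        spec = FacilitySpec()
        bagasse = Stream({"fiber": 20000.0, "h2o": 8000.0})
        res = run_facilities(bagasse, [Stream({})], 5.0, 0.0, 100.0, spec)
        bound = res.fuel_energy_GJ_per_h * spec.turbogenerator_efficiency * 277.778
        assert res.electricity_produced_kwh_per_h <= bound


class TestSimulate:
    def test_baseline_annual_production_near_design_capacity(self, baseline_run):
        assert baseline_run["system"].annual_tal_t == pytest.approx(13385.0, rel=0.05)

    def test_doubling_feed_doubles_product_exactly(self, cfg):
        double = copy.deepcopy(cfg)
        double["feedstock"]["annual_feed_wet_t"] *= 2.0
        base = simulate(cfg)
        scaled = simulate(double)
        assert scaled.annual_tal_t == pytest.approx(2.0 * base.annual_tal_t, rel=1e-9)

    def test_mass_and_carbon_closure(self, baseline_run):
        system = baseline_run["system"]
        assert system.mass_closure_residual < 1e-6
        assert system.carbon_closure_residual < 1e-6

    def test_simulate_is_deterministic(self, cfg):
        a, b = simulate(cfg), simulate(copy.deepcopy(cfg))
        assert a.annual_tal_t == b.annual_tal_t
        assert a.electricity_exported_kwh_per_h == b.electricity_exported_kwh_per_h
        assert a.unit_sizes == b.unit_sizes
        for name in a.streams:
            assert a.streams[name].flows == b.streams[name].flows

    def test_export_is_produced_minus_consumed_floored_at_zero(self, baseline_run):
        system = baseline_run["system"]
        expected = max(
            0.0,
            system.electricity_produced_kwh_per_h
            - system.electricity_consumed_kwh_per_h,
        )
        assert system.electricity_exported_kwh_per_h == pytest.approx(expected)

    def test_recovery_monotone_decreasing_in_decarb(self, cfg):
        recoveries = []
        for conv in (0.05, 0.209, 0.4):
            trial = copy.deepcopy(cfg)
            trial["solubility"]["decarb_anchors"] = [[2.10, conv], [11.0, conv]]
            recoveries.append(simulate(trial).overall_recovery)
        assert recoveries == sorted(recoveries, reverse=True)
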