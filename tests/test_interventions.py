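import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltshift import (
    InterventionSpec,
    SodiumProfile,
    build_schedule,
    get_intervention,
    intervention_cost_stream,
    load_registry,
    mg_to_mmol,
    required_annual_step,
    sex_scaled_reduction,
    solve_tax_schedule,
)
from saltshift.interventions import INTERVENTION_NAMES

PROFILE = SodiumProfile()


@pytest.mark.parametrize("mg, mmol", [(525, 22.8), (296, 12.9), (0, 0.0),
                                      (1244, 54.1)])
def test_mg_to_mmol_printed_conversions(mg, mmol):
    assert round(mg_to_mmol(mg), 1) == mmol


def test_mg_to_mmol_rejects_negative_mass():
    with pytest.raises(ValueError):
        mg_to_mmol(-1.0)


@given(st.floats(min_value=0, max_value=1e4, allow_nan=False))
@settings(max_examples=50, deadline=None)
def test_mass_molar_round_trip(mass):
    assert mg_to_mmol(mass) * 22.99 == pytest.approx(mass, abs=1e-9)


@pytest.mark.parametrize("sex, expected", [("male", 25.82), ("female", 20.04)])
def test_sex_scaled_reduction_uses_intake_ratios(sex, expected):
    assert sex_scaled_reduction(22.8, sex) == pytest.approx(expected,
                                                            abs=0.005)


def test_sex_scaled_reduction_zero_is_zero():
    assert sex_scaled_reduction(0.0, "male") == 0.0
    with pytest.raises(ValueError):
        sex_scaled_reduction(-1.0, "male")


def test_registry_contains_all_eight_interventions():
    registry = load_registry()
    assert set(registry) == set(INTERVENTION_NAMES)
    for spec in registry.values():
        assert spec.effect_mean > 0
        assert spec.direct_cost > 0


def test_counselling_effect_is_population_diluted():
    # 7.6 mmol/d per counselled hour x 4600 h/yr over 2.3 M adults
    spec = get_intervention("counselling")
    assert spec.effect_mean == pytest.approx(7.6 * 4600 / 2_300_000)
    assert spec.cost_recurring


class TestSchedules:
    def test_uk_package_ramps_to_full_effect_in_seven_years(self):
        sched = build_schedule(get_intervention("uk_package"))
        assert sched.cumulative_at(7) == pytest.approx(22.7)
        # equal annual increments of ~3.2 mmol/d
        assert np.allclose(sched.annual_reductions, 22.7 / 7)
        assert round(float(sched.annual_reductions[0]), 1) == 3.2
        assert sched.cumulative_at(30) == pytest.approx(22.7)

    def test_mandatory_all_is_immediate(self):
        sched = build_schedule(get_intervention("mandatory_all"))
        assert sched.cumulative_at(1) == pytest.approx(22.8)

    def test_uk_media_is_a_share_of_the_package(self):
        sched = build_schedule(get_intervention("uk_media"))
        assert sched.cumulative_at(7) == pytest.approx(6.81)
        assert round(sched.cumulative_at(7), 1) == 6.8

    def test_sinking_lid_reaches_target_in_six_years(self):
        sched = build_schedule(get_intervention("sinking_lid"))
        total = (3544 - 2300) / 22.99
        assert sched.cumulative_at(6) == pytest.approx(total)
        assert round(float(sched.annual_reductions[0]), 1) == 9.0
        assert sched.cumulative_at(40) == pytest.approx(total)

    def test_cumulative_reduction_never_exceeds_sex_baseline(self):
        for name in INTERVENTION_NAMES:
            sched = build_schedule(get_intervention(name))
            for sex in ("male", "female"):
                series = sched.series(80, sex)
                assert np.all(series <= PROFILE.intake(sex) / 22.99 + 1e-12)
                assert np.all(np.diff(series) >= -1e-12)

    def test_sunset_reverts_reduction_to_zero(self):
        spec = get_intervention("mandatory_all", sunset_year=20)
        sched = build_schedule(spec)
        assert sched.cumulative_at(20) == pytest.approx(22.8)
        assert sched.cumulative_at(21) == 0.0

    def test_unknown_schedule_kind_is_rejected(self):
        spec = get_intervention("mandatory_all")
        bad = InterventionSpec(**{**spec.__dict__, "schedule": "quadratic"})
        with pytest.raises(ValueError, match="schedule"):
            build_schedule(bad)


class TestTaxSchedule:
    BASELINE = 3544 / 22.99

    def solve(self, **kw):
        args = dict(baseline=self.BASELINE, target_mg=2300, elasticity=-0.1,
                    annual_cap=0.20, horizon=10)
        args.update(kw)
        return solve_tax_schedule(**args)

    def test_first_year_reduction_is_largest_at_6_5(self):
        sched = self.solve()
        assert round(float(sched.annual_reductions[0]), 1) == 6.5
        assert np.all(np.diff(sched.annual_reductions) < 0)

    def test_target_intake_reached_at_horizon(self):
        sched = self.solve()
        final_intake = self.BASELINE - sched.cumulative_at(10)
        assert final_intake == pytest.approx(2300 / 22.99, abs=0.1)

    def test_implied_price_increase_reported(self):
        sched = self.solve()
        p = 1 - (2300 / 3544) ** 0.1
        assert sched.annual_price_increase == pytest.approx(p / 0.1)

    def test_target_equal_to_baseline_gives_zero_schedule(self):
        sched = self.solve(target_mg=3544, horizon=1)
        assert np.allclose(sched.cumulative, 0.0)

    def test_infeasible_horizon_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            self.solve(annual_cap=0.01)

    def test_target_above_baseline_raises(self):
        with pytest.raises(ValueError):
            self.solve(target_mg=4000)

    def test_nonnegative_elasticity_raises(self):
        with pytest.raises(ValueError):
            self.solve(elasticity=0.1)


@pytest.mark.parametrize("baseline, target, years, step", [
    (3544, 2300, 6, 9.0),
    (3544, 3544, 4, 0.0),
    (3544, 2300, 3, 18.0),
])
def test_required_annual_step(baseline, target, years, step):
    assert required_annual_step(baseline, target, years) == step


def test_required_annual_step_rejects_nonpositive_years():
    with pytest.raises(ValueError):
        required_annual_step(3544, 2300, 0)


class TestCostStreams:
    def test_counselling_recurs_every_year(self):
        spec = get_intervention("counselling")
        for year in (0, 1, 30, 64):
            assert intervention_cost_stream(spec, year) == 575_000

    def test_label_programme_recurs(self):
        spec = get_intervention("endorsement_label")
        assert intervention_cost_stream(spec, 30) == 621_000

    def test_law_costs_are_one_off(self):
        spec = get_intervention("mandatory_all")
        assert intervention_cost_stream(spec, 0) == 3_680_000
        assert intervention_cost_stream(spec, 5) == 0.0

    def test_campaign_costs_fall_in_year_zero(self):
        assert intervention_cost_stream(get_intervention("uk_package"),
                                        0) == 12_100_000
        assert intervention_cost_stream(get_intervention("uk_media"),
                                        0) == 10_400_000

    def test_extra_recurring_enforcement_cost(self):
        spec = get_intervention("mandatory_all",
                                extra_recurring_cost=100_000.0)
        assert intervention_cost_stream(spec, 0) == 3_780_000
        assert intervention_cost_stream(spec, 5) == 100_000.0

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            intervention_cost_stream(get_intervention("counselling"), -1)
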