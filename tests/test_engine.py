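import math

import numpy as np
import pytest

from saltshift import (
    CohortState,
    EconomicSpec,
    ReductionSchedule,
    TransitionRates,
    TrendSpec,
    annual_cost,
    annual_qaly,
    get_intervention,
    project_rate,
    run_cohort,
    step_cohort,
)
from saltshift.strata import CostSet, StratumKey

from conftest import make_uniform_bundle


class TestProjectRate:
    def test_base_year_is_unchanged(self):
        assert project_rate(0.01, -0.02, 2011, 2026) == 0.01

    def test_two_years_of_decline(self):
        assert project_rate(0.01, -0.02, 2013, 2026) \
            == pytest.approx(0.01 * 0.98 ** 2)

    def test_held_constant_after_trend_end(self):
        held = project_rate(0.01, -0.02, 2040, 2026)
        assert held == pytest.approx(0.01 * 0.98 ** 15)
        assert held == project_rate(0.01, -0.02, 2026, 2026)

    def test_rejects_years_before_base(self):
        with pytest.raises(ValueError):
            project_rate(0.01, -0.02, 2010, 2026)


class TestStepCohort:
    def test_zero_rates_change_only_age_and_year(self):
        state = CohortState(healthy=0.6, chd_later=0.3, dead=0.1,
                            current_age=50, calendar_year=2015)
        new = step_cohort(state, TransitionRates(0, 0, 0, 0, 0))
        assert new.healthy == 0.6
        assert new.chd_later == pytest.approx(0.3)
        assert new.dead == pytest.approx(0.1)
        assert new.current_age == 51 and new.calendar_year == 2016

    def test_certain_incidence_moves_everyone_to_first_year_chd(self):
        new = step_cohort(CohortState(), TransitionRates(1, 0, 0, 0, 0))
        assert new.chd_year1 == pytest.approx(1.0)
        assert new.healthy == 0.0

    def test_two_state_toy_decays_geometrically(self):
        # healthy/dead only, 10% annual mortality: 0.9, 0.81, 0.729
        state = CohortState()
        rates = TransitionRates(0, 0, 0, 0, 0.1)
        for expected in (0.9, 0.81, 0.729):
            state = step_cohort(state, rates)
            assert state.healthy == pytest.approx(expected)
            assert state.alive == pytest.approx(expected)

    def test_first_year_tunnel_empties_into_later_state(self):
        state = CohortState(healthy=0.0, chd_year1=1.0)
        new = step_cohort(state, TransitionRates(0, 0, 0.2, 0, 0))
        assert new.chd_later == pytest.approx(0.8)
        assert new.dead == pytest.approx(0.2)
        assert new.chd_year1 == 0.0

    def test_occupancy_conserved_over_many_random_steps(self):
        rng = np.random.default_rng(42)
        state = CohortState()
        for i in range(10_000):
            r = rng.uniform(0, 0.3, size=5)
            state = step_cohort(state, TransitionRates(*r))
            assert abs(state.occupancies().sum() - 1.0) < 1e-9
            if state.alive < 1e-12:  # restart once everyone has died
                state = CohortState(
                    healthy=0.5, chd_year1=0.1, chd_later=0.15,
                    stroke_year1=0.1, stroke_later=0.15, dead=0.0)


class TestAccrual:
    def test_healthy_year_worth_one_minus_pyld(self):
        assert annual_qaly(CohortState(), pyld=0.288) == pytest.approx(0.712)

    def test_dead_accrue_nothing(self):
        state = CohortState(healthy=0, dead=1)
        assert annual_qaly(state) == 0.0
        costs = annual_cost(state, CostSet(2381, 16258, 5395, 20553, 5991))
        assert costs == {"cvd": 0.0, "non_cvd": 0.0}

    def test_disease_year_loses_disability_weight(self):
        state = CohortState(healthy=0, chd_later=1)
        assert annual_qaly(state, pyld=0.288) == pytest.approx(0.631)

    def test_costs_split_by_category_and_tunnel(self):
        costs = CostSet(2381, 16258, 5395, 20553, 5991)
        healthy = annual_cost(CohortState(), costs)
        assert healthy == {"cvd": 0.0, "non_cvd": 2381.0}
        first_year = annual_cost(CohortState(healthy=0, chd_year1=1), costs)
        assert first_year["cvd"] == 16258.0
        assert first_year["non_cvd"] == 2381.0
        later = annual_cost(CohortState(healthy=0, stroke_later=1), costs)
        assert later["cvd"] == 5991.0


# ----------------------------------------------------------------------
# independent brute-force oracle: per-stratum pure-Python enumeration
# ----------------------------------------------------------------------

_LAW = {30: 5.5, 40: 6.6, 50: 9.2, 60: 10.3}


def _oracle_hr(band, strongest, weakest):
    if band <= 40:
        return strongest
    if band >= 85:
        return weakest
    f = (band - 40) / 45.0
    return math.exp((1 - f) * math.log(strongest) + f * math.log(weakest))


def oracle_run(bundle, reduction=0.0, discount=0.03):
    """Pure-Python per-stratum enumeration of the cohort simulation."""
    totals = {"qalys_disc": 0.0, "cost_cvd_disc": 0.0,
              "cost_non_cvd_disc": 0.0}
    for key, pop in bundle.population.items():
        age0 = key.age_band + 2.5
        h, c1, cl, s1, sl, d = 1.0, 0.0, 0.0, 0.0, 0.0, 0.0
        t = 0
        while age0 + t < 100.0:
            age = age0 + t
            band = min(95, int(age) // 5 * 5)
            bkey = StratumKey(key.sex, band, key.ethnicity)
            e, c = bundle.epi[bkey], bundle.costs[bkey]
            k = min(2011 + t, 2026) - 2011
            f_inc = 0.98 ** k
            apc = -0.0225 if key.ethnicity == "maori" else -0.0175
            m = e.background_mortality * (1 + apc) ** k
            dna = reduction * (4013 if key.sex == "male" else 3115) / 3544
            dsbp = _LAW[min(60, int(age) // 10 * 10)] * dna / 100.0
            pic = e.chd_incidence * f_inc \
                * _oracle_hr(band, 0.49, 0.67) ** (dsbp / 20)
            pis = e.stroke_incidence * f_inc \
                * _oracle_hr(band, 0.38, 0.67) ** (dsbp / 20)
            cfc = e.chd_case_fatality * f_inc
            cfs = e.stroke_case_fatality * f_inc

            disc = (1 + discount) ** (-t)
            q = (h * (1 - e.pyld)
                 + (c1 + cl) * max(0.0, 1 - e.pyld - 0.081)
                 + (s1 + sl) * max(0.0, 1 - e.pyld - 0.226))
            totals["qalys_disc"] += q * pop * disc
            totals["cost_non_cvd_disc"] += (1 - d) * c.healthy_annual \
                * pop * disc
            totals["cost_cvd_disc"] += (
                c1 * c.chd_first_year + cl * c.chd_subsequent
                + s1 * c.stroke_first_year + sl * c.stroke_subsequent
            ) * pop * disc

            h, c1, cl, s1, sl, d = (
                h * (1 - pic - pis) * (1 - m),
                h * pic,
                (c1 + cl) * (1 - cfc) * (1 - m),
                h * pis,
                (s1 + sl) * (1 - cfs) * (1 - m),
                d + h * (1 - pic - pis) * m
                + (c1 + cl) * (1 - (1 - cfc) * (1 - m))
                + (s1 + sl) * (1 - (1 - cfs) * (1 - m)),
            )
            t += 1
    return totals


@pytest.mark.parametrize("reduction", [0.0, 22.8])
def test_engine_matches_brute_force_enumeration(bundle, reduction):
    schedule = None
    spec = None
    if reduction:
        spec = get_intervention("mandatory_all")
        from saltshift import build_schedule
        schedule = build_schedule(spec)
    result = run_cohort(bundle, schedule, detail=False)
    expected = oracle_run(bundle, reduction=reduction)
    for name, value in expected.items():
        assert result.totals[name] == pytest.approx(value, rel=1e-9)


def test_single_stratum_three_cycle_hand_calculation():
    """Uniform toy world cross-checked against an explicit 3-cycle tally."""
    b = make_uniform_bundle(chd_inc=0.01, stroke_inc=0.0, chd_cf=0.1,
                            stroke_cf=0.0, bg_mort=0.05, pyld=0.0,
                            healthy_cost=1000.0, population=1.0)
    econ = EconomicSpec(discount_rate=0.0)
    trend = TrendSpec(incidence_apc=0.0, case_fatality_apc=0.0,
                      mortality_apc_nonmaori=0.0, mortality_apc_maori=0.0)
    result = run_cohort(b, None, trend, econ, detail=True)
    # hand calculation for any one stratum, first three cycles:
    # y0: h=1                 -> qaly 1
    # y1: h=.99*.95=.9405, c1=.01
    # y2: h=.9405*.99*.95 etc.
    h0, c10, cl0, d0 = 1.0, 0.0, 0.0, 0.0
    expect_q = []
    h, c1, cl, d = h0, c10, cl0, d0
    for _ in range(3):
        expect_q.append(h + c1 + cl)  # pyld=0, dw only on chd states
        expect_q[-1] = h + (c1 + cl) * (1 - 0.081)
        h, c1, cl, d = (h * 0.99 * 0.95, h * 0.01,
                        (c1 + cl) * 0.9 * 0.95,
                        d + h * 0.99 * 0.05
                        + (c1 + cl) * (1 - 0.9 * 0.95))
    got = result.by_year["qalys_undisc"].to_numpy()[:3] / 52.0  # 52 strata
    assert got == pytest.approx(expect_q, rel=1e-9)


class TestRunCohort:
    def test_population_linearity(self, uniform_bundle):
        base = run_cohort(uniform_bundle, detail=False)
        doubled = uniform_bundle.copy()
        doubled.population = {k: 2 * v
                              for k, v in uniform_bundle.population.items()}
        big = run_cohort(doubled, detail=False)
        for k in ("qalys_disc", "cost_cvd_disc", "cost_non_cvd_disc"):
            assert big.totals[k] == pytest.approx(2 * base.totals[k],
                                                  rel=1e-12)

    def test_null_schedule_equals_no_schedule_except_direct_costs(
            self, uniform_bundle):
        zero = ReductionSchedule(cumulative=np.zeros(5), horizon=5)
        spec = get_intervention("mandatory_all")
        with_zero = run_cohort(uniform_bundle, zero, intervention=spec,
                               detail=False)
        without = run_cohort(uniform_bundle, None, detail=False)
        assert with_zero.totals["qalys_disc"] \
            == pytest.approx(without.totals["qalys_disc"], rel=1e-12)
        assert with_zero.totals["cost_cvd_disc"] \
            == pytest.approx(without.totals["cost_cvd_disc"], rel=1e-12)
        assert with_zero.totals["cost_intervention_disc"] \
            == pytest.approx(3_680_000.0)
        assert without.totals["cost_intervention_disc"] == 0.0

    def test_everyone_dead_or_censored_by_horizon(self, bundle):
        result = run_cohort(bundle, detail=True)
        final_alive = result.by_year["alive"].iloc[-1]
        assert final_alive < 0.05 * bundle.total_adults

    def test_discounted_totals_below_undiscounted(self, fitted):
        for run in fitted.runs.values():
            assert run.totals["qalys_disc"] <= run.totals["qalys_undisc"]
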