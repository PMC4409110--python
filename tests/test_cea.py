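import numpy as np
import pandas as pd
import pytest

from saltshift import (
    StratumKey,
    all_strata,
    backcalculate_do_nothing,
    compute_icer,
    decompose_per_adult,
    equity_substitution,
    get_intervention,
    inequality_report,
    run_cohort,
    shift_incidence,
)
from saltshift.cea import DOMINANT, UNDEFINED, combined_multiplier
from saltshift.engine import TrajectoryResult
from saltshift.strata import band_midpoint

from conftest import make_uniform_bundle

CURRENT_PRACTICE = [get_intervention("counselling"),
                    get_intervention("endorsement_label")]


class TestBackCalculation:
    def test_empty_current_practice_leaves_bundle_unchanged(self, bundle):
        out = backcalculate_do_nothing(bundle, [])
        pd.testing.assert_frame_equal(out.to_frame(), bundle.to_frame())

    def test_reapplying_current_practice_round_trips(self, bundle):
        do_nothing = backcalculate_do_nothing(bundle, CURRENT_PRACTICE)
        for key in all_strata():
            age = band_midpoint(key.age_band)
            for disease in ("chd", "stroke"):
                mult = combined_multiplier(CURRENT_PRACTICE, key.sex, age,
                                           disease)
                reapplied = shift_incidence(
                    getattr(do_nothing.epi[key], f"{disease}_incidence"),
                    mult, "apply")
                observed = getattr(bundle.epi[key], f"{disease}_incidence")
                assert reapplied == pytest.approx(observed, abs=1e-9)

    def test_incidence_inflated_by_modest_factor(self, bundle):
        # counselling + label at full effect imply a sub-percent incidence
        # shift at mid-ages
        mult = combined_multiplier(CURRENT_PRACTICE, "male", 55.0, "chd")
        assert 1.002 < 1.0 / mult < 1.02
        do_nothing = backcalculate_do_nothing(bundle, CURRENT_PRACTICE)
        key = StratumKey("male", 55, "non_maori")
        ratio = (do_nothing.epi[key].chd_incidence
                 / bundle.epi[key].chd_incidence)
        assert ratio == pytest.approx(1.0 / mult, rel=1e-12)

    def test_untouched_fields_preserved(self, bundle):
        do_nothing = backcalculate_do_nothing(bundle, CURRENT_PRACTICE)
        key = StratumKey("female", 70, "maori")
        assert do_nothing.epi[key].chd_case_fatality \
            == bundle.epi[key].chd_case_fatality
        assert do_nothing.costs[key] == bundle.costs[key]


class TestICER:
    def test_cost_saving_with_gain_is_dominant(self):
        assert compute_icer(-34_000_000, 7_900) == DOMINANT

    def test_zero_over_zero_is_undefined(self):
        assert compute_icer(0.0, 0.0) == UNDEFINED

    def test_positive_ratio(self):
        assert compute_icer(6_900_000, 200) == pytest.approx(34_500)

    def test_costly_with_no_gain_is_dominated(self):
        assert compute_icer(5.0, 0.0) == "Dominated"

    def test_negative_qalys_rejected(self):
        with pytest.raises(ValueError):
            compute_icer(1.0, -1.0)


def _fake_run(direct=0.0, cvd=0.0, non_cvd=0.0):
    totals = {"cost_intervention_disc": direct, "cost_cvd_disc": cvd,
              "cost_non_cvd_disc": non_cvd, "qalys_disc": 0.0}
    return TrajectoryResult(by_year=pd.DataFrame(), totals=totals)


class TestPerAdultDecomposition:
    @pytest.mark.parametrize("direct, cvd, non_cvd, net", [
        (1.40, -509.0, 245.0, -262.6),
        (3.60, -1.00, 0.40, 3.00),
        (1.40, -956.0, 474.0, -480.6),
        (0.0, 0.0, 0.0, 0.0),
    ])
    def test_components_sum_to_net(self, direct, cvd, non_cvd, net):
        pa = decompose_per_adult(_fake_run(direct, cvd, non_cvd),
                                 _fake_run(), total_adults=1.0)
        assert pa["net"] == pytest.approx(net, abs=1e-9)
        assert pa["net"] == pytest.approx(
            pa["direct"] + pa["cvd_delta"] + pa["non_cvd_delta"], abs=1e-12)

    def test_zero_adults_rejected(self):
        with pytest.raises(ValueError):
            decompose_per_adult(_fake_run(), _fake_run(), 0)


class TestInequality:
    def test_identical_ethnic_inputs_give_unit_ratio(self, uniform_bundle):
        # equal secular trends too, so the ethnic groups stay identical
        from saltshift import TrendSpec
        trend = TrendSpec(mortality_apc_maori=-0.0175)
        run = run_cohort(uniform_bundle, trend=trend, detail=True)
        report = inequality_report(run, {})
        # cohorts starting at 90+ are censored (age 100) before the report
        # year: their rates are undefined
        live = report[report["age_band"] < 90]
        assert np.allclose(live["do_nothing_rate_ratio"], 1.0)
        assert np.allclose(live["do_nothing_rate_diff"], 0.0, atol=1e-9)
        assert report[report["age_band"] >= 90] \
            ["do_nothing_rate_maori"].isna().all()

    def test_default_bundle_mid_age_ratio_matches_generator_band(
            self, fitted):
        t6 = fitted.table6()
        row = t6[(t6["sex"] == "male") & (t6["age_band"] == 50)].iloc[0]
        assert 3.0 <= row["do_nothing_rate_ratio"] <= 6.0
        # the 75-79 cohort is 85+ by the report year, where the generator's
        # ethnic ratio has attenuated; Maori rates must still be higher
        old = t6[(t6["sex"] == "male") & (t6["age_band"] == 75)].iloc[0]
        assert 1.3 <= old["do_nothing_rate_ratio"] <= 3.2

    def test_mandatory_all_cuts_maori_rates_more_in_absolute_terms(
            self, fitted):
        t6 = fitted.table6()
        row = t6[(t6["sex"] == "male") & (t6["age_band"] == 50)].iloc[0]
        drop_maori = (row["do_nothing_rate_maori"]
                      - row["mandatory_all_rate_maori"])
        drop_non = (row["do_nothing_rate_non_maori"]
                    - row["mandatory_all_rate_non_maori"])
        assert drop_maori > drop_non > 0
        # rate difference narrows in absolute terms
        assert row["mandatory_all_rate_diff"] < row["do_nothing_rate_diff"]

    def test_qaly_gains_positive_for_effective_intervention(self, fitted):
        t6 = fitted.table6()
        assert (t6["mandatory_all_qaly_gain_maori"] > 0).all()
        assert (t6["mandatory_all_qaly_gain_non_maori"] > 0).all()


class TestEquitySubstitution:
    def test_substitution_is_idempotent(self, bundle):
        once = equity_substitution(bundle)
        twice = equity_substitution(once)
        pd.testing.assert_frame_equal(once.to_frame(), twice.to_frame())

    def test_already_equal_bundle_unchanged(self, uniform_bundle):
        out = equity_substitution(uniform_bundle)
        pd.testing.assert_frame_equal(out.to_frame(),
                                      uniform_bundle.to_frame())

    def test_maori_background_fields_match_non_maori(self, bundle):
        out = equity_substitution(bundle)
        for key in all_strata():
            if key.ethnicity != "maori":
                continue
            ref = out.epi[StratumKey(key.sex, key.age_band, "non_maori")]
            assert out.epi[key].background_mortality \
                == ref.background_mortality
            assert out.epi[key].pyld == ref.pyld
            # disease rates untouched
            assert out.epi[key].chd_incidence \
                == bundle.epi[key].chd_incidence

    def test_equity_world_expands_maori_gains(self, model, fitted):
        """Lower competing mortality/morbidity raises Maori QALY gains."""
        eq = model.scenario_model("equity")
        eq.specs = {"mandatory_all": model.specs["mandatory_all"]}
        eq_res = eq.fit()
        t6_eq = inequality_report(eq_res.comparator, eq_res.runs)
        t6 = fitted.table6(["mandatory_all"])
        merged = t6.merge(t6_eq, on=["sex", "age_band"],
                          suffixes=("", "_eq"))
        gain = merged["mandatory_all_qaly_gain_maori"]
        gain_eq = merged["mandatory_all_qaly_gain_maori_eq"]
        assert (gain_eq >= gain - 1e-12).all()
        assert (gain_eq > gain).any()
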