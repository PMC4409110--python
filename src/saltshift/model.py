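"""Model/Results facade over the simulation pipeline.

:class:`SaltReductionModel` bundles the baseline world, the intervention
set and the epidemiological/economic settings; ``fit()`` back-calculates
the do-nothing comparator, runs every intervention through the Markov
engine and returns a :class:`SaltReductionResults` carrying incremental
QALYs, net costs, ICERs, per-adult cost decompositions, uncertainty
intervals (when a PSA is requested) and the standard output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import cea as _cea
from .cea import CEAResult, backcalculate_do_nothing, compare, compute_icer, \
    equity_substitution, inequality_report
from .engine import EconomicSpec, TrajectoryResult, TrendSpec, run_cohort, \
    simulate
from .interventions import INTERVENTION_NAMES, InterventionSpec, \
    SodiumProfile, build_schedule, load_registry
from .risk import BPCoefficientTable, HazardRatioTable, default_hr_tables, \
    he_macgregor_bp_table, law_bp_table
from .strata import BaselineBundle
from .synthetic import GeneratorConfig, generate_baseline
from .uncertainty import ParamDistribution, PSAConfig, interval_bounds, \
    tornado as _tornado

CURRENT_PRACTICE = ("counselling", "endorsement_label")


class SaltReductionModel:
    """Markov cohort cost-utility model of sodium-reduction policies.

    Parameters
    ----------
    bundle
        Observed (current-practice) baseline world.
    interventions
        Names or specs of the interventions to evaluate; defaults to all
        eight.
    current_practice
        Interventions whose effects are embedded in the observed rates and
        must be removed to construct the do-nothing comparator.
    """

    def __init__(self, bundle: BaselineBundle,
                 interventions=None,
                 *,
                 current_practice=CURRENT_PRACTICE,
                 profile: SodiumProfile | None = None,
                 trend: TrendSpec | None = None,
                 econ: EconomicSpec | None = None,
                 bp_table: BPCoefficientTable | None = None,
                 hr_tables: dict[str, HazardRatioTable] | None = None):
        self.bundle = bundle.validate()
        self.profile = profile or SodiumProfile()
        self.trend = trend or TrendSpec()
        self.econ = econ or EconomicSpec()
        self.bp_table = bp_table or law_bp_table()
        self.hr_tables = hr_tables or default_hr_tables()

        registry = load_registry(self.profile)
        if interventions is None:
            interventions = list(INTERVENTION_NAMES)
        self.specs: dict[str, InterventionSpec] = {}
        for item in interventions:
            spec = registry[item] if isinstance(item, str) else item
            self.specs[spec.name] = spec

        self.current_practice = tuple(
            registry[n] if isinstance(n, str) else n for n in current_practice)
        self.do_nothing_bundle = backcalculate_do_nothing(
            self.bundle, self.current_practice, self.profile,
            self.hr_tables, self.bp_table)

    # ------------------------------------------------------------------
    @classmethod
    def from_synthetic(cls, seed: int = 1,
                       config: GeneratorConfig | None = None,
                       **kwargs) -> "SaltReductionModel":
        """Build a model on a synthetic baseline generated from ``seed``."""
        return cls(generate_baseline(seed, config), **kwargs)

    @property
    def total_adults(self) -> float:
        return self.bundle.total_adults

    def _run(self, schedule, spec=None, detail=True, **scales):
        return run_cohort(self.do_nothing_bundle, schedule, self.trend,
                          self.econ, intervention=spec,
                          hr_tables=self.hr_tables, bp_table=self.bp_table,
                          detail=detail, **scales)

    # ------------------------------------------------------------------
    def fit(self, psa: PSAConfig | int | None = None,
            seed: int = 0) -> "SaltReductionResults":
        """Run comparator and interventions; optionally attach a PSA.

        ``psa`` may be a :class:`PSAConfig` or a number of draws; ``seed``
        is used when ``psa`` is given as an integer.
        """
        comparator = self._run(None)
        runs: dict[str, TrajectoryResult] = {}
        results: dict[str, CEAResult] = {}
        schedules = {}
        for name, spec in self.specs.items():
            schedules[name] = build_schedule(spec, self.profile)
            runs[name] = self._run(schedules[name], spec)
            results[name] = compare(runs[name], comparator, spec,
                                    self.total_adults)

        psa_draws = None
        psa_config = None
        if psa is not None:
            psa_config = psa if isinstance(psa, PSAConfig) \
                else PSAConfig(n_draws=int(psa), seed=seed)
            psa_draws = self._run_psa(comparator, schedules, results,
                                      psa_config)

        return SaltReductionResults(
            model=self, comparator=comparator, runs=runs, results=results,
            schedules=schedules, psa_draws=psa_draws, psa_config=psa_config)

    # ------------------------------------------------------------------
    def shared_psa_registry(self) -> list[ParamDistribution]:
        """Draw-index-shared uncertain parameters (common random numbers)."""
        return [
            ParamDistribution("effect_z", "normal", 0.0, 1.0),
            ParamDistribution("hr_chd_factor", "normal", 1.0, 0.10,
                              truncate_low=0.05),
            ParamDistribution("hr_stroke_factor", "normal", 1.0, 0.10,
                              truncate_low=0.05),
            ParamDistribution("health_cost_factor", "gamma", 1.0, 0.10),
            ParamDistribution("cost_z", "normal", 0.0, 1.0),
        ]

    def tornado_registry(self, spec: InterventionSpec
                         ) -> list[ParamDistribution]:
        """One-way analysis parameters for one intervention."""
        return [
            ParamDistribution("effect_mmol", spec.effect_distribution,
                              spec.effect_mean, spec.effect_sd,
                              truncate_low=0.0),
            ParamDistribution("hr_chd_factor", "normal", 1.0, 0.10,
                              truncate_low=0.05),
            ParamDistribution("hr_stroke_factor", "normal", 1.0, 0.10,
                              truncate_low=0.05),
            ParamDistribution("health_cost_factor", "gamma", 1.0, 0.10),
            ParamDistribution("intervention_cost_nzd", spec.cost_distribution,
                              spec.direct_cost, spec.cost_sd,
                              truncate_low=0.0),
        ]

    def _run_psa(self, comparator, schedules, results, config: PSAConfig):
        """Vectorised PSA: one engine batch per intervention, shared draws."""
        from .uncertainty import draw_parameters
        shared = draw_parameters(self.shared_psa_registry(), config.seed,
                                 config.n_draws)
        z = shared["effect_z"].to_numpy()
        hr_c = shared["hr_chd_factor"].to_numpy()
        hr_s = shared["hr_stroke_factor"].to_numpy()
        health = shared["health_cost_factor"].to_numpy()
        cost_u = stats.norm.cdf(shared["cost_z"].to_numpy())

        arrays = self.do_nothing_bundle.as_arrays()
        comp_health_cost = (comparator.totals["cost_cvd_disc"]
                            + comparator.totals["cost_non_cvd_disc"])
        frames = {}
        for name, spec in self.specs.items():
            effect = np.maximum(spec.effect_mean + z * spec.effect_sd, 0.0)
            eff_scale = effect / spec.effect_mean
            cost_dist = ParamDistribution(
                "cost", spec.cost_distribution, spec.direct_cost,
                spec.cost_sd, truncate_low=0.0)
            cost_scale = cost_dist.from_uniform(cost_u) / spec.direct_cost
            raw = simulate(arrays, schedules[name], self.trend, self.econ,
                           hr_tables=self.hr_tables, bp_table=self.bp_table,
                           intervention=spec, effect_scale=eff_scale,
                           hr_scale_chd=hr_c, hr_scale_stroke=hr_s,
                           cost_scale=health,
                           intervention_cost_scale=cost_scale)
            tot = raw["totals"]
            inc_q = tot["qalys_disc"] - comparator.totals["qalys_disc"]
            net = (tot["cost_cvd_disc"] + tot["cost_non_cvd_disc"]
                   - comp_health_cost * health
                   + tot["cost_intervention_disc"])
            frames[name] = pd.DataFrame({
                "draw": np.arange(config.n_draws),
                "intervention": name,
                "incremental_qalys": inc_q,
                "net_cost_nzd": net,
            })
            lo_q, hi_q = interval_bounds(inc_q, config.interval)
            lo_c, hi_c = interval_bounds(net, config.interval)
            results[name].uncertainty = {
                "incremental_qalys": (lo_q, hi_q),
                "net_cost_nzd": (lo_c, hi_c),
            }
            positive = inc_q > 0
            ratio_draws = net[positive] / inc_q[positive]
            results[name].psa_means = {
                "incremental_qalys": float(inc_q.mean()),
                "net_cost_nzd": float(net.mean()),
                "icer_mean_of_ratios": float(ratio_draws.mean())
                if positive.any() else np.nan,
                "icer_ratio_of_means": float(net.mean() / inc_q.mean())
                if inc_q.mean() > 0 else np.nan,
            }
            if net.mean() > 0 and positive.any():
                lo_i, hi_i = interval_bounds(ratio_draws, config.interval)
                results[name].uncertainty["icer"] = (lo_i, hi_i)
        return pd.concat(frames.values(), ignore_index=True)

    # ------------------------------------------------------------------
    def tornado(self, intervention: str = "mandatory_all",
                output: str = "incremental_qalys") -> pd.DataFrame:
        """One-way tornado analysis for one intervention."""
        spec = self.specs[intervention]
        schedule = build_schedule(spec, self.profile)
        comparator = self._run(None, detail=False)

        def closure(params: dict) -> dict:
            run = self._run(
                schedule, spec, detail=False,
                effect_scale=params["effect_mmol"] / spec.effect_mean,
                hr_scale_chd=params["hr_chd_factor"],
                hr_scale_stroke=params["hr_stroke_factor"],
                cost_scale=params["health_cost_factor"],
                intervention_cost_scale=(params["intervention_cost_nzd"]
                                         / spec.direct_cost),
            )
            inc_q = run.totals["qalys_disc"] - comparator.totals["qalys_disc"]
            net = (run.totals["cost_cvd_disc"]
                   + run.totals["cost_non_cvd_disc"]
                   - (comparator.totals["cost_cvd_disc"]
                      + comparator.totals["cost_non_cvd_disc"])
                   * params["health_cost_factor"]
                   + run.totals["cost_intervention_disc"])
            return {"incremental_qalys": inc_q, "net_cost_nzd": net}

        return _tornado(closure, self.tornado_registry(spec), output=output)

    # ------------------------------------------------------------------
    # scenario analyses
    # ------------------------------------------------------------------
    def scenario_model(self, name: str) -> "SaltReductionModel":
        """A re-parameterised copy of this model for a named scenario."""
        bundle = self.bundle
        specs = dict(self.specs)
        trend, econ = self.trend, self.econ
        bp_table, profile = self.bp_table, self.profile

        if name == "baseline":
            pass
        elif name == "discount_0":
            econ = replace(econ, discount_rate=0.0)
        elif name == "discount_6":
            econ = replace(econ, discount_rate=0.06)
        elif name == "sunset_20y":
            specs = {n: replace(s, sunset_year=20) if s.mandatory else s
                     for n, s in specs.items()}
        elif name == "costs_plus_50pct":
            specs = {n: replace(s, direct_cost=1.5 * s.direct_cost,
                                cost_sd=1.5 * s.cost_sd)
                     for n, s in specs.items()}
        elif name in ("media_share_15", "media_share_45"):
            share = 0.15 if name.endswith("15") else 0.45
            alt = load_registry(profile, media_share=share)
            if "uk_media" in specs:
                specs["uk_media"] = alt["uk_media"]
        elif name == "he_macgregor_bp":
            bp_table = he_macgregor_bp_table()
        elif name == "cfr_reduced":
            bundle = _scale_case_fatality(bundle, 0.8)
        elif name in ("pe_low", "pe_high"):
            e = -0.05 if name == "pe_low" else -0.2
            if "salt_tax" in specs:
                s = specs["salt_tax"]
                specs["salt_tax"] = replace(
                    s, schedule_params={**s.schedule_params, "elasticity": e})
        elif name == "enforcement_costs_aus":
            per_year = 0.5 * 0.49 * self.total_adults
            specs = {n: replace(s, extra_recurring_cost=per_year)
                     if s.mandatory else s for n, s in specs.items()}
        elif name == "equity":
            bundle = equity_substitution(bundle)
        else:
            raise ValueError(f"unknown scenario {name!r}")

        return SaltReductionModel(
            bundle, list(specs.values()),
            current_practice=self.current_practice, profile=profile,
            trend=trend, econ=econ, bp_table=bp_table,
            hr_tables=self.hr_tables)

    SCENARIO_NAMES = ("discount_0", "discount_6", "sunset_20y",
                      "costs_plus_50pct", "media_share_15", "media_share_45",
                      "he_macgregor_bp", "cfr_reduced", "pe_low", "pe_high",
                      "enforcement_costs_aus", "equity")

    def run_scenarios(self, scenarios=None) -> pd.DataFrame:
        """Deterministic expected-value reruns under named scenarios."""
        names = list(scenarios) if scenarios else ["baseline",
                                                   *self.SCENARIO_NAMES]
        rows = []
        for sc in names:
            res = self.scenario_model(sc).fit()
            for name, r in res.results.items():
                rows.append({"scenario": sc, "intervention": name,
                             "incremental_qalys": r.incremental_qalys,
                             "net_cost_nzd": r.net_cost,
                             "icer": r.icer})
        return pd.DataFrame(rows)


def _scale_case_fatality(bundle: BaselineBundle,
                         factor: float) -> BaselineBundle:
    out = bundle.copy()
    out.epi = {
        k: replace(e,
                   chd_case_fatality=min(1.0, e.chd_case_fatality * factor),
                   stroke_case_fatality=min(1.0,
                                            e.stroke_case_fatality * factor))
        for k, e in bundle.epi.items()}
    return out


# ----------------------------------------------------------------------
@dataclass
class SaltReductionResults:
    """Fitted results: comparator, per-intervention runs and CEA outputs."""

    model: SaltReductionModel
    comparator: TrajectoryResult
    runs: dict[str, TrajectoryResult]
    results: dict[str, CEAResult]
    schedules: dict
    psa_draws: pd.DataFrame | None = None
    psa_config: PSAConfig | None = None

    # ------------------------------------------------------------------
    def table4(self) -> pd.DataFrame:
        """Population totals: health-system cost, QALYs, ICER per intervention.

        The first row is the do-nothing comparator (absolute totals,
        no intervention costs); subsequent rows are incremental.
        """
        comp = self.comparator.totals
        rows = [{
            "intervention": "do_nothing",
            "health_system_cost_nzd": comp["cost_cvd_disc"]
            + comp["cost_non_cvd_disc"],
            "qalys": comp["qalys_disc"],
            "icer": "Not applicable",
        }]
        for name, r in self.results.items():
            row = {"intervention": name,
                   "health_system_cost_nzd": r.net_cost,
                   "qalys": r.incremental_qalys,
                   "icer": r.icer}
            if r.uncertainty:
                row["cost_lo"], row["cost_hi"] = r.uncertainty["net_cost_nzd"]
                row["qalys_lo"], row["qalys_hi"] = \
                    r.uncertainty["incremental_qalys"]
            if r.psa_means:
                row["icer_mean_of_ratios"] = r.psa_means["icer_mean_of_ratios"]
                row["icer_ratio_of_means"] = r.psa_means["icer_ratio_of_means"]
            rows.append(row)
        return pd.DataFrame(rows)

    def table5(self) -> pd.DataFrame:
        """Per-adult cost decomposition, baseline and incremental sections."""
        n = self.model.total_adults
        comp = self.comparator.totals
        rows = [{
            "section": "baseline", "intervention": "do_nothing",
            "direct": 0.0,
            "cvd": comp["cost_cvd_disc"] / n,
            "non_cvd": comp["cost_non_cvd_disc"] / n,
            "net": (comp["cost_cvd_disc"] + comp["cost_non_cvd_disc"]) / n,
        }]
        for name, run in self.runs.items():
            t = run.totals
            rows.append({
                "section": "baseline", "intervention": name,
                "direct": t["cost_intervention_disc"] / n,
                "cvd": t["cost_cvd_disc"] / n,
                "non_cvd": t["cost_non_cvd_disc"] / n,
                "net": (t["cost_intervention_disc"] + t["cost_cvd_disc"]
                        + t["cost_non_cvd_disc"]) / n,
            })
        for name, r in self.results.items():
            pa = r.per_adult_costs
            rows.append({
                "section": "incremental", "intervention": name,
                "direct": pa["direct"], "cvd": pa["cvd_delta"],
                "non_cvd": pa["non_cvd_delta"], "net": pa["net"],
            })
        return pd.DataFrame(rows)

    def table6(self, interventions=("counselling", "mandatory_all"),
               report_year: int = 2021, equity: bool = False) -> pd.DataFrame:
        """Ethnic inequality impacts after the interventions have bedded in."""
        chosen = {n: self.runs[n] for n in interventions if n in self.runs}
        df = inequality_report(self.comparator, chosen, report_year)
        if equity:
            eq_model = self.model.scenario_model("equity")
            eq_model.specs = {n: self.model.specs[n] for n in chosen}
            eq_res = eq_model.fit()
            eq_df = inequality_report(eq_res.comparator, eq_res.runs,
                                      report_year)
            gain_cols = [c for c in eq_df.columns if "_qaly_gain_" in c]
            df = df.merge(
                eq_df[["sex", "age_band", *gain_cols]].rename(
                    columns={c: f"{c}_equity" for c in gain_cols}),
                on=["sex", "age_band"])
        return df

    def ce_plane(self) -> pd.DataFrame:
        """Per-draw incremental (QALY, net cost) coordinates for plotting."""
        if self.psa_draws is None:
            raise ValueError("no PSA attached; fit with psa=...")
        return self.psa_draws.copy()

    def tornado(self, intervention: str = "mandatory_all",
                output: str = "incremental_qalys") -> pd.DataFrame:
        return self.model.tornado(intervention, output)

    def run_scenarios(self, scenarios=None) -> pd.DataFrame:
        return self.model.run_scenarios(scenarios)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Human-readable results table."""
        lines = [
            "Sodium-reduction cost-utility analysis "
            f"(NZ$ {self.model.econ.currency_year}, "
            f"{self.model.econ.discount_rate:.0%} discount)",
            f"Adults modelled: {self.model.total_adults:,.0f}; "
            f"comparator: do nothing (current practice removed)",
            "",
            f"{'Intervention':<22}{'QALYs gained':>14}{'Net cost (NZ$m)':>17}"
            f"{'ICER':>16}",
            "-" * 69,
        ]
        for name, r in self.results.items():
            icer = r.icer if isinstance(r.icer, str) \
                else f"{r.icer:,.0f}/QALY"
            lines.append(f"{name:<22}{r.incremental_qalys:>14,.0f}"
                         f"{r.net_cost / 1e6:>17,.1f}{icer:>16}")
        if self.psa_config is not None:
            lines.append("")
            lines.append(f"Uncertainty: {self.psa_config.n_draws} Monte "
                         f"Carlo draws, {self.psa_config.interval:.0%} "
                         "percentile intervals")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<SaltReductionResults: {len(self.results)} interventions, "
                f"psa={'yes' if self.psa_draws is not None else 'no'}>")
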