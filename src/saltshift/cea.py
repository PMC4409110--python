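"""Generalised cost-effectiveness analysis.

All interventions — including the two that are current practice
(counselling and the endorsement label programme) — are evaluated against a
counterfactual "do nothing" world in which none of them exist.  The
do-nothing world is constructed by back-calculating disease incidence, i.e.
dividing observed rates by the incidence multipliers the current-practice
interventions imply.  Outputs are incremental QALYs, net costs, ICERs with
dominance labelling, a per-adult cost decomposition and ethnic-inequality
measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import TrajectoryResult
from .interventions import InterventionSpec, SodiumProfile, \
    sex_scaled_reduction
from .risk import BPCoefficientTable, HazardRatioTable, default_hr_tables, \
    law_bp_table, scale_hazard_ratio, shift_incidence, sodium_to_sbp
from .strata import AGE_BANDS, BaselineBundle, BaselineEpi, SEXES, \
    StratumKey, all_strata, band_midpoint

GDP_PER_CAPITA_NZD = 45_000  # nominal 2011 GDP/capita cost-effectiveness anchor
NZD_PER_USD_PPP = 1.521  # 2011 purchasing-power conversion (45,000 / 29,600)

DOMINANT = "Dominant"
DOMINATED = "Dominated"
UNDEFINED = "Undefined"


def combined_multiplier(specs: Sequence[InterventionSpec], sex: str,
                        age: float, disease: str,
                        profile: SodiumProfile | None = None,
                        hr_tables: dict[str, HazardRatioTable] | None = None,
                        bp_table: BPCoefficientTable | None = None) -> float:
    """Product of incidence multipliers of several interventions at full effect.

    Independent policies acting through the same blood-pressure mechanism
    compose multiplicatively on incidence.
    """
    profile = profile or SodiumProfile()
    hr_tables = hr_tables or default_hr_tables()
    bp_table = bp_table or law_bp_table()
    hr = hr_tables[disease].hr(age)
    mult = 1.0
    for spec in specs:
        delta = sex_scaled_reduction(spec.effect_mean, sex, profile)
        mult *= scale_hazard_ratio(hr, sodium_to_sbp(delta, age, bp_table))
    return mult


def backcalculate_do_nothing(observed: BaselineBundle,
                             current_practice: Sequence[InterventionSpec],
                             profile: SodiumProfile | None = None,
                             hr_tables: dict[str, HazardRatioTable] | None = None,
                             bp_table: BPCoefficientTable | None = None,
                             ) -> BaselineBundle:
    """Inflate observed incidence to the world without current practice."""
    if not current_practice:
        return observed.copy()
    out = observed.copy()
    new_epi: dict[StratumKey, BaselineEpi] = {}
    for key in all_strata():
        e = observed.epi[key]
        age = band_midpoint(key.age_band)
        m_chd = combined_multiplier(current_practice, key.sex, age, "chd",
                                    profile, hr_tables, bp_table)
        m_str = combined_multiplier(current_practice, key.sex, age, "stroke",
                                    profile, hr_tables, bp_table)
        if m_chd <= 0 or m_str <= 0:
            raise ValueError("degenerate zero multiplier in back-calculation")
        new_epi[key] = replace(
            e,
            chd_incidence=shift_incidence(e.chd_incidence, m_chd, "remove"),
            stroke_incidence=shift_incidence(e.stroke_incidence, m_str,
                                             "remove"),
        )
    out.epi = new_epi
    return out


def compute_icer(net_cost: float, qalys: float):
    """ICER (NZ$ per QALY) or a dominance flag.

    Cost-saving with positive health gain is ``Dominant`` (no ratio
    reported); zero health gain yields ``Dominated`` when costs rise and
    ``Undefined`` otherwise.
    """
    if qalys < 0:
        raise ValueError("incremental QALYs must be non-negative here")
    if qalys == 0:
        return DOMINATED if net_cost > 0 else UNDEFINED
    if net_cost < 0:
        return DOMINANT
    return net_cost / qalys


def icer_vs_threshold(icer, threshold: float = GDP_PER_CAPITA_NZD) -> str:
    """Classify an ICER against the GDP-per-capita threshold."""
    if icer == DOMINANT:
        return "cost-saving"
    if isinstance(icer, str):
        return "not cost-effective"
    return "cost-effective" if icer <= threshold else "not cost-effective"


@dataclass
class CEAResult:
    """Incremental results for one intervention against do-nothing."""

    name: str
    label: str
    incremental_qalys: float
    net_cost: float  # NZ$, discounted, health system + intervention
    icer: object  # NZ$/QALY or a dominance flag string
    per_adult_costs: dict[str, float]
    cost_breakdown: dict[str, float] = field(default_factory=dict)
    uncertainty: dict[str, tuple[float, float]] | None = None
    psa_means: dict[str, float] | None = None

    def as_row(self) -> dict:
        row = {
            "intervention": self.name,
            "label": self.label,
            "incremental_qalys": self.incremental_qalys,
            "net_cost_nzd": self.net_cost,
            "icer": self.icer,
            "cost_effectiveness": icer_vs_threshold(self.icer),
        }
        if self.uncertainty:
            for key, (lo, hi) in self.uncertainty.items():
                row[f"{key}_lo"], row[f"{key}_hi"] = lo, hi
        return row


def decompose_per_adult(intervention: TrajectoryResult,
                        do_nothing: TrajectoryResult,
                        total_adults: float) -> dict[str, float]:
    """Per-adult incremental cost decomposition (direct, CVD, non-CVD, net)."""
    if total_adults <= 0:
        raise ValueError("adult count must be positive")
    direct = (intervention.totals["cost_intervention_disc"]
              - do_nothing.totals["cost_intervention_disc"]) / total_adults
    cvd = (intervention.totals["cost_cvd_disc"]
           - do_nothing.totals["cost_cvd_disc"]) / total_adults
    non_cvd = (intervention.totals["cost_non_cvd_disc"]
               - do_nothing.totals["cost_non_cvd_disc"]) / total_adults
    return {"direct": direct, "cvd_delta": cvd, "non_cvd_delta": non_cvd,
            "net": direct + cvd + non_cvd}


def compare(intervention_run: TrajectoryResult,
            do_nothing_run: TrajectoryResult,
            spec: InterventionSpec,
            total_adults: float) -> CEAResult:
    """Build a :class:`CEAResult` from a pair of trajectory runs."""
    dq = (intervention_run.totals["qalys_disc"]
          - do_nothing_run.totals["qalys_disc"])
    per_adult = decompose_per_adult(intervention_run, do_nothing_run,
                                    total_adults)
    net = per_adult["net"] * total_adults
    return CEAResult(
        name=spec.name,
        label=spec.label,
        incremental_qalys=dq,
        net_cost=net,
        icer=compute_icer(net, max(dq, 0.0)),
        per_adult_costs=per_adult,
        cost_breakdown={
            "direct": per_adult["direct"] * total_adults,
            "cvd_delta": per_adult["cvd_delta"] * total_adults,
            "non_cvd_delta": per_adult["non_cvd_delta"] * total_adults,
        },
    )


# ----------------------------------------------------------------------
# ethnic inequality outputs
# ----------------------------------------------------------------------

def _stratum_groups(strata: list[StratumKey]):
    idx: dict[tuple[str, int, str], list[int]] = {}
    for i, k in enumerate(strata):
        idx.setdefault((k.sex, k.age_band, k.ethnicity), []).append(i)
    return idx


def inequality_report(do_nothing: TrajectoryResult,
                      interventions: dict[str, TrajectoryResult],
                      report_year: int = 2021) -> pd.DataFrame:
    """Ethnic inequality measures by sex and baseline age band.

    CVD mortality rates in the report year are model deaths that year
    divided by persons alive that year (per 100,000); rate differences and
    ratios compare Maori with non-Maori within sex and age band.  QALY
    gains per individual accumulate (discounted) from the base year to the
    report year.  Age bands label the cohort's age in the base year.
    """
    runs = {"do_nothing": do_nothing, **interventions}
    for name, run in runs.items():
        if run.per_stratum is None:
            raise ValueError(f"run {name!r} lacks per-stratum detail")
    strata = do_nothing.strata
    t_report = report_year - do_nothing.base_year
    span = slice(0, t_report)  # accrual years base..report
    groups = _stratum_groups(strata)

    rows = []
    for sex in SEXES:
        for band in AGE_BANDS:
            row: dict[str, object] = {"sex": sex, "age_band": band}
            for name, run in runs.items():
                ps = run.per_stratum
                rates = {}
                for eth in ("maori", "non_maori"):
                    ii = groups[(sex, band, eth)]
                    deaths = ps["cvd_deaths"][t_report, ii].sum()
                    alive = ps["alive"][t_report, ii].sum()
                    rates[eth] = (deaths / alive * 1e5) if alive > 0 \
                        else np.nan
                row[f"{name}_rate_maori"] = rates["maori"]
                row[f"{name}_rate_non_maori"] = rates["non_maori"]
                row[f"{name}_rate_diff"] = rates["maori"] - rates["non_maori"]
                row[f"{name}_rate_ratio"] = (
                    rates["maori"] / rates["non_maori"]
                    if rates["non_maori"] else np.nan)
                for eth in ("maori", "non_maori"):
                    ii = groups[(sex, band, eth)]
                    pop0 = ps["alive"][0, ii].sum()
                    q = ps["qalys_disc"][span, ii].sum()
                    if name == "do_nothing":
                        # expected remaining-life QALYs per individual
                        q_total = ps["qalys_disc"][:, ii].sum()
                        row[f"do_nothing_qalys_{eth}"] = q_total / pop0
                        row[f"_dn_10y_{eth}"] = q / pop0
                    else:
                        row[f"{name}_qaly_gain_{eth}"] = \
                            q / pop0 - row[f"_dn_10y_{eth}"]
            rows.append(row)
    df = pd.DataFrame(rows)
    return df[[c for c in df.columns if not c.startswith("_dn_10y")]]


def equity_substitution(bundle: BaselineBundle) -> BaselineBundle:
    """Give Maori strata non-Maori background mortality and morbidity.

    Disease rates are untouched; only the competing background mortality
    and the background disability (pYLD) are substituted, so the envelope
    for potential health gain no longer penalises Maori for poorer
    background health.  Idempotent.
    """
    out = bundle.copy()
    new_epi = dict(out.epi)
    for key in all_strata():
        if key.ethnicity != "maori":
            continue
        ref = out.epi[StratumKey(key.sex, key.age_band, "non_maori")]
        new_epi[key] = replace(
            out.epi[key],
            background_mortality=ref.background_mortality,
            pyld=ref.pyld,
        )
    out.epi = new_epi
    return out
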