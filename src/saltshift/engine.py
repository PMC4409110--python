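"""Annual-cycle Markov cohort engine.

Each of the 52 strata is simulated as a closed cohort from the 2011 base
year to death or age 100 through six occupancy compartments: healthy,
first-year CHD, later-year CHD, first-year stroke, later-year stroke and
dead.  The first-year compartments are cost tunnels only — they carry the
higher first-year treatment cost and are otherwise identical to the
later-year states.  Secular declines in incidence, case fatality and
background mortality run to a trend end year and are then held constant.
QALYs and costs are accrued on start-of-cycle occupancy (no half-cycle
correction) and discounted to the base year.

Within a cycle, disease incidence is applied to the healthy state first and
background mortality to the non-incident remainder; prevalent cases face
case fatality and background mortality as independent risks.  Transition
probabilities therefore never sum above one and occupancy is conserved
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .interventions import InterventionSpec, ReductionSchedule, \
    intervention_cost_stream
from .risk import BPCoefficientTable, HazardRatioTable, default_hr_tables, \
    law_bp_table
from .strata import AGE_BANDS, BaselineBundle, BundleArrays, CostSet, \
    StratumKey, band_midpoint

DW_CHD = 0.081
DW_STROKE = 0.226
OCCUPANCY_TOL = 1e-6


@dataclass(frozen=True)
class TrendSpec:
    """Secular annual percentage changes applied from the base year."""

    incidence_apc: float = -0.02
    case_fatality_apc: float = -0.02
    mortality_apc_nonmaori: float = -0.0175
    mortality_apc_maori: float = -0.0225
    trend_end_year: int = 2026
    post_trend_apc: float = 0.0


@dataclass(frozen=True)
class EconomicSpec:
    """Discounting and horizon settings (2011 NZ$)."""

    discount_rate: float = 0.03
    horizon_age: float = 100.0
    currency_year: int = 2011

    def __post_init__(self):
        if self.discount_rate < 0:
            raise ValueError("discount rate must be non-negative")


def project_rate(base_rate: float, apc: float, year: int,
                 trend_end: int, base_year: int = 2011) -> float:
    """Project a base-year rate to ``year`` with an annual percentage change.

    The trend runs from the base year to ``trend_end`` and the rate is held
    constant thereafter.
    """
    if year < base_year:
        raise ValueError(f"year {year} precedes base year {base_year}")
    return base_rate * (1.0 + apc) ** (min(year, trend_end) - base_year)


# ----------------------------------------------------------------------
# single-state operations (readable reference forms of the engine cycle)
# ----------------------------------------------------------------------

@dataclass
class CohortState:
    """Occupancy fractions of one cohort at the start of a cycle."""

    healthy: float = 1.0
    chd_year1: float = 0.0
    chd_later: float = 0.0
    stroke_year1: float = 0.0
    stroke_later: float = 0.0
    dead: float = 0.0
    current_age: float = 37.5
    calendar_year: int = 2011

    def occupancies(self) -> np.ndarray:
        return np.array([self.healthy, self.chd_year1, self.chd_later,
                         self.stroke_year1, self.stroke_later, self.dead])

    def validate(self) -> "CohortState":
        occ = self.occupancies()
        if np.any(occ < -1e-12):
            raise ValueError("negative occupancy")
        if abs(occ.sum() - 1.0) > 1e-9:
            raise ValueError(f"occupancy sums to {occ.sum()}, not 1")
        return self

    @property
    def alive(self) -> float:
        return 1.0 - self.dead


@dataclass(frozen=True)
class TransitionRates:
    """Annual transition probabilities for one cycle of one stratum."""

    chd_incidence: float
    stroke_incidence: float
    chd_case_fatality: float
    stroke_case_fatality: float
    background_mortality: float

    def validate(self) -> "TransitionRates":
        for f in ("chd_incidence", "stroke_incidence", "chd_case_fatality",
                  "stroke_case_fatality", "background_mortality"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f}={v} outside [0, 1]")
        return self


def step_cohort(state: CohortState, rates: TransitionRates) -> CohortState:
    """Advance one cohort by one annual cycle."""
    state.validate()
    rates.validate()
    pic, pis = rates.chd_incidence, rates.stroke_incidence
    total_inc = pic + pis
    if total_inc > 1.0:  # joint incidence cannot exceed the healthy pool
        pic, pis = pic / total_inc, pis / total_inc
    m = rates.background_mortality
    surv_c = (1.0 - rates.chd_case_fatality) * (1.0 - m)
    surv_s = (1.0 - rates.stroke_case_fatality) * (1.0 - m)

    h = state.healthy
    chd_all = state.chd_year1 + state.chd_later
    stroke_all = state.stroke_year1 + state.stroke_later
    new = CohortState(
        healthy=h * (1.0 - pic - pis) * (1.0 - m),
        chd_year1=h * pic,
        chd_later=chd_all * surv_c,
        stroke_year1=h * pis,
        stroke_later=stroke_all * surv_s,
        dead=(state.dead + h * (1.0 - pic - pis) * m
              + chd_all * (1.0 - surv_c) + stroke_all * (1.0 - surv_s)),
        current_age=state.current_age + 1,
        calendar_year=state.calendar_year + 1,
    )
    if abs(new.occupancies().sum() - 1.0) > OCCUPANCY_TOL:
        raise ArithmeticError("occupancy drifted beyond tolerance")
    return new


def annual_qaly(state: CohortState, dw_chd: float = DW_CHD,
                dw_stroke: float = DW_STROKE, pyld: float = 0.0) -> float:
    """QALYs accrued per cohort member in one cycle.

    A healthy year is worth ``1 - pyld`` (background morbidity); disease
    years additionally lose the disease disability weight, floored at zero.
    """
    for v in (dw_chd, dw_stroke, pyld):
        if not 0.0 <= v <= 1.0:
            raise ValueError("disability weights and pYLD must be in [0, 1]")
    chd = state.chd_year1 + state.chd_later
    stroke = state.stroke_year1 + state.stroke_later
    return (state.healthy * (1.0 - pyld)
            + chd * max(0.0, 1.0 - pyld - dw_chd)
            + stroke * max(0.0, 1.0 - pyld - dw_stroke))


def annual_cost(state: CohortState, costs: CostSet) -> dict[str, float]:
    """Health-system costs per cohort member in one cycle, by category.

    Every living person accrues the healthy-state annual cost (non-CVD);
    disease occupants additionally accrue the matching excess cost (CVD),
    with the first-year tunnel states carrying the first-year amount.
    """
    non_cvd = state.alive * costs.healthy_annual
    cvd = (state.chd_year1 * costs.chd_first_year
           + state.chd_later * costs.chd_subsequent
           + state.stroke_year1 * costs.stroke_first_year
           + state.stroke_later * costs.stroke_subsequent)
    return {"cvd": cvd, "non_cvd": non_cvd}


# ----------------------------------------------------------------------
# vectorised whole-population simulation
# ----------------------------------------------------------------------

@dataclass
class TrajectoryResult:
    """Output of one population run under one scenario."""

    by_year: pd.DataFrame  # year-indexed aggregate measures
    totals: dict[str, float]
    per_stratum: dict[str, np.ndarray] | None = None  # (T, 52) detail arrays
    strata: list[StratumKey] | None = None
    base_year: int = 2011

    @property
    def qalys(self) -> float:
        return self.totals["qalys_disc"]

    @property
    def total_cost(self) -> float:
        return (self.totals["cost_cvd_disc"] + self.totals["cost_non_cvd_disc"]
                + self.totals["cost_intervention_disc"])


def _trend_factors(trend: TrendSpec, base_year: int, years: np.ndarray,
                   is_maori: np.ndarray):
    k = np.minimum(years, trend.trend_end_year) - base_year
    f_inc = (1.0 + trend.incidence_apc) ** k
    f_cf = (1.0 + trend.case_fatality_apc) ** k
    f_bg_nm = (1.0 + trend.mortality_apc_nonmaori) ** k
    f_bg_m = (1.0 + trend.mortality_apc_maori) ** k
    f_bg = np.where(is_maori[None, :], f_bg_m[:, None], f_bg_nm[:, None])
    return f_inc, f_cf, f_bg  # (T,), (T,), (T, 52)


def _as_batch(x, B: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.shape[0] not in (1, B):
        raise ValueError(f"batch parameter of length {arr.shape[0]} "
                         f"incompatible with batch size {B}")
    return arr.reshape(-1, 1)


def simulate(arrays: BundleArrays,
             schedule: ReductionSchedule | None = None,
             trend: TrendSpec | None = None,
             econ: EconomicSpec | None = None,
             *,
             hr_tables: dict[str, HazardRatioTable] | None = None,
             bp_table: BPCoefficientTable | None = None,
             intervention: InterventionSpec | None = None,
             effect_scale=1.0,
             hr_scale_chd=1.0,
             hr_scale_stroke=1.0,
             cost_scale=1.0,
             intervention_cost_scale=1.0,
             detail: bool = False,
             dw_chd: float = DW_CHD,
             dw_stroke: float = DW_STROKE,
             ) -> dict:
    """Run the full population, optionally over a batch of parameter draws.

    The four ``*_scale`` arguments accept scalars or length-B arrays; all
    draws share the simulation loop (common random numbers sit with the
    caller).  Returns per-draw discounted and undiscounted totals, and with
    ``detail=True`` (batch size 1) per-year and per-stratum traces.
    """
    trend = trend or TrendSpec()
    econ = econ or EconomicSpec()
    hr_tables = hr_tables or default_hr_tables()
    bp_table = bp_table or law_bp_table()

    B = max(np.atleast_1d(np.asarray(s)).shape[0]
            for s in (effect_scale, hr_scale_chd, hr_scale_stroke,
                      cost_scale, intervention_cost_scale))
    if detail and B != 1:
        raise ValueError("detail traces require a single parameter set")
    eff = _as_batch(effect_scale, B)
    hmc = _as_batch(hr_scale_chd, B)
    hms = _as_batch(hr_scale_stroke, B)
    cmul = _as_batch(cost_scale, B)
    imul = _as_batch(intervention_cost_scale, B)

    S = len(arrays.strata)
    start_ages = arrays.start_ages
    pop = arrays.population
    base_year = arrays.base_year
    T = int(np.ceil(econ.horizon_age - start_ages.min()))
    years = base_year + np.arange(T)
    f_inc, f_cf, f_bg = _trend_factors(trend, base_year, years,
                                       arrays.is_maori)

    ages = start_ages[None, :] + np.arange(T)[:, None]  # (T, S)
    active = ages < econ.horizon_age
    band_idx = np.clip((ages.astype(int) - AGE_BANDS[0]) // 5,
                       0, len(AGE_BANDS) - 1)
    rows = np.arange(S)

    # sex-scaled sodium reduction per (T, S)
    if schedule is not None:
        male = schedule.series(T, "male")
        female = schedule.series(T, "female")
        dna = np.where(arrays.is_male[None, :], male[:, None],
                       female[:, None])
    else:
        dna = np.zeros((T, S))
    coef = np.empty((T, S))
    for t in range(T):
        coef[t] = [bp_table.coefficient(max(30.0, a)) for a in ages[t]]
    hr_c_bands = hr_tables["chd"].as_array()
    hr_s_bands = hr_tables["stroke"].as_array()

    disc = (1.0 + econ.discount_rate) ** (-np.arange(T))

    # state arrays (B, S)
    h = np.ones((B, S))
    c1 = np.zeros((B, S))
    cl = np.zeros((B, S))
    s1 = np.zeros((B, S))
    sl = np.zeros((B, S))
    dead = np.zeros((B, S))

    tot = {k: np.zeros(B) for k in
           ("qalys_disc", "qalys_undisc", "cost_cvd_disc",
            "cost_non_cvd_disc", "cost_intervention_disc",
            "cvd_deaths", "life_years")}
    if detail:
        per_year = {k: np.zeros(T) for k in
                    ("alive", "qalys_disc", "qalys_undisc", "cost_cvd_disc",
                     "cost_non_cvd_disc", "cost_intervention_disc",
                     "cvd_deaths")}
        per_stratum = {k: np.zeros((T, S)) for k in
                       ("alive", "qalys_disc", "cvd_deaths",
                        "cost_cvd_disc", "cost_non_cvd_disc")}

    for t in range(T):
        act = active[t]
        if not act.any():
            break
        bi = band_idx[t]
        inc_c = arrays.chd_incidence[rows, bi] * f_inc[t]
        inc_s = arrays.stroke_incidence[rows, bi] * f_inc[t]
        cf_c = np.minimum(arrays.chd_case_fatality[rows, bi] * f_cf[t], 1.0)
        cf_s = np.minimum(arrays.stroke_case_fatality[rows, bi] * f_cf[t], 1.0)
        bg = np.minimum(arrays.background_mortality[rows, bi] * f_bg[t], 1.0)
        pyld = arrays.pyld[rows, bi]

        # intervention pathway: sodium -> sBP -> incidence multiplier
        if schedule is not None or np.any(eff != 1.0):
            dsbp = coef[t][None, :] * (dna[t][None, :] * eff) / 100.0
            mult_c = np.clip(hr_c_bands[bi][None, :] * hmc, 1e-9,
                             1.0) ** (dsbp / 20.0)
            mult_s = np.clip(hr_s_bands[bi][None, :] * hms, 1e-9,
                             1.0) ** (dsbp / 20.0)
        else:
            mult_c = mult_s = np.ones((1, S))
        pic = np.minimum(inc_c[None, :] * mult_c, 1.0)
        pis = np.minimum(inc_s[None, :] * mult_s, 1.0)
        total_inc = pic + pis
        over = total_inc > 1.0
        if over.any():
            pic = np.where(over, pic / total_inc, pic)
            pis = np.where(over, pis / total_inc, pis)

        # accrual on start-of-cycle occupancy, masked once a cohort
        # passes the horizon age
        mask = act[None, :].astype(float)
        alive = (1.0 - dead) * mask
        chd_all = (c1 + cl) * mask
        stroke_all = (s1 + sl) * mask
        qaly_pp = (h * mask * (1.0 - pyld)
                   + chd_all * np.maximum(0.0, 1.0 - pyld - dw_chd)
                   + stroke_all * np.maximum(0.0, 1.0 - pyld - dw_stroke))
        qalys = qaly_pp @ pop
        cost_non_cvd = (alive * arrays.healthy_annual[rows, bi]) @ pop
        cost_cvd = ((c1 * arrays.chd_first_year[rows, bi]
                     + cl * arrays.chd_subsequent[rows, bi]
                     + s1 * arrays.stroke_first_year[rows, bi]
                     + sl * arrays.stroke_subsequent[rows, bi]) * mask) @ pop
        cvd_deaths_s = (chd_all * cf_c[None, :]
                        + stroke_all * cf_s[None, :]) * pop[None, :]
        cvd_deaths = cvd_deaths_s.sum(axis=1)
        if intervention is not None:
            int_cost = intervention_cost_stream(intervention, t)
        else:
            int_cost = 0.0

        tot["qalys_disc"] += qalys * disc[t]
        tot["qalys_undisc"] += qalys
        tot["cost_cvd_disc"] += cost_cvd * cmul[:, 0] * disc[t]
        tot["cost_non_cvd_disc"] += cost_non_cvd * cmul[:, 0] * disc[t]
        tot["cost_intervention_disc"] += int_cost * imul[:, 0] * disc[t]
        tot["cvd_deaths"] += cvd_deaths
        tot["life_years"] += (alive @ pop)

        if detail:
            per_year["alive"][t] = (alive @ pop)[0]
            per_year["qalys_disc"][t] = qalys[0] * disc[t]
            per_year["qalys_undisc"][t] = qalys[0]
            per_year["cost_cvd_disc"][t] = cost_cvd[0] * disc[t]
            per_year["cost_non_cvd_disc"][t] = cost_non_cvd[0] * disc[t]
            per_year["cost_intervention_disc"][t] = int_cost * disc[t]
            per_year["cvd_deaths"][t] = cvd_deaths[0]
            per_stratum["alive"][t] = (alive * pop[None, :])[0]
            per_stratum["qalys_disc"][t] = (qaly_pp * pop[None, :])[0] * disc[t]
            per_stratum["cvd_deaths"][t] = cvd_deaths_s[0]
            per_stratum["cost_cvd_disc"][t] = \
                ((c1 * arrays.chd_first_year[rows, bi]
                  + cl * arrays.chd_subsequent[rows, bi]
                  + s1 * arrays.stroke_first_year[rows, bi]
                  + sl * arrays.stroke_subsequent[rows, bi])
                 * mask * pop[None, :])[0] * disc[t]
            per_stratum["cost_non_cvd_disc"][t] = \
                (alive * arrays.healthy_annual[rows, bi]
                 * pop[None, :])[0] * disc[t]

        # transition (active strata only; inactive are frozen)
        surv_c = (1.0 - cf_c) * (1.0 - bg)
        surv_s = (1.0 - cf_s) * (1.0 - bg)
        h_stay = (1.0 - pic - pis)
        new_h = h * h_stay * (1.0 - bg)[None, :]
        new_c1 = h * pic
        new_cl = (c1 + cl) * surv_c[None, :]
        new_s1 = h * pis
        new_sl = (s1 + sl) * surv_s[None, :]
        new_dead = 1.0 - (new_h + new_c1 + new_cl + new_s1 + new_sl)
        upd = act[None, :]
        h = np.where(upd, new_h, h)
        c1 = np.where(upd, new_c1, c1)
        cl = np.where(upd, new_cl, cl)
        s1 = np.where(upd, new_s1, s1)
        sl = np.where(upd, new_sl, sl)
        dead = np.where(upd, new_dead, dead)
        total = h + c1 + cl + s1 + sl + dead
        if np.any(np.abs(total - 1.0) > OCCUPANCY_TOL):
            raise ArithmeticError("occupancy drifted beyond tolerance")

    out = {"totals": tot, "batch_size": B, "years": years,
           "base_year": base_year}
    if detail:
        out["per_year"] = per_year
        out["per_stratum"] = per_stratum
    return out


def run_cohort(bundle: BaselineBundle,
               schedule: ReductionSchedule | None = None,
               trend: TrendSpec | None = None,
               econ: EconomicSpec | None = None,
               *,
               intervention: InterventionSpec | None = None,
               hr_tables: dict[str, HazardRatioTable] | None = None,
               bp_table: BPCoefficientTable | None = None,
               detail: bool = True,
               **scales) -> TrajectoryResult:
    """Deterministic population run returning a :class:`TrajectoryResult`."""
    arrays = bundle.as_arrays()
    raw = simulate(arrays, schedule, trend, econ, hr_tables=hr_tables,
                   bp_table=bp_table, intervention=intervention,
                   detail=detail, **scales)
    totals = {k: float(v[0]) for k, v in raw["totals"].items()}
    if detail:
        by_year = pd.DataFrame({"year": raw["years"], **raw["per_year"]})
    else:
        by_year = pd.DataFrame()
    return TrajectoryResult(
        by_year=by_year,
        totals=totals,
        per_stratum=raw.get("per_stratum"),
        strata=arrays.strata,
        base_year=raw["base_year"],
    )
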