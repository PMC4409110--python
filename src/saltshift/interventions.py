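"""The eight sodium-reduction interventions as schedules over time.

Each intervention is a named policy with a population-mean sodium-reduction
effect (mmol/day at full effect), a phase-in schedule over calendar time, a
direct cost stream and an uncertainty specification.  Schedules are built
for the population-mean adult and rescaled to men and women by the ratio of
the sex-specific baseline intake to the population-mean intake.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

INTERVENTION_NAMES = (
    "counselling",
    "endorsement_label",
    "mandatory_3g",
    "mandatory_all",
    "uk_package",
    "uk_media",
    "salt_tax",
    "sinking_lid",
)


@dataclass(frozen=True)
class SodiumProfile:
    """Baseline daily sodium intake (mg/day) of the adult population."""

    intake_male: float = 4013.0
    intake_female: float = 3115.0
    intake_mean: float = 3544.0
    na_molar_mass: float = 22.99  # mg per mmol of sodium

    def __post_init__(self):
        if min(self.intake_male, self.intake_female, self.intake_mean,
               self.na_molar_mass) <= 0:
            raise ValueError("sodium profile values must be positive")
        if not self.intake_female < self.intake_mean < self.intake_male:
            raise ValueError("expected female < mean < male intake")

    def intake(self, sex: str) -> float:
        if sex == "male":
            return self.intake_male
        if sex == "female":
            return self.intake_female
        raise ValueError(f"unknown sex {sex!r}")

    def sex_ratio(self, sex: str) -> float:
        return self.intake(sex) / self.intake_mean

    def intake_mean_mmol(self) -> float:
        return self.intake_mean / self.na_molar_mass


def mg_to_mmol(mass: float, na_molar_mass: float = 22.99) -> float:
    """Convert a sodium mass (mg/day) to mmol/day."""
    if mass < 0:
        raise ValueError("sodium mass must be non-negative")
    return mass / na_molar_mass


def sex_scaled_reduction(population_mean_reduction: float, sex: str,
                         profile: SodiumProfile | None = None) -> float:
    """Scale a population-mean reduction to one sex by its intake ratio."""
    if population_mean_reduction < 0:
        raise ValueError("reduction must be non-negative")
    profile = profile or SodiumProfile()
    return population_mean_reduction * profile.sex_ratio(sex)


def required_annual_step(baseline_mg: float, target_mg: float, years: int,
                         na_molar_mass: float = 22.99) -> float:
    """Annual mmol/day reduction needed to reach a target in ``years``."""
    if years <= 0:
        raise ValueError("years must be positive")
    if baseline_mg < target_mg:
        raise ValueError("baseline below target")
    return round((baseline_mg - target_mg) / na_molar_mass / years, 1)


@dataclass(frozen=True)
class InterventionSpec:
    """Named policy with effect size, schedule, costs and uncertainty."""

    name: str
    label: str
    effect_mean: float  # mmol/day population-mean reduction at full effect
    effect_sd: float
    effect_distribution: str  # "normal"
    schedule: str  # immediate | linear | tax | sinking_lid
    phase_years: int
    direct_cost: float  # NZ$ (per year if recurring, once at year 0 if not)
    cost_recurring: bool
    cost_sd: float
    cost_distribution: str  # gamma | normal
    mandatory: bool = False
    sunset_year: int | None = None
    extra_recurring_cost: float = 0.0  # NZ$/year, e.g. ongoing enforcement
    schedule_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.effect_mean < 0 or self.phase_years < 1 or self.direct_cost < 0:
            raise ValueError(f"invalid intervention spec {self.name!r}")


def _counselling_effect(components: dict) -> float:
    # per-hour trial effect diluted over the whole adult population
    return (components["per_hour_effect_mmol"] * components["annual_hours"]
            / components["adult_population"])


def _counselling_sd(components: dict) -> float:
    # first-order sd of the product of the two uncertain components
    rel = math.hypot(
        components["per_hour_sd_mmol"] / components["per_hour_effect_mmol"],
        components["annual_hours_sd"] / components["annual_hours"])
    return _counselling_effect(components) * rel


def load_registry(profile: SodiumProfile | None = None,
                  media_share: float | None = None,
                  ) -> dict[str, InterventionSpec]:
    """Load the eight named interventions with their default parameters."""
    profile = profile or SodiumProfile()
    raw = json.loads(
        resources.files("saltshift.data").joinpath("interventions.json")
        .read_text("utf-8"))
    specs: dict[str, InterventionSpec] = {}
    for name, r in raw.items():
        params = dict(r.get("schedule_params", {}))
        effect = r["effect_mean_mmol"]
        sd = None
        if name == "counselling":
            comp = r["effect_components"]
            effect = _counselling_effect(comp)
            sd = _counselling_sd(comp)
            params["components"] = comp
        elif name == "uk_media":
            comp = r["effect_components"]
            share = media_share if media_share is not None \
                else comp["campaign_share"]
            effect = share * comp["package_total_mmol"]
            params["campaign_share"] = share
        elif r["schedule"] in ("tax", "sinking_lid"):
            effect = (profile.intake_mean - params["target_mg"]) \
                / profile.na_molar_mass
        if sd is None:
            sd = effect * r["effect_sd_fraction"]
        specs[name] = InterventionSpec(
            name=name,
            label=r["label"],
            effect_mean=float(effect),
            effect_sd=float(sd),
            effect_distribution=r["effect_distribution"],
            schedule=r["schedule"],
            phase_years=int(r["phase_years"]),
            direct_cost=float(r["cost_nzd"]),
            cost_recurring=bool(r["cost_recurring"]),
            cost_sd=float(r["cost_nzd"]) * r["cost_sd_fraction"],
            cost_distribution=r["cost_distribution"],
            mandatory=bool(r["mandatory"]),
            schedule_params=params,
        )
    return specs


def get_intervention(name: str, profile: SodiumProfile | None = None,
                     **overrides) -> InterventionSpec:
    registry = load_registry(profile)
    if name not in registry:
        raise ValueError(f"unknown intervention {name!r}; "
                         f"expected one of {INTERVENTION_NAMES}")
    spec = registry[name]
    return replace(spec, **overrides) if overrides else spec


@dataclass(frozen=True)
class ReductionSchedule:
    """Cumulative population-mean sodium reduction by years since start.

    ``cumulative[t-1]`` is the reduction in place during year ``t`` (year 1
    = the first modelled year).  Values persist at the final level for the
    lifetime of the cohort unless a sunset year is set, after which the
    reduction reverts to zero.
    """

    cumulative: np.ndarray  # mmol/day, population mean, years 1..horizon
    horizon: int
    profile: SodiumProfile = field(default_factory=SodiumProfile)
    sunset_year: int | None = None
    annual_price_increase: float | None = None  # tax schedules only

    def __post_init__(self):
        c = np.asarray(self.cumulative, dtype=float)
        if np.any(np.diff(c) < -1e-12):
            raise ValueError("cumulative reduction must be nondecreasing")
        if np.any(c < 0) or np.any(c > self.profile.intake_mean_mmol()):
            raise ValueError("cumulative reduction outside [0, baseline]")

    def cumulative_at(self, year: int, sex: str | None = None) -> float:
        """Reduction (mmol/day) in force during year ``year`` (1-based)."""
        if year < 1:
            raise ValueError("year is 1-based")
        if self.sunset_year is not None and year > self.sunset_year:
            return 0.0
        idx = min(year, len(self.cumulative)) - 1
        value = float(self.cumulative[idx])
        if sex is None:
            return value
        scaled = sex_scaled_reduction(value, sex, self.profile)
        return min(scaled, self.profile.intake(sex) / self.profile.na_molar_mass)

    def series(self, years: int, sex: str | None = None) -> np.ndarray:
        return np.array([self.cumulative_at(t, sex)
                         for t in range(1, years + 1)])

    @property
    def annual_reductions(self) -> np.ndarray:
        return np.diff(np.concatenate([[0.0], self.cumulative]))

    def with_sunset(self, sunset_year: int | None) -> "ReductionSchedule":
        return replace(self, sunset_year=sunset_year)

    def scaled(self, factor: float) -> "ReductionSchedule":
        """Schedule with all reductions multiplied by ``factor`` (PSA use)."""
        limit = self.profile.intake_mean_mmol()
        return replace(self, cumulative=np.clip(
            self.cumulative * factor, 0.0, limit))


def solve_tax_schedule(baseline: float, target_mg: float, elasticity: float,
                       annual_cap: float, horizon: int,
                       profile: SodiumProfile | None = None,
                       ) -> ReductionSchedule:
    """Excise-tax schedule reaching a target intake over a fixed horizon.

    A constant proportional annual demand reduction
    ``p = 1 - (target/baseline)**(1/horizon)`` reaches the target exactly at
    the horizon; ``p`` must not exceed the annual cap on demand change.  The
    implied annual price increase is ``p / |elasticity|``.  Absolute yearly
    reductions decrease geometrically, so the first year's is the largest.

    ``baseline`` is in mmol/day; ``target_mg`` in mg/day.
    """
    profile = profile or SodiumProfile()
    target = target_mg / profile.na_molar_mass
    if target > baseline:
        raise ValueError("target above baseline intake")
    if elasticity >= 0:
        raise ValueError("price elasticity of demand must be negative")
    if not 0 < annual_cap <= 1:
        raise ValueError("annual cap must be in (0, 1]")
    if horizon < 1:
        raise ValueError("horizon must be at least one year")
    p = 1.0 - (target / baseline) ** (1.0 / horizon)
    if p > annual_cap + 1e-12:
        raise ValueError(
            f"infeasible horizon: required annual demand reduction {p:.3f} "
            f"exceeds the cap {annual_cap}")
    intake = baseline * (1.0 - p) ** np.arange(1, horizon + 1)
    return ReductionSchedule(
        cumulative=baseline - intake,
        horizon=horizon,
        profile=profile,
        annual_price_increase=p / abs(elasticity),
    )


def build_schedule(spec: InterventionSpec,
                   profile: SodiumProfile | None = None,
                   ) -> ReductionSchedule:
    """Build the reduction schedule for a named intervention."""
    profile = profile or SodiumProfile()
    if spec.schedule == "immediate":
        sched = ReductionSchedule(
            cumulative=np.array([spec.effect_mean]), horizon=1,
            profile=profile)
    elif spec.schedule == "linear":
        steps = np.arange(1, spec.phase_years + 1) / spec.phase_years
        sched = ReductionSchedule(
            cumulative=spec.effect_mean * steps, horizon=spec.phase_years,
            profile=profile)
    elif spec.schedule == "tax":
        p = spec.schedule_params
        sched = solve_tax_schedule(
            baseline=profile.intake_mean_mmol(),
            target_mg=p["target_mg"],
            elasticity=p["elasticity"],
            annual_cap=p["annual_cap"],
            horizon=p["horizon_years"],
            profile=profile,
        )
    elif spec.schedule == "sinking_lid":
        p = spec.schedule_params
        total = (profile.intake_mean - p["target_mg"]) / profile.na_molar_mass
        years = int(p["target_years"])
        steps = np.minimum(np.arange(1, years + 1) * (total / years), total)
        sched = ReductionSchedule(cumulative=steps, horizon=years,
                                  profile=profile)
    else:
        raise ValueError(f"unknown schedule kind {spec.schedule!r} "
                         f"for intervention {spec.name!r}")
    return sched.with_sunset(spec.sunset_year)


def intervention_cost_stream(spec: InterventionSpec, year_offset: int) -> float:
    """Direct intervention cost (NZ$) accruing in year ``year_offset``.

    Offset 0 is the first modelled year.  One-off law/campaign costs fall
    entirely in year 0; programme costs recur every year for the lifetime
    of the cohort.
    """
    if year_offset < 0:
        raise ValueError("year offset must be non-negative")
    recurring = spec.extra_recurring_cost
    if spec.cost_recurring:
        return spec.direct_cost + recurring
    return (spec.direct_cost if year_offset == 0 else 0.0) + recurring
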