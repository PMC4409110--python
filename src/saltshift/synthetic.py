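"""Synthetic baseline generator.

The real baseline inputs (CHD/stroke incidence, case fatality, prevalence,
background mortality, morbidity, per-state costs and population counts by
sex x age x ethnicity) come from a non-public linked administrative dataset.
This module generates a baseline world with the same aggregate structure so
the whole pipeline runs and can be tested without any restricted data:

* CVD incidence and case fatality rise log-linearly with age, anchored to
  published CVD mortality magnitudes for non-Maori men and women;
* Maori rates exceed non-Maori rates, with an implied CVD-mortality rate
  ratio of about 4.5 at ages 50-54 falling to about 2.4 at 75-79;
* first-year disease costs are several-fold larger than subsequent-year
  costs, anchored to the published 60-64-year-old female cost set;
* population counts follow a plausible NZ-like 35+ age pyramid normalised
  to 2.3 million adults.

Determinism: the same (seed, config) always yields a bit-identical bundle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .strata import (
    AGE_BANDS,
    BaselineBundle,
    BaselineEpi,
    CostSet,
    StratumKey,
    all_strata,
    band_midpoint,
)

# Health-system cost scale-ups covering known gaps in the source data:
# disease costs are scaled by 1.2 at every age; non-diseased ("healthy")
# costs by 1.1 / 1.2 / 1.3 for ages 65-74 / 75-84 / 85+.
DISEASE_COST_SCALE = 1.2
_HEALTHY_SCALE_STEPS = ((85, 1.3), (75, 1.2), (65, 1.1))


def healthy_cost_scale(age_band: int) -> float:
    if age_band not in AGE_BANDS:
        raise ValueError(f"unknown age band {age_band!r}")
    for lo, factor in _HEALTHY_SCALE_STEPS:
        if age_band >= lo:
            return factor
    return 1.0


def scale_costs(raw_disease_cost: float, raw_healthy_cost: float,
                age_band: int) -> tuple[float, float]:
    """Apply the data-gap scale-up factors to a (disease, healthy) cost pair."""
    if raw_disease_cost < 0 or raw_healthy_cost < 0:
        raise ValueError("costs must be non-negative")
    return (raw_disease_cost * DISEASE_COST_SCALE,
            raw_healthy_cost * healthy_cost_scale(age_band))


@dataclass(frozen=True)
class GeneratorConfig:
    """Anchors and gradients for the synthetic baseline.

    CVD mortality anchors are per 100,000 per year for non-Maori in the
    published 2021 reporting year; the generator back-projects them to the
    2011 base year with the secular incidence/case-fatality trend.
    """

    base_year: int = 2011
    total_adults: int = 2_300_000

    # non-Maori CVD mortality anchors per 100,000 (2021 reporting year)
    cvd_mortality_50_54: dict[str, float] = field(
        default_factory=lambda: {"male": 35.0, "female": 21.0})
    cvd_mortality_75_79: dict[str, float] = field(
        default_factory=lambda: {"male": 514.0, "female": 453.0})
    anchor_trend_apc: float = -0.02  # used to back-project the anchors
    anchor_trend_years: int = 10

    # Maori:non-Maori implied CVD mortality rate ratio, log-linear in age
    maori_ratio_50_54: float = 4.5
    maori_ratio_75_79: float = 2.4

    # disease mix and severity
    chd_mortality_share: float = 0.5  # share of CVD deaths from CHD
    chd_case_fatality_50_54: float = 0.04  # deaths per prevalent case-year
    case_fatality_log_slope: float = 0.025  # per year of age
    stroke_case_fatality_ratio: float = 1.3
    prevalence_shortfall: float = 0.9  # stored / steady-state prevalence

    # background (non-CVD) mortality, Gompertz-like
    background_mortality_50_54_male: float = 0.0025
    background_mortality_log_slope: float = 0.095
    background_mortality_female_ratio: float = 0.65

    # background morbidity (prevalent YLD per person)
    pyld_60_64_maori_female: float = 0.288
    pyld_log_slope: float = 0.018
    pyld_maori_ratio: float = 1.3

    # cost anchors: 60-64 female, values as stored in the bundle (i.e. after
    # the data-gap scale-up and after removing the CVD-attributable share
    # from the healthy-state cost)
    healthy_cost_60_64_female: float = 2_381.0
    chd_cost_first_year: float = 16_258.0
    chd_cost_subsequent: float = 5_395.0
    stroke_cost_first_year: float = 20_553.0
    stroke_cost_subsequent: float = 5_991.0
    healthy_cost_log_slope: float = 0.02  # per year of age
    disease_cost_log_slope: float = 0.005
    cvd_attributable_fraction: float = 0.10  # removed from healthy_annual

    # population pyramid
    maori_share_35_39: float = 0.14
    maori_share_log_slope: float = -0.035  # per year of age
    band_weights: tuple[float, ...] = (
        1.00, 0.97, 0.93, 0.90, 0.86, 0.78, 0.66,
        0.52, 0.38, 0.25, 0.14, 0.06, 0.02)

    # stochastic jitter on the epidemiological age curves
    incidence_jitter_sd: float = 0.05
    incidence_jitter_clip: float = 0.15
    case_fatality_jitter_sd: float = 0.02
    case_fatality_jitter_clip: float = 0.03

    def validate(self) -> "GeneratorConfig":
        for name in ("total_adults", "maori_ratio_50_54", "maori_ratio_75_79",
                     "chd_case_fatality_50_54", "healthy_cost_60_64_female",
                     "chd_cost_first_year", "stroke_cost_first_year",
                     "background_mortality_50_54_male",
                     "pyld_60_64_maori_female"):
            if getattr(self, name) <= 0:
                raise ValueError(f"generator anchor {name} must be positive")
        for d in (self.cvd_mortality_50_54, self.cvd_mortality_75_79):
            if set(d) != {"male", "female"} or any(v <= 0 for v in d.values()):
                raise ValueError("CVD mortality anchors need positive "
                                 "male/female entries")
        if len(self.band_weights) != len(AGE_BANDS):
            raise ValueError("band_weights must cover the 13 age bands")
        if not 0 <= self.cvd_attributable_fraction < 1:
            raise ValueError("cvd_attributable_fraction must be in [0, 1)")
        return self


def _maori_mortality_ratio(cfg: GeneratorConfig, age: float) -> float:
    """Maori:non-Maori implied CVD mortality ratio at an attained age."""
    log_slope = math.log(cfg.maori_ratio_75_79 / cfg.maori_ratio_50_54) / 25.0
    return float(np.clip(
        cfg.maori_ratio_50_54 * math.exp(log_slope * (age - 52.5)), 1.0, 8.0))


def _monotone_jitter(rng: np.random.Generator, n: int, sd: float,
                     clip: float) -> np.ndarray:
    """Cumulative log-scale jitter whose per-band steps are bounded.

    Bounding each step below the deterministic log-gradient of the curve it
    perturbs keeps the jittered curves nondecreasing in age.
    """
    steps = np.clip(rng.normal(0.0, sd, size=n - 1), -clip, clip)
    return np.concatenate([[0.0], np.cumsum(steps)])


def _largest_remainder_round(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer counts proportional to weights, summing exactly to total."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(raw - base)[::-1]
    base[order[:short]] += 1
    return base


def generate_baseline(seed: int,
                      config: GeneratorConfig | None = None) -> BaselineBundle:
    """Generate a complete synthetic :class:`BaselineBundle`."""
    cfg = (config or GeneratorConfig()).validate()
    rng = np.random.default_rng(seed)
    ages = np.array([band_midpoint(b) for b in AGE_BANDS])
    n = len(AGE_BANDS)

    back = (1.0 + cfg.anchor_trend_apc) ** (-cfg.anchor_trend_years)

    # deterministic case-fatality curves (shared across sexes/ethnicities
    # before the Maori ratio); jitter added per sex below
    cf_chd_det = cfg.chd_case_fatality_50_54 * np.exp(
        cfg.case_fatality_log_slope * (ages - 52.5))
    ratio_curve = np.array([_maori_mortality_ratio(cfg, a) for a in ages])
    sqrt_ratio = np.sqrt(ratio_curve)

    epi: dict[StratumKey, BaselineEpi] = {}
    costs: dict[StratumKey, CostSet] = {}

    for sex in ("male", "female"):
        # non-Maori implied CVD mortality per person-year in the base year,
        # log-linear through the two published anchors
        m_50 = cfg.cvd_mortality_50_54[sex] / 1e5 * back
        m_75 = cfg.cvd_mortality_75_79[sex] / 1e5 * back
        slope = math.log(m_75 / m_50) / 25.0
        mort = m_50 * np.exp(slope * (ages - 52.5))

        jit_inc_c = _monotone_jitter(rng, n, cfg.incidence_jitter_sd,
                                     cfg.incidence_jitter_clip)
        jit_inc_s = _monotone_jitter(rng, n, cfg.incidence_jitter_sd,
                                     cfg.incidence_jitter_clip)
        jit_cf_c = _monotone_jitter(rng, n, cfg.case_fatality_jitter_sd,
                                    cfg.case_fatality_jitter_clip)
        jit_cf_s = _monotone_jitter(rng, n, cfg.case_fatality_jitter_sd,
                                    cfg.case_fatality_jitter_clip)

        cf_chd = cf_chd_det * np.exp(jit_cf_c)
        cf_str = cf_chd_det * cfg.stroke_case_fatality_ratio * np.exp(jit_cf_s)
        inc_chd = cfg.chd_mortality_share * mort / cf_chd * np.exp(jit_inc_c)
        inc_str = ((1.0 - cfg.chd_mortality_share) * mort / cf_str
                   * np.exp(jit_inc_s))

        bg = (cfg.background_mortality_50_54_male
              * np.exp(cfg.background_mortality_log_slope * (ages - 52.5)))
        if sex == "female":
            bg = bg * cfg.background_mortality_female_ratio

        pyld_nm = (cfg.pyld_60_64_maori_female / cfg.pyld_maori_ratio
                   * np.exp(cfg.pyld_log_slope * (ages - 62.5)))

        # healthy cost anchored at the 60-64 female stored value; the raw
        # (pre scale-up, pre CVD-share-removal) surface is reconstructed so
        # that the anchor stratum reproduces the published figure exactly
        healthy_raw_anchor = (cfg.healthy_cost_60_64_female
                              / (1.0 - cfg.cvd_attributable_fraction))
        healthy_raw = healthy_raw_anchor * np.exp(
            cfg.healthy_cost_log_slope * (ages - 62.5))
        disease_raw = {
            "chd_first_year": cfg.chd_cost_first_year / DISEASE_COST_SCALE,
            "chd_subsequent": cfg.chd_cost_subsequent / DISEASE_COST_SCALE,
            "stroke_first_year": cfg.stroke_cost_first_year / DISEASE_COST_SCALE,
            "stroke_subsequent": cfg.stroke_cost_subsequent / DISEASE_COST_SCALE,
        }
        disease_age = np.exp(cfg.disease_cost_log_slope * (ages - 62.5))

        for eth in ("non_maori", "maori"):
            if eth == "maori":
                # the implied-mortality ratio splits evenly (square root)
                # between incidence and case fatality; background mortality
                # follows the same declining-with-age ratio
                f_inc, f_cf, f_bg = sqrt_ratio, sqrt_ratio, sqrt_ratio
                f_pyld = cfg.pyld_maori_ratio
            else:
                f_inc = f_cf = f_bg = np.ones(n)
                f_pyld = 1.0

            e_inc_c = np.clip(inc_chd * f_inc, 0.0, 0.95)
            e_inc_s = np.clip(inc_str * f_inc, 0.0, 0.95)
            e_cf_c = np.clip(cf_chd * f_cf, 0.0, 0.95)
            e_cf_s = np.clip(cf_str * f_cf, 0.0, 0.95)
            e_bg = np.clip(bg * f_bg, 0.0, 0.95)
            e_pyld = np.clip(pyld_nm * f_pyld, 0.0, 0.95)
            prev_c = (e_inc_c / (e_inc_c + e_cf_c + e_bg)
                      * cfg.prevalence_shortfall)
            prev_s = (e_inc_s / (e_inc_s + e_cf_s + e_bg)
                      * cfg.prevalence_shortfall)

            for bi, band in enumerate(AGE_BANDS):
                key = StratumKey(sex, band, eth)
                epi[key] = BaselineEpi(
                    chd_incidence=float(e_inc_c[bi]),
                    stroke_incidence=float(e_inc_s[bi]),
                    chd_case_fatality=float(e_cf_c[bi]),
                    stroke_case_fatality=float(e_cf_s[bi]),
                    chd_prevalence=float(prev_c[bi]),
                    stroke_prevalence=float(prev_s[bi]),
                    background_mortality=float(e_bg[bi]),
                    pyld=float(e_pyld[bi]),
                )
                scale_d = DISEASE_COST_SCALE * disease_age[bi]
                costs[key] = CostSet(
                    healthy_annual=float(
                        healthy_raw[bi]
                        * (1.0 - cfg.cvd_attributable_fraction)
                        * healthy_cost_scale(band)),
                    chd_first_year=float(disease_raw["chd_first_year"] * scale_d),
                    chd_subsequent=float(disease_raw["chd_subsequent"] * scale_d),
                    stroke_first_year=float(
                        disease_raw["stroke_first_year"] * scale_d),
                    stroke_subsequent=float(
                        disease_raw["stroke_subsequent"] * scale_d),
                )

    # population pyramid: band weights, declining Maori share, mild female
    # skew at older ages
    weights = np.asarray(cfg.band_weights, dtype=float)
    band_counts = _largest_remainder_round(weights, cfg.total_adults)
    population: dict[StratumKey, float] = {}
    for bi, band in enumerate(AGE_BANDS):
        age = ages[bi]
        maori_share = float(np.clip(
            cfg.maori_share_35_39
            * math.exp(cfg.maori_share_log_slope * (age - 37.5)),
            0.005, 0.5))
        male_share = float(np.clip(0.50 - 0.05 * (age - 37.5) / 60.0,
                                   0.30, 0.60))
        cell_w = np.array([
            male_share * maori_share,           # male maori
            male_share * (1 - maori_share),     # male non-maori
            (1 - male_share) * maori_share,     # female maori
            (1 - male_share) * (1 - maori_share),
        ])
        cells = _largest_remainder_round(cell_w, int(band_counts[bi]))
        population[StratumKey("male", band, "maori")] = float(cells[0])
        population[StratumKey("male", band, "non_maori")] = float(cells[1])
        population[StratumKey("female", band, "maori")] = float(cells[2])
        population[StratumKey("female", band, "non_maori")] = float(cells[3])

    return BaselineBundle(epi=epi, costs=costs, population=population,
                          base_year=cfg.base_year).validate()


def implied_cvd_mortality(bundle: BaselineBundle, key: StratumKey) -> float:
    """CVD mortality per person-year implied by incidence x case fatality."""
    e = bundle.epi[key]
    return (e.chd_incidence * e.chd_case_fatality
            + e.stroke_incidence * e.stroke_case_fatality)


def check_coherence(bundle: BaselineBundle,
                    tolerance: float = 0.5) -> pd.DataFrame:
    """Steady-state coherence check of prevalence against incidence.

    For each stratum and disease the prevalence implied by a steady state,
    ``incidence / (incidence + case_fatality + background_mortality)``, is
    compared with the stored prevalence; strata deviating by more than
    ``tolerance`` (relative) are flagged.  Empirical prevalence from
    administrative data with a finite look-back window runs low, so the
    default tolerance is generous.  Returns a report frame; never raises.
    """
    rows = []
    for key in all_strata():
        e = bundle.epi[key]
        for disease in ("chd", "stroke"):
            inc = getattr(e, f"{disease}_incidence")
            cf = getattr(e, f"{disease}_case_fatality")
            stored = getattr(e, f"{disease}_prevalence")
            denom = inc + cf + e.background_mortality
            implied = inc / denom if denom > 0 else 0.0
            if implied > 0:
                deviation = abs(stored - implied) / implied
            else:
                deviation = 0.0 if stored == 0 else math.inf
            rows.append({
                "sex": key.sex, "age_band": key.age_band,
                "ethnicity": key.ethnicity, "disease": disease,
                "stored_prevalence": stored, "implied_prevalence": implied,
                "relative_deviation": deviation,
                "flagged": bool(deviation > tolerance),
            })
    return pd.DataFrame(rows)
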