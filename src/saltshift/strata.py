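"""Population strata and baseline input containers.

The modelled population is a closed cohort of adults aged 35+ divided into
52 strata: sex (male/female) x thirteen 5-year age bands (35-39 ... 95+)
x ethnicity (Maori / non-Maori).  Every epidemiological rate, cost and
population count is keyed by one of these strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

SEXES = ("male", "female")
ETHNICITIES = ("maori", "non_maori")
AGE_BANDS = tuple(range(35, 100, 5))  # 35, 40, ..., 95 ("95+")
N_BANDS = len(AGE_BANDS)
BASE_YEAR_DEFAULT = 2011


class StratumKey(NamedTuple):
    """One (sex, age band, ethnicity) population cell."""

    sex: str
    age_band: int
    ethnicity: str

    def validate(self) -> "StratumKey":
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}")
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(f"unknown ethnicity {self.ethnicity!r}")
        return self


def all_strata() -> list[StratumKey]:
    """The 52 strata in canonical (sex, band, ethnicity) order."""
    return [
        StratumKey(s, b, e) for s in SEXES for b in AGE_BANDS for e in ETHNICITIES
    ]


def band_of_age(age: float) -> int:
    """5-year band start containing ``age`` (bands half-open, 95+ absorbs)."""
    if age < AGE_BANDS[0]:
        raise ValueError(f"age {age} below modelled range (35+)")
    return min(AGE_BANDS[-1], int(age) // 5 * 5)


def band_midpoint(band: int) -> float:
    """Mid-band age used as a cohort's starting age (97.5 for 95+)."""
    return band + 2.5


EPI_FIELDS = (
    "chd_incidence",
    "stroke_incidence",
    "chd_case_fatality",
    "stroke_case_fatality",
    "chd_prevalence",
    "stroke_prevalence",
    "background_mortality",
    "pyld",
)

COST_FIELDS = (
    "healthy_annual",
    "chd_first_year",
    "chd_subsequent",
    "stroke_first_year",
    "stroke_subsequent",
)


@dataclass(frozen=True)
class BaselineEpi:
    """Annual epidemiological rates for one stratum.

    Incidence and background mortality are events per person-year, case
    fatality is deaths per prevalent case-year, prevalence is a proportion
    and ``pyld`` is the background (comorbidity) years lived with disability
    per person, i.e. the morbidity deducted from a full-health year.
    """

    chd_incidence: float
    stroke_incidence: float
    chd_case_fatality: float
    stroke_case_fatality: float
    chd_prevalence: float
    stroke_prevalence: float
    background_mortality: float
    pyld: float

    def validate(self) -> "BaselineEpi":
        for f in EPI_FIELDS:
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f}={v} outside [0, 1]")
        return self


@dataclass(frozen=True)
class CostSet:
    """Annual health-system costs (2011 NZ$) for one stratum.

    ``healthy_annual`` is the cost of a person with neither CHD nor stroke
    (CVD-attributable component removed); disease costs are *excess* over
    that, split into a first-year and a subsequent-year amount.
    """

    healthy_annual: float
    chd_first_year: float
    chd_subsequent: float
    stroke_first_year: float
    stroke_subsequent: float

    def validate(self) -> "CostSet":
        for f in COST_FIELDS:
            if getattr(self, f) < 0:
                raise ValueError(f"{f} negative")
        if self.chd_first_year < self.chd_subsequent:
            raise ValueError("CHD first-year cost below subsequent-year cost")
        if self.stroke_first_year < self.stroke_subsequent:
            raise ValueError("stroke first-year cost below subsequent-year cost")
        return self


@dataclass
class BaselineBundle:
    """Complete baseline world: rates, costs and population for all strata."""

    epi: dict[StratumKey, BaselineEpi]
    costs: dict[StratumKey, CostSet]
    population: dict[StratumKey, float]
    base_year: int = BASE_YEAR_DEFAULT

    @property
    def total_adults(self) -> float:
        return float(sum(self.population.values()))

    def validate(self) -> "BaselineBundle":
        expected = set(all_strata())
        for name, mapping in (("epi", self.epi), ("costs", self.costs),
                              ("population", self.population)):
            missing = expected - set(mapping)
            if missing:
                raise ValueError(f"{name} missing strata: {sorted(missing)[:3]}...")
        for k, e in self.epi.items():
            e.validate()
        for k, c in self.costs.items():
            c.validate()
        for k, n in self.population.items():
            if n <= 0:
                raise ValueError(f"non-positive population in {k}")
        return self

    # ------------------------------------------------------------------
    # tabular round trip
    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in all_strata():
            row: dict[str, object] = {
                "sex": key.sex,
                "age_band": key.age_band,
                "ethnicity": key.ethnicity,
            }
            e, c = self.epi[key], self.costs[key]
            row.update({f: getattr(e, f) for f in EPI_FIELDS})
            row.update({f: getattr(c, f) for f in COST_FIELDS})
            row["population"] = self.population[key]
            row["base_year"] = self.base_year
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BaselineBundle":
        epi: dict[StratumKey, BaselineEpi] = {}
        costs: dict[StratumKey, CostSet] = {}
        pop: dict[StratumKey, float] = {}
        base_years = set(df["base_year"].astype(int))
        if len(base_years) != 1:
            raise ValueError(f"inconsistent base_year column: {base_years}")
        for _, r in df.iterrows():
            key = StratumKey(str(r["sex"]), int(r["age_band"]),
                             str(r["ethnicity"])).validate()
            epi[key] = BaselineEpi(**{f: float(r[f]) for f in EPI_FIELDS})
            costs[key] = CostSet(**{f: float(r[f]) for f in COST_FIELDS})
            pop[key] = float(r["population"])
        return cls(epi=epi, costs=costs, population=pop,
                   base_year=base_years.pop()).validate()

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BaselineBundle":
        return cls.from_frame(pd.read_csv(path))

    def copy(self) -> "BaselineBundle":
        return BaselineBundle(dict(self.epi), dict(self.costs),
                              dict(self.population), self.base_year)

    # ------------------------------------------------------------------
    # dense array view used by the simulation engine
    # ------------------------------------------------------------------
    def as_arrays(self) -> "BundleArrays":
        """Rates/costs as (stratum, attained-band) arrays.

        Row s corresponds to ``all_strata()[s]``; column b holds the value
        the cohort experiences once its attained age falls in band
        ``AGE_BANDS[b]`` (sex and ethnicity fixed per row).
        """
        strata = all_strata()
        shape = (len(strata), N_BANDS)
        out = {f: np.empty(shape) for f in EPI_FIELDS + COST_FIELDS}
        for si, key in enumerate(strata):
            for bi, band in enumerate(AGE_BANDS):
                bkey = StratumKey(key.sex, band, key.ethnicity)
                e, c = self.epi[bkey], self.costs[bkey]
                for f in EPI_FIELDS:
                    out[f][si, bi] = getattr(e, f)
                for f in COST_FIELDS:
                    out[f][si, bi] = getattr(c, f)
        population = np.array([self.population[k] for k in strata])
        return BundleArrays(
            strata=strata,
            population=population,
            base_year=self.base_year,
            **out,
        )


@dataclass
class BundleArrays:
    """Dense view of a :class:`BaselineBundle` (see ``as_arrays``)."""

    strata: list[StratumKey]
    population: np.ndarray  # (52,)
    base_year: int
    chd_incidence: np.ndarray  # (52, 13) by attained band
    stroke_incidence: np.ndarray
    chd_case_fatality: np.ndarray
    stroke_case_fatality: np.ndarray
    chd_prevalence: np.ndarray
    stroke_prevalence: np.ndarray
    background_mortality: np.ndarray
    pyld: np.ndarray
    healthy_annual: np.ndarray
    chd_first_year: np.ndarray
    chd_subsequent: np.ndarray
    stroke_first_year: np.ndarray
    stroke_subsequent: np.ndarray

    @property
    def start_ages(self) -> np.ndarray:
        return np.array([band_midpoint(k.age_band) for k in self.strata])

    @property
    def is_maori(self) -> np.ndarray:
        return np.array([k.ethnicity == "maori" for k in self.strata])

    @property
    def is_male(self) -> np.ndarray:
        return np.array([k.sex == "male" for k in self.strata])
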