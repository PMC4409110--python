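"""Sodium -> blood pressure -> CVD incidence pathway.

A change in daily sodium intake maps to a change in systolic blood
pressure (sBP) through age-specific regression coefficients, and the sBP
change maps to CHD and stroke incidence multipliers through age-specific
hazard ratios per 20 mm Hg, applied on the log scale so the effect is
multiplicative in the sBP change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .strata import AGE_BANDS

# mm Hg change in sBP per 100 mmol/day change in sodium, by age decade
# (meta-regression of salt-reduction trials); the 60-69 coefficient is held
# for ages 70+ as a conservative default.
LAW_BP_COEFFICIENTS = {30: 5.5, 40: 6.6, 50: 9.2, 60: 10.3}

# flat alternative from the He & MacGregor meta-analysis of longer trials
# (approximately 5.8 mm Hg per 100 mmol/day at all ages), used in scenario
# analyses; weaker than the age-specific curve above ages 50.
HE_MACGREGOR_BP_COEFFICIENTS = {30: 5.8, 40: 5.8, 50: 5.8, 60: 5.8}


@dataclass(frozen=True)
class BPCoefficientTable:
    """sBP change (mm Hg) per 100 mmol/day sodium change, by age decade."""

    coefficients: dict[int, float] = field(
        default_factory=lambda: dict(LAW_BP_COEFFICIENTS))
    extrapolate_70_plus: str = "hold"  # "hold" or "linear"

    def coefficient(self, age: float) -> float:
        if age < 30:
            raise ValueError(f"age {age} below the supported range (30+)")
        decades = sorted(self.coefficients)
        decade = min(decades[-1], int(age) // 10 * 10)
        if age >= decades[-1] + 10 and self.extrapolate_70_plus == "linear":
            # continue the slope of the last two decades
            lo, hi = decades[-2], decades[-1]
            slope = (self.coefficients[hi] - self.coefficients[lo]) / 10.0
            return self.coefficients[hi] + slope * (int(age) // 10 * 10 - hi)
        return self.coefficients[decade]


def law_bp_table() -> BPCoefficientTable:
    return BPCoefficientTable(dict(LAW_BP_COEFFICIENTS))


def he_macgregor_bp_table() -> BPCoefficientTable:
    return BPCoefficientTable(dict(HE_MACGREGOR_BP_COEFFICIENTS))


def sodium_to_sbp(delta_sodium: float, age: float,
                  table: BPCoefficientTable | None = None) -> float:
    """sBP reduction (mm Hg) for a sodium reduction of ``delta_sodium`` mmol/d."""
    if delta_sodium < 0:
        raise ValueError("sodium reduction must be non-negative")
    table = table or law_bp_table()
    return table.coefficient(age) * delta_sodium / 100.0


@dataclass(frozen=True)
class HazardRatioTable:
    """Hazard ratios for a 20 mm Hg sBP reduction, by 5-year age band.

    The protective effect attenuates with age: the default tables
    interpolate log-linearly from the strongest published ratio (ages up to
    44) to the weakest (85+).  Per-band uncertainty is 10 percent of the
    point estimate.
    """

    disease: str
    by_band: dict[int, float]
    sd_fraction: float = 0.10

    def __post_init__(self):
        for band, hr in self.by_band.items():
            if not 0.0 < hr <= 1.0:
                raise ValueError(f"hazard ratio {hr} at band {band} "
                                 "outside (0, 1]")

    def hr(self, age: float) -> float:
        band = min(AGE_BANDS[-1], max(AGE_BANDS[0], int(age) // 5 * 5))
        return self.by_band[band]

    def as_array(self) -> np.ndarray:
        return np.array([self.by_band[b] for b in AGE_BANDS])


def _interpolated_hr_table(disease: str, strongest: float,
                           weakest: float) -> HazardRatioTable:
    # strongest HR up to age 44, weakest at 85+, log-linear between
    by_band: dict[int, float] = {}
    for band in AGE_BANDS:
        if band <= 40:
            by_band[band] = strongest
        elif band >= 85:
            by_band[band] = weakest
        else:
            frac = (band - 40) / 45.0
            by_band[band] = math.exp(
                (1 - frac) * math.log(strongest) + frac * math.log(weakest))
    return HazardRatioTable(disease, by_band)


def default_hr_tables() -> dict[str, HazardRatioTable]:
    """Default CHD (0.49-0.67) and stroke (0.38-0.67) tables."""
    return {
        "chd": _interpolated_hr_table("chd", 0.49, 0.67),
        "stroke": _interpolated_hr_table("stroke", 0.38, 0.67),
    }


def scale_hazard_ratio(hr20, delta_sbp):
    """Incidence multiplier for a ``delta_sbp`` mm Hg sBP reduction.

    ``hr20 ** (delta_sbp / 20)``: multiplicative in the sBP change, equal to
    ``hr20`` at exactly 20 mm Hg and 1 at zero.  Accepts scalars or arrays.
    """
    hr20 = np.asarray(hr20, dtype=float)
    delta_sbp = np.asarray(delta_sbp, dtype=float)
    if np.any(hr20 <= 0):
        raise ValueError("hazard ratio must be positive")
    if np.any(delta_sbp < 0):
        raise ValueError("sBP reduction must be non-negative")
    out = hr20 ** (delta_sbp / 20.0)
    return float(out) if out.ndim == 0 else out


def shift_incidence(baseline_rate: float, multiplier: float,
                    direction: str = "apply") -> float:
    """Apply or remove an incidence multiplier.

    ``apply`` scales a rate down under an intervention; ``remove`` inverts
    the operation and is used to back-calculate counterfactual rates for a
    world without current practice (clamped at 1 if inflation overshoots).
    """
    if not 0.0 <= baseline_rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if not 0.0 < multiplier <= 1.0:
        raise ValueError("multiplier must be in (0, 1]")
    if direction == "apply":
        return baseline_rate * multiplier
    if direction == "remove":
        out = baseline_rate / multiplier
        if out > 1.0:
            import warnings
            warnings.warn("back-calculated rate clamped to 1.0")
            return 1.0
        return out
    raise ValueError(f"unknown direction {direction!r}")


def incidence_multiplier(delta_sodium: float, age: float,
                         hr_table: HazardRatioTable,
                         bp_table: BPCoefficientTable | None = None) -> float:
    """Composite multiplier: sodium reduction -> sBP -> incidence."""
    delta_sbp = sodium_to_sbp(delta_sodium, age, bp_table)
    return scale_hazard_ratio(hr_table.hr(age), delta_sbp)
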