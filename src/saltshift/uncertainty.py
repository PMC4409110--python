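"""Probabilistic sensitivity analysis and one-way (tornado) analysis.

Parameter uncertainty is propagated by Monte Carlo: each uncertain input
has a normal or gamma distribution (gamma moment-matched from mean and sd),
one value per draw, with a single shared random stream per draw index so
that incremental comparisons across interventions use common random
numbers.  Implausible normal draws (e.g. negative sodium reductions) are
truncated and counted, not resampled, keeping the number of draws fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ParamDistribution:
    """One uncertain input parameter."""

    name: str
    family: str  # "normal" | "gamma"
    mean: float
    sd: float
    truncate_low: float | None = None
    truncate_high: float | None = None

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.family not in ("normal", "gamma"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family == "gamma" and self.mean <= 0:
            raise ValueError("gamma requires a positive mean")

    @property
    def gamma_shape(self) -> float:
        return (self.mean / self.sd) ** 2

    @property
    def gamma_scale(self) -> float:
        return self.sd ** 2 / self.mean

    def _frozen(self):
        if self.family == "normal":
            return stats.norm(self.mean, self.sd)
        return stats.gamma(self.gamma_shape, scale=self.gamma_scale)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        if self.family == "normal":
            x = rng.normal(self.mean, self.sd, size=n)
        else:
            x = rng.gamma(self.gamma_shape, self.gamma_scale, size=n)
        return self._truncate(x)

    def from_uniform(self, u: np.ndarray) -> np.ndarray:
        """Inverse-CDF transform of shared uniforms (common random numbers)."""
        if self.sd == 0:
            return np.full(np.shape(u), self.mean)
        return self._truncate(self._frozen().ppf(u))

    def _truncate(self, x: np.ndarray) -> np.ndarray:
        lo = -np.inf if self.truncate_low is None else self.truncate_low
        hi = np.inf if self.truncate_high is None else self.truncate_high
        return np.clip(x, lo, hi)

    def percentile(self, q: float) -> float:
        if self.sd == 0:
            return self.mean
        return float(self._truncate(np.asarray(self._frozen().ppf(q))))


@dataclass(frozen=True)
class PSAConfig:
    n_draws: int = 2000
    seed: int = 0
    interval: float = 0.95

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("need at least one draw")
        if not 0 < self.interval < 1:
            raise ValueError("interval must be in (0, 1)")


def draw_parameters(registry: list[ParamDistribution], seed: int,
                    n_draws: int = 2000) -> pd.DataFrame:
    """Sample all registry parameters; reproducible for a given seed.

    Draws one shared uniform stream per parameter name ordering, so the
    same seed always yields bit-identical samples.  Truncation counts are
    attached as ``frame.attrs['truncated']``.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    truncated = {}
    for p in registry:
        raw = p.draw(rng, n_draws)
        cols[p.name] = raw
        lo = -np.inf if p.truncate_low is None else p.truncate_low
        hi = np.inf if p.truncate_high is None else p.truncate_high
        truncated[p.name] = int(np.sum((raw <= lo) | (raw >= hi))) \
            if p.sd > 0 and (np.isfinite(lo) or np.isfinite(hi)) else 0
    df = pd.DataFrame(cols)
    df.attrs["truncated"] = truncated
    return df


def interval_bounds(x: np.ndarray, interval: float = 0.95
                    ) -> tuple[float, float]:
    """Central percentile interval as order statistics of the draws."""
    # rounded so that e.g. interval=0.95 hits the exact 0.025 tail mass
    alpha = round((1.0 - interval) / 2.0, 12)
    lo = np.quantile(x, alpha, method="inverted_cdf")
    hi = np.quantile(x, round(1.0 - alpha, 12), method="inverted_cdf")
    return float(lo), float(hi)


@dataclass
class PSAResult:
    draws: pd.DataFrame  # one row per draw: parameters and outputs
    outputs: list[str]
    summary: pd.DataFrame  # mean / lo / hi per output
    n_failed: int = 0
    truncated: dict = field(default_factory=dict)


def run_psa(model_closure, registry: list[ParamDistribution],
            config: PSAConfig | None = None) -> PSAResult:
    """Monte Carlo propagation of the registry through a model closure.

    The closure maps a parameter set to a dict of scalar outputs.  It is
    called once with the full draw frame if it can handle frames
    (vectorised models), otherwise once per draw; failing draws are
    recorded, excluded from summaries and counted.
    """
    config = config or PSAConfig()
    params = draw_parameters(registry, config.seed, config.n_draws)
    n_failed = 0
    try:
        outputs = model_closure(params)
        out_df = pd.DataFrame(outputs)
        if len(out_df) != len(params):
            raise TypeError("closure did not vectorise over draws")
    except (TypeError, ValueError, KeyError):
        records = []
        for _, row in params.iterrows():
            try:
                records.append(model_closure(row.to_dict()))
            except Exception:
                records.append(None)
                n_failed += 1
        out_df = pd.DataFrame([r for r in records if r is not None])
        if n_failed:
            params = params.loc[[i for i, r in enumerate(records)
                                 if r is not None]].reset_index(drop=True)
    outputs = list(out_df.columns)
    summary_rows = []
    for name in outputs:
        x = out_df[name].to_numpy(dtype=float)
        lo, hi = interval_bounds(x, config.interval)
        summary_rows.append({"output": name, "mean": float(np.mean(x)),
                             "lo": lo, "hi": hi})
    draws = pd.concat([params.reset_index(drop=True),
                       out_df.reset_index(drop=True)], axis=1)
    return PSAResult(draws=draws, outputs=outputs,
                     summary=pd.DataFrame(summary_rows).set_index("output"),
                     n_failed=n_failed,
                     truncated=params.attrs.get("truncated", {}))


def tornado(model_closure, registry: list[ParamDistribution],
            output: str | None = None) -> pd.DataFrame:
    """One-way sensitivity analysis at the 2.5th/97.5th percentiles.

    Each parameter in turn is set to its tail percentiles with all others
    at their means; bars are ranked by the absolute output range they
    induce.  The closure maps a parameter dict to a scalar or a dict of
    outputs (``output`` selects one).
    """
    if not registry:
        raise ValueError("tornado needs at least one parameter")

    def evaluate(params: dict) -> float:
        res = model_closure(params)
        if isinstance(res, dict):
            if output is None:
                raise ValueError("closure returns a dict; pass output=")
            return float(res[output])
        return float(res)

    means = {p.name: p.mean for p in registry}
    base = evaluate(means)
    rows = []
    for p in registry:
        lo_params = dict(means)
        hi_params = dict(means)
        lo_params[p.name] = p.percentile(0.025)
        hi_params[p.name] = p.percentile(0.975)
        at_lo = evaluate(lo_params)
        at_hi = evaluate(hi_params)
        rows.append({
            "parameter": p.name,
            "value_at_p2_5": at_lo,
            "value_at_p97_5": at_hi,
            "low": min(at_lo, at_hi),
            "high": max(at_lo, at_hi),
            "range": abs(at_hi - at_lo),
            "baseline": base,
        })
    df = pd.DataFrame(rows).sort_values("range", ascending=False)
    return df.reset_index(drop=True)


def run_scenarios(model, scenarios=None) -> pd.DataFrame:
    """Scenario runner: delegates to the model's scenario machinery."""
    return model.run_scenarios(scenarios)
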