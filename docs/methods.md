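# Methods

## Model structure

The population is a closed cohort of adults aged 35+ in the 2011 base
year, partitioned into 52 strata (sex × thirteen 5-year age bands,
35–39 … 95+, × Māori/non-Māori). Each stratum advances in annual cycles
through six compartments: healthy, CHD year 1, CHD later, stroke year 1,
stroke later, dead. The year-1 compartments are *cost tunnels*: they exist
only so that the first year of disease carries its higher treatment cost;
QALY arithmetic treats them identically to the later-year states. There
are no CHD↔stroke transitions and no recurrent-event states — the first
event fixes the disease path — and the cohort is closed (no births,
migration or new 35-year-olds).

Within one cycle, transition probabilities are applied sequentially so
occupancy is conserved exactly:

1. the healthy face CHD and stroke incidence (jointly renormalised in the
   rare case their sum exceeds 1);
2. healthy non-incident people face background (non-CVD) mortality;
3. prevalent cases face case fatality and background mortality as
   independent risks, `1 − (1 − cf)(1 − m)`.

Newly incident people do not face case fatality in their incidence year;
they enter the year-1 state and face it the following cycle. Deaths via
case fatality are attributed to CVD; background deaths of disease
occupants are not.

Cohorts start at their band midpoint (37.5, 42.5, …, 97.5) and are
simulated until the cohort's age reaches 100, at which point survivors are
censored (no further QALYs or costs). QALYs and costs accrue on
start-of-cycle occupancy with no half-cycle correction — the procedure
being reproduced uses plain annual cycles.

As a cohort ages, its epidemiological rates, costs and background
morbidity are looked up at its *attained* age band (a 35–39 cohort uses
40–44 rates five years in), as are the blood-pressure coefficient and
hazard ratio. Anything else would discard the age gradients that dominate
CVD epidemiology.

## Risk pathway

A population-mean sodium reduction (mmol/day) is rescaled to each sex by
its share of baseline intake (4013/3544 for men, 3115/3544 for women;
population mean 3544 mg/day, 22.99 mg/mmol). The sBP change is
`β(age) · ΔNa / 100` with β = 5.5, 6.6, 9.2, 10.3 mm Hg per 100 mmol/day
for ages 30–39, 40–49, 50–59, 60–69; the 60–69 value is held for 70+
(conservative; a linear extrapolation is available as a config option). An
alternative flat coefficient table (≈5.8 mm Hg/100 mmol at all ages, after
the longer-trial meta-analysis) is available for scenario analysis;
swapping tables changes magnitudes, never signs.

Incidence multipliers are `HR20^(ΔsBP/20)` — multiplicative in the sBP
change, exactly HR20 at 20 mm Hg. Published tables give only the age
*ranges* of HR20 (CHD 0.49–0.67, stroke 0.38–0.67, SD 10 % of the point
estimate); the defaults here assign the strongest ratio up to age 44 and
the weakest at 85+, log-linearly interpolated between, and are fully
overridable. Multipliers act on incidence only; case fatality is governed
by its own secular trend.

## Secular trends, economics

Incidence and case fatality decline 2.0 %/year, background mortality
1.75 %/year (non-Māori) and 2.25 %/year (Māori), all from 2011 to
`trend_end_year` and constant thereafter. The default trend end is 2026
(the primary text of the source procedure; one footnote says 2031, so the
year is a config field). Costs are 2011 NZ$; the discount rate is 3 %/year
(0 % and 6 % as scenarios); the cost-effectiveness threshold is the
nominal GDP per capita of NZ$45,000. Future growth in unit health costs is
not modelled.

Health-system costs accrue to every living person (the "healthy" annual
cost, non-CVD category) plus disease-state excess costs (CVD category,
first-year vs subsequent). Costs of the last six months of life are taken
as embedded in the state costs; there is no separate dying-cost state.

## Interventions

The eight policies are shipped as a JSON registry
(`saltshift/data/interventions.json`). Effects are population-mean
mmol/day reductions at full effect; schedules are:

| name | effect (mmol/d) | schedule | direct cost (NZ$) |
|---|---|---|---|
| counselling | 0.0152 | immediate | 575,000/yr, recurring |
| endorsement_label | 1.7 (SD 20 %) | immediate | 621,000/yr, recurring |
| mandatory_3g | 12.9 (SD 10 %) | immediate | 3.68 M one-off |
| mandatory_all | 22.8 (SD 10 %) | immediate | 3.68 M one-off |
| uk_package | 22.7 (SD 10 %) | 7 equal annual steps | 12.1 M one-off |
| uk_media | 0.30 × 22.7 (SD 30 %) | 7 equal annual steps | 10.4 M one-off |
| salt_tax | to 2300 mg/d (SD 10 %) | solved, 10 years | 3.68 M one-off |
| sinking_lid | to 2300 mg/d (SD 10 %) | 9.0 mmol/d/yr, 6 years | 3.68 M one-off |

Notes on the judgement calls:

- **Counselling** is quoted per counselled hour (7.6 mmol/day, SD 0.8)
  with 4600 h/year (SD 920) delivered nationally; the population-mean
  effect is the product diluted over 2.3 M adults (0.0152 mmol/day) — the
  only reading consistent with its tiny health gain. Its SD combines both
  components first-order (≈0.0034).
- **Salt tax**: the stated facts are the −0.1 price elasticity of demand,
  a 20 % cap on any one year's demand reduction, the 2300 mg/day target
  and a 10-year horizon. The year-by-year rule adopted is a constant
  proportional demand reduction `p = 1 − (target/baseline)^(1/10)`
  (≈4.2 %/year), which reproduces both the printed 6.5 mmol/day first-year
  reduction and the 10-year horizon; absolute yearly reductions then
  decrease geometrically. The implied annual price increase `p/|ε|` is
  reported on the schedule. Whether the 20 % cap binds demand or price is
  ambiguous in the source; the solver caps demand, and the elasticity
  (hence price path) is a scenario variable.
- **Sinking lid**: `(3544 − 2300)/22.99/6 ≈ 9.0` mmol/day per year for six
  years.
- Effects persist for the cohort's lifetime unless a sunset year is set
  (scenario: 20-year sunset for the mandatory laws, after which intake
  reverts). Tax/lid effect-size uncertainty is not quoted in the source
  tables; the 10 % SD of the other mandatory interventions is applied to
  the whole schedule, consistent with the ≈±20 % uncertainty intervals
  shown for their outputs.

## Generalised CEA

Every intervention (including the two current-practice programmes) is
compared against a *do-nothing* world. Observed incidence is divided by
the product of the current-practice incidence multipliers (counselling +
label at full effect, composed multiplicatively since both act through the
same BP mechanism), evaluated at each stratum's band-midpoint age;
re-applying the multipliers reproduces the observed rates to 1e-9. ICERs
are net discounted cost over incremental QALYs; cost-saving interventions
with positive gains are labelled Dominant. Because PSA means of ratios and
ratios of means differ, both conventions are reported. The per-adult cost
decomposition (direct + ΔCVD + Δnon-CVD = net) divides discounted total
increments by the 2.3 M adults.

Ethnic-inequality outputs take model CVD deaths in a report year (default
2021, ten years in) divided by persons alive that year, per 100,000, with
Māori:non-Māori differences and ratios within sex × baseline age band, and
per-individual discounted QALY gains accumulated over the ten years.
Cohorts censored at age 100 before the report year yield undefined rates.
The *equity* scenario gives Māori strata the non-Māori background
mortality and pYLD (disease rates untouched, idempotent), so the envelope
for potential health gain no longer penalises Māori background health.

## Uncertainty analysis

PSA parameters per draw: intervention effect size (normal, truncated at
zero — truncations are logged and counted, not resampled, keeping n
fixed), CHD and stroke hazard-ratio factors (normal, mean 1, SD 10 %),
a health-system cost factor (gamma, mean 1, SD 10 %), and the intervention
direct cost (gamma or normal per the registry; gamma is moment-matched,
shape = (mean/sd)², scale = sd²/mean). One shared random stream per draw
index supplies all interventions (common random numbers); the intervention
cost draw shares a uniform through each spec's inverse CDF. Disability
weight uncertainty is quantified only in an unavailable technical report
and is not sampled. The comparator's QALYs are draw-invariant (no
intervention, so no HR exposure) and its costs are linear in the cost
factor, so comparator draws are derived exactly from the deterministic
run. Uncertainty intervals are central 95 % percentile intervals (order
statistics); default 2000 draws.

The tornado analysis perturbs each parameter alone to its 2.5th/97.5th
percentile with the others at their means and ranks by absolute output
range. On the default synthetic baseline the effect-size bar ranks first
and the stroke-HR bar exceeds the CHD-HR bar, matching the qualitative
finding that gains are mediated more by stroke.

## Synthetic baseline generator

The real inputs come from a non-public linked administrative dataset, so
the generator emulates its aggregate structure; all anchors are config
(`GeneratorConfig`) with these defaults:

- **CVD mortality age curves**: non-Māori implied CVD mortality
  (Σ incidence × case fatality over both diseases) is log-linear in age
  through published 2021 rates (men 35 and 514 per 100,000 at 50–54 and
  75–79; women 21 and 453), back-projected to 2011 by the 2 %/year trend.
- **Ethnic gradient**: the Māori:non-Māori implied-mortality ratio is
  log-linear from 4.5 at 50–54 to 2.4 at 75–79 (clipped to [1, 8]), split
  as a square root equally between incidence and case fatality so the
  implied-mortality ratio is exact by construction; background mortality
  follows the same declining ratio, which also keeps Māori steady-state
  prevalence ≥ non-Māori.
- **Disease mix**: CVD mortality splits 50:50 CHD:stroke with stroke case
  fatality 1.3× CHD (CHD case fatality 0.04 at 50–54, log-slope
  0.025/year of age). In this 35+ cohort stroke is thus a comparable
  contributor to CVD death and — with its stronger hazard ratio, higher
  disability weight and higher case fatality — the dominant mediator of
  BP-related health gains, the structure the analysis reports for the
  real data.
- **Background mortality**: Gompertz-like, 0.0025/year at 50–54 for
  non-Māori men (log-slope 0.095/year of age), women ×0.65.
- **Morbidity**: pYLD log-linear in age (slope 0.018/year), Māori ×1.3,
  anchored so a Māori woman aged 60–64 has pYLD 0.288 (QALY ceiling
  0.712).
- **Prevalence**: 0.9 × the steady-state value
  `inc/(inc + cf + background mortality)`, reflecting that empirical
  prevalence from finite look-back administrative data runs low. The
  coherence checker (`check_coherence`) compares stored prevalence to the
  steady state and flags relative deviations beyond a tolerance (default
  ±50 %); it replaces the external coherence software used on the real
  data with this single steady-state identity.
- **Costs**: anchored to the published 60–64 female set (healthy 2,381;
  CHD 16,258/5,395; stroke 20,553/5,991 NZ$) with mild log-age gradients
  (healthy 0.02/yr, disease 0.005/yr) and no sex difference (none is
  published). Scale-ups for known data gaps: disease costs ×1.2 at all
  ages; healthy costs ×1.1/1.2/1.3 at 65–74/75–84/85+. A 10 % CVD-
  attributable share is removed from the healthy-state cost to avoid
  double counting (the source states the removal but not the fraction).
  The stored anchor-stratum values reproduce the published figures
  exactly.
- **Population**: 2.3 M adults; declining band weights, Māori share
  falling from 14 % at 35–39 (log-slope −0.035/year), a mild female skew
  at older ages; integerised by largest-remainder so counts sum exactly.
- **Stochasticity**: seeded log-scale jitter on the incidence and
  case-fatality age curves with per-band steps bounded below each curve's
  deterministic log-gradient, so age-monotonicity and the Māori ≥
  non-Māori ordering hold for every seed, and identical seeds give
  bit-identical bundles.

What the generator does *not* emulate: within-stratum heterogeneity,
correlation between costs and severity, cohort effects in the trends, sex
differences in unit costs, and real prevalence-incidence imbalances beyond
the uniform 0.9 shortfall. Tests passing on this baseline therefore
validate the pipeline's mechanics and comparative structure, not the
published population totals — those depend on the restricted data.

## Numerical choices and degenerate inputs

Occupancy is checked against drift (>1e-6 raises) every cycle. Joint
incidence above 1 is renormalised proportionally; trended case fatality
and mortality are capped at 1. Back-calculated incidence above 1 is
clamped with a warning. Zero-QALY disease states floor at 0 when
pYLD + disability weight exceeds 1. Schedules reject negative or
decreasing cumulative reductions and cap sex-scaled reductions at the
sex-specific baseline intake. An infeasible tax horizon (required annual
demand reduction above the cap) raises rather than silently capping.
Percentile intervals round the tail mass to 12 decimals so a 95 % interval
uses exactly the 2.5 %/97.5 % order statistics.

## Problem sizes

The default analysis simulates 52 strata × 63 annual cycles; a
deterministic fit of all eight interventions takes ≈0.2 s, a 2000-draw PSA
≈6 s and the full scenario grid a few seconds, so the shipped test suite
and the acceptance script use the full default sizes rather than reduced
ones.

## Known limitations

Model-structure uncertainty is not captured; no potassium, BMI or other
risk factors; no BP trend over time; no recurrent events or CHD↔stroke
transitions; societal-perspective costs and tax-revenue projections are
out of scope (a revenue computation from user-supplied price and volume
data would be straightforward but has no anchored default). The
counselling direct-cost stream (NZ$575k/year for the cohort's lifetime,
discounted) is roughly twice the per-adult direct cost the source tables
imply, whose exact costing detail is unpublished; this raises the
counselling ICER here relative to the published one without affecting any
comparative conclusion.
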