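# saltshift

Markov cohort simulation and cost-utility analysis of dietary
sodium-reduction policies, with New Zealand-style inputs.

High dietary sodium raises systolic blood pressure (sBP) and with it the
incidence of coronary heart disease (CHD) and stroke. `saltshift` models
what eight policies that lower population sodium intake — dietitian
counselling, an endorsement food label, mandatory 25 % sodium reductions in
three food groups or in all processed foods, the UK media/reformulation
package, its media component alone, a salt excise tax, and a "sinking lid"
on the salt supply — would do to lifetime health gains (QALYs), health-system
costs and ethnic inequality in a closed adult cohort. It is written for
health-economic modellers and epidemiologists who want a tested, scriptable
re-implementation of this class of analysis.

## Model

A closed cohort aged 35+ (2.3 million adults in 52 strata of sex × 5-year
age band × ethnicity) is simulated in annual cycles from 2011 until death or
age 100 through the states

```
healthy → {CHD, stroke} → dead        (dead absorbing; no CHD↔stroke moves)
```

with first-year/subsequent-year cost tunnels inside each disease state.
The causal pathway for an intervention delivering a sodium reduction
Δ<sub>Na</sub> (mmol/day, sex-scaled by intake ratios 4013/3544 and
3115/3544) is

- Δ<sub>sBP</sub> = β(age) · Δ<sub>Na</sub>/100, with β = 5.5/6.6/9.2/10.3
  mm Hg per 100 mmol/day for ages 30–39/40–49/50–59/60+;
- incidence multiplier = HR<sub>20</sub>(age)<sup>Δ<sub>sBP</sub>/20</sup>,
  with HR<sub>20</sub> ∈ [0.49, 0.67] for CHD and [0.38, 0.67] for stroke,
  attenuating with age.

Incidence and case fatality decline 2 %/year (background mortality
1.75 %/2.25 % for non-Māori/Māori) until 2026, then hold. QALYs weight each
life year by 1 − pYLD − disability weight (CHD 0.081, stroke 0.226); costs
and QALYs are discounted at 3 %/year to 2011. Every intervention is
compared against a *do-nothing* world obtained by back-calculating the
effects of the two current-practice programmes out of the observed rates
(generalised cost-effectiveness analysis). Parameter uncertainty is
propagated by 2000-draw Monte Carlo (PSA) with common random numbers, and
one-way tornado analyses rank parameters by induced output range.

The original analysis drew its baseline rates and per-event costs from a
non-public linked administrative dataset. `saltshift` ships a synthetic
baseline generator that reproduces that data's aggregate structure
(age-increasing incidence and case fatality, Māori:non-Māori CVD mortality
ratios of ≈4.5 at 50–54 and ≈2.4 at 75–79, first-year disease costs several
times subsequent-year costs, a plausible NZ age pyramid), so the whole
pipeline runs and is testable without restricted data. Results on the
synthetic baseline are structurally, not numerically, comparable with the
published population totals.

## Worked example

```python
import saltshift as ss

model = ss.SaltReductionModel.from_synthetic(seed=1)
result = model.fit()          # add psa=ss.PSAConfig(2000, seed=0) for UIs
print(result.summary())
```

prints

```
Sodium-reduction cost-utility analysis (NZ$ 2011, 3% discount)
Adults modelled: 2,300,000; comparator: do nothing (current practice removed)

Intervention            QALYs gained  Net cost (NZ$m)            ICER
---------------------------------------------------------------------
counselling                      120             16.0    133,860/QALY
endorsement_label             13,363            -56.0        Dominant
mandatory_3g                 100,591           -556.8        Dominant
mandatory_all                176,522           -985.0        Dominant
uk_package                   146,387           -838.1        Dominant
uk_media                      44,342           -245.1        Dominant
salt_tax                     320,918         -1,909.6        Dominant
sinking_lid                  352,795         -2,065.7        Dominant
```

QALYs gained and net cost are lifetime, discounted increments over the
do-nothing comparator. "Dominant" means the intervention both gains QALYs
and saves money, so no cost-per-QALY ratio is reported; only counselling
has a positive net cost, because dietitian time recurs every year while its
population-diluted sodium effect (0.0152 mmol/day) is tiny. The supply-side
policies (sinking lid, salt tax) give the largest gains because they drive
intake all the way to the 2300 mg/day target; mandatory reformulation beats
the voluntary programmes. `result.table4()`, `.table5()`, `.table6()`,
`.ce_plane()` and `.tornado()` expose the population totals, per-adult cost
decomposition, ethnic-inequality measures, cost-effectiveness-plane
coordinates and one-way sensitivity rankings as DataFrames, and
`model.run_scenarios()` replays the analysis under named scenario settings
(discount 0 %/6 %, 20-year sunset clause, +50 % intervention costs,
alternative BP meta-analysis, reduced case fatality, media-share and
price-elasticity variants, enforcement costs, equity substitution).

The same pipeline is scriptable from a shell:

```bash
saltshift synth --seed 1 --out baseline.csv
saltshift run --all --psa-n 2000 --outdir out/   # table4/5/6, CE plane, log
saltshift tornado --intervention mandatory_all
```

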