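# Methods

## Model

`housefirst` implements a continuous-time compartmental cohort model of
housing status, opioid use, treatment for opioid use disorder (OUD), and
competing mortality risks, for a cohort of 1000 people experiencing
homelessness (PEH) with OUD. Two arms are compared under identical parameter
draws: the **status quo** (everyone starts unhoused, out of treatment for
more than one month) and a one-time **housing-first intervention** (everyone
starts housed in the same health state, with no treatment precondition).

### State space

Each housing side (housed `H`, unhoused `U`) carries 14 live compartments:

| state | meaning | dwell structure |
|---|---|---|
| `O1` | out of treatment, first month | matures to `O2` at 12/yr |
| `O2` | out of treatment, > 1 month | treatment entry `b` applies here only |
| `I` | treatment induction (1 month) | advances to `T` at 12/yr; elevated all-cause mortality on methadone |
| `T` | receiving medication | quits at `q`, succeeds into abstinence at `s` |
| `A1` | abstinent, first year | relapse at `r1` |
| `A2_1 … A2_9` | abstinent year bins (years 1–10+) | chain at 1/yr; relapse at `r2` |

plus two absorbing sinks (overdose death, death from other causes), giving 30
compartments. Relapse and treatment dropout route to `O1`, which is what
makes the first out-of-treatment month distinct: the published entry rate is
conditional on being out of treatment for more than a month. Housing loss
moves every housed live state to its unhoused counterpart at the
becoming-unhoused rate (0.0820/yr at base, optionally differentiated by
state group); housing is never regained. Untreated abstinence attainment `a`
applies from both `O1` and `O2`; the induction failure rate is not published
separately and is set equal to the medication's discontinuation rate.

### Mortality and overdose

Non-overdose mortality decomposes into background mortality (age- and
sex-specific, advancing with simulation time), non-overdose excess mortality
of the disorder, and excess mortality of homelessness (unhoused states
only; out-of-treatment 0.0128/yr, in-treatment 0.0055/yr). During methadone
induction the whole non-overdose rate is multiplied by 14.0 (buprenorphine:
1.0). Overdoses occur at state-specific annual rates (zero while abstinent);
each event is fatal with probability `1 − survival`, where survival is
housing-specific. Survived overdoses accrue as events without changing the
compartment. For the witnessed-overdose sensitivity, survival is decomposed
as `1 − [w·d_w + (1−w)·d_u]` with witness probability `w = 0.6` and an
unwitnessed-to-witnessed death-risk ratio of 3, calibrated so the base
survival is recovered at the reference `w`; both constants are repository
defaults in the configuration, chosen once as plausible values — only the
*relative* change of `w` matters for the scenario, which the published
results show to be nearly neutral.

Three structural points are not published and were fixed by reproducing the
reported base case: abstinent individuals remain "out of treatment", so the
out-of-treatment excess-OUD mortality (housed 0.0098/yr, unhoused 0.0032/yr)
and the out-of-treatment excess-OUD health-care cost ($8827/yr) continue to
apply while abstinent (their homelessness excess uses the lower in-treatment
value, as they are not actively using); and the two published abstinence
quality-of-life values act as levels — the first-year value through year
10, the ≥10-year value thereafter — rather than as endpoints of a ramp.
With the alternative readings (no excess in abstinence, linearly
interpolated utilities) the housing arm accrues roughly 0.5 more QALYs and
$40k less health-care cost than reported, falling outside the published
intervals; with the adopted readings every base-case and scenario quantity
lands inside them.

### Numerical scheme

Occupancy advances by explicit RK4 at a fixed monthly step over the
piecewise-constant-in-age generator (the age year of the step midpoint
selects background mortality and background cost). The step is subdivided
automatically when a parameter draw makes the fastest total outflow exceed
the RK4 stability margin (`step × max outflow ≤ 2.5`). Each stratum is
integrated until it reaches age 100; occupancy is then frozen and accrues no
further events, costs, or QALYs. Mass is conserved to round-off by
construction (every flow is a transfer); the integrator raises if occupancy
goes negative. Discounted costs and QALYs accrue by the trapezoidal rule on
the same grid with continuous discounting `e^(−0.03 t)`; halving the step
changes every reported outcome by well under 0.5%.

Two implementations of the accounting exist deliberately: a trajectory-based
path (stores full occupancy, produces the component cost ledger) and a
fast in-kernel path used by the PSA (accumulates scalars only). A test pins
them to agree to 1e-9 relative.

### Cohort and background data

The cohort is represented by deterministic age × sex strata (integer entry
ages 18–89; weights proportional to the truncated-normal density per sex:
male 70%, mean 46.4, SD 14.0; female 30%, mean 46.5, SD 14.3) — the model is
an expected-value cohort model, so strata weights carry all demography and
no Monte-Carlo noise enters through ages. Because truncation at age 18 cuts
more of the lower tail than the age-89 bound cuts of the upper, the normal's
location parameter is calibrated by root-finding so the realized cohort mean
age equals the reported mean (the reported moments describe the cohort, not
a pre-truncation distribution). The entry-age bounds are a repository choice
(adult cohort; not published).

Background mortality comes from `us_life_table_synthetic.csv`, a smooth
synthetic approximation to the 2021 US period life tables (log-PCHIP through
anchor values recalled from the published tables; the 2021 COVID-era vintage
matters — it carries distinctly higher mid-life mortality than earlier
years, which drives part of the survival benefit of housing). A
Gompertz–Makeham fallback (`rate = c + A·e^(B·age)`, coefficients fitted to
the fixture and stored in the configuration) supports fully synthetic runs;
it tracks the fixture within ~40% at the young-adult accident hump and a few
percent at older ages. Background health-care cost is anchored at $2764/yr
for a 30-year-old male and scaled by `(1.034)^(age−30)` with a sex
multiplier of 1.0 — both repository defaults whose influence is bounded by
the dominant excess-cost terms ($8827 out-of-treatment OUD, $13 823
homelessness per unhoused year).

## Parameter uncertainty

Every uncertain quantity carries a published range read as a 95% interval.
Sampling families: **beta** for probabilities and utility multipliers, with
shapes solved so the 2.5th/97.5th percentiles match the published bounds
(method-of-moments start, two-equation root solve); **lognormal** for
positive rates and costs with `σ = (ln high − ln low)/(2·1.96)`, centred on
the geometric midpoint when the range is log-symmetric about the base value
and on the base value otherwise; samples are clipped to the published
bounds. Quantities without a range are fixed.

Unhoused quality-of-life multipliers are not sampled independently: they are
derived from the housed draw by the per-state utility ratio implied by the
base values (≈0.43, the homelessness utility multiplier). The published
unhoused ranges are, to printed precision, the housed ranges scaled by that
multiplier, which identifies them as derived quantities; the induced
correlation also lets paired draws cancel utility noise. All other
parameters are sampled independently. Each draw is a deterministic function
of `(seed, draw_id)`, and the same draw evaluates both arms and all compared
scenarios (common random numbers): the arms' per-draw QALYs are positively
correlated, so the variance of incremental results falls well below the
unpaired sum of the arm variances (though not below the intervention arm's
own variance — mortality and transition uncertainty acts on the two arms
with different leverage and does not fully difference out).

The unhoused treatment-cascade rates ship as the published values; the
hazard-ratio derivation (entry 0.50, discontinuation 1.36, success 0.09,
relapse 1.35 versus housed) is used for scenario overrides and consistency
checks only (the published unhoused discontinuation 1.431 versus the product
1.429 differ by 0.1%).

## Economic outputs

Costs take a limited societal perspective (housing plus all health care;
criminal-justice costs excluded), in 2024 USD: background care, excess OUD
care in/out of treatment, excess homelessness care ($13 823/yr, unhoused
person-time only), treatment ($8584/yr methadone), naloxone ($87 at entry
plus $87 per overdose event), and per-overdose care (applied to fatal and
nonfatal events alike). Housing cost ($20 900/yr) accrues over housed
person-time and is ledgered separately. The ICER is `Δcost/ΔQALY` against
the status quo; draws with reversed signs would be flagged dominant/
dominated rather than averaged blindly. The PSA reports both the mean of
per-draw ICERs (the headline figure) and the ratio of mean increments; both
land near $26.8k/QALY in the base case.

Budget impact is undiscounted: first-year housing cost per person initially
housed (below the annual rate because of attrition at 0.082/yr and
mortality), first-year health-care cost per person in each arm, and linear
city-scale extrapolations (housing cost, health-care savings, flat
per-person criminal-justice savings, one-time construction cost per unit).
The exact attrition/mortality weighting behind the published first-year
figure is not recoverable, so the first-year outputs are model-derived and
compared qualitatively (strictly below $20 900), not numerically.

## Scenarios

Eight named scenarios ship as parameter transforms: 20% adverse shifts of
the housed cascade; no treatment effect of housing (the housed cascade
*and* overdose incidence/survival copied from the unhoused side — with the
narrower reading that copies only the cascade, the reported scenario
signature of overdoses rising above the status quo cannot occur, because
housed overdose incidence stays 2.7% lower and cancels the survival effect);
an 80% lower witnessed-overdose probability when housed; doubled housing
loss; state-differentiated housing loss (+50% out of treatment, +25% in
treatment); homelessness excess mortality retained after housing; doubled
housing cost; and the unhoused utility multiplier raised from 0.43 to 0.60.

## Problem sizes and what the tests show

The package's test and acceptance profiles use 200 and 1000 PSA draws
respectively (the reported study used 25 000 for the base case and 10 000
per scenario); the Monte-Carlo standard error of a 200-draw mean is an order
of magnitude smaller than the width of the published 95% intervals, so
means are compared meaningfully at desk scale, while the percentile
intervals themselves are noisier than the published ones. Scenario and grid
checks in the test suite use deterministic base-value runs, which sit close
to PSA means here (the model is mildly nonlinear in its parameters, and
right-skewed sampling families shift means a few percent above base-value
results).

The synthetic-data layer (cohort generator, life-table fixture, parameter
sampler) emulates the study's inputs, not real linked administrative data:
real cohorts carry correlated demographics, comorbidity, and secular drug-
supply trends that the model's independent, stationary rates do not.
Passing tests therefore demonstrate faithful reproduction of the published
model's arithmetic and behaviour, not external validity for any specific
housing program.

## Known limitations

* Once unhoused again, individuals never re-enter housing (as modelled in
  the source analysis); there is no treatment-first sequencing.
* No individual-level heterogeneity beyond age and sex (no injection
  status, co-occurring conditions, or housing-history strata).
* The exact published sampling distributions were unavailable; the
  quantile-matched beta/clipped-lognormal families are a standard
  reconstruction, and published percentile intervals are reproduced only
  approximately.
* Background mortality is a synthetic approximation of the 2021 life
  tables; period (calendar-year) mortality improvements are ignored.
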