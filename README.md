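# housefirst

Cost-effectiveness simulation of a housing-first intervention for people
experiencing homelessness (PEH) with opioid use disorder (OUD).

Overdose is the leading cause of death among PEH, and unhoused people with
OUD enter and stay in treatment at far lower rates than housed people.
`housefirst` asks what providing permanent supportive housing to this
population — with no sobriety or treatment precondition — does to overdoses,
deaths, lifetime costs, and quality-adjusted life-years (QALYs), and what it
costs per QALY gained. The intended users are health-economics and policy
modellers who want a transparent, tested re-implementation of this analysis
that they can re-parameterize.

## Model

A continuous-time compartmental cohort model tracks 1000 PEH with OUD
(70% male; mean age ≈ 46) through health states
`{out of treatment (first month / >1 month), treatment induction, receiving
medication, abstinent (by duration, 1-year bins up to ≥10 y)}` on a housed
and an unhoused side, plus two absorbing death states (overdose, other
causes). Writing `x(t)` for the occupancy vector of one age×sex stratum,

```
dx/dt = Q(a(t))ᵀ x ,
```

with the generator `Q` assembled from annual rates: treatment entry `b`,
discontinuation `q`, success `s`, untreated abstinence `a`, relapse `r₁/r₂`,
housing loss (0.082/yr, housed → unhoused, never reversed), overdose
incidence `λ` with per-event fatality `1 − p_surv`, and mortality split into
age/sex background `μ(a)`, excess-OUD, and excess-homelessness components.
Discounted costs (limited societal perspective: housing plus all health
care, 2024 USD) and QALYs accrue as `∫ e^(−0.03 t) c(x(t)) dt`. Two arms are
compared under common random numbers — status quo (start unhoused) versus a
one-time housing intervention (start housed) — yielding the incremental
cost-effectiveness ratio ICER = Δcost/ΔQALY. A probabilistic sensitivity
analysis (PSA) redraws every uncertain parameter from its published range
(quantile-matched beta / lognormal families). See `docs/methods.md` for
assumptions, parameters, and numerical choices.

## Worked example

```python
import housefirst as hf

params = hf.load_parameter_set()           # packaged base-case configuration
cohort = hf.build_cohort()                 # 1000 persons, 70% male, ages 18-89

outcomes, icer = hf.run_base_case(params, cohort)
sq, hi = outcomes["status_quo"], outcomes["housing"]
print(f"status quo : {sq.events.deaths_total:5.0f} deaths/1000 over 5 y, "
      f"{sq.qalys:4.2f} QALYs, ${sq.costs.total/1e3:5.0f}k total cost")
print(f"housing    : {hi.events.deaths_total:5.0f} deaths/1000 over 5 y, "
      f"{hi.qalys:4.2f} QALYs, ${hi.costs.total/1e3:5.0f}k total cost "
      f"(${hi.costs.housing/1e3:.0f}k housing)")
print(f"incremental: ${icer.delta_cost/1e3:4.0f}k for {icer.delta_qaly:4.2f} QALYs "
      f"-> ${icer.icer:,.0f} per QALY gained")
```

prints

```
status quo :   181 deaths/1000 over 5 y, 3.87 QALYs, $  404k total cost
housing    :   143 deaths/1000 over 5 y, 7.58 QALYs, $  502k total cost ($147k housing)
incremental: $  98k for 3.71 QALYs -> $26,553 per QALY gained
```

i.e. at base parameter values the intervention prevents ~38 deaths per 1000
people over five years and roughly doubles discounted lifetime QALYs
(housed person-time has both lower mortality and a much higher utility
weight), at about $26.6k per QALY gained — far below conventional US
willingness-to-pay thresholds. `hf.run_psa(params, cohort, n_draws, seed)`
adds parameter uncertainty and percentile intervals;
`hf.SCENARIOS` holds the named sensitivity analyses (e.g.
`"no_treatment_effect"`, `"doubled_housing_cost"`).

The same is available from the shell:

```bash
housefirst simulate --arm housing          # deterministic single run (JSON)
housefirst psa --draws 1000 --seed 1       # PSA with summary table (CSV)
housefirst grid --draws 200                # housing-cost x unhoused-cost grid
housefirst budget                          # budget-impact report (JSON)
```

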