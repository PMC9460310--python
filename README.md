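# saltsim

A discrete-time Markov cohort macro-simulation of population dietary
salt reduction and cardiovascular disease burden in Japan, for health
economists and nutrition-policy modellers.

## The model

A closed cohort of Japanese adults aged 40–79 in 2019 (n = 66,955,000),
stratified by sex and 10-year age group, moves among six mutually exclusive
health states in annual cycles over a 10-year horizon:

```
healthy ──► chronic IHD ──► death from IHD
        ──► chronic stroke ──► death from stroke
        ──► death from other causes (from any live state)
```

At baseline the cohort is split by disease prevalence. Each cycle, incident
events arise at probability `1 − exp(−λ·m)` (λ the annual incidence rate,
`m` the scenario's incidence multiplier); a fraction `f` of events are
first-ever (drawn from the healthy state), the rest recurrent (drawn from
the same disease's chronic state). Each event is fatal with the 28-day case
fatality `c` (→ disease death within the cycle) or non-fatal (→ the chronic
state next cycle). Other-cause mortality — the all-cause rate minus both
disease rates — applies equally to the non-event remainder of every live
state. Death states are absorbing; there is no return to health and no
cross-disease transition.

Salt-reduction scenarios lower each stratum's mean intake at a constant
annual rate `r = 1 − (target/baseline)^(1/10)`, calibrated so the
*age-adjusted* (2010 standard population) two-sex mean reaches the target
(8, 6, or 5 g/day) in year 10. Intake changes act through systolic blood
pressure: `ΔSBP = β·Δsalt` (β the stratum's regression coefficient), and
incidence scales log-linearly, `m = RR^(ΔSBP/10 mmHg)`. Lowered SBP affects
incidence only, never survival after onset.

Costs: one inpatient episode per incident event (fatal or not) and an
annual outpatient + drug cost per person-year in a chronic state, in JPY,
discounted at 2%/year with the first cycle (2019) undiscounted, and
converted to USD at 109.01 JPY/USD for reporting. Scenario impact is the
base-case-minus-scenario difference in cumulative events, deaths, and
discounted expenditures.

Because the stratified input tables behind the published national
projections are not redistributable here, the package ships a synthetic
parameter generator that emulates their structure and plausible magnitudes;
every pipeline stage is exercised against those fixtures and against an
independent closed-form expenditure ledger.

## Worked example

```sh
python examples/project_scenarios.py
```

prints (synthetic parameters, seed 42):

```
base case (salt held at 2019 levels, 10 years):
  incident cases: 2,257,633 IHD, 2,792,638 stroke
  deaths:         699,154 IHD, 344,819 stroke
  discounted expenditures: USD 172.2 billion

target 8 g/day (annual reduction rate 2.5%):
  averted events: 165,461 (3.3%)
  averted deaths: 33,517 (3.2%)
  saved:          USD 3.65 billion (2.1%)
```

Reading: holding salt at 2019 levels, the cohort accrues ~5.1 million
IHD/stroke events costing USD 172 billion (discounted) over the decade;
reaching the 8 g/day national goal — a 2.5%/year decline in mean intake —
would avert ~3% of those events and ~2% of the spending. Deeper targets
(6, 5 g/day) avert strictly more. The other examples cover fixture
generation, first-cycle expenditure validation, and the one-way
sensitivity tornado; a thin CLI (`saltsim synth|run|validate|dsa`) wraps
the same calls for shell use.

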