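# Methods

## Model structure

The simulation is a deterministic (expected-value) Markov cohort model: a
closed population, fixed at its 2019 membership, is propagated through six
health states — healthy, chronic IHD, chronic stroke, and three absorbing
death states (IHD, stroke, other causes) — in annual cycles. The model is
stratified by sex and 10-year age group (40–49 … 70–79; eight strata), and
each stratum evolves independently with its own parameters. Occupancies are
real-valued person counts; nothing is rounded during propagation.

Two simplifying assumptions are structural. First, other-cause mortality is
identical in the healthy and chronic states: it is computed per stratum as
the all-cause rate minus the two disease-specific rates, floored at zero
(a flag and a warning are raised if flooring occurs; it never does on the
synthetic defaults, whose all-cause rate is assembled as other-cause plus
the disease rates). Second, the effect of salt reduction is immediate, with
no phase-in lag.

### Within-cycle ordering and the acute phase

Transition probabilities are assembled per stratum and cycle in a fixed
order so a hand ledger can reproduce them flow by flow:

1. Incident events are drawn first from each live state. The per-stratum
   event total is `E = (1 − exp(−λ·m)) · alive`, where `λ` is the annual
   incidence rate, `m` the scenario's incidence multiplier, and `alive` the
   stratum's live occupancy at cycle start. A proportion `f` (first-ever
   share) of `E` is sourced from the healthy state and `1 − f` from the
   same disease's chronic state; per-source probabilities are events over
   source occupancy, and a source probability above 1 is a hard error
   naming the stratum and disease.
2. Each event resolves within the cycle: fatal with probability equal to
   the 28-day case fatality (to the disease death state), otherwise to the
   disease's chronic state at the next cycle start. The acute phase is not
   a persistent state.
3. Other-cause mortality applies to the non-event remainder of every live
   state; the residual stays put.

Disease deaths therefore arise *only* as incident events × case fatality;
the disease-specific mortality rates enter the model solely through the
other-cause subtraction. No chronic-state excess disease mortality is
modelled — incidence, acute case fatality, and residual mortality fully
determine the transition probabilities — but the mortality tables stay in
the schema, making that alternative reading a contained change. There are no cross-disease transitions (a chronic IHD patient
cannot have a stroke) and no re-entry to health. Strata do not age across
10-year bands during the 10-year horizon.

Rates convert to one-cycle probabilities as `p = 1 − exp(−rate)`, the
standard exponential (competing-risk-consistent) conversion.

The engine propagates occupancies with a vector–matrix product against a
per-stratum, per-cycle 6×6 row-stochastic matrix (checked to 1e-12). The
test suite re-implements the propagation as an explicit per-flow ledger
with no matrix algebra and requires agreement to 1e-12, and checks
conservation (live occupancy + cumulative deaths = baseline population) at
1e-9 relative every cycle — the engine also asserts it at run time.

## Scenarios and the effect pathway

The base case holds every stratum's mean salt intake at its 2019 value.
Target scenarios reduce intake at one uniform multiplicative rate across
all strata, `r = 1 − (target/baseline)^(1/years)`, where `baseline` is the
two-sex age-adjusted mean (sexes pooled within age group by population
share, age groups weighted by the 2010 standard population). Stratum means
in year t are `baseline_s · (1 − r)^t`, so the age-adjusted mean hits the
target exactly in the final year (asserted at 1e-9 relative). The printed
target labels "<6" and "<5" g/day are implemented as equality to 6.0 and
5.0, since a strict inequality has no operational meaning for a calibrated
endpoint. Published annual reduction rates are never hard-coded; they are
always derived from the data, so they shift with the baseline.

SBP responds linearly to salt (`ΔSBP = β·Δsalt`, per stratum, Δ measured
against the 2019 baseline each cycle), and incidence scales log-linearly
(`m = RR^(ΔSBP/increment)`, increment 10 mmHg by default and stored as
data rather than hard-coded). The same multiplier applies to first-ever
and recurrent events: the incidence rate governs both, and nothing in the
pathway distinguishes a first event from a recurrence. Multipliers never touch case fatality or any mortality: the
assumption that salt reduction does not alter survival after onset is
enforced by construction, since the engine receives multipliers only
through the incidence term.

## Costs and discounting

Chronic-state occupancy at cycle start is billed the annual outpatient +
drug cost; every incident event, fatal or not, is billed one inpatient
episode (patients exit via inpatient care before the death/survival
split). No half-cycle correction is applied — the convention is chosen so
the model's first cycle reproduces baseline-year spending exactly. Costs
are discounted by `(1 + rate)^−(t−1)` at 2%/year by default: the first
cycle represents the 2019 baseline year and is undiscounted, which is what
lets the validation check hold as an equality under nonzero discounting.
All accounting is in JPY; USD conversion (109.01 JPY/USD, the 2019 annual
average) happens only at reporting.

## Validation

The first annual cycle of the base case must reproduce the reference 2019
expenditure table — outpatient and inpatient, per disease and sex — cell
by cell at 1e-9 relative. The reference is computed by an independent
closed-form ledger (`N·prevalence·outpatient_cost` and
`(1 − exp(−λ))·N·inpatient_cost` per stratum) that never calls the Markov
engine, so the check compares two independent arithmetic routes rather
than the engine against itself. A 1% perturbation of any single cell is
required to be detected and named.

## Synthetic parameters

The generator emulates the structure of the real input tables with
canonical central values chosen once for plausibility: population counts
are the published 2019 per-stratum estimates (total 66,955,000); salt
intake 8.9–11.3 g/day, higher in men and rising with age (age-adjusted
mean ≈ 10.2 g/day, near the ~9.9 g/day the national survey implies);
SBP 118–142 mmHg rising with age; prevalence, incidence, and mortality
rising at least three-fold from the youngest to the oldest stratum;
first-ever shares 0.75–0.92; 28-day case fatality 0.20–0.36 for IHD and
0.06–0.17 for stroke; annual outpatient + drug costs 150–270 thousand JPY
and inpatient episodes 1.4–2.9 million JPY. The salt–SBP coefficients are
0.25–0.75 mmHg per g/day, rising with age, consistent with published
regression analyses of Japanese communities; under the deepest target they
shift SBP by low single-digit mmHg and yield averted fractions of the same
order as published national projections (a few percent). Relative risks
per 10 mmHg are 1.45 (IHD) and 1.65 (stroke) with asymmetric CIs.
Confidence bounds for incidence, prevalence, the salt–SBP coefficients,
and the relative risks are fixed multiples of the point values, so the
one-way sensitivity machinery always has settings to sweep.

Jitter is multiplicative — `value · (1 + noise_scale·u)`, `u ~ U(−1, 1)`,
seeded, default half-width 5% — and clipped into each family's valid
range, so any seed yields a parameter set that passes validation
bit-reproducibly. `noise_scale = 0` returns the canonical values
independent of seed. What the fixtures do *not* emulate: the actual
appendix values (results are not cell-comparable to published tables),
parameter correlations across strata beyond the built-in age/sex
gradients, sampling uncertainty (CIs are stylised multiples), and secular
trends. Passing tests therefore demonstrate the correctness and internal
consistency of the machinery under realistic magnitudes, not numeric
reproduction of the published projections.

## Sensitivity analysis

One-way deterministic analyses perturb one family at a time: discount rate
(0, 2, 4%), salt–SBP coefficients, and each disease's incidence,
prevalence, and relative risk at their CI bounds — eight analyses, each
substituting the whole stratified family at once (one-way means one
family, not one cell). Every substituted parameter set is checked by
per-family SHA-256 digest to differ from base in exactly the analysed
family, and the embedded base run is required to equal the main analysis
bit for bit. The outcome is the cumulative discounted expenditure saving
(scenario vs base), pooled and per sex, in USD; results are ranked by
pooled range width with lexical tie-breaks. On synthetic defaults the
ranking reproduces the expected qualitative pattern (salt–SBP association
and stroke relative risk widest), though that ordering depends on the
stylised CIs and is reported, not asserted.

## Numerical choices and sizes

Row-stochasticity tolerance 1e-12; conservation 1e-9 relative; scenario
endpoint calibration 1e-9 relative; first-cycle validation 1e-9 relative
per cell. Degenerate inputs: zero occupancy with zero events gives
probability 0 (never 0/0); events exceeding a source occupancy, prevalence
pairs summing to ≥1, negative rates, and protective relative risks (<1)
are hard errors; an all-cause rate below the disease rates floors
other-cause mortality at zero with a warning rather than an error. CSV
round-trips read with round-trip float precision so a written parameter
set reloads digest-identical.

Default problem sizes: 8 strata × 10 cycles per run; the property suites
use 100 seeds (conservation), 50 random instances × 10 cycles
(ledger-vs-matrix), and 20 seeds × 4 scenarios (dose–response), which
keeps the whole suite under a minute on one core while exercising every
code path.

## Known limitations

No long-term-care or disability costs; no diseases beyond IHD and stroke;
no cohort entry at age 40 or exit at 80 (closed-cohort projections are
conditional on the 2019 membership); no probabilistic sensitivity
analysis; no explicit competing-risks correction beyond the other-cause
subtraction; no nonlinear salt–SBP dose response or effect lag.
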