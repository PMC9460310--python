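"""The discrete-time Markov cohort engine.

A closed cohort, stratified by sex and 10-year age group, moves among six
mutually exclusive health states in annual cycles:

    HEALTHY -> CHRONIC_IHD / CHRONIC_STROKE (non-fatal first-ever event)
            -> DEAD_IHD / DEAD_STROKE       (fatal first-ever event)
            -> DEAD_OTHER
    CHRONIC_d -> CHRONIC_d (stay, or non-fatal recurrence)
              -> DEAD_d    (fatal recurrence)
              -> DEAD_OTHER
    DEAD_*    -> absorbing

Disease deaths arise only as incident events times the 28-day case
fatality: the acute phase is resolved within the event cycle (death by the
end of the cycle, or transfer to the chronic state at the next cycle
start), and the published disease-specific mortality rates serve solely to
compute the residual other-cause mortality.  Other-cause mortality applies
to the non-event remainder of each live state and is assumed equal across
the healthy and chronic states.  No return to health, no cross-disease
transitions, no stratum ageing over the horizon.

Costs: one inpatient episode per incident event (fatal or not), and the
annual outpatient + drug cost for each person-year started in a chronic
state.  Discounting is (1 + rate)^-(t - 1), so the first cycle — the 2019
baseline year the model is validated against — is undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .params import DISEASES, ModelParameters, SaltsimError
from .pathway import apply_pathway
from .scenarios import Scenario, build_trajectory

_ROW_TOL = 1e-12
_CONSERVATION_RTOL = 1e-9


class HealthState(IntEnum):
    HEALTHY = 0
    CHRONIC_IHD = 1
    CHRONIC_STROKE = 2
    DEAD_IHD = 3
    DEAD_STROKE = 4
    DEAD_OTHER = 5


STATE_NAMES = tuple(s.name for s in HealthState)
_CHRONIC = {"ihd": HealthState.CHRONIC_IHD, "stroke": HealthState.CHRONIC_STROKE}
_DEAD = {"ihd": HealthState.DEAD_IHD, "stroke": HealthState.DEAD_STROKE}


class EngineError(SaltsimError):
    """A transition-probability assembly or propagation failure."""


def rate_to_probability(rate: float) -> float:
    """Annual event rate -> one-cycle probability, 1 - exp(-rate)."""
    if rate < 0:
        raise EngineError(f"rate must be non-negative, got {rate}")
    return -np.expm1(-rate)


def discount_factor(cycle_year: int, rate: float) -> float:
    """Present-value factor (1 + rate)^-(cycle_year - 1); year 1 undiscounted."""
    if cycle_year < 1:
        raise EngineError(f"cycle_year must be >= 1, got {cycle_year}")
    if rate < 0:
        raise EngineError(f"discount rate must be non-negative, got {rate}")
    return (1.0 + rate) ** (-(cycle_year - 1))


def other_cause_mortality(
    all_cause: float, ihd_mort: float, stroke_mort: float
) -> tuple[float, bool]:
    """Residual non-cardiovascular mortality rate, floored at zero.

    Returns ``(rate, floored)``; ``floored`` is True when the disease rates
    exceed the all-cause rate and the residual was clipped.
    """
    if min(all_cause, ihd_mort, stroke_mort) < 0:
        raise EngineError("mortality rates must be non-negative")
    residual = all_cause - ihd_mort - stroke_mort
    if residual < 0:
        return 0.0, True
    return residual, False


def initial_state_vector(
    population: float, prev_ihd: float, prev_stroke: float
) -> np.ndarray:
    """Split a stratum across healthy/chronic states by baseline prevalence."""
    if prev_ihd + prev_stroke >= 1:
        raise EngineError(
            f"prevalences sum to {prev_ihd + prev_stroke} >= 1; "
            "the healthy state would be empty or negative"
        )
    v = np.zeros(len(HealthState))
    v[HealthState.CHRONIC_IHD] = population * prev_ihd
    v[HealthState.CHRONIC_STROKE] = population * prev_stroke
    v[HealthState.HEALTHY] = population - v[1] - v[2]
    return v


def split_incident_events(
    incidence: float,
    multiplier: float,
    prop_first_ever: float,
    healthy: float,
    chronic: float,
    stratum_alive: float,
    label: str = "",
) -> tuple[float, float, float, float]:
    """Divide a cycle's incident events between first-ever and recurrent.

    Total events E = (1 - exp(-incidence x multiplier)) x alive; a fraction
    ``prop_first_ever`` arises in the healthy state, the rest as recurrences
    in the disease's own chronic state.  Returns
    ``(first_events, recurrent_events, p_first, p_recurrent)`` where the
    probabilities are per-occupant of the source state.
    """
    p_event = rate_to_probability(incidence * multiplier)
    total = p_event * stratum_alive
    first = prop_first_ever * total
    recurrent = (1.0 - prop_first_ever) * total

    def _prob(events: float, occupancy: float, source: str) -> float:
        if events <= 0:
            return 0.0
        if occupancy <= 0 or events > occupancy * (1 + 1e-12):
            raise EngineError(
                f"{label or 'stratum'}: {source} events {events:.6g} exceed "
                f"occupancy {occupancy:.6g}"
            )
        return min(events / occupancy, 1.0)

    return first, recurrent, _prob(first, healthy, "first-ever"), _prob(
        recurrent, chronic, "recurrent"
    )


def build_transition_matrix(
    p_first: dict[str, float],
    p_recurrent: dict[str, float],
    case_fatality: dict[str, float],
    p_other: float,
) -> np.ndarray:
    """Assemble one stratum-cycle 6x6 row-stochastic transition matrix.

    Ordering within a cycle: incident events are drawn first from each live
    state; other-cause mortality applies to the non-event remainder; the
    residual stays put.  A fatal event (probability x 28-day case fatality)
    leads to the disease death state, a non-fatal one to the disease's
    chronic state.  Dead rows are identity; nothing re-enters HEALTHY.
    """
    for d in DISEASES:
        for p, what in ((p_first[d], "first-ever"), (p_recurrent[d], "recurrent"),
                        (case_fatality[d], "case fatality")):
            if not (0 <= p <= 1):
                raise EngineError(f"{what} probability for {d} out of [0,1]: {p}")
    if not (0 <= p_other <= 1):
        raise EngineError(f"other-cause probability out of [0,1]: {p_other}")
    event_total = p_first["ihd"] + p_first["stroke"]
    if event_total > 1 + _ROW_TOL:
        raise EngineError(
            f"competing first-ever event probabilities sum to {event_total} > 1"
        )

    m = np.zeros((6, 6))
    h = HealthState.HEALTHY
    for d in DISEASES:
        m[h, _DEAD[d]] = p_first[d] * case_fatality[d]
        m[h, _CHRONIC[d]] = p_first[d] * (1.0 - case_fatality[d])
    rest = 1.0 - event_total
    m[h, HealthState.DEAD_OTHER] = rest * p_other
    m[h, h] = rest * (1.0 - p_other)

    for d in DISEASES:
        c = _CHRONIC[d]
        p_rec, cf = p_recurrent[d], case_fatality[d]
        m[c, _DEAD[d]] = p_rec * cf
        m[c, HealthState.DEAD_OTHER] = (1.0 - p_rec) * p_other
        m[c, c] = p_rec * (1.0 - cf) + (1.0 - p_rec) * (1.0 - p_other)

    for s in (HealthState.DEAD_IHD, HealthState.DEAD_STROKE, HealthState.DEAD_OTHER):
        m[s, s] = 1.0

    rows = m.sum(axis=1)
    if np.max(np.abs(rows - 1.0)) > _ROW_TOL:
        raise EngineError(f"row sums deviate from 1: {rows}")
    return m


@dataclass
class CohortTrajectory:
    """State occupancies and per-cycle tallies for one scenario run.

    occupancy  (sex, age_group, cycle 0..T) x health state, persons
    tallies    (sex, age_group, cycle 1..T) x event/death/cost columns;
               cost columns exist undiscounted and with ``_disc`` suffix (JPY)
    """

    scenario: Scenario
    occupancy: pd.DataFrame
    tallies: pd.DataFrame
    floored_strata: list[tuple[str, str]] = field(default_factory=list)

    def first_cycle_expenditures(self) -> pd.DataFrame:
        """Undiscounted cycle-1 spending by (disease, sex) and care type."""
        t1 = self.tallies.xs(1, level="cycle")
        rows = []
        for d in DISEASES:
            by_sex = t1.groupby(level="sex", sort=False)[
                [f"outpatient_{d}", f"inpatient_{d}"]
            ].sum()
            for sex, row in by_sex.iterrows():
                rows.append(
                    {
                        "disease": d,
                        "sex": sex,
                        "outpatient": row[f"outpatient_{d}"],
                        "inpatient": row[f"inpatient_{d}"],
                    }
                )
        return pd.DataFrame(rows).set_index(["disease", "sex"])


_TALLY_COLS = (
    ["first_ever_ihd", "recurrent_ihd", "first_ever_stroke", "recurrent_stroke",
     "deaths_ihd", "deaths_stroke", "deaths_other"]
    + [f"{kind}_{d}" for d in DISEASES for kind in ("outpatient", "inpatient")]
    + [f"{kind}_{d}_disc" for d in DISEASES for kind in ("outpatient", "inpatient")]
)


def run_cohort(params: ModelParameters, scenario: Scenario) -> CohortTrajectory:
    """Propagate every stratum over the horizon and tally events and costs.

    Each stratum is independent: its transition matrix is rebuilt every
    cycle from the scenario's incidence multipliers, applied to the cycle's
    starting occupancy via a vector-matrix product.  A conservation check
    (live occupancy + cumulative deaths = baseline population) runs every
    cycle at 1e-9 relative tolerance.
    """
    salt_traj = build_trajectory(params, scenario)
    _, multipliers = apply_pathway(params, salt_traj)
    T = params.horizon_years
    dr = params.costs.discount_rate

    occ_rows, tally_rows, occ_keys, tally_keys = [], [], [], []
    floored_strata: list[tuple[str, str]] = []

    for stratum in params.population.index:
        sex, age = stratum
        n0 = float(params.population[stratum])
        prev = {d: float(params.epi[d].prevalence[stratum]) for d in DISEASES}
        cf = {d: float(params.epi[d].case_fatality_28d[stratum]) for d in DISEASES}
        f_first = {d: float(params.epi[d].prop_first_ever[stratum]) for d in DISEASES}
        inc = {d: float(params.epi[d].incidence[stratum]) for d in DISEASES}
        oc = {d: float(params.costs.outpatient_drug[d][stratum]) for d in DISEASES}
        ic = {d: float(params.costs.inpatient[d][stratum]) for d in DISEASES}

        other_rate, floored = other_cause_mortality(
            float(params.all_cause_mortality[stratum]),
            float(params.epi["ihd"].disease_mortality[stratum]),
            float(params.epi["stroke"].disease_mortality[stratum]),
        )
        if floored:
            floored_strata.append(stratum)
        p_other = rate_to_probability(other_rate)

        v = initial_state_vector(n0, prev["ihd"], prev["stroke"])
        occ_rows.append(v.copy())
        occ_keys.append((sex, age, 0))

        for t in range(1, T + 1):
            alive = float(v[:3].sum())
            firsts, recs, p_first, p_rec = {}, {}, {}, {}
            for d in DISEASES:
                firsts[d], recs[d], p_first[d], p_rec[d] = split_incident_events(
                    inc[d],
                    float(multipliers[d].loc[stratum, t]),
                    f_first[d],
                    float(v[HealthState.HEALTHY]),
                    float(v[_CHRONIC[d]]),
                    alive,
                    label=f"({sex}, {age}) {d} cycle {t}",
                )
            m = build_transition_matrix(p_first, p_rec, cf, p_other)

            events = {d: firsts[d] + recs[d] for d in DISEASES}
            non_event_alive = (
                v[HealthState.HEALTHY] * (1.0 - p_first["ihd"] - p_first["stroke"])
                + v[HealthState.CHRONIC_IHD] * (1.0 - p_rec["ihd"])
                + v[HealthState.CHRONIC_STROKE] * (1.0 - p_rec["stroke"])
            )
            df_t = discount_factor(t, dr)
            tally = {
                "first_ever_ihd": firsts["ihd"],
                "recurrent_ihd": recs["ihd"],
                "first_ever_stroke": firsts["stroke"],
                "recurrent_stroke": recs["stroke"],
                "deaths_ihd": events["ihd"] * cf["ihd"],
                "deaths_stroke": events["stroke"] * cf["stroke"],
                "deaths_other": non_event_alive * p_other,
            }
            for d in DISEASES:
                outp = float(v[_CHRONIC[d]]) * oc[d]  # cycle-start chronic occupancy
                inp = events[d] * ic[d]               # fatal and non-fatal alike
                tally[f"outpatient_{d}"] = outp
                tally[f"inpatient_{d}"] = inp
                tally[f"outpatient_{d}_disc"] = outp * df_t
                tally[f"inpatient_{d}_disc"] = inp * df_t
            tally_rows.append(tally)
            tally_keys.append((sex, age, t))

            v = v @ m
            occ_rows.append(v.copy())
            occ_keys.append((sex, age, t))
            if abs(v.sum() - n0) > _CONSERVATION_RTOL * n0:
                raise EngineError(
                    f"conservation violated in stratum ({sex}, {age}) "
                    f"at cycle {t}: total {v.sum()!r} vs baseline {n0!r}"
                )

    idx_names = ["sex", "age_group", "cycle"]
    occupancy = pd.DataFrame(
        occ_rows,
        index=pd.MultiIndex.from_tuples(occ_keys, names=idx_names),
        columns=list(STATE_NAMES),
    )
    tallies = pd.DataFrame(
        tally_rows,
        index=pd.MultiIndex.from_tuples(tally_keys, names=idx_names),
        columns=_TALLY_COLS,
    )
    return CohortTrajectory(
        scenario=scenario,
        occupancy=occupancy,
        tallies=tallies,
        floored_strata=floored_strata,
    )


@dataclass(frozen=True)
class ValidationCell:
    """One failing cell of the first-cycle expenditure validation."""

    disease: str
    sex: str
    care_type: str
    modeled: float
    reference: float


def validate_first_cycle(
    trajectory: CohortTrajectory,
    reference: pd.DataFrame,
    rtol: float = 1e-9,
) -> list[ValidationCell]:
    """Compare modeled first-cycle spending against an external reference.

    ``reference`` is a (disease, sex)-indexed frame with ``outpatient`` and
    ``inpatient`` columns (undiscounted JPY), e.g. the 2019 national
    expenditure statistics the model is calibrated to reproduce.  Returns
    the list of cells differing beyond ``rtol`` relative (empty = pass).
    """
    modeled = trajectory.first_cycle_expenditures()
    if set(modeled.index) != set(reference.index):
        raise SaltsimError(
            "reference table must cover exactly the modeled (disease, sex) cells"
        )
    failures: list[ValidationCell] = []
    for (disease, sex) in modeled.index:
        for care_type in ("outpatient", "inpatient"):
            got = float(modeled.loc[(disease, sex), care_type])
            want = float(reference.loc[(disease, sex), care_type])
            scale = max(abs(want), 1.0)
            if abs(got - want) > rtol * scale:
                failures.append(ValidationCell(disease, sex, care_type, got, want))
    return failures
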