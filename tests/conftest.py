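import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import saltsim as ss

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params() -> ss.ModelParameters:
    """The canonical synthetic parameter set (seed 0, default jitter)."""
    return ss.generate_parameters(ss.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def base_trajectory(default_params) -> ss.CohortTrajectory:
    return ss.run_cohort(default_params, ss.make_scenario(default_params, "base"))


def make_uniform_params(
    population: float = 1000.0,
    prev_ihd: float = 0.1,
    prev_stroke: float = 0.1,
    incidence_ihd: float = 0.01,
    incidence_stroke: float = 0.01,
    mortality_ihd: float = 0.001,
    mortality_stroke: float = 0.001,
    all_cause: float = 0.01,
    first_ever: float = 0.8,
    case_fatality: float = 0.2,
    beta: float = 1.0,
    rr_ihd: float = 1.5,
    rr_stroke: float = 2.0,
    outpatient: float = 100_000.0,
    inpatient: float = 1_000_000.0,
    mean_salt: float = 10.0,
    mean_sbp: float = 130.0,
    discount_rate: float = 0.02,
    horizon: int = 10,
) -> ss.ModelParameters:
    """A toy parameter set with the same value in every stratum.

    Every stratum then evolves identically, so single-stratum hand ledgers
    apply to each of the eight strata unchanged.
    """
    idx = ss.stratum_index()

    def s(v, name=None):
        return pd.Series(float(v), index=idx, name=name)

    epi = {}
    for d, inc, mort in (
        ("ihd", incidence_ihd, mortality_ihd),
        ("stroke", incidence_stroke, mortality_stroke),
    ):
        prev = prev_ihd if d == "ihd" else prev_stroke
        epi[d] = ss.EpiParams(
            disease=d,
            prevalence=s(prev),
            incidence=s(inc),
            disease_mortality=s(mort),
            prop_first_ever=s(first_ever),
            case_fatality_28d=s(case_fatality),
            prevalence_ci=pd.DataFrame({"low": s(prev * 0.9), "high": s(prev * 1.1)}),
            incidence_ci=pd.DataFrame({"low": s(inc * 0.9), "high": s(inc * 1.1)}),
        )
    return ss.ModelParameters(
        population=s(population),
        mean_salt=s(mean_salt),
        mean_sbp=s(mean_sbp),
        epi=epi,
        all_cause_mortality=s(all_cause),
        effects=ss.EffectParams(
            sbp_per_salt=s(beta),
            rr_per_increment={"ihd": rr_ihd, "stroke": rr_stroke},
            increment_mmhg=10.0,
            sbp_per_salt_ci=pd.DataFrame({"low": s(beta * 0.7), "high": s(beta * 1.3)}),
            rr_ci={"ihd": (max(1.0, rr_ihd - 0.2), rr_ihd + 0.2),
                   "stroke": (max(1.0, rr_stroke - 0.2), rr_stroke + 0.2)},
        ),
        costs=ss.CostParams(
            outpatient_drug={d: s(outpatient) for d in ss.DISEASES},
            inpatient={d: s(inpatient) for d in ss.DISEASES},
            discount_rate=discount_rate,
        ),
        std_pop=pd.Series(0.25, index=list(ss.AGE_GROUPS)),
        horizon_years=horizon,
    )


@pytest.fixture
def uniform_params() -> ss.ModelParameters:
    return make_uniform_params()


def ledger_step(v, p_first, p_rec, case_fatality, p_other):
    """Independent explicit per-flow propagation of one stratum-cycle.

    Bookkeeps every individual flow (events by source, fatal/non-fatal
    split, other-cause deaths on the non-event remainder) without any
    matrix algebra, as an oracle for the engine's matrix-product path.
    """
    H = ss.HealthState
    healthy, c_ihd, c_str, d_ihd, d_str, d_oth = (float(v[s]) for s in H)

    first = {d: healthy * p_first[d] for d in ss.DISEASES}
    rec = {"ihd": c_ihd * p_rec["ihd"], "stroke": c_str * p_rec["stroke"]}
    fatal = {d: (first[d] + rec[d]) * case_fatality[d] for d in ss.DISEASES}
    nonfatal = {d: (first[d] + rec[d]) - fatal[d] for d in ss.DISEASES}

    healthy_rem = healthy - first["ihd"] - first["stroke"]
    c_ihd_rem = c_ihd - rec["ihd"]
    c_str_rem = c_str - rec["stroke"]
    other_deaths = (healthy_rem + c_ihd_rem + c_str_rem) * p_other

    out = np.zeros(6)
    out[H.HEALTHY] = healthy_rem * (1 - p_other)
    out[H.CHRONIC_IHD] = c_ihd_rem * (1 - p_other) + nonfatal["ihd"]
    out[H.CHRONIC_STROKE] = c_str_rem * (1 - p_other) + nonfatal["stroke"]
    out[H.DEAD_IHD] = d_ihd + fatal["ihd"]
    out[H.DEAD_STROKE] = d_str + fatal["stroke"]
    out[H.DEAD_OTHER] = d_oth + other_deaths
    return out
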