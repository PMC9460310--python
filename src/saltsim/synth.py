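"""Reproducible synthetic model parameters.

The generator produces a full :class:`~saltsim.params.ModelParameters` whose
structure matches the real input tables (sex x 10-year-age-group strata for
salt, SBP, disease epidemiology, costs) and whose magnitudes are plausible
for Japanese adults aged 40-79 in 2019: salt intake rising with age and
higher in men, SBP rising with age, incidence and mortality rising steeply
with age, 28-day case fatality higher for IHD than stroke.  Population
counts are the published 2019 estimates per stratum (total 66,955,000);
other central values are canonical profiles chosen once, jittered
multiplicatively around those centres under a fixed seed.

These fixtures exercise every pipeline stage without any external download;
they are NOT the study's actual appendix inputs and results computed from
them are not comparable to published projections cell by cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (
    AGE_GROUPS,
    DISEASES,
    CostParams,
    EffectParams,
    EpiParams,
    ModelParameters,
    SaltsimError,
    stratum_index,
)

# --- canonical central values (male 40-49 .. 70-79, then female) -------------

_POPULATION = [9_373_000, 8_160_000, 7_930_000, 7_332_000,
               9_147_000, 8_118_000, 8_302_000, 8_593_000]  # sums to 66,955,000
_MEAN_SALT = [10.5, 10.7, 11.1, 11.3, 8.9, 9.2, 9.7, 9.9]          # g/day
_MEAN_SBP = [125.0, 130.0, 137.0, 142.0, 118.0, 126.0, 133.0, 140.0]  # mmHg

_PREVALENCE = {
    "ihd":    [0.005, 0.015, 0.035, 0.060, 0.002, 0.006, 0.016, 0.040],
    "stroke": [0.006, 0.014, 0.030, 0.055, 0.004, 0.010, 0.022, 0.048],
}
_INCIDENCE = {  # events per person-year
    "ihd":    [0.0014, 0.0035, 0.0060, 0.0095, 0.0003, 0.0008, 0.0023, 0.0063],
    "stroke": [0.0018, 0.0036, 0.0052, 0.0075, 0.0015, 0.0032, 0.0055, 0.0081],
}
_DISEASE_MORTALITY = {  # deaths per person-year
    "ihd":    [0.00025, 0.00075, 0.0017, 0.0038, 0.00006, 0.00020, 0.00075, 0.0024],
    "stroke": [0.00018, 0.00042, 0.0009, 0.0019, 0.00013, 0.00033, 0.00075, 0.0017],
}
_FIRST_EVER = {
    "ihd":    [0.90, 0.85, 0.80, 0.75, 0.92, 0.88, 0.84, 0.78],
    "stroke": [0.88, 0.84, 0.80, 0.76, 0.90, 0.86, 0.82, 0.78],
}
_CASE_FATALITY = {
    "ihd":    [0.22, 0.26, 0.30, 0.36, 0.20, 0.24, 0.29, 0.35],
    "stroke": [0.07, 0.09, 0.12, 0.17, 0.06, 0.08, 0.11, 0.16],
}
_ALL_CAUSE_OTHER = [0.0012, 0.0031, 0.0076, 0.0210,
                    0.0007, 0.0017, 0.0038, 0.0118]  # other-cause part
# SBP change (mmHg) per g/day salt change; steeper at older ages
_SBP_PER_SALT = [0.25, 0.40, 0.55, 0.70, 0.30, 0.45, 0.60, 0.75]
_RR = {"ihd": 1.45, "stroke": 1.65}          # per 10 mmHg SBP
_RR_CI = {"ihd": (1.30, 1.62), "stroke": (1.45, 1.90)}

_OUTPATIENT = {  # JPY per person-year in the chronic state
    "ihd":    [190_000, 210_000, 240_000, 270_000, 160_000, 184_000, 216_000, 250_000],
    "stroke": [170_000, 190_000, 220_000, 256_000, 150_000, 176_000, 204_000, 240_000],
}
_INPATIENT = {  # JPY per incident event
    "ihd":    [1_450_000, 1_520_000, 1_600_000, 1_700_000,
               1_380_000, 1_450_000, 1_540_000, 1_650_000],
    "stroke": [2_350_000, 2_480_000, 2_650_000, 2_900_000,
               2_250_000, 2_400_000, 2_580_000, 2_850_000],
}
# 2010 census population by age group (thousands), pooled sexes, for weights
_STD_POP_2010 = [16_700, 16_100, 18_200, 13_000]


@dataclass(frozen=True)
class SyntheticConfig:
    """Controls for the generator.

    noise_scale is the half-width of the multiplicative jitter band around
    each canonical central value (0 disables jitter entirely, so the output
    is seed-independent).
    """

    seed: int = 0
    noise_scale: float = 0.05
    horizon_years: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_scale <= 0.5):
            raise SaltsimError(
                f"noise_scale must be in [0, 0.5], got {self.noise_scale}"
            )


def _series(values, name=None) -> pd.Series:
    return pd.Series(list(values), index=stratum_index(), dtype=float, name=name)


def generate_parameters(config: SyntheticConfig = SyntheticConfig()) -> ModelParameters:
    """Build a complete, always-valid parameter set under a fixed seed.

    Jitter is multiplicative, value * (1 + noise_scale * u) with
    u ~ Uniform(-1, 1), then clipped into each family's valid range so that
    the result passes :func:`~saltsim.params.validate_parameters` for any
    seed.  The all-cause mortality rate is assembled as jittered other-cause
    plus the (jittered) disease mortalities, so it never falls below their
    sum and the engine's floor never triggers on synthetic data.
    """
    rng = np.random.default_rng(config.seed)

    def jitter(values, lo=0.0, hi=np.inf):
        v = np.asarray(values, dtype=float)
        if config.noise_scale > 0:
            v = v * (1.0 + config.noise_scale * rng.uniform(-1.0, 1.0, size=v.shape))
        return np.clip(v, lo, hi)

    salt = _series(jitter(_MEAN_SALT, 0.5, 29.5), "mean_salt")
    sbp = _series(jitter(_MEAN_SBP, 81.0, 219.0), "mean_sbp")

    epi: dict[str, EpiParams] = {}
    disease_mort: dict[str, np.ndarray] = {}
    for d in DISEASES:
        prev = jitter(_PREVALENCE[d], 0.0, 0.45)
        inc = jitter(_INCIDENCE[d], 0.0)
        mort = jitter(_DISEASE_MORTALITY[d], 0.0)
        disease_mort[d] = mort
        epi[d] = EpiParams(
            disease=d,
            prevalence=_series(prev, f"{d}_prevalence"),
            incidence=_series(inc, f"{d}_incidence"),
            disease_mortality=_series(mort, f"{d}_mortality"),
            prop_first_ever=_series(jitter(_FIRST_EVER[d], 0.0, 1.0), f"{d}_first_ever"),
            case_fatality_28d=_series(
                jitter(_CASE_FATALITY[d], 0.0, 0.95), f"{d}_case_fatality"
            ),
            prevalence_ci=pd.DataFrame(
                {"low": prev * 0.85, "high": prev * 1.15}, index=stratum_index()
            ),
            incidence_ci=pd.DataFrame(
                {"low": inc * 0.85, "high": inc * 1.15}, index=stratum_index()
            ),
        )

    other = jitter(_ALL_CAUSE_OTHER, 0.0)
    all_cause = _series(
        other + disease_mort["ihd"] + disease_mort["stroke"], "all_cause_mortality"
    )

    beta = jitter(_SBP_PER_SALT, 0.0)
    rr = {d: float(max(1.0, jitter([_RR[d]], 1.0)[0])) for d in DISEASES}
    effects = EffectParams(
        sbp_per_salt=_series(beta, "sbp_per_salt"),
        rr_per_increment=rr,
        increment_mmhg=10.0,
        sbp_per_salt_ci=pd.DataFrame(
            {"low": beta * 0.7, "high": beta * 1.3}, index=stratum_index()
        ),
        rr_ci={
            d: (min(_RR_CI[d][0], rr[d]), max(_RR_CI[d][1], rr[d])) for d in DISEASES
        },
    )

    costs = CostParams(
        outpatient_drug={
            d: _series(jitter(_OUTPATIENT[d], 0.0), f"{d}_outpatient") for d in DISEASES
        },
        inpatient={
            d: _series(jitter(_INPATIENT[d], 0.0), f"{d}_inpatient") for d in DISEASES
        },
    )

    std = np.asarray(_STD_POP_2010, dtype=float)
    return ModelParameters(
        population=_series(_POPULATION, "population"),
        mean_salt=salt,
        mean_sbp=sbp,
        epi=epi,
        all_cause_mortality=all_cause,
        effects=effects,
        costs=costs,
        std_pop=pd.Series(std / std.sum(), index=list(AGE_GROUPS), name="weight"),
        horizon_years=config.horizon_years,
    )


def generate_reference_expenditures(params: ModelParameters) -> pd.DataFrame:
    """Expected first-cycle (2019) expenditures, by an independent closed form.

    For each stratum, in the first annual cycle of the status-quo scenario:

    * chronic occupancy at cycle start is N x prevalence, so outpatient+drug
      spending is N x prevalence x annual outpatient cost;
    * incident events number (1 - exp(-incidence)) x N (everyone initially
      alive is at risk), each billed one inpatient episode whether fatal or not.

    The arithmetic here deliberately never touches the Markov engine, so the
    first-cycle validation check compares two independent routes.  Returns a
    (disease, sex)-indexed frame with columns ``outpatient`` and ``inpatient``
    in JPY, undiscounted.
    """
    rows = []
    for d in DISEASES:
        e = params.epi[d]
        n = params.population
        outpatient = n * e.prevalence * params.costs.outpatient_drug[d]
        events = (1.0 - np.exp(-e.incidence)) * n
        inpatient = events * params.costs.inpatient[d]
        for sex in params.population.index.get_level_values("sex").unique():
            rows.append(
                {
                    "disease": d,
                    "sex": sex,
                    "outpatient": float(outpatient.xs(sex, level="sex").sum()),
                    "inpatient": float(inpatient.xs(sex, level="sex").sum()),
                }
            )
    return pd.DataFrame(rows).set_index(["disease", "sex"])


def write_fixture(out_dir, config: SyntheticConfig = SyntheticConfig()):
    """Write a loadable fixture directory plus the reference expenditure table."""
    from .io import write_parameters

    params = generate_parameters(config)
    root = write_parameters(params, out_dir)
    generate_reference_expenditures(params).reset_index().to_csv(
        root / "reference_expenditures.csv", index=False
    )
    return root
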