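"""Domain types for the salt-reduction Markov cohort model.

The model is stratified by sex and 10-year age group (eight strata) and
tracks two cardiovascular diseases, ischemic heart disease (IHD, ICD-10
I20-I25) and stroke (I60-I69).  Every stratified quantity is held as a
:class:`pandas.Series` indexed by the (sex, age_group) MultiIndex returned
by :func:`stratum_index`, so tables align by construction and validation
can speak in terms of named strata.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

SEXES: tuple[str, ...] = ("male", "female")
AGE_GROUPS: tuple[str, ...] = ("40-49", "50-59", "60-69", "70-79")
DISEASES: tuple[str, ...] = ("ihd", "stroke")


class SaltsimError(Exception):
    """Base class for errors raised by this package."""


class ParameterError(SaltsimError):
    """A parameter table is malformed, incomplete, or out of range."""


def stratum_index() -> pd.MultiIndex:
    """The canonical (sex, age_group) index shared by all stratified tables."""
    return pd.MultiIndex.from_product(
        [list(SEXES), list(AGE_GROUPS)], names=["sex", "age_group"]
    )


def as_stratum_series(values, name: str | None = None) -> pd.Series:
    """Coerce a mapping/sequence to a float Series on the canonical index.

    Raises :class:`ParameterError` naming any missing stratum.
    """
    idx = stratum_index()
    s = pd.Series(values, dtype=float)
    if not isinstance(s.index, pd.MultiIndex):
        raise ParameterError(f"{name or 'table'}: expected (sex, age_group) index")
    missing = idx.difference(s.index)
    if len(missing) > 0:
        sex, age = missing[0]
        raise ParameterError(
            f"{name or 'table'}: missing stratum ({sex}, {age})"
        )
    out = s.reindex(idx)
    out.name = name
    return out


@dataclass
class EpiParams:
    """Epidemiological inputs for one disease.

    prevalence          proportion of the stratum in the chronic state at baseline
    incidence           incident events per person-year (all events, first-ever
                        plus recurrent)
    disease_mortality   deaths from the disease per person-year; used only to
                        derive residual other-cause mortality
    prop_first_ever     proportion of incident events occurring in people with
                        no disease history (sourced from the healthy state)
    case_fatality_28d   probability an incident event is fatal within 28 days
    """

    disease: str
    prevalence: pd.Series
    incidence: pd.Series
    disease_mortality: pd.Series
    prop_first_ever: pd.Series
    case_fatality_28d: pd.Series
    prevalence_ci: pd.DataFrame | None = None  # columns: low, high
    incidence_ci: pd.DataFrame | None = None


@dataclass
class EffectParams:
    """The salt -> SBP -> incidence effect pathway inputs.

    sbp_per_salt        regression coefficient beta: mmHg change in mean SBP
                        per g/day change in salt intake, per stratum
    rr_per_increment    relative risk of incidence per `increment_mmhg` higher
                        SBP, per disease (applied log-linearly)
    increment_mmhg      the SBP increment the relative risks refer to
    """

    sbp_per_salt: pd.Series
    rr_per_increment: dict[str, float]
    increment_mmhg: float = 10.0
    sbp_per_salt_ci: pd.DataFrame | None = None
    rr_ci: dict[str, tuple[float, float]] | None = None


@dataclass
class CostParams:
    """Healthcare cost inputs, held in JPY; USD conversion happens at reporting.

    outpatient_drug     outpatient care + drug prescription cost per person-year
                        spent in the chronic state, per disease per stratum (JPY)
    inpatient           acute inpatient cost per incident event (fatal or not),
                        per disease per stratum (JPY)
    """

    outpatient_drug: dict[str, pd.Series]
    inpatient: dict[str, pd.Series]
    currency_code: str = "JPY"
    jpy_per_usd: float = 109.01
    discount_rate: float = 0.02


@dataclass
class ModelParameters:
    """All model inputs, one validated container.

    Stratified fields are Series on the canonical (sex, age_group) index;
    ``std_pop`` is an age-group-indexed weight vector used for age adjustment.
    """

    population: pd.Series
    mean_salt: pd.Series
    mean_sbp: pd.Series
    epi: dict[str, EpiParams]
    all_cause_mortality: pd.Series
    effects: EffectParams
    costs: CostParams
    std_pop: pd.Series
    horizon_years: int = 10

    def copy(self) -> "ModelParameters":
        import copy as _copy

        return _copy.deepcopy(self)

    def equals(self, other: "ModelParameters", rtol: float = 0.0) -> bool:
        """Value equality across every table (exact by default)."""
        return family_digests(self) == family_digests(other) if rtol == 0.0 else (
            len(diff_families(self, other)) == 0
        )


@dataclass(frozen=True)
class Violation:
    """One validation finding: errors invalidate, warnings only flag."""

    table: str
    stratum: str
    fieldname: str
    message: str
    severity: str = "error"  # "error" | "warning"


def _check_range(
    out: list[Violation],
    table: str,
    series: pd.Series,
    lo: float,
    hi: float,
    lo_open: bool = False,
    hi_open: bool = False,
) -> None:
    for key, v in series.items():
        stratum = ", ".join(map(str, key)) if isinstance(key, tuple) else str(key)
        bad = (
            not np.isfinite(v)
            or (v < lo or (lo_open and v == lo))
            or (v > hi or (hi_open and v == hi))
        )
        if bad:
            out.append(
                Violation(
                    table,
                    stratum,
                    series.name or table,
                    f"value {v!r} outside "
                    f"{'(' if lo_open else '['}{lo}, {hi}{')' if hi_open else ']'}",
                )
            )


def validate_parameters(params: ModelParameters) -> list[Violation]:
    """Check every container invariant; return all findings (empty = valid).

    Pure reporting: never mutates its input and never raises on bad values.
    An all-cause mortality rate below the summed disease mortality is reported
    as a *warning* (the engine floors residual other-cause mortality at zero);
    everything else is an error.
    """
    out: list[Violation] = []
    _check_range(out, "population", params.population, 1, np.inf)
    _check_range(out, "mean_salt", params.mean_salt, 0, 30, lo_open=True, hi_open=True)
    _check_range(out, "mean_sbp", params.mean_sbp, 80, 220, lo_open=True, hi_open=True)

    for d in DISEASES:
        e = params.epi[d]
        _check_range(out, f"{d}_prevalence", e.prevalence, 0, 1)
        _check_range(out, f"{d}_incidence", e.incidence, 0, np.inf)
        _check_range(out, f"{d}_mortality", e.disease_mortality, 0, np.inf)
        _check_range(out, f"{d}_first_ever", e.prop_first_ever, 0, 1)
        _check_range(out, f"{d}_case_fatality", e.case_fatality_28d, 0, 1)
        for ci, point, tab in (
            (e.prevalence_ci, e.prevalence, f"{d}_prevalence"),
            (e.incidence_ci, e.incidence, f"{d}_incidence"),
        ):
            if ci is not None:
                bad = (ci["low"] > point) | (point > ci["high"])
                for key in point.index[bad]:
                    out.append(
                        Violation(
                            tab, ", ".join(key), "ci",
                            "confidence bounds do not bracket the point value",
                        )
                    )

    prev_sum = params.epi["ihd"].prevalence + params.epi["stroke"].prevalence
    for key in prev_sum.index[prev_sum >= 1]:
        out.append(
            Violation(
                "prevalence", ", ".join(key), "prevalence",
                "IHD + stroke prevalence must be < 1",
            )
        )

    _check_range(out, "all_cause_mortality", params.all_cause_mortality, 0, np.inf)
    disease_sum = (
        params.epi["ihd"].disease_mortality + params.epi["stroke"].disease_mortality
    )
    floored = params.all_cause_mortality < disease_sum
    for key in params.all_cause_mortality.index[floored]:
        out.append(
            Violation(
                "all_cause_mortality", ", ".join(key), "rate",
                "all-cause mortality below IHD + stroke mortality; "
                "other-cause mortality will be floored at 0",
                severity="warning",
            )
        )

    eff = params.effects
    _check_range(out, "sbp_per_salt", eff.sbp_per_salt, 0, np.inf)
    if eff.sbp_per_salt_ci is not None:
        bad = (eff.sbp_per_salt_ci["low"] > eff.sbp_per_salt) | (
            eff.sbp_per_salt > eff.sbp_per_salt_ci["high"]
        )
        for key in eff.sbp_per_salt.index[bad]:
            out.append(
                Violation(
                    "sbp_per_salt", ", ".join(key), "ci",
                    "confidence bounds do not bracket the point value",
                )
            )
    if eff.increment_mmhg <= 0:
        out.append(
            Violation("relative_risk", "-", "increment_mmhg", "increment must be > 0")
        )
    for d in DISEASES:
        rr = eff.rr_per_increment[d]
        if not np.isfinite(rr) or rr < 1:
            out.append(
                Violation(
                    "relative_risk", "-", d,
                    f"relative risk per increment must be >= 1, got {rr!r}",
                )
            )
        if eff.rr_ci is not None and d in eff.rr_ci:
            lo, hi = eff.rr_ci[d]
            if not (lo <= rr <= hi):
                out.append(
                    Violation(
                        "relative_risk", "-", d,
                        "confidence bounds do not bracket the point value",
                    )
                )

    for d in DISEASES:
        _check_range(out, f"{d}_outpatient_cost", params.costs.outpatient_drug[d], 0, np.inf)
        _check_range(out, f"{d}_inpatient_cost", params.costs.inpatient[d], 0, np.inf)
    if params.costs.jpy_per_usd <= 0:
        out.append(Violation("config", "-", "jpy_per_usd", "exchange rate must be > 0"))
    if not (0 <= params.costs.discount_rate <= 0.10):
        out.append(
            Violation("config", "-", "discount_rate", "discount rate must be in [0, 0.10]")
        )

    if (params.std_pop < 0).any() or params.std_pop.sum() <= 0:
        out.append(
            Violation(
                "standard_population", "-", "weight",
                "weights must be non-negative with positive total",
            )
        )
    if params.horizon_years < 1:
        out.append(Violation("config", "-", "horizon_years", "horizon must be >= 1"))
    return out


# --- digests -----------------------------------------------------------------

def _digest_values(arrays: Iterable[np.ndarray]) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a, dtype=float).tobytes())
    return h.hexdigest()


def family_digests(params: ModelParameters) -> dict[str, str]:
    """SHA-256 digest per parameter family.

    Used by the sensitivity module to assert that a substituted run differs
    from base in exactly one family, and for run metadata.
    """
    d: dict[str, str] = {
        "population": _digest_values([params.population.to_numpy()]),
        "mean_salt": _digest_values([params.mean_salt.to_numpy()]),
        "mean_sbp": _digest_values([params.mean_sbp.to_numpy()]),
        "all_cause_mortality": _digest_values([params.all_cause_mortality.to_numpy()]),
        "sbp_per_salt": _digest_values([params.effects.sbp_per_salt.to_numpy()]),
        "std_pop": _digest_values([params.std_pop.to_numpy()]),
        "config": _digest_values(
            [
                np.array(
                    [
                        params.horizon_years,
                        params.costs.jpy_per_usd,
                        params.effects.increment_mmhg,
                    ]
                )
            ]
        ),
        "discount_rate": _digest_values([np.array([params.costs.discount_rate])]),
    }
    for dis in DISEASES:
        e = params.epi[dis]
        d[f"{dis}_prevalence"] = _digest_values([e.prevalence.to_numpy()])
        d[f"{dis}_incidence"] = _digest_values([e.incidence.to_numpy()])
        d[f"{dis}_mortality"] = _digest_values([e.disease_mortality.to_numpy()])
        d[f"{dis}_first_ever"] = _digest_values([e.prop_first_ever.to_numpy()])
        d[f"{dis}_case_fatality"] = _digest_values([e.case_fatality_28d.to_numpy()])
        d[f"{dis}_rr"] = _digest_values(
            [np.array([params.effects.rr_per_increment[dis]])]
        )
        d[f"{dis}_outpatient_cost"] = _digest_values(
            [params.costs.outpatient_drug[dis].to_numpy()]
        )
        d[f"{dis}_inpatient_cost"] = _digest_values(
            [params.costs.inpatient[dis].to_numpy()]
        )
    return d


def diff_families(a: ModelParameters, b: ModelParameters) -> list[str]:
    """Names of parameter families whose values differ between two containers."""
    da, db = family_digests(a), family_digests(b)
    return sorted(k for k in da if da[k] != db[k])


def parameter_digest(params: ModelParameters) -> str:
    """A single digest over every family, for run metadata / determinism checks."""
    h = hashlib.sha256()
    for k, v in sorted(family_digests(params).items()):
        h.update(k.encode())
        h.update(v.encode())
    return h.hexdigest()
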