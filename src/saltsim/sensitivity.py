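"""One-way deterministic sensitivity analysis.

Each analysis perturbs exactly one parameter family — the discount rate
(0-4%), the salt-SBP coefficients, or a disease's incidence, prevalence, or
relative risk (95% CI bounds) — holding everything else at base values,
and re-runs the full pipeline (base case and target scenario) at the low,
base, and high settings.  The outcome is the cumulative discounted saving
of healthcare expenditures (scenario vs status quo), per sex and pooled,
in USD.  Results are ranked by outcome-range width into a tornado table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import pandas as pd

from .engine import run_cohort
from .outcomes import compare, convert_currency, summarize
from .params import DISEASES, ModelParameters, SaltsimError, diff_families
from .scenarios import Scenario, make_scenario

#: parameter families examined, in canonical order
FAMILIES = (
    "discount_rate",
    "sbp_per_salt",
    "ihd_incidence", "stroke_incidence",
    "ihd_prevalence", "stroke_prevalence",
    "ihd_rr", "stroke_rr",
)


@dataclass(frozen=True)
class SensitivitySpec:
    """Low/high settings for one parameter family.

    For ``discount_rate`` and ``*_rr`` the settings are scalars; for the
    stratified families they are full per-stratum Series.  ``low`` and
    ``high`` refer to the parameter value, not the outcome direction.
    """

    parameter_id: str
    low: Any
    high: Any


@dataclass
class SensitivityResult:
    """Savings (USD, pooled and per sex) at the low/base/high settings."""

    parameter_id: str
    savings: dict[str, dict[str, float]]  # setting -> {"pooled", "male", "female"}

    @property
    def width(self) -> float:
        return abs(self.savings["high"]["pooled"] - self.savings["low"]["pooled"])


def substitute(params: ModelParameters, parameter_id: str, setting: Any) -> ModelParameters:
    """Deep-copy ``params`` with one family replaced by ``setting``."""
    p = params.copy()
    if parameter_id == "discount_rate":
        p.costs.discount_rate = float(setting)
    elif parameter_id == "sbp_per_salt":
        p.effects.sbp_per_salt = pd.Series(setting, index=p.effects.sbp_per_salt.index,
                                           dtype=float, name="sbp_per_salt")
    elif parameter_id.endswith("_rr"):
        d = parameter_id[: -len("_rr")]
        if d not in DISEASES:
            raise SaltsimError(f"unknown parameter family {parameter_id!r}")
        p.effects.rr_per_increment[d] = float(setting)
    elif parameter_id.endswith("_incidence") or parameter_id.endswith("_prevalence"):
        d, field = parameter_id.split("_", 1)
        if d not in DISEASES:
            raise SaltsimError(f"unknown parameter family {parameter_id!r}")
        s = pd.Series(setting, index=params.epi[d].incidence.index, dtype=float,
                      name=parameter_id)
        if field == "incidence":
            p.epi[d].incidence = s
        else:
            p.epi[d].prevalence = s
    else:
        raise SaltsimError(f"unknown parameter family {parameter_id!r}")
    return p


def default_specs(params: ModelParameters) -> list[SensitivitySpec]:
    """The standard analysis set: discount 0-4% plus every CI-bounded family."""
    specs = [SensitivitySpec("discount_rate", 0.0, 0.04)]
    eff = params.effects
    if eff.sbp_per_salt_ci is not None:
        specs.append(
            SensitivitySpec(
                "sbp_per_salt", eff.sbp_per_salt_ci["low"], eff.sbp_per_salt_ci["high"]
            )
        )
    for d in DISEASES:
        e = params.epi[d]
        if e.incidence_ci is not None:
            specs.append(
                SensitivitySpec(f"{d}_incidence", e.incidence_ci["low"], e.incidence_ci["high"])
            )
        if e.prevalence_ci is not None:
            specs.append(
                SensitivitySpec(f"{d}_prevalence", e.prevalence_ci["low"], e.prevalence_ci["high"])
            )
        if eff.rr_ci is not None and d in eff.rr_ci:
            specs.append(SensitivitySpec(f"{d}_rr", eff.rr_ci[d][0], eff.rr_ci[d][1]))
    return specs


def _savings(params: ModelParameters, scenario_name: str,
             target: float | None) -> dict[str, float]:
    base = make_scenario(params, "base")
    scen = make_scenario(params, scenario_name, target_salt=target)
    s_base = summarize(run_cohort(params, base), params.costs)
    s_scen = summarize(run_cohort(params, scen), params.costs)
    cmp = compare(s_base, s_scen)
    cost_cols = [c for c in cmp.averted.columns if c.endswith("_jpy")]
    by_sex = cmp.by_sex()[cost_cols].sum(axis=1)
    out = {"pooled": convert_currency(cmp.saved_cost_jpy(), params.costs.jpy_per_usd)}
    for sex, jpy in by_sex.items():
        out[sex] = convert_currency(float(jpy), params.costs.jpy_per_usd)
    return out


def run_one_way(
    params: ModelParameters, scenario: Scenario, spec: SensitivitySpec
) -> SensitivityResult:
    """Three full pipeline runs with one family at its low/base/high setting.

    Each substituted parameter set is checked (by per-family digest) to
    differ from base in exactly the analysed family; scenario reduction
    rates are re-derived from each substituted set, though only the salt
    baseline — unchanged by every family here — enters that calibration.
    """
    savings: dict[str, dict[str, float]] = {}
    for setting_name, setting in (
        ("low", spec.low), ("base", None), ("high", spec.high)
    ):
        if setting is None:
            p = params
        else:
            p = substitute(params, spec.parameter_id, setting)
            changed = [f for f in diff_families(params, p) if f != "config"]
            if changed not in ([], [spec.parameter_id]):
                raise SaltsimError(
                    f"substitution for {spec.parameter_id!r} changed families {changed}"
                )
        savings[setting_name] = _savings(p, scenario.name, scenario.target_salt)
    return SensitivityResult(parameter_id=spec.parameter_id, savings=savings)


def tornado_table(results: list[SensitivityResult]) -> pd.DataFrame:
    """Rank results by descending pooled range width (ties: lexical id)."""
    if not results:
        raise SaltsimError("tornado table needs at least one sensitivity result")
    rows = [
        {
            "parameter": r.parameter_id,
            "savings_low_usd": r.savings["low"]["pooled"],
            "savings_base_usd": r.savings["base"]["pooled"],
            "savings_high_usd": r.savings["high"]["pooled"],
            "width_usd": r.width,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    return (
        df.sort_values(["width_usd", "parameter"], ascending=[False, True])
        .reset_index(drop=True)
    )
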