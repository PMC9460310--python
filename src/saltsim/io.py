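"""Reading and writing parameter tables.

One delimited CSV per parameter family (columns ``sex, age_group, value``
plus optional ``ci_low, ci_high``), a two-row ``relative_risk.csv`` keyed by
disease, per-disease cost tables keyed by ``disease, sex, age_group``, an
age-group-keyed ``standard_population.csv``, and a YAML run configuration.
This layout diffs cleanly and mirrors how the inputs are organised by source.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import yaml

from .params import (
    AGE_GROUPS,
    DISEASES,
    SEXES,
    CostParams,
    EffectParams,
    EpiParams,
    ModelParameters,
    ParameterError,
    as_stratum_series,
    stratum_index,
    validate_parameters,
)

CONFIG_NAME = "config.yaml"

# stratified tables with an optional CI pair
_CI_TABLES = {
    "ihd_prevalence", "ihd_incidence", "stroke_prevalence", "stroke_incidence",
    "sbp_per_salt",
}
_STRATUM_TABLES = [
    "population", "mean_salt", "mean_sbp",
    "ihd_prevalence", "ihd_incidence", "ihd_mortality",
    "ihd_first_ever", "ihd_case_fatality",
    "stroke_prevalence", "stroke_incidence", "stroke_mortality",
    "stroke_first_ever", "stroke_case_fatality",
    "all_cause_mortality", "sbp_per_salt",
]


def _read_stratum_table(path: Path, name: str) -> tuple[pd.Series, pd.DataFrame | None]:
    if not path.exists():
        raise ParameterError(f"{name}: missing table file {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("sex", "age_group", "value"):
        if col not in df.columns:
            raise ParameterError(f"{name}: missing column '{col}' in {path.name}")
    df = df.set_index(["sex", "age_group"])
    series = as_stratum_series(df["value"], name=name)
    ci = None
    if {"ci_low", "ci_high"}.issubset(df.columns):
        ci = pd.DataFrame(
            {"low": df["ci_low"], "high": df["ci_high"]}, dtype=float
        ).reindex(stratum_index())
    return series, ci


def _read_disease_stratum_table(path: Path, name: str) -> dict[str, pd.Series]:
    if not path.exists():
        raise ParameterError(f"{name}: missing table file {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    out: dict[str, pd.Series] = {}
    for d in DISEASES:
        sub = df[df["disease"] == d].set_index(["sex", "age_group"])["value"]
        if sub.empty:
            raise ParameterError(f"{name}: no rows for disease '{d}'")
        out[d] = as_stratum_series(sub, name=f"{d}_{name}")
    return out


def load_parameters(tables_path: str | os.PathLike,
                    config_path: str | os.PathLike | None = None) -> ModelParameters:
    """Load a parameter directory into a validated :class:`ModelParameters`.

    ``tables_path`` is the fixture directory; ``config_path`` defaults to
    ``config.yaml`` inside it.  Raises :class:`ParameterError` naming the
    offending table, stratum and field on any violation.
    """
    root = Path(tables_path)
    cfg_path = Path(config_path) if config_path is not None else root / CONFIG_NAME
    if not cfg_path.exists():
        raise ParameterError(f"config: missing file {cfg_path}")
    with open(cfg_path) as fh:
        cfg = yaml.safe_load(fh) or {}

    tables: dict[str, pd.Series] = {}
    cis: dict[str, pd.DataFrame | None] = {}
    for name in _STRATUM_TABLES:
        tables[name], cis[name] = _read_stratum_table(root / f"{name}.csv", name)

    rr_path = root / "relative_risk.csv"
    if not rr_path.exists():
        raise ParameterError(f"relative_risk: missing table file {rr_path}")
    rr_df = pd.read_csv(rr_path, float_precision="round_trip").set_index("disease")
    rr = {}
    rr_ci = {}
    for d in DISEASES:
        if d not in rr_df.index:
            raise ParameterError(f"relative_risk: no row for disease '{d}'")
        rr[d] = float(rr_df.loc[d, "value"])
        if {"ci_low", "ci_high"}.issubset(rr_df.columns):
            rr_ci[d] = (float(rr_df.loc[d, "ci_low"]), float(rr_df.loc[d, "ci_high"]))

    outpatient = _read_disease_stratum_table(root / "outpatient_cost.csv", "outpatient_cost")
    inpatient = _read_disease_stratum_table(root / "inpatient_cost.csv", "inpatient_cost")

    sp_path = root / "standard_population.csv"
    if not sp_path.exists():
        raise ParameterError(f"standard_population: missing table file {sp_path}")
    sp = pd.read_csv(sp_path, float_precision="round_trip").set_index("age_group")["value"].astype(float)
    missing = [a for a in AGE_GROUPS if a not in sp.index]
    if missing:
        raise ParameterError(f"standard_population: missing age group {missing[0]}")
    sp = sp.reindex(list(AGE_GROUPS))

    epi = {
        d: EpiParams(
            disease=d,
            prevalence=tables[f"{d}_prevalence"],
            incidence=tables[f"{d}_incidence"],
            disease_mortality=tables[f"{d}_mortality"],
            prop_first_ever=tables[f"{d}_first_ever"],
            case_fatality_28d=tables[f"{d}_case_fatality"],
            prevalence_ci=cis[f"{d}_prevalence"],
            incidence_ci=cis[f"{d}_incidence"],
        )
        for d in DISEASES
    }
    params = ModelParameters(
        population=tables["population"],
        mean_salt=tables["mean_salt"],
        mean_sbp=tables["mean_sbp"],
        epi=epi,
        all_cause_mortality=tables["all_cause_mortality"],
        effects=EffectParams(
            sbp_per_salt=tables["sbp_per_salt"],
            rr_per_increment=rr,
            increment_mmhg=float(cfg.get("rr_increment_mmhg", 10.0)),
            sbp_per_salt_ci=cis["sbp_per_salt"],
            rr_ci=rr_ci or None,
        ),
        costs=CostParams(
            outpatient_drug=outpatient,
            inpatient=inpatient,
            currency_code=str(cfg.get("currency_code", "JPY")),
            jpy_per_usd=float(cfg.get("jpy_per_usd", 109.01)),
            discount_rate=float(cfg.get("discount_rate", 0.02)),
        ),
        std_pop=sp,
        horizon_years=int(cfg.get("horizon_years", 10)),
    )

    errors = [v for v in validate_parameters(params) if v.severity == "error"]
    if errors:
        v = errors[0]
        raise ParameterError(
            f"{v.table} (stratum {v.stratum}, field {v.fieldname}): {v.message}"
            + (f" [+{len(errors) - 1} more]" if len(errors) > 1 else "")
        )
    return params


def _write_stratum_table(path: Path, series: pd.Series,
                         ci: pd.DataFrame | None = None) -> None:
    df = series.rename("value").reset_index()
    if ci is not None:
        df["ci_low"] = ci["low"].to_numpy()
        df["ci_high"] = ci["high"].to_numpy()
    df.to_csv(path, index=False)


def write_parameters(params: ModelParameters, out_dir: str | os.PathLike) -> Path:
    """Write a parameter container as a fixture directory; returns the path."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)

    _write_stratum_table(root / "population.csv", params.population)
    _write_stratum_table(root / "mean_salt.csv", params.mean_salt)
    _write_stratum_table(root / "mean_sbp.csv", params.mean_sbp)
    _write_stratum_table(root / "all_cause_mortality.csv", params.all_cause_mortality)
    _write_stratum_table(
        root / "sbp_per_salt.csv",
        params.effects.sbp_per_salt,
        params.effects.sbp_per_salt_ci,
    )
    for d in DISEASES:
        e = params.epi[d]
        _write_stratum_table(root / f"{d}_prevalence.csv", e.prevalence, e.prevalence_ci)
        _write_stratum_table(root / f"{d}_incidence.csv", e.incidence, e.incidence_ci)
        _write_stratum_table(root / f"{d}_mortality.csv", e.disease_mortality)
        _write_stratum_table(root / f"{d}_first_ever.csv", e.prop_first_ever)
        _write_stratum_table(root / f"{d}_case_fatality.csv", e.case_fatality_28d)

    rr_rows = []
    for d in DISEASES:
        row = {"disease": d, "value": params.effects.rr_per_increment[d]}
        if params.effects.rr_ci and d in params.effects.rr_ci:
            row["ci_low"], row["ci_high"] = params.effects.rr_ci[d]
        rr_rows.append(row)
    pd.DataFrame(rr_rows).to_csv(root / "relative_risk.csv", index=False)

    for fname, family in (
        ("outpatient_cost.csv", params.costs.outpatient_drug),
        ("inpatient_cost.csv", params.costs.inpatient),
    ):
        rows = []
        for d in DISEASES:
            df = family[d].rename("value").reset_index()
            df.insert(0, "disease", d)
            rows.append(df)
        pd.concat(rows).to_csv(root / fname, index=False)

    params.std_pop.rename("value").rename_axis("age_group").reset_index().to_csv(
        root / "standard_population.csv", index=False
    )

    with open(root / CONFIG_NAME, "w") as fh:
        yaml.safe_dump(
            {
                "horizon_years": int(params.horizon_years),
                "discount_rate": float(params.costs.discount_rate),
                "jpy_per_usd": float(params.costs.jpy_per_usd),
                "rr_increment_mmhg": float(params.effects.increment_mmhg),
                "currency_code": params.costs.currency_code,
            },
            fh,
            sort_keys=True,
        )
    return root
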