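"""Summaries and scenario-versus-base comparisons.

Cumulative incident cases (first-ever + recurrent, fatal included), deaths
by cause, and discounted expenditures per disease and care type, per
stratum and pooled; comparisons report averted counts and saved spending,
absolutely and as percentages of the base case.  Currency is carried in
JPY at full precision and converted to USD only for reporting; percentages
are computed from unrounded accumulators and rounded half-up only at
rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .engine import CohortTrajectory
from .params import DISEASES, CostParams, SaltsimError

#: cumulative per-stratum summary columns (costs discounted, JPY)
SUMMARY_COLS = (
    "incidence_ihd", "incidence_stroke",
    "deaths_ihd", "deaths_stroke", "deaths_other",
    "outpatient_ihd_jpy", "inpatient_ihd_jpy",
    "outpatient_stroke_jpy", "inpatient_stroke_jpy",
)
_COST_COLS = [c for c in SUMMARY_COLS if c.endswith("_jpy")]


def convert_currency(amount_jpy: float, jpy_per_usd: float) -> float:
    """JPY -> USD at the configured annual-average exchange rate."""
    if jpy_per_usd <= 0:
        raise SaltsimError(f"exchange rate must be positive, got {jpy_per_usd}")
    return amount_jpy / jpy_per_usd


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (2.9883 -> 3.0 at 1 decimal), as in reports."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage_of_base(part: float, base: float) -> float:
    """100 x part / base, unrounded; 0 when the base is 0."""
    return 0.0 if base == 0 else 100.0 * part / base


@dataclass
class OutcomeSummary:
    """Cumulative outcomes over the horizon.

    ``table`` holds one row per stratum (columns :data:`SUMMARY_COLS`);
    ``population`` the baseline counts; ``jpy_per_usd`` the reporting rate.
    """

    scenario: str
    table: pd.DataFrame
    population: pd.Series
    jpy_per_usd: float

    def pooled(self) -> pd.Series:
        return self.table.sum(axis=0)

    def by_sex(self) -> pd.DataFrame:
        return self.table.groupby(level="sex", sort=False).sum()

    def total_cost_jpy(self) -> float:
        return float(self.pooled()[_COST_COLS].sum())

    def total_cost_usd(self) -> float:
        return convert_currency(self.total_cost_jpy(), self.jpy_per_usd)


def summarize(trajectory: CohortTrajectory, costs: CostParams) -> OutcomeSummary:
    """Accumulate a trajectory's tallies over cycles into an OutcomeSummary."""
    t = trajectory.tallies.groupby(level=["sex", "age_group"], sort=False).sum()
    table = pd.DataFrame(
        {
            "incidence_ihd": t["first_ever_ihd"] + t["recurrent_ihd"],
            "incidence_stroke": t["first_ever_stroke"] + t["recurrent_stroke"],
            "deaths_ihd": t["deaths_ihd"],
            "deaths_stroke": t["deaths_stroke"],
            "deaths_other": t["deaths_other"],
            "outpatient_ihd_jpy": t["outpatient_ihd_disc"],
            "inpatient_ihd_jpy": t["inpatient_ihd_disc"],
            "outpatient_stroke_jpy": t["outpatient_stroke_disc"],
            "inpatient_stroke_jpy": t["inpatient_stroke_disc"],
        }
    )
    pop = trajectory.occupancy.xs(0, level="cycle").sum(axis=1)
    return OutcomeSummary(
        scenario=trajectory.scenario.name,
        table=table.reindex(pop.index),
        population=pop,
        jpy_per_usd=costs.jpy_per_usd,
    )


@dataclass
class OutcomeComparison:
    """Base-case minus scenario differences, absolute and relative.

    ``averted`` has the same shape as a summary table; percentages are
    derived on demand from the unrounded accumulators.
    """

    base: OutcomeSummary
    scenario: OutcomeSummary
    averted: pd.DataFrame

    def pooled(self) -> pd.Series:
        return self.averted.sum(axis=0)

    def by_sex(self) -> pd.DataFrame:
        return self.averted.groupby(level="sex", sort=False).sum()

    def averted_events(self) -> float:
        p = self.pooled()
        return float(p["incidence_ihd"] + p["incidence_stroke"])

    def averted_deaths(self) -> float:
        p = self.pooled()
        return float(p["deaths_ihd"] + p["deaths_stroke"])

    def saved_cost_jpy(self) -> float:
        return float(self.pooled()[_COST_COLS].sum())

    def saved_cost_usd(self) -> float:
        return convert_currency(self.saved_cost_jpy(), self.base.jpy_per_usd)

    def percent(self, what: str = "events") -> float:
        """Averted quantity as an unrounded percentage of the base case."""
        bp = self.base.pooled()
        if what == "events":
            return percentage_of_base(
                self.averted_events(),
                float(bp["incidence_ihd"] + bp["incidence_stroke"]),
            )
        if what == "deaths":
            return percentage_of_base(
                self.averted_deaths(), float(bp["deaths_ihd"] + bp["deaths_stroke"])
            )
        if what == "cost":
            return percentage_of_base(self.saved_cost_jpy(), self.base.total_cost_jpy())
        raise SaltsimError(f"unknown comparison quantity {what!r}")


def compare(base: OutcomeSummary, scenario: OutcomeSummary) -> OutcomeComparison:
    """Element-wise base - scenario differences on matching strata."""
    if not base.table.index.equals(scenario.table.index):
        raise SaltsimError("summaries cover different strata; cannot compare")
    return OutcomeComparison(
        base=base, scenario=scenario, averted=base.table - scenario.table
    )


def table2(summary: OutcomeSummary) -> pd.DataFrame:
    """Render a cumulative-projection table per sex/age row.

    Counts rounded to integers, percentages of the baseline population to
    one decimal (half-up), expenditures in million USD; sex totals precede
    their age rows, mirroring how such projections are usually tabulated.
    """
    rows = []
    rate = summary.jpy_per_usd

    def _row(label_sex: str, label_age: str, tbl: pd.Series, pop: float) -> dict:
        out = {"sex": label_sex, "age_group": label_age, "population": int(round(pop))}
        for d in DISEASES:
            out[f"incidence_{d}"] = int(round(tbl[f"incidence_{d}"]))
            out[f"incidence_{d}_pct"] = round_half_up(
                percentage_of_base(tbl[f"incidence_{d}"], pop), 1
            )
            out[f"deaths_{d}"] = int(round(tbl[f"deaths_{d}"]))
            out[f"deaths_{d}_pct"] = round_half_up(
                percentage_of_base(tbl[f"deaths_{d}"], pop), 1
            )
        for d in DISEASES:
            for kind in ("outpatient", "inpatient"):
                out[f"{kind}_{d}_musd"] = round_half_up(
                    convert_currency(tbl[f"{kind}_{d}_jpy"], rate) / 1e6, 0
                )
        return out

    for sex in summary.table.index.get_level_values("sex").unique():
        sub = summary.table.xs(sex, level="sex")
        pop = summary.population.xs(sex, level="sex")
        rows.append(_row(sex, "40-79", sub.sum(axis=0), float(pop.sum())))
        for age in sub.index:
            rows.append(_row(sex, age, sub.loc[age], float(pop.loc[age])))
    return pd.DataFrame(rows)


def comparison_table(comparisons: list[OutcomeComparison]) -> pd.DataFrame:
    """One row per scenario: averted events/deaths, savings, and percentages."""
    rows = []
    for c in comparisons:
        rows.append(
            {
                "scenario": c.scenario.scenario,
                "averted_events": int(round(c.averted_events())),
                "averted_events_pct": round_half_up(c.percent("events"), 1),
                "averted_deaths": int(round(c.averted_deaths())),
                "averted_deaths_pct": round_half_up(c.percent("deaths"), 1),
                "saved_musd": round_half_up(c.saved_cost_usd() / 1e6, 0),
                "saved_pct": round_half_up(c.percent("cost"), 1),
            }
        )
    cols = ["scenario", "averted_events", "averted_events_pct", "averted_deaths",
            "averted_deaths_pct", "saved_musd", "saved_pct"]
    return pd.DataFrame(rows, columns=cols)
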