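"""Salt-intake scenarios.

The comparator holds mean dietary salt intake at its 2019 baseline; the
intervention scenarios reduce it at a constant annual rate, uniform across
all sex and age strata, calibrated so that the *age-adjusted* (2010 standard
population) two-sex mean reaches the target (8, 6, or 5 g/day) at the end of
the horizon.  With a uniform multiplicative rate, each stratum's mean in
year t is baseline x (1 - r)^t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import AGE_GROUPS, ModelParameters, SaltsimError

#: preset name -> target g/day (None = status quo)
PRESET_TARGETS: dict[str, float | None] = {
    "base": None,
    "8g": 8.0,
    "6g": 6.0,
    "5g": 5.0,
}


@dataclass(frozen=True)
class Scenario:
    """A named salt-trajectory rule.

    For the base case ``target_salt`` is None and the annual reduction rate
    is exactly zero; for target scenarios the rate is derived from the
    age-adjusted baseline so the target is met in ``years_to_target`` years.
    """

    name: str
    target_salt: float | None
    years_to_target: int
    annual_reduction_rate: float

    @property
    def is_base(self) -> bool:
        return self.target_salt is None


def age_adjusted_mean(
    values: pd.Series,
    std_pop: pd.Series,
    population: pd.Series | None = None,
) -> float:
    """Age-standardised mean of a stratified quantity.

    ``std_pop`` holds one weight per age group (normalised internally).  If
    ``values`` carries a (sex, age_group) index, the sexes are first combined
    within each age group by their population share (``population`` required);
    an age-group-only Series is weighted directly.
    """
    w = std_pop.reindex(list(AGE_GROUPS)).astype(float)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise SaltsimError("age adjustment weights must have a positive total")
    w = w / total

    if isinstance(values.index, pd.MultiIndex):
        if population is None:
            raise SaltsimError(
                "population shares are required to pool sexes within age groups"
            )
        pooled = (values * population).groupby(level="age_group").sum() / (
            population.groupby(level="age_group").sum()
        )
        values = pooled
    values = values.reindex(list(AGE_GROUPS))
    return float((values * w).sum())


def annual_reduction_rate(baseline_adj_mean: float, target: float, years: int) -> float:
    """Constant annual rate r with baseline x (1 - r)^years = target."""
    if years < 1:
        raise SaltsimError(f"years must be >= 1, got {years}")
    if not (0 < target <= baseline_adj_mean):
        raise SaltsimError(
            f"target {target} g/day must be positive and not exceed the "
            f"age-adjusted baseline {baseline_adj_mean:.3f} g/day"
        )
    return 1.0 - (target / baseline_adj_mean) ** (1.0 / years)


def make_scenario(
    params: ModelParameters,
    name: str,
    target_salt: float | None = None,
    years_to_target: int | None = None,
) -> Scenario:
    """Build a scenario from a preset name or an explicit target.

    Presets: ``base`` (status quo), ``8g``, ``6g``, ``5g``.  Explicit targets
    override the preset lookup.  The derived rate uses the two-sex
    age-adjusted baseline salt intake of ``params``.
    """
    years = int(years_to_target or params.horizon_years)
    if target_salt is None and name in PRESET_TARGETS:
        target_salt = PRESET_TARGETS[name]
    if target_salt is None:
        return Scenario(name=name, target_salt=None,
                        years_to_target=years, annual_reduction_rate=0.0)
    baseline = age_adjusted_mean(params.mean_salt, params.std_pop, params.population)
    rate = annual_reduction_rate(baseline, float(target_salt), years)
    return Scenario(name=name, target_salt=float(target_salt),
                    years_to_target=years, annual_reduction_rate=rate)


def build_trajectory(params: ModelParameters, scenario: Scenario) -> pd.DataFrame:
    """Per-stratum mean salt intake for cycle years 1..horizon (g/day).

    Year t mean is baseline x (1 - r)^t: the 2019 observation is year 0 and
    reduction starts in the first cycle, so the age-adjusted mean hits the
    target exactly at ``years_to_target``.
    """
    T = params.horizon_years
    r = scenario.annual_reduction_rate
    factors = (1.0 - r) ** np.arange(1, T + 1)
    traj = pd.DataFrame(
        np.outer(params.mean_salt.to_numpy(), factors),
        index=params.mean_salt.index,
        columns=pd.RangeIndex(1, T + 1, name="year"),
    )
    return traj
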