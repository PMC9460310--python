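"""Salt -> systolic blood pressure -> incidence effect pathway.

Two epidemiological links, applied per stratum and cycle:

* a linear salt-SBP association: dSBP = beta x dSalt, with beta the
  stratum's regression coefficient (mmHg per g/day);
* a log-linear SBP-incidence association: incidence is scaled by
  RR^(dSBP / increment), the standard convention for per-increment
  relative risks (increment 10 mmHg by default).

The change in SBP at cycle t is measured against the 2019 baseline (not
chained year on year; the two are equivalent under log-linearity).  The
multipliers feed *incidence only* — case fatality and mortality never see
them, reflecting the assumption that lowered SBP prevents events but does
not alter survival after onset.
"""

from __future__ import annotations

import pandas as pd

from .params import DISEASES, ModelParameters


def sbp_change(delta_salt: float, beta: float) -> float:
    """Mean SBP change (mmHg) for a salt intake change (g/day): beta x delta."""
    return beta * delta_salt


def incidence_multiplier(delta_sbp: float, rr: float, increment: float = 10.0) -> float:
    """Multiplicative incidence adjustment RR^(delta_sbp / increment).

    Equals 1 at no SBP change and falls below 1 for SBP reductions
    (delta_sbp < 0) whenever rr > 1.
    """
    return rr ** (delta_sbp / increment)


def apply_pathway(
    params: ModelParameters, salt_trajectory: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Map a salt trajectory to SBP trajectories and incidence multipliers.

    Returns ``(sbp_trajectory, multipliers)`` where both are indexed like the
    salt trajectory (strata x cycle years) and ``multipliers`` holds one
    frame per disease.  A base-case trajectory (salt equal to baseline every
    year) yields the baseline SBP and all multipliers exactly 1.
    """
    baseline = params.mean_salt
    beta = params.effects.sbp_per_salt
    delta_salt = salt_trajectory.sub(baseline, axis=0)
    delta_sbp = delta_salt.mul(beta, axis=0)
    sbp_traj = delta_sbp.add(params.mean_sbp, axis=0)

    inc = params.effects.increment_mmhg
    multipliers = {
        d: params.effects.rr_per_increment[d] ** (delta_sbp / inc) for d in DISEASES
    }
    return sbp_traj, multipliers
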