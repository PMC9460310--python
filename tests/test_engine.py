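"""Markov engine: primitives, matrix assembly, propagation, validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import saltsim as ss
from saltsim.engine import EngineError, HealthState

from conftest import ledger_step, make_uniform_params


class TestRateToProbability:
    @pytest.mark.parametrize(
        "rate,expected",
        [
            (0.0, 0.0),
            (0.02, 0.019801326693244747),
            (5.0, 0.9932620530009145),
        ],
    )
    def test_closed_form(self, rate, expected):
        assert ss.rate_to_probability(rate) == pytest.approx(expected, rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(EngineError):
            ss.rate_to_probability(-0.1)

    @given(rate=st.floats(0, 30))
    def test_result_in_unit_interval(self, rate):
        p = ss.rate_to_probability(rate)
        assert 0 <= p < 1


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "year,rate,expected",
        [
            (1, 0.02, 1.0),
            (1, 0.0, 1.0),
            (2, 0.02, 0.9803921568627451),
            (10, 0.02, 0.8367552658726582),
        ],
    )
    def test_first_cycle_undiscounted_convention(self, year, rate, expected):
        assert ss.discount_factor(year, rate) == pytest.approx(expected, rel=1e-12)

    def test_invalid_cycle_rejected(self):
        with pytest.raises(EngineError):
            ss.discount_factor(0, 0.02)


class TestOtherCauseMortality:
    def test_subtraction(self):
        assert ss.other_cause_mortality(0.010, 0.001, 0.002) == (
            pytest.approx(0.007), False)

    def test_floor_flag(self):
        rate, floored = ss.other_cause_mortality(0.010, 0.012, 0.000)
        assert rate == 0.0 and floored

    def test_all_zero(self):
        assert ss.other_cause_mortality(0.0, 0.0, 0.0) == (0.0, False)


class TestInitialStateVector:
    def test_zero_prevalence_all_healthy(self):
        v = ss.initial_state_vector(500, 0.0, 0.0)
        assert v[HealthState.HEALTHY] == 500 and v.sum() == 500

    def test_hand_arithmetic(self):
        v = ss.initial_state_vector(1000, 0.1, 0.2)
        assert list(v) == [700, 100, 200, 0, 0, 0]

    def test_prevalences_summing_to_one_rejected(self):
        with pytest.raises(EngineError):
            ss.initial_state_vector(1000, 0.6, 0.4)

    @given(
        n=st.floats(1, 1e7),
        p1=st.floats(0, 0.45),
        p2=st.floats(0, 0.45),
    )
    def test_conservation(self, n, p1, p2):
        assert ss.initial_state_vector(n, p1, p2).sum() == pytest.approx(n)


class TestSplitIncidentEvents:
    def test_zero_incidence_yields_no_events(self):
        out = ss.split_incident_events(0.0, 1.0, 0.8, 700, 100, 1000)
        assert out == (0.0, 0.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        """Alive 1000 (700 healthy, 100 chronic), event prob 0.01, f=0.8."""
        rate = -np.log(0.99)  # makes the one-cycle probability exactly 0.01
        first, rec, p_first, p_rec = ss.split_incident_events(
            rate, 1.0, 0.8, 700, 100, 1000
        )
        assert first == pytest.approx(8.0)
        assert rec == pytest.approx(2.0)
        assert p_first == pytest.approx(8 / 700)
        assert p_rec == pytest.approx(0.02)

    def test_all_first_ever_when_f_is_one(self):
        first, rec, p_first, p_rec = ss.split_incident_events(
            0.05, 1.0, 1.0, 700, 100, 1000
        )
        assert rec == 0.0 and p_rec == 0.0 and first > 0

    def test_events_exceeding_source_occupancy_rejected(self):
        # nearly all events recurrent but the chronic state holds 1 person
        with pytest.raises(EngineError, match="recurrent"):
            ss.split_incident_events(0.5, 1.0, 0.1, 600, 1, 1000, label="toy")


class TestBuildTransitionMatrix:
    @staticmethod
    def _zeros():
        z = {"ihd": 0.0, "stroke": 0.0}
        return dict(p_first=dict(z), p_recurrent=dict(z), case_fatality=dict(z))

    def test_no_events_no_deaths_is_identity(self):
        m = ss.build_transition_matrix(**self._zeros(), p_other=0.0)
        assert np.array_equal(m, np.eye(6))

    def test_healthy_row_hand_assembly(self):
        """First-ever IHD 0.01, case fatality 0.2, other-cause 0.005.

        Events are drawn first; other-cause mortality hits the 0.99
        non-event remainder: DEAD_IHD 0.002, CHRONIC_IHD 0.008,
        DEAD_OTHER 0.99 x 0.005, stay 0.99 x 0.995.
        """
        m = ss.build_transition_matrix(
            p_first={"ihd": 0.01, "stroke": 0.0},
            p_recurrent={"ihd": 0.0, "stroke": 0.0},
            case_fatality={"ihd": 0.2, "stroke": 0.0},
            p_other=0.005,
        )
        h = HealthState.HEALTHY
        assert m[h, HealthState.DEAD_IHD] == pytest.approx(0.002)
        assert m[h, HealthState.CHRONIC_IHD] == pytest.approx(0.008)
        assert m[h, HealthState.DEAD_OTHER] == pytest.approx(0.99 * 0.005)
        assert m[h, h] == pytest.approx(0.99 * 0.995)

    def test_dead_rows_are_identity_and_no_reentry_to_healthy(self):
        m = ss.build_transition_matrix(
            p_first={"ihd": 0.02, "stroke": 0.01},
            p_recurrent={"ihd": 0.05, "stroke": 0.04},
            case_fatality={"ihd": 0.3, "stroke": 0.1},
            p_other=0.01,
        )
        for s in (HealthState.DEAD_IHD, HealthState.DEAD_STROKE, HealthState.DEAD_OTHER):
            assert m[s, s] == 1.0 and m[s].sum() == 1.0
        assert (m[1:, HealthState.HEALTHY] == 0).all()
        # no cross-disease chronic transitions
        assert m[HealthState.CHRONIC_IHD, HealthState.CHRONIC_STROKE] == 0
        assert m[HealthState.CHRONIC_STROKE, HealthState.CHRONIC_IHD] == 0

    @given(
        pfi=st.floats(0, 0.4), pfs=st.floats(0, 0.4),
        pri=st.floats(0, 1), prs=st.floats(0, 1),
        cfi=st.floats(0, 1), cfs=st.floats(0, 1),
        po=st.floats(0, 1),
    )
    def test_row_stochasticity_over_random_valid_inputs(
        self, pfi, pfs, pri, prs, cfi, cfs, po
    ):
        m = ss.build_transition_matrix(
            p_first={"ihd": pfi, "stroke": pfs},
            p_recurrent={"ihd": pri, "stroke": prs},
            case_fatality={"ihd": cfi, "stroke": cfs},
            p_other=po,
        )
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert (m >= 0).all() and (m <= 1).all()


class TestRunCohort:
    def test_no_events_no_deaths_is_static(self):
        p = make_uniform_params(
            incidence_ihd=0.0, incidence_stroke=0.0,
            mortality_ihd=0.0, mortality_stroke=0.0, all_cause=0.0,
        )
        traj = ss.run_cohort(p, ss.make_scenario(p, "base"))
        occ = traj.occupancy
        for cycle in range(p.horizon_years + 1):
            pd.testing.assert_frame_equal(
                occ.xs(cycle, level="cycle"), occ.xs(0, level="cycle")
            )
        t = traj.tallies.sum()
        assert t[["deaths_ihd", "deaths_stroke", "deaths_other"]].sum() == 0
        assert (t[[c for c in t.index if c.startswith("inpatient")]] == 0).all()
        assert (t[[c for c in t.index if c.startswith("outpatient")]] > 0).all()

    def test_one_cycle_hand_ledger(self):
        """N=1000 per stratum, one cycle, every flow checked by hand."""
        p = make_uniform_params(
            population=1000, prev_ihd=0.1, prev_stroke=0.2,
            incidence_ihd=-np.log(0.99), incidence_stroke=0.0,
            mortality_ihd=0.0, mortality_stroke=0.0,
            all_cause=-np.log(0.995),  # one-cycle other-cause prob exactly 0.005
            first_ever=0.8, case_fatality=0.2,
            outpatient=100.0, inpatient=1000.0,
            horizon=1, discount_rate=0.02,
        )
        traj = ss.run_cohort(p, ss.make_scenario(p, "base"))
        s = ("male", "40-49")
        # events: E = 0.01 * 1000 = 10; 8 first-ever from 700, 2 recurrent from 100
        t = traj.tallies.loc[(*s, 1)]
        assert t["first_ever_ihd"] == pytest.approx(8.0)
        assert t["recurrent_ihd"] == pytest.approx(2.0)
        assert t["deaths_ihd"] == pytest.approx(2.0)  # 10 x 0.2
        # other-cause deaths: non-event alive (1000 - 10) x 0.005
        assert t["deaths_other"] == pytest.approx(990 * 0.005)
        # costs: outpatient on cycle-start chronic occupancy; inpatient per event
        assert t["outpatient_ihd"] == pytest.approx(100 * 100.0)
        assert t["outpatient_stroke"] == pytest.approx(200 * 100.0)
        assert t["inpatient_ihd"] == pytest.approx(10 * 1000.0)
        assert t["inpatient_ihd_disc"] == t["inpatient_ihd"]  # cycle 1 undiscounted
        # occupancies after the cycle
        v = traj.occupancy.loc[(*s, 1)]
        assert v["HEALTHY"] == pytest.approx((700 - 8) * 0.995)
        assert v["CHRONIC_IHD"] == pytest.approx((100 - 2) * 0.995 + 10 * 0.8)
        assert v["CHRONIC_STROKE"] == pytest.approx(200 * 0.995)
        assert v["DEAD_IHD"] == pytest.approx(2.0)
        assert v["DEAD_OTHER"] == pytest.approx(990 * 0.005)
        assert v.sum() == pytest.approx(1000.0)

    def test_null_scenario_reproduces_base_case_exactly(self, default_params):
        p = default_params
        baseline = ss.age_adjusted_mean(p.mean_salt, p.std_pop, p.population)
        null = ss.make_scenario(p, "null", target_salt=baseline)
        assert null.annual_reduction_rate == 0.0
        base_traj = ss.run_cohort(p, ss.make_scenario(p, "base"))
        null_traj = ss.run_cohort(p, null)
        assert (base_traj.occupancy.to_numpy()
                == null_traj.occupancy.to_numpy()).all()
        assert (base_traj.tallies.to_numpy()
                == null_traj.tallies.to_numpy()).all()

    def test_conservation_and_absorption(self, default_params, base_trajectory):
        occ = base_trajectory.occupancy
        n0 = default_params.population
        for stratum in n0.index:
            sub = occ.loc[stratum]
            totals = sub.sum(axis=1).to_numpy()
            assert np.allclose(totals, float(n0[stratum]), rtol=1e-9)
            dead = sub[["DEAD_IHD", "DEAD_STROKE", "DEAD_OTHER"]].to_numpy()
            assert (np.diff(dead, axis=0) >= -1e-9).all()

    def test_matrix_propagation_matches_flow_ledger(self, uniform_params):
        p = uniform_params
        traj = ss.run_cohort(p, ss.make_scenario(p, "base"))
        s = ("female", "60-69")
        inc = float(p.epi["ihd"].incidence[s])
        q = ss.rate_to_probability(
            float(p.all_cause_mortality[s])
            - float(p.epi["ihd"].disease_mortality[s])
            - float(p.epi["stroke"].disease_mortality[s])
        )
        v = traj.occupancy.loc[(*s, 0)].to_numpy()
        for cycle in range(1, p.horizon_years + 1):
            alive = v[:3].sum()
            p_first, p_rec = {}, {}
            for d, cstate in (("ihd", 1), ("stroke", 2)):
                _, _, p_first[d], p_rec[d] = ss.split_incident_events(
                    float(p.epi[d].incidence[s]), 1.0,
                    float(p.epi[d].prop_first_ever[s]),
                    v[0], v[cstate], alive,
                )
            cf = {d: float(p.epi[d].case_fatality_28d[s]) for d in ss.DISEASES}
            v = ledger_step(v, p_first, p_rec, cf, q)
            engine_v = traj.occupancy.loc[(*s, cycle)].to_numpy()
            np.testing.assert_allclose(engine_v, v, rtol=1e-12, atol=1e-9)

    def test_discounting_contract(self):
        p0 = make_uniform_params(discount_rate=0.0)
        p2 = make_uniform_params(discount_rate=0.02)
        t0 = ss.run_cohort(p0, ss.make_scenario(p0, "base")).tallies.sum()
        t2 = ss.run_cohort(p2, ss.make_scenario(p2, "base")).tallies.sum()
        for col in ("outpatient_ihd", "inpatient_stroke"):
            assert t0[f"{col}_disc"] == pytest.approx(t0[col], rel=1e-12)
            assert t2[f"{col}_disc"] < t2[col]

    def test_floored_strata_are_reported(self):
        p = make_uniform_params(all_cause=0.0005, mortality_ihd=0.001)
        traj = ss.run_cohort(p, ss.make_scenario(p, "base"))
        assert len(traj.floored_strata) == 8


class TestValidateFirstCycle:
    def test_reference_matches(self, default_params, base_trajectory):
        ref = ss.generate_reference_expenditures(default_params)
        assert ss.validate_first_cycle(base_trajectory, ref) == []

    def test_perturbed_cell_is_detected_exactly(self, default_params, base_trajectory):
        ref = ss.generate_reference_expenditures(default_params)
        ref.loc[("stroke", "female"), "inpatient"] *= 1.01
        failures = ss.validate_first_cycle(base_trajectory, ref)
        assert [(f.disease, f.sex, f.care_type) for f in failures] == [
            ("stroke", "female", "inpatient")
        ]

    def test_zero_costs_validate_against_zero_reference(self):
        p = make_uniform_params(outpatient=0.0, inpatient=0.0)
        traj = ss.run_cohort(p, ss.make_scenario(p, "base"))
        ref = ss.generate_reference_expenditures(p)
        assert ss.validate_first_cycle(traj, ref) == []

    def test_shape_mismatch_rejected(self, default_params, base_trajectory):
        ref = ss.generate_reference_expenditures(default_params)
        with pytest.raises(ss.SaltsimError, match="cover"):
            ss.validate_first_cycle(base_trajectory, ref.iloc[:2])
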