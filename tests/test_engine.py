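"""Cohort engine: state space, transitions, accrual, and comparisons."""

import dataclasses

import numpy as np
import pytest

from mammocea.engine import (
    CohortState,
    annual_transition,
    break_even_age,
    build_state_space,
    compare_arms,
    run_arm,
    screening_event,
    _empty_row,
)
from mammocea.lifetables import synth_lifetable, synth_post75_incidence
from mammocea.params import CostParams, EconomicSettings, ParameterError


def zero_risk_arm(aidm):
    return dataclasses.replace(
        aidm,
        detection_biennial={"40_54": 0.0, "55_74": 0.0},
        interval_annual={"40_54": 0.0, "55_74": 0.0},
    )


class TestStateSpace:
    @pytest.mark.parametrize("max_tunnel,expected", [(9, 48), (1, 8), (10, 53)])
    def test_state_count(self, max_tunnel, expected):
        assert build_state_space(max_tunnel).n_states == expected

    def test_indices_dense_and_unique(self):
        sp = build_state_space(9)
        idx = [sp.healthy]
        for stage in ("0", "I", "II", "III"):
            idx += [sp.cancer(stage, t) for t in range(1, 10)]
        idx += [sp.metastatic(t) for t in range(1, 10)]
        idx += [sp.dead_bc, sp.dead_other]
        assert sorted(idx) == list(range(sp.n_states))

    def test_tunnel_year_caps_at_max(self):
        sp = build_state_space(9)
        assert sp.cancer("I", 15) == sp.cancer("I", 9)
        assert sp.metastatic(15) == sp.metastatic(9)


class TestScreeningEvent:
    def test_detected_mass_follows_stage_distribution(self, aidm, cancer, costs, settings):
        sp = build_state_space(9)
        cohort = CohortState.initial(sp, settings)
        cohort.age = 56  # 55-74 band
        row = _empty_row(56, 16)
        screening_event(cohort, aidm, cancer, costs, row, 1.0)
        detected = 1000 * aidm.detection_biennial["55_74"]
        assert row["new_screen_cancers"] == pytest.approx(detected)
        dist = cancer.stage_dist("screening", "55_74")
        assert cohort.occupancy[sp.cancer("I", 1)] == pytest.approx(
            detected * dist.prob("I")
        )
        assert dist.prob("I") == pytest.approx(0.624, abs=0.001)
        assert cohort.occupancy[sp.metastatic(1)] == pytest.approx(
            detected * dist.prob("IV")
        )
        assert cohort.occupancy.sum() == pytest.approx(1000)

    def test_zero_detection_keeps_cohort_but_costs_accrue(
        self, aidm, cancer, costs, settings
    ):
        sp = build_state_space(9)
        cohort = CohortState.initial(sp, settings)
        arm = zero_risk_arm(aidm)
        row = _empty_row(40, 0)
        screening_event(cohort, arm, cancer, costs, row, 1.0)
        assert cohort.occupancy[sp.healthy] == 1000
        assert row["cost_mammography"] == pytest.approx(30.5 * 1000)
        assert row["cost_ai"] == pytest.approx(1.9 * 1000)

    def test_reading_count_accounting(self, aidm, cdm, cancer, costs, settings):
        """16,970 exams and 679 conferences imply 23,419 human readings
        under the AI triage policy (70% single, 30% double, two readers
        per conference)."""
        exams, conferences = 16_970, 679
        reads = (aidm.human_read_share + aidm.double_read_share) * exams
        reads += 2 * conferences
        assert reads == pytest.approx(23_419, abs=1)
        # conventional policy: every exam read twice
        reads_cdm = (cdm.human_read_share + cdm.double_read_share) * 16_953
        reads_cdm += 2 * 661
        assert reads_cdm == pytest.approx(35_228, abs=1)

    def test_non_screening_age_rejected(self, aidm, cancer, costs, settings):
        cohort = CohortState.initial(build_state_space(9), settings)
        cohort.age = 41
        with pytest.raises(ParameterError):
            screening_event(cohort, aidm, cancer, costs, _empty_row(41, 1), 1.0)


class TestAnnualTransition:
    @pytest.fixture
    def quiet_world(self, aidm):
        """No background mortality, no incidence."""
        lt = synth_lifetable(a=1e-12, b=0.0)
        inc = synth_post75_incidence(level=0.0)
        return zero_risk_arm(aidm), lt, inc

    def test_stage_iii_year2_metastasis_flow(self, quiet_world, cancer, settings):
        arm, lt, inc = quiet_world
        sp = build_state_space(9)
        cohort = CohortState.initial(sp, settings)
        cohort.occupancy[:] = 0
        cohort.occupancy[sp.cancer("III", 2)] = 100.0
        annual_transition(cohort, arm, cancer, lt, inc, _empty_row(50, 10))
        # 7.6% progress; the new arrivals face the year-1 metastatic death
        # risk within the same cycle (substeps are sequential)
        assert cohort.occupancy[sp.cancer("III", 2)] == pytest.approx(92.4, abs=1e-6)
        moved = cohort.occupancy[sp.metastatic(1)] + cohort.occupancy[sp.dead_bc]
        assert moved == pytest.approx(7.6, abs=1e-6)
        assert cohort.occupancy[sp.metastatic(1)] == pytest.approx(
            7.6 * (1 - 0.368), abs=1e-6
        )

    def test_metastatic_year1_death_flow(self, quiet_world, cancer, settings):
        arm, lt, inc = quiet_world
        sp = build_state_space(9)
        cohort = CohortState.initial(sp, settings)
        cohort.occupancy[:] = 0
        cohort.occupancy[sp.metastatic(1)] = 100.0
        annual_transition(cohort, arm, cancer, lt, inc, _empty_row(50, 10))
        assert cohort.occupancy[sp.dead_bc] == pytest.approx(36.8, abs=1e-6)

    def test_zero_risk_identity(self, quiet_world, settings, cancer):
        arm, lt, inc = quiet_world
        sp = build_state_space(9)
        cohort = CohortState.initial(sp, settings)
        before = cohort.occupancy.copy()
        annual_transition(cohort, arm, cancer, lt, inc, _empty_row(50, 10))
        np.testing.assert_allclose(cohort.occupancy, before, atol=1e-6)

    def test_other_cause_death_hits_all_alive_states(self, aidm, cancer, settings):
        lt = synth_lifetable(a=0.1, b=0.0)  # constant qx = 0.1
        inc = synth_post75_incidence(level=0.0)
        arm = zero_risk_arm(aidm)
        sp = build_state_space(9)
        cohort = CohortState.initial(sp, settings)
        cohort.occupancy[:] = 0
        cohort.occupancy[sp.healthy] = 500.0
        cohort.occupancy[sp.cancer("II", 3)] = 300.0
        cohort.occupancy[sp.metastatic(9)] = 200.0
        annual_transition(cohort, arm, cancer, lt, inc, _empty_row(50, 10))
        assert cohort.occupancy[sp.dead_other] == pytest.approx(100.0)


class TestRunArm:
    def test_mass_conserved_every_cycle(self, base_fit, settings):
        df = base_fit.arm_result.trace.to_frame()
        # alive + cumulative deaths must equal the cohort; the engine
        # asserts conservation at 1e-9 internally every cycle, so a
        # completed run is itself the evidence
        assert len(df) == settings.terminal_age - settings.start_age + 1
        assert (df["alive"] <= settings.cohort_size + 1e-9).all()
        assert (df["alive"].diff().dropna() <= 1e-9).all()  # no resurrection

    def test_discounted_cost_not_above_undiscounted(self, base_fit):
        for res in (base_fit.arm_result, base_fit.comparator_result):
            for r in res.trace.rows[1:]:
                assert r["cost_total"] <= r["cost_undiscounted"] + 1e-9

    def test_zero_risk_qalys_match_closed_form(
        self, aidm, cancer, utilities, settings, costs
    ):
        lt = synth_lifetable()
        inc = synth_post75_incidence(level=0.0)
        arm = zero_risk_arm(aidm)
        res = run_arm(arm, cancer, lt, utilities, inc, settings, costs)
        expected = 0.0
        survivors = settings.cohort_size
        for cycle, age in enumerate(range(40, 111)):
            survivors *= 1 - lt.qx_at(age)
            expected += (
                survivors * utilities.weight_at(age) * 1.03 ** (-cycle)
            )
        assert res.total_qaly == pytest.approx(expected, rel=1e-9)

    def test_zero_cost_arm_costs_nothing(self, aidm, cancer, utilities, settings):
        lt = synth_lifetable()
        inc = synth_post75_incidence(level=0.0)
        free = CostParams(
            invitation=0, mammography=0, radiologist_hourly=1e-9,
            ai_licence_per_exam=0, conference_unit=0, recall_unit=0,
        )
        arm = dataclasses.replace(zero_risk_arm(aidm), reading_unit_cost=0.0)
        res = run_arm(arm, cancer, lt, utilities, inc, settings, free)
        assert res.total_cost == 0.0

    def test_raising_stage_cost_raises_total_cost(self, base_model):
        import mammocea.params as p

        res0 = base_model.fit()
        bumped = dict(base_model.cancer.tunnels)
        s2 = bumped["II"]
        bumped["II"] = dataclasses.replace(
            s2, cost_by_year=tuple(c + 1000 for c in s2.cost_by_year)
        )
        cancer2 = p.CancerParams(base_model.cancer.stage_distributions, bumped)
        model2 = dataclasses.replace(base_model, cancer=cancer2)
        res1 = model2.fit()
        assert res1.arm_result.total_cost > res0.arm_result.total_cost
        assert res1.arm_result.total_qaly == res0.arm_result.total_qaly

    def test_raising_detection_raises_detected_counts(self, base_model):
        res0 = base_model.fit()
        arm2 = dataclasses.replace(
            base_model.arm,
            detection_biennial={
                b: min(1.0, 1.5 * v)
                for b, v in base_model.arm.detection_biennial.items()
            },
        )
        model2 = dataclasses.replace(base_model, arm=arm2)
        res1 = model2.fit()
        assert (
            res1.arm_result.counts["new_screen_cancers"]
            > res0.arm_result.counts["new_screen_cancers"]
        )


class TestComparison:
    def test_identical_arms_are_a_wash(self, base_model):
        res = base_model.fit()
        inc = compare_arms(res.comparator_result, res.comparator_result)
        assert inc.incremental_cost == 0.0
        assert inc.incremental_qaly == 0.0
        assert inc.icer is None
        assert inc.break_even_age == 40  # tie rule: cumulative 0 at start

    def test_quadrant_labels(self, base_fit):
        inc = compare_arms(base_fit.arm_result, base_fit.comparator_result)
        rev = compare_arms(base_fit.comparator_result, base_fit.arm_result)
        assert inc.label == "dominant"
        assert rev.label == "dominated"
        assert rev.incremental_cost == -inc.incremental_cost

    def test_icer_is_ratio(self, base_fit):
        inc = base_fit.incremental
        assert inc.icer == pytest.approx(
            inc.incremental_cost / inc.incremental_qaly
        )

    def test_break_even_strictly_cheaper_arm(self, base_fit):
        a = base_fit.arm_result.trace
        b = base_fit.comparator_result.trace
        # against a comparator with every cost doubled, the arm is cheaper
        # from the first cycle
        import copy

        b2 = copy.deepcopy(a)
        for r in b2.rows:
            r["cost_total"] *= 2
        assert break_even_age(a, b2) == 40
        # reversed: never breaks even
        assert break_even_age(b2, a) is None
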