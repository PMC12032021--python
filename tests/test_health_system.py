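import collections
import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

import mnhsim as m
from mnhsim.health_system import ServiceOverrides, indicated_interventions
from mnhsim.params import CareSeekingModel, InterventionSpec
from mnhsim.rand import KeyedRng, RandomSource

JAN = dt.date(2023, 1, 15)


class TestCareSeekingProbability:
    def test_null_model_gives_half(self, woman):
        model = CareSeekingModel("anc_start", intercept=0.0)
        assert m.careseeking_probability(model, woman) == pytest.approx(0.5)

    def test_intercept_only_closed_form(self, woman):
        model = CareSeekingModel("anc_start", intercept=1.3)
        assert m.careseeking_probability(model, woman) == pytest.approx(
            1.0 / (1.0 + math.exp(-1.3)))

    def test_covariates_shift_probability(self, params, woman):
        model = params.careseeking["facility_delivery"]
        base = m.careseeking_probability(model, woman)
        woman.wealth_quintile = 5
        woman.education_level = 2
        assert m.careseeking_probability(model, woman) > base


class TestAncSchedule:
    def test_zero_transition_gives_single_visit(self, params, woman):
        import copy

        ps = copy.deepcopy(params)
        ps.anc_transition_prob = 0.0
        sched = m.plan_anc_schedule(woman, ps, KeyedRng(RandomSource(1), woman.id, 0))
        assert len(sched) == 1

    def test_certain_transitions_from_month_two_reach_eight_contacts(self, params, woman):
        import copy

        ps = copy.deepcopy(params)
        ps.anc_transition_prob = 1.0
        ps.anc_first_visit_month_dist = {2: 1.0}
        sched = m.plan_anc_schedule(woman, ps, KeyedRng(RandomSource(1), woman.id, 0))
        assert [k for k, _ in sched] == list(range(1, 9))
        assert [month for _, month in sched] == list(range(2, 10))

    def test_visit_count_distribution_matches_markov_chain(self, params, woman):
        """Observed visit counts vs the direct geometric-chain computation."""
        import copy

        ps = copy.deepcopy(params)
        tp = 0.7
        ps.anc_transition_prob = tp
        ps.anc_first_visit_month_dist = {2: 1.0}
        n = 6000
        rs = RandomSource(9)
        counts = collections.Counter(
            len(m.plan_anc_schedule(woman, ps, KeyedRng(rs, i, 0))) for i in range(n))
        for k in range(1, 9):
            p_k = tp ** (k - 1) * (1 - tp) if k < 8 else tp ** 7
            lo, hi = binom.ppf([0.005, 0.995], n, p_k)
            assert lo <= counts[k] <= hi, f"count {k}: {counts[k]} outside [{lo},{hi}]"


class TestEmergencyCareseeking:
    def test_degenerate_probabilities(self):
        rng = np.random.default_rng(0)
        assert m.emergency_careseeking(rng, 1.0) is True
        assert m.emergency_careseeking(rng, 0.0) is False

    def test_frequency_within_binomial_bounds(self):
        n, p = 10_000, 0.7
        rs = RandomSource(3)
        hits = sum(m.emergency_careseeking(KeyedRng(rs, i, 0), p) for i in range(n))
        lo, hi = binom.ppf([0.005, 0.995], n, p)
        assert lo <= hits <= hi


class TestSqueezeAndDelays:
    def test_equality_case(self):
        assert m.compute_squeeze_factor(60, 60) == 0.0

    def test_fourfold_demand_is_the_delay_three_boundary(self):
        assert m.compute_squeeze_factor(240, 60) == 3.0

    def test_under_demand_is_negative(self):
        assert m.compute_squeeze_factor(30, 60) == -0.5

    def test_degenerate_budget_rejected(self):
        with pytest.raises(ValueError):
            m.compute_squeeze_factor(10, 0)

    @settings(max_examples=100, deadline=None)
    @given(req=st.floats(0, 1e4), avail=st.floats(0.01, 1e4))
    def test_formula_matches_oracle(self, req, avail):
        assert m.compute_squeeze_factor(req, avail) == pytest.approx(req / avail - 1.0)

    def test_delay_three_strict_inequality(self):
        rng = np.random.default_rng(0)
        assert m.assess_delays(rng, 0, 0, 3.01, 3.0)[2] is True
        assert m.assess_delays(rng, 0, 0, 3.0, 3.0)[2] is False
        assert m.assess_delays(rng, 0, 0, 3.01, 3.0, d3_disabled=True)[2] is False

    def test_all_zero_inputs_give_no_delays(self):
        rng = np.random.default_rng(0)
        assert m.assess_delays(rng, 0.0, 0.0, 0.0, 3.0) == (False, False, False)

    def test_delay_one_frequency(self):
        n = 10_000
        rs = RandomSource(4)
        hits = sum(m.assess_delays(KeyedRng(rs, i, 0), 0.5, 0.0, 0.0, 3.0)[0]
                   for i in range(n))
        lo, hi = binom.ppf([0.005, 0.995], n, 0.5)
        assert lo <= hits <= hi


class TestInterventionDelivery:
    def _spec(self, **kw):
        base = dict(name="x", klass="curative", hsi_types=("pnc_maternal",),
                    competence_prob=1.0, consumable_availability={},
                    treatment_rr=0.5)
        base.update(kw)
        return InterventionSpec(**base)

    def test_perfect_factors_always_deliver(self, params):
        spec = self._spec(consumable_availability={"drug": 1.0})
        rng = np.random.default_rng(0)
        assert all(m.attempt_intervention_delivery(spec, params, rng)
                   for _ in range(50))

    def test_zero_competence_never_delivers(self, params):
        spec = self._spec(competence_prob=0.0)
        rng = np.random.default_rng(0)
        assert not any(m.attempt_intervention_delivery(spec, params, rng)
                       for _ in range(50))

    def test_product_of_independent_factors(self, params):
        spec = self._spec(consumable_availability={"drug": 0.8}, competence_prob=0.9)
        rs = RandomSource(5)
        n = 10_000
        hits = sum(m.attempt_intervention_delivery(spec, params, KeyedRng(rs, i, 0))
                   for i in range(n))
        lo, hi = binom.ppf([0.005, 0.995], n, 0.72)
        assert lo <= hits <= hi

    def test_emonc_staffing_is_an_extra_factor(self, params):
        import copy

        ps = copy.deepcopy(params)
        ps.emonc_staffing_prob = 0.0
        spec = self._spec(emonc_class="BEmONC")
        rng = np.random.default_rng(0)
        assert not any(m.attempt_intervention_delivery(spec, ps, rng)
                       for _ in range(50))

    def test_fixed_probability_override_replaces_product(self, params):
        spec = self._spec(competence_prob=0.0)
        ov = ServiceOverrides(fixed_delivery_prob={"delivery:BEmONC": 1.0})
        rng = np.random.default_rng(0)
        assert m.attempt_intervention_delivery(spec, params, rng, overrides=ov,
                                               quality_key="delivery:BEmONC")
        ov.fixed_delivery_prob["delivery:BEmONC"] = 0.0
        spec2 = self._spec(competence_prob=1.0)
        assert not m.attempt_intervention_delivery(spec2, params, rng, overrides=ov,
                                                   quality_key="delivery:BEmONC")

    def test_quality_max_pins_every_factor(self, params):
        spec = self._spec(consumable_availability={"drug": 0.0}, competence_prob=0.0,
                          emonc_class="CEmONC")
        ov = ServiceOverrides(quality_max={"pnc"})
        rng = np.random.default_rng(0)
        assert m.attempt_intervention_delivery(spec, params, rng, overrides=ov,
                                               service="pnc")


class TestExecuteHsi:
    def test_uncomplicated_anc_contact_delivers_preventatives_in_12_minutes(
            self, params, woman):
        woman.is_pregnant = True
        woman.gestational_age = 120
        woman.parity = 0
        ov = ServiceOverrides(quality_max={"anc"})
        ev = m.execute_hsi("anc", woman, params, None,
                           KeyedRng(RandomSource(1), woman.id, 0),
                           overrides=ov, date=JAN)
        assert ev.required_minutes == {"nurse_midwife": 12.0}
        delivered = set(ev.delivered_interventions)
        assert {"iron_folic_acid", "iptp_malaria", "calcium_supplementation"} <= delivered
        assert "iron_folic_acid" in woman._preventions

    def test_uncomplicated_delivery_attempts_only_prophylaxis(self, params, woman):
        woman.is_pregnant = True
        woman.gestational_age = 270
        woman.labour_state = "term"
        ev = m.execute_hsi("delivery_bemonc", woman, params, None,
                           KeyedRng(RandomSource(2), woman.id, 0), date=JAN)
        attempted = set(ev.attempted_interventions)
        assert attempted <= {"clean_birth_practices", "amtsl"}
        assert "avd" not in attempted and "uterotonics" not in attempted

    def test_intervention_never_delivered_without_indication(self, params, woman):
        woman.is_pregnant = True
        woman.gestational_age = 270
        woman.labour_state = "term"
        specs = indicated_interventions("delivery_bemonc", woman, params)
        assert all(s.klass != "curative" for s in specs)
        woman.active_conditions["obstructed_labour"] = JAN
        specs = indicated_interventions("delivery_bemonc", woman, params)
        assert "avd" in {s.name for s in specs}

    def test_exhausted_ledger_still_runs_with_delay_three(self, params, woman):
        woman.postnatal_week = 1
        woman.active_conditions["sepsis_postnatal"] = JAN
        ledger = m.HcwLedger(params, population_size=1000)
        day = JAN
        ledger.remaining_for(day)
        for key in ledger.remaining_for(day):
            ledger.remaining_for(day)[key] = 0.0
        ev = m.execute_hsi("pnc_maternal", woman, params, ledger,
                           KeyedRng(RandomSource(3), woman.id, 0), date=day)
        assert math.isinf(ev.squeeze)
        assert ev.delays[2] is True

    def test_sequential_depletion_reproducible_squeeze(self, params):
        ledger = m.HcwLedger(params, population_size=1000)
        budget = ledger.daily_budget[("health-centre", "nurse_midwife")]
        s1 = ledger.request("health-centre", {"nurse_midwife": budget}, day=JAN)
        assert s1 == pytest.approx(0.0)
        s2 = ledger.request("health-centre", {"nurse_midwife": budget}, day=JAN)
        assert math.isinf(s2)
        # a different day has a fresh budget
        s3 = ledger.request("health-centre", {"nurse_midwife": budget},
                            day=JAN + dt.timedelta(days=1))
        assert s3 == pytest.approx(0.0)

    def test_unknown_hsi_type_rejected(self, params, woman):
        with pytest.raises(ValueError):
            m.execute_hsi("outpatient_x", woman, params, None,
                          KeyedRng(RandomSource(1), woman.id, 0))

    def test_screening_marks_detection_enabling_treatment(self, params, woman):
        woman.is_pregnant = True
        woman.gestational_age = 180
        woman.active_conditions["gestational_diabetes"] = JAN
        ov = ServiceOverrides(quality_max={"anc", "inpatient_antenatal"})
        m.execute_hsi("anc", woman, params, None,
                      KeyedRng(RandomSource(5), woman.id, 0), overrides=ov, date=JAN)
        assert "gestational_diabetes" in woman._detected
        m.execute_hsi("inpatient_antenatal", woman, params, None,
                      KeyedRng(RandomSource(5), woman.id, 1), overrides=ov, date=JAN)
        assert woman._treatments.get("gestational_diabetes")
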