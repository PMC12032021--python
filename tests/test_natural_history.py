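import copy
import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

import mnhsim as m
from mnhsim.natural_history import (
    apply_phase_onsets,
    effective_onset_probability,
    gestational_month,
    onset_probability,
)
from mnhsim.rand import KeyedRng, RandomSource

JAN = dt.date(2023, 1, 1)


def make_pregnant(woman, gest_days=0):
    woman.is_pregnant = True
    woman.gestational_age = gest_days
    woman.postnatal_week = None
    return woman


class TestOnsetProbability:
    def test_multiplicative_modifier(self):
        assert onset_probability(0.01, [2.0]) == pytest.approx(0.02)

    def test_clipped_at_one(self):
        assert onset_probability(0.6, [2.0]) == 1.0

    def test_identity_with_no_modifiers(self):
        assert onset_probability(0.37, []) == 0.37

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            onset_probability(0.1, [0.0])

    @settings(max_examples=100, deadline=None)
    @given(b=st.floats(0, 1), rrs=st.lists(st.floats(0.01, 50), max_size=5))
    def test_result_always_a_probability(self, b, rrs):
        assert 0.0 <= onset_probability(b, rrs) <= 1.0


class TestLabourCategory:
    @pytest.mark.parametrize("weeks,expected", [
        (34, "preterm"), (36.9, "preterm"), (37, "term"), (39, "term"),
        (41.9, "term"), (42, "post-term"), (43, "post-term"),
    ])
    def test_standard_cutpoints(self, weeks, expected):
        assert m.determine_labour_category(int(weeks * 7)) == expected


class TestAntenatalCycle:
    def test_zero_baselines_only_advance_gestation(self, params, woman):
        ps = copy.deepcopy(params)
        for c in ps.conditions:
            c.baseline_risk = 0.0
        make_pregnant(woman, 60)
        before = dict(woman.active_conditions)
        out = m.apply_antenatal_cycle(woman, ps, KeyedRng(RandomSource(1), woman.id, 0))
        assert woman.gestational_age == 90
        assert woman.active_conditions == before
        assert out["ended"] is None

    def test_antenatal_stillbirth_ends_pregnancy_without_livebirth(self, params, woman):
        ps = copy.deepcopy(params)
        for c in ps.conditions:
            c.baseline_risk = 1.0 if c.name == "antenatal_stillbirth" else 0.0
        make_pregnant(woman, 150)  # month 6, inside the stillbirth window
        out = m.apply_antenatal_cycle(woman, ps, KeyedRng(RandomSource(1), woman.id, 0))
        assert out["ended"] == "antenatal_stillbirth"
        assert "antenatal_stillbirth" not in woman.active_conditions  # fetal, not morbidity

    def test_requires_pregnancy(self, params, woman):
        with pytest.raises(ValueError):
            m.apply_antenatal_cycle(woman, params, KeyedRng(RandomSource(1), woman.id, 0))

    def test_onsets_within_binomial_bounds(self, params):
        cond = params.condition("pre_eclampsia_mild")
        n = 10_000
        women = [w for w in m.make_fixture_population(3 * n, seed=8, params=params)
                 if w.sex == "F"][:n]
        rs = RandomSource(21)
        hits = 0
        for w in women:
            w.risk_flags.clear()
            make_pregnant(w, 130)  # gestational month 5: in window, no modifiers
            out = m.apply_antenatal_cycle(w, params, KeyedRng(rs, w.id, 1))
            hits += cond.name in out["onsets"]
        lo, hi = binom.ppf([0.005, 0.995], n, cond.baseline_risk)
        assert lo <= hits <= hi


class TestProgression:
    def test_zero_probability_is_stable(self, params, woman):
        ps = copy.deepcopy(params)
        ps.condition("pre_eclampsia_mild").progression = ("pre_eclampsia_severe", 0.0)
        make_pregnant(woman, 160)
        woman.active_conditions["pre_eclampsia_mild"] = JAN
        m.apply_progression(woman, ps, KeyedRng(RandomSource(2), woman.id, 0))
        assert "pre_eclampsia_mild" in woman.active_conditions

    def test_certain_chain_reaches_eclampsia_in_two_steps(self, params, woman):
        ps = copy.deepcopy(params)
        ps.condition("pre_eclampsia_mild").progression = ("pre_eclampsia_severe", 1.0)
        ps.condition("pre_eclampsia_severe").progression = ("eclampsia", 1.0)
        make_pregnant(woman, 160)
        woman.active_conditions["pre_eclampsia_mild"] = JAN
        m.apply_progression(woman, ps, KeyedRng(RandomSource(2), woman.id, 0))
        assert "pre_eclampsia_severe" in woman.active_conditions
        m.apply_progression(woman, ps, KeyedRng(RandomSource(2), woman.id, 1))
        assert "eclampsia" in woman.active_conditions
        assert "pre_eclampsia_mild" not in woman.active_conditions

    def test_transitions_within_binomial_bounds(self, params):
        p = params.condition("pre_eclampsia_mild").progression[1]
        n = 8000
        women = [w for w in m.make_fixture_population(3 * n, seed=9, params=params)
                 if w.sex == "F"][:n]
        rs = RandomSource(5)
        hits = 0
        for w in women:
            make_pregnant(w, 160)
            w.active_conditions["pre_eclampsia_mild"] = JAN
            out = m.apply_progression(w, params, KeyedRng(rs, w.id, 2),
                                      phase="antenatal-monthly")
            hits += bool(out)
        lo, hi = binom.ppf([0.005, 0.995], n, p)
        assert lo <= hits <= hi


class TestIntrapartum:
    def test_zero_risks_uncomplicated(self, params, woman):
        ps = copy.deepcopy(params)
        for c in ps.conditions:
            c.baseline_risk = 0.0
        make_pregnant(woman, 270)
        woman.labour_state = "term"
        fired = m.apply_intrapartum_complications(
            woman, ps, KeyedRng(RandomSource(3), woman.id, 0))
        assert fired == []

    def test_untreated_obstruction_raises_rupture_risk(self, params, woman):
        make_pregnant(woman, 270)
        woman.labour_state = "term"
        rupture = params.condition("uterine_rupture")
        base = effective_onset_probability(rupture, woman)
        woman.active_conditions["obstructed_labour"] = JAN
        raised = effective_onset_probability(rupture, woman)
        assert raised == pytest.approx(base * 4.0)
        # treated obstruction no longer multiplies the risk
        woman._treatments["obstructed_labour"] = [0.5]
        assert effective_onset_probability(rupture, woman) == pytest.approx(base)

    def test_complication_counts_within_binomial_bounds(self, params):
        cond = params.condition("obstructed_labour")
        n = 10_000
        women = [w for w in m.make_fixture_population(3 * n, seed=10, params=params)
                 if w.sex == "F"][:n]
        rs = RandomSource(6)
        hits = 0
        for w in women:
            make_pregnant(w, 270)
            w.labour_state = "term"
            fired = m.apply_intrapartum_complications(w, params, KeyedRng(rs, w.id, 3))
            hits += cond.name in fired
        lo, hi = binom.ppf([0.005, 0.995], n, cond.baseline_risk)
        assert lo <= hits <= hi

    def test_requires_labour(self, params, woman):
        make_pregnant(woman, 270)
        with pytest.raises(ValueError):
            m.apply_intrapartum_complications(woman, params,
                                              KeyedRng(RandomSource(1), woman.id, 0))


class TestPostnatalNeonatal:
    def _newborn(self, params, preterm):
        [nb] = m.make_fixture_population(1, seed=11, params=params)
        nb.neonatal_age_days = 0
        nb._preterm = preterm
        nb.risk_flags.clear()
        return nb

    def test_week_outside_window_rejected(self, params, woman):
        woman.postnatal_week = 0
        with pytest.raises(ValueError):
            m.apply_postnatal_neonatal_cycle(woman, 7, params,
                                             KeyedRng(RandomSource(1), woman.id, 0))
        nb = self._newborn(params, preterm=False)
        with pytest.raises(ValueError):
            m.apply_postnatal_neonatal_cycle(nb, 4, params,
                                             KeyedRng(RandomSource(1), nb.id, 0))

    def test_rds_risk_gated_on_prematurity(self, params):
        rds = params.condition("preterm_rds")
        preterm = self._newborn(params, preterm=True)
        term = self._newborn(params, preterm=False)
        ctx = {"week": 0}
        assert effective_onset_probability(rds, preterm, ctx) == rds.baseline_risk
        assert effective_onset_probability(rds, term, ctx) == 0.0

    def test_birth_only_conditions_cannot_fire_later(self, params):
        nb = self._newborn(params, preterm=True)
        nb.neonatal_age_days = 7
        fired = apply_phase_onsets(nb, "neonatal", params,
                                   KeyedRng(RandomSource(1), nb.id, 0), {"week": 1})
        assert "preterm_rds" not in fired and "neonatal_encephalopathy" not in fired

    def test_neonatal_sepsis_within_binomial_bounds(self, params):
        cond = params.condition("neonatal_sepsis")
        n = 10_000
        rs = RandomSource(8)
        hits = 0
        for i in range(n):
            nb = self._newborn(params, preterm=False)
            nb.id = i
            nb.neonatal_age_days = 14
            fired = m.apply_postnatal_neonatal_cycle(nb, 2, params, KeyedRng(rs, i, 4))
            hits += cond.name in fired
        lo, hi = binom.ppf([0.005, 0.995], n, cond.baseline_risk)
        assert lo <= hits <= hi


class TestPhaseGating:
    def test_no_condition_fires_outside_its_phase(self, params):
        """With every baseline at 1, a phase cycle only ever fires conditions
        declared for that phase."""
        ps = copy.deepcopy(params)
        for c in ps.conditions:
            c.baseline_risk = 1.0
            c.requires = ""
            c.window = (0, 60) if c.phase != "antenatal-monthly" else (1, 10)
        rs = RandomSource(12)
        for phase in ("antenatal-monthly", "intrapartum", "postnatal-weekly", "neonatal"):
            [p] = m.make_fixture_population(1, seed=13, params=ps)
            p.risk_flags.clear()
            if phase == "antenatal-monthly":
                make_pregnant(p, 150)
            elif phase == "intrapartum":
                make_pregnant(p, 270)
                p.labour_state = "term"
            elif phase == "postnatal-weekly":
                p.postnatal_week = 1
            else:
                p.neonatal_age_days = 7
            fired = apply_phase_onsets(p, phase, ps, KeyedRng(rs, p.id, 5),
                                       {"week": 1, "gestational_month": 6})
            allowed = {c.name for c in ps.conditions if phase in c.phases}
            assert set(fired) <= allowed
            assert fired  # the cycle does fire the at-risk conditions


def test_gestational_month_indexing(params, woman):
    make_pregnant(woman, 0)
    assert gestational_month(woman) == 1
    woman.gestational_age = 89
    assert gestational_month(woman) == 3
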