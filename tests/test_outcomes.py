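import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

import mnhsim as m
from mnhsim.outcomes import DalyLedger, death_category
from mnhsim.rand import KeyedRng, RandomSource

JAN = dt.date(2023, 1, 15)


class TestCombineDisabilityWeights:
    def test_empty_is_zero(self):
        assert m.combine_disability_weights([]) == 0.0

    def test_cap_at_one(self):
        assert m.combine_disability_weights([0.6, 0.7]) == 1.0

    def test_additive_below_cap(self):
        assert m.combine_disability_weights([0.114, 0.324]) == pytest.approx(0.438)

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            m.combine_disability_weights([1.2])

    @settings(max_examples=100, deadline=None)
    @given(ws=st.lists(st.floats(0, 1), max_size=8))
    def test_always_a_weight(self, ws):
        assert 0.0 <= m.combine_disability_weights(ws) <= 1.0


class TestAdjustedDeathProbability:
    def test_untreated_cfr_unchanged(self):
        assert m.adjusted_death_probability(0.1, []) == 0.1

    def test_multiplicative_treatment_effect(self):
        assert m.adjusted_death_probability(0.1, [0.5]) == pytest.approx(0.05)

    def test_one_delay_attenuates_the_effect(self):
        # effective rr = 1 - (1-0.5) * 0.75 = 0.625 -> 0.1 * 0.625
        got = m.adjusted_death_probability(0.1, [0.5], (True, False, False), 0.25)
        assert got == pytest.approx(0.0625)

    def test_invalid_rr_rejected(self):
        with pytest.raises(ValueError):
            m.adjusted_death_probability(0.1, [0.0])

    @settings(max_examples=100, deadline=None)
    @given(cfr=st.floats(0, 1), rrs=st.lists(st.floats(0.05, 1), max_size=4),
           extra=st.floats(0.05, 1),
           att=st.floats(0, 0.9))
    def test_monotone_in_treatments_and_delays(self, cfr, rrs, extra, att):
        no_delay = (False, False, False)
        one_delay = (True, False, False)
        base = m.adjusted_death_probability(cfr, rrs, no_delay, att)
        assert m.adjusted_death_probability(cfr, rrs + [extra], no_delay, att) <= base + 1e-12
        assert m.adjusted_death_probability(cfr, rrs, one_delay, att) >= base - 1e-12


class TestApplyDeath:
    def _person(self, params, cause, neonatal=False):
        [p] = m.make_fixture_population(1, seed=2, params=params)
        if neonatal:
            p.neonatal_age_days = 3
            p.date_of_birth = JAN
        p.active_conditions[cause] = JAN
        return p

    def test_zero_probability_never_kills(self, params):
        p = self._person(params, "pph_primary")
        for i in range(50):
            assert m.apply_death(p, "pph_primary", 0.0, KeyedRng(RandomSource(i), p.id, i),
                                 JAN, params) is None
        assert p.alive

    def test_certain_death_categorised_maternal_direct(self, params):
        p = self._person(params, "pph_primary")
        ev = m.apply_death(p, "pph_primary", 1.0, KeyedRng(RandomSource(1), p.id, 0),
                           JAN, params)
        assert ev is not None and not p.alive
        assert ev.category == "maternal-direct"
        assert ev.yll > 0

    def test_neonatal_category(self, params):
        p = self._person(params, "neonatal_sepsis", neonatal=True)
        assert death_category(params, p, "neonatal_sepsis") == "neonatal"

    def test_death_rate_within_binomial_bounds(self, params):
        n, p_death = 10_000, 0.02
        rs = RandomSource(7)
        deaths = 0
        for i in range(n):
            person = self._person(params, "sepsis_postnatal")
            person.id = i
            ev = m.apply_death(person, "sepsis_postnatal", p_death,
                               KeyedRng(rs, i, 0), JAN, params)
            deaths += ev is not None
        lo, hi = binom.ppf([0.005, 0.995], n, p_death)
        assert lo <= deaths <= hi

    def test_requires_the_condition(self, params):
        [p] = m.make_fixture_population(1, seed=2, params=params)
        with pytest.raises(ValueError):
            m.apply_death(p, "pph_primary", 0.5, KeyedRng(RandomSource(1), p.id, 0),
                          JAN, params)


class TestAccrueDalys:
    def test_no_conditions_no_increment(self, params):
        ledger = DalyLedger()
        people = m.make_fixture_population(5, seed=3, params=params)
        m.accrue_dalys(ledger, people, 2023, params)
        assert ledger.dalys(2023, "maternal") == 0.0

    def test_single_weight_for_a_year(self, params):
        import copy

        ps = copy.deepcopy(params)
        ps.condition("maternal_anaemia").disability_weight = 0.3
        [p] = m.make_fixture_population(1, seed=3, params=ps)
        p.active_conditions["maternal_anaemia"] = JAN
        ledger = DalyLedger()
        for _ in range(12):
            m.accrue_dalys(ledger, [p], 2023, ps)
        assert ledger.yld[(2023, "maternal")] == pytest.approx(0.3)

    def test_neonatal_yll_is_a_life_table_lookup(self, params):
        [p] = m.make_fixture_population(1, seed=4, params=params)
        p.date_of_birth = JAN
        p.neonatal_age_days = 2
        p.active_conditions["neonatal_sepsis"] = JAN
        ledger = DalyLedger()
        ev = m.apply_death(p, "neonatal_sepsis", 1.0, KeyedRng(RandomSource(2), p.id, 0),
                           JAN, params, ledger)
        expected = params.remaining_life_expectancy(0)
        assert ev.yll == pytest.approx(expected)
        assert ledger.yll[(2023, "neonatal")] == pytest.approx(expected)

    def test_null_model_conservation(self, params):
        """Zero weights and zero CFRs produce zero DALYs and zero deaths."""
        import copy

        ps = copy.deepcopy(params)
        for c in ps.conditions:
            c.disability_weight = 0.0
            c.untreated_cfr = 0.0
        people = m.make_fixture_population(6, seed=5, params=ps)
        ledger = DalyLedger()
        for p in people:
            p.active_conditions["maternal_anaemia"] = JAN
        m.accrue_dalys(ledger, people, 2023, ps)
        assert ledger.dalys(2023, "maternal") == 0.0
        for p in people:
            ev = m.apply_death(p, "maternal_anaemia",
                               m.adjusted_death_probability(0.0, []),
                               KeyedRng(RandomSource(3), p.id, 0), JAN, ps)
            assert ev is None and p.alive


class TestPeriodRates:
    def test_mmr_formula(self):
        mmr, _, _ = m.compute_period_rates(3305, 0, 0, 1_000_000)
        assert mmr == pytest.approx(330.5)

    def test_zero_deaths_zero_rates(self):
        assert m.compute_period_rates(0, 0, 0, 1000) == (0.0, 0.0, 0.0)

    def test_zero_live_births_rejected(self):
        with pytest.raises(ZeroDivisionError):
            m.compute_period_rates(1, 1, 1, 0)

    def test_reported_rates_imply_a_consistent_denominator(self):
        """Back-solving the implied live-birth denominator from the reported
        period totals and rates gives the same answer for MMR and NMR."""
        lb_from_mmr = 19_541 / 330.5 * 1e5
        lb_from_nmr = 99_902 / 16.9 * 1e3
        assert lb_from_mmr == pytest.approx(5.91e6, rel=0.01)
        assert lb_from_nmr == pytest.approx(lb_from_mmr, rel=0.01)

    def test_sbr_denominator_variants(self):
        _, _, sbr_total = m.compute_period_rates(0, 0, 50, 950)
        _, _, sbr_live = m.compute_period_rates(0, 0, 50, 950, sbr_denominator="live")
        assert sbr_total == pytest.approx(50.0)
        assert sbr_live == pytest.approx(50 / 950 * 1e3)
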