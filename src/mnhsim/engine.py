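"""Simulation engine: the monthly master clock and the pregnancy lifecycle.

Each run advances a whole population month by month: background demography
and conception first, then one antenatal step per pregnant woman (care
contacts, onsets, progression, possible pregnancy loss), labour when
gestation completes (or preterm labour fires), and a nested weekly loop over
the 6-week postnatal / 28-day neonatal window executed within the month of
delivery.  Mortality is applied per complication episode after care has been
determined; DALYs accrue alongside.

All stochastic decisions use counter-based streams keyed by (seed, purpose,
person, month) so paired scenario runs share common random numbers.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .cohort import Population, initialise_population, monthly_demographic_update, initiate_pregnancies
from .health_system import (
    HcwLedger,
    ServiceOverrides,
    careseeking_probability,
    emergency_careseeking,
    execute_hsi,
    plan_anc_schedule,
)
from .natural_history import (
    apply_antenatal_cycle,
    apply_intrapartum_complications,
    apply_postnatal_neonatal_cycle,
    determine_labour_category,
    effective_onset_probability,
)
from .outcomes import DalyLedger, accrue_dalys, adjusted_death_probability, apply_death
from .params import ParameterSet, generate_default_parameters
from .rand import KeyedRng, RandomSource
from .scenarios import ScenarioConfig, apply_scenario, build_scenario
from .summary import RunResult

WEEK_FRACTION = 7.0 / 365.25

# conditions referred from routine ANC detection to inpatient antenatal care
_INPATIENT_REFERRAL = {"gestational_diabetes", "gestational_htn_severe",
                       "pre_eclampsia_severe", "eclampsia"}
_PREGNANCY_LOSS = {"ectopic_pregnancy", "abortion_complications"}
_NEWBORN_INHERITED_PREVENTIONS = {"acs_preterm", "clean_birth_practices"}
_PPH_CONDITIONS = {"pph_primary", "pph_secondary"}


@dataclass
class SimulationConfig:
    """Desk-scale run configuration (defaults are deliberately small)."""

    scenario: str = "SQ"
    population_size: int = 7000
    model_to_real_ratio: float = 2000.0
    start: dt.date = dt.date(2021, 1, 1)
    end: dt.date = dt.date(2028, 1, 1)
    runs: int = 4
    base_seed: int = 0
    output_dir: str | None = None
    write_event_logs: bool = False  # per-run HSI and death logs (large CSVs)

    def validate(self) -> None:
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.end <= self.start:
            raise ValueError("end must be after start")
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")


class _Tally:
    """Per-year counters for one run."""

    def __init__(self):
        self.counts: dict = {}

    def add(self, year: int, key: str, value: float = 1.0) -> None:
        self.counts[(year, key)] = self.counts.get((year, key), 0.0) + value

    def get(self, year: int, key: str) -> float:
        return self.counts.get((year, key), 0.0)

    def keys_like(self, prefix: str) -> set:
        return {k for (_, k) in self.counts if k.startswith(prefix)}


class _Run:
    """State and behaviour of one simulation run."""

    def __init__(self, params: ParameterSet, scenario: ScenarioConfig,
                 config: SimulationConfig, run_seed: int):
        self.params = params
        self.scenario = scenario
        self.config = config
        self.rs = RandomSource(run_seed % 2**31)
        self.pop = initialise_population(config.population_size,
                                         config.model_to_real_ratio,
                                         seed=run_seed % 2**31)
        self.ledger = HcwLedger(params, config.population_size)
        self.daly = DalyLedger()
        self.tally = _Tally()
        self.overrides = ServiceOverrides()
        self._switched = False
        self.hsi_log: list = []
        self.death_log: list = []

    # -- small helpers -----------------------------------------------------

    def _day(self, date: dt.date, purpose: str, pid: int, t: int) -> dt.date:
        day = 1 + int(self.rs.uniform("day:" + purpose, pid, t) * 28)
        return dt.date(date.year, date.month, day)

    def _seeks(self, purpose: str, pid: int, t: int, p: float) -> bool:
        return emergency_careseeking(KeyedRng(self.rs, pid, t, purpose + ":"), p)

    def _careseek_prob(self, service: str, person, intercept_override=None) -> float:
        model = self.params.careseeking[service]
        if intercept_override is not None:
            model = dataclasses.replace(model, intercept=intercept_override)
        return careseeking_probability(model, person)

    def _hsi(self, hsi_type: str, person, t: int, date: dt.date,
             facility: str, emergency: bool = False):
        ev = execute_hsi(hsi_type, person, self.params, self.ledger,
                         KeyedRng(self.rs, person.id, t, f"hsi:{hsi_type}:"),
                         overrides=self.overrides, facility_level=facility,
                         date=date, emergency=emergency)
        year = date.year
        self.tally.add(year, f"hsi_{hsi_type}")
        for cadre, minutes in ev.required_minutes.items():
            self.tally.add(year, f"minutes_{cadre}", minutes)
        self.hsi_log.append(ev)
        return ev

    def _death_stage(self, person, t: int, date: dt.date, mother=None) -> bool:
        """Episode mortality: one adjusted draw per new fatal condition."""
        if not hasattr(person, "_death_drawn"):
            person._death_drawn = set()
        for cond in self.params.conditions:
            name = cond.name
            if cond.untreated_cfr <= 0 or cond.fetal:
                continue
            if name not in person.active_conditions or name in person._death_drawn:
                continue
            person._death_drawn.add(name)
            p = adjusted_death_probability(
                cond.untreated_cfr, person._treatments.get(name, []),
                person._delays.get(name, (False, False, False)),
                self.params.delay_attenuation)
            ev = apply_death(person, name, p, KeyedRng(self.rs, person.id, t, "mort:"),
                             date, self.params, self.daly)
            if ev is not None:
                side = "neonatal" if ev.category == "neonatal" else "maternal"
                self.tally.add(date.year, f"{side}_deaths_{name}")
                self.death_log.append(ev)
                return True
        return False

    # -- pregnancy lifecycle ----------------------------------------------

    def _plan_pregnancy(self, woman, date: dt.date, t: int) -> None:
        woman._age_now = woman.age_years(date)
        woman._death_drawn = set()
        if "anc" in self.overrides.service_disabled:
            return
        if self.overrides.anc_start_intercept is not None and \
                self.overrides.anc_start_intercept >= 29.0:
            starts = True
        else:
            p = self._careseek_prob("anc_start", woman, self.overrides.anc_start_intercept)
            starts = self.rs.uniform("anc-start", woman.id, t) < p
        if starts:
            woman._anc_schedule = plan_anc_schedule(
                woman, self.params, KeyedRng(self.rs, woman.id, t, "plan:"),
                self.overrides)

    def _antenatal_month(self, woman, date: dt.date, t: int) -> None:
        from .natural_history import gestational_month

        m = gestational_month(woman)
        # routine ANC contact scheduled for this gestational month
        if "anc" not in self.overrides.service_disabled and \
                any(month == m for _, month in woman._anc_schedule):
            self._hsi("anc", woman, t, self._day(date, "anc", woman.id, t),
                      "health-centre")
            woman.anc_visits_attended += 1
            referable = (woman._detected & _INPATIENT_REFERRAL) - set(woman._treatments)
            if referable:
                self._hsi("inpatient_antenatal", woman, t,
                          self._day(date, "inpat", woman.id, t), "district-hospital")

        cycle = apply_antenatal_cycle(
            woman, self.params, KeyedRng(self.rs, woman.id, t, "nh:"), date)

        # emergency care-seeking for symptomatic new complications
        emergencies = [n for n in cycle["onsets"]
                       if self.params.condition(n).emergency and not self.params.condition(n).fetal]
        emergencies += [to for _, to in cycle["transitions"]
                        if self.params.condition(to).emergency]
        for name in emergencies:
            if name in _PREGNANCY_LOSS:
                # post-abortion / ectopic care: never modified by scenarios
                if self._seeks(f"emseek:{name}", woman.id, t, self.params.emergency_careseek_prob):
                    self._hsi("pac", woman, t, self._day(date, "pac", woman.id, t),
                              "district-hospital", emergency=True)
            else:
                p = (self.overrides.emergency_careseek_antenatal
                     if self.overrides.emergency_careseek_antenatal is not None
                     else self.params.emergency_careseek_prob)
                if self._seeks(f"emseek:{name}", woman.id, t, p):
                    self._hsi("inpatient_antenatal", woman, t,
                              self._day(date, "emerg", woman.id, t),
                              "district-hospital", emergency=True)

        died = self._death_stage(woman, t, date)
        if died:
            return

        if cycle["ended"] is not None:
            if cycle["ended"] == "antenatal_stillbirth":
                self.tally.add(date.year, "stillbirths_antenatal")
            accrue_dalys(self.daly, [woman], date.year, self.params)
            self._end_pregnancy(woman)
            return

        if cycle["labour"] == "preterm":
            self._labour(woman, date, t, woman.gestational_age - 15)
        elif woman.gestational_age >= 300:
            self._labour(woman, date, t, 300)
        elif woman.gestational_age >= 270:
            if "post_term_pregnancy" not in woman.active_conditions and \
                    self.rs.uniform("postterm", woman.id, t) < self.params.postterm_prob:
                woman.active_conditions["post_term_pregnancy"] = date
            else:
                self._labour(woman, date, t, 270)

    def _labour(self, woman, date: dt.date, t: int, gest_days: int) -> None:
        params, rs = self.params, self.rs
        woman.labour_state = determine_labour_category(gest_days)
        complications = apply_intrapartum_complications(
            woman, params, KeyedRng(rs, woman.id, t, "ip:"), stage="complications",
            date=date)

        # delivery setting
        if self.overrides.facility_all:
            facility = True
        else:
            p = self._careseek_prob("facility_delivery", woman,
                                    self.overrides.facility_intercept)
            facility = rs.uniform("facility", woman.id, t) < p
        if not facility and complications:
            # obstetric emergency at home: care-seeking for facility delivery
            facility = self._seeks("emseek:delivery", woman.id, t,
                                   params.emergency_careseek_prob)
        hospital = rs.uniform("hospital", woman.id, t) < params.facility_hospital_share
        day = self._day(date, "delivery", woman.id, t)

        delivered: set = set()
        if facility:
            woman.delivery_setting = "hospital" if hospital else "health-centre"
            hsi_type = "delivery_cemonc" if hospital else "delivery_bemonc"
            level = "district-hospital" if hospital else "health-centre"
            ev = self._hsi(hsi_type, woman, t, day, level)
            delivered.update(ev.delivered_interventions)
            self.tally.add(date.year, "facility_deliveries")
        else:
            woman.delivery_setting = "home"
            self.tally.add(date.year, "home_births")

        sequelae = apply_intrapartum_complications(
            woman, params, KeyedRng(rs, woman.id, t, "ip2:"), stage="sequelae",
            date=date)
        if "uterine_rupture" in sequelae and woman.delivery_setting == "hospital":
            ev = self._hsi("delivery_cemonc", woman, t, day, "district-hospital",
                           emergency=True)
            delivered.update(ev.delivered_interventions)

        # intrapartum stillbirth, reduced by operative delivery
        sb_cond = params.condition("intrapartum_stillbirth")
        p_sb = effective_onset_probability(sb_cond, woman)
        for name in ("avd", "caesarean_section"):
            if name in delivered:
                p_sb *= params.intervention(name).treatment_rr
        stillbirth = rs.uniform("ip-stillbirth", woman.id, t) < p_sb

        self.tally.add(date.year, "women_delivered")
        if woman.anc_visits_attended >= 4:
            self.tally.add(date.year, "women_anc4")

        newborn = None
        if stillbirth:
            self.tally.add(date.year, "stillbirths_intrapartum")
        else:
            newborn = self._make_newborn(woman, date, t)
            self.tally.add(date.year, "live_births")

        woman.parity += 1
        woman.is_pregnant = False
        woman.gestational_age = None
        woman.postnatal_week = 0
        woman._anc_schedule = []

        self._death_stage(woman, t, date)
        self._postnatal_window(woman if woman.alive else None, newborn, date, t)

    def _make_newborn(self, mother, date: dt.date, t: int):
        from .cohort import PersonRecord

        nid = self.pop.new_id()
        female = self.rs.uniform("sex", nid, t) < self.params.female_fraction
        newborn = PersonRecord(
            id=nid, sex="F" if female else "M", date_of_birth=date,
            district=mother.district, urban=mother.urban,
            wealth_quintile=mother.wealth_quintile,
            education_level=mother.education_level,
            neonatal_age_days=0,
        )
        newborn._mother_id = mother.id
        newborn._preterm = mother.labour_state == "preterm"
        newborn._preventions = set(mother._preventions) & _NEWBORN_INHERITED_PREVENTIONS
        newborn._death_drawn = set()
        self.pop.add(newborn)
        return newborn

    def _postnatal_window(self, mother, newborn, date: dt.date, t: int) -> None:
        """Nested weekly loop over the postnatal/neonatal window."""
        params = self.params
        at_facility = mother is not None and mother.delivery_setting in ("health-centre", "hospital")
        delivery_hsi = None
        delivery_level = None
        if at_facility:
            hospital = mother.delivery_setting == "hospital"
            delivery_hsi = "delivery_cemonc" if hospital else "delivery_bemonc"
            delivery_level = "district-hospital" if hospital else "health-centre"
        pnc_disabled = "pnc" in self.overrides.service_disabled

        for week in range(0, 7):
            m_onsets: list = []
            n_onsets: list = []
            if mother is not None and mother.alive:
                mother.postnatal_week = week
                m_onsets = apply_postnatal_neonatal_cycle(
                    mother, week, params, KeyedRng(self.rs, mother.id, t, f"pn{week}:"),
                    date=date)
            if newborn is not None and newborn.alive and week <= 3:
                newborn.neonatal_age_days = week * 7
                n_onsets = apply_postnatal_neonatal_cycle(
                    newborn, week, params, KeyedRng(self.rs, newborn.id, t, f"nn{week}:"),
                    mother=mother, date=date)

            if week == 0:
                self._week0_care(mother, newborn, m_onsets, n_onsets,
                                 at_facility, delivery_hsi, delivery_level,
                                 pnc_disabled, date, t)
            else:
                self._late_week_care(mother, newborn, m_onsets, n_onsets, week, date, t)

            if mother is not None and mother.alive:
                self._death_stage(mother, t, date)
            if newborn is not None and newborn.alive and week <= 3:
                self._death_stage(newborn, t, date, mother=mother)

            alive_now = [p for p in (mother, newborn)
                         if p is not None and p.alive and (p is mother or week <= 3)]
            accrue_dalys(self.daly, alive_now, date.year, params,
                         fraction_of_year=WEEK_FRACTION)

        if mother is not None and mother.alive:
            if mother.received_pnc:
                self.tally.add(date.year, "women_pnc")
            self._end_pregnancy(mother)
        if newborn is not None and newborn.alive:
            if newborn.received_pnc:
                self.tally.add(date.year, "newborn_pnc")
            newborn.neonatal_age_days = None
            newborn.active_conditions = {}
            newborn._treatments = {}
            newborn._delays = {}
            newborn._preterm = False

    def _week0_care(self, mother, newborn, m_onsets, n_onsets, at_facility,
                    delivery_hsi, delivery_level, pnc_disabled, date, t) -> None:
        # immediate care in the delivery room for birth complications
        if at_facility and mother is not None and mother.alive and \
                any(self.params.condition(n).emergency for n in m_onsets):
            self._hsi(delivery_hsi, mother, t, self._day(date, "pp0", mother.id, t),
                      delivery_level, emergency=True)
        if at_facility and newborn is not None and newborn.alive and \
                any(self.params.condition(n).emergency for n in n_onsets):
            self._hsi(delivery_hsi, newborn, t, self._day(date, "nb0", newborn.id, t),
                      delivery_level, emergency=True)
        if not at_facility:
            self._emergency_postnatal(mother, m_onsets, date, t, maternal=True)
            self._emergency_postnatal(newborn, n_onsets, date, t, maternal=False)

        # routine early PNC (first contact within 48 h of birth)
        if pnc_disabled:
            return
        if mother is not None and mother.alive:
            p = 1.0 if self.overrides.pnc_all else self._careseek_prob(
                "pnc_maternal", mother, self.overrides.pnc_maternal_intercept)
            if self.rs.uniform("pnc-mat", mother.id, t) < p:
                self._hsi("pnc_maternal", mother, t,
                          self._day(date, "pncm", mother.id, t), "health-centre")
                mother.received_pnc = True
        if newborn is not None and newborn.alive:
            careseeker = mother if mother is not None else newborn
            p = 1.0 if self.overrides.pnc_all else self._careseek_prob(
                "pnc_neonatal", careseeker, self.overrides.pnc_neonatal_intercept)
            if self.rs.uniform("pnc-neo", newborn.id, t) < p:
                self._hsi("pnc_neonatal", newborn, t,
                          self._day(date, "pncn", newborn.id, t), "health-centre")
                newborn.received_pnc = True

    def _late_week_care(self, mother, newborn, m_onsets, n_onsets, week, date, t) -> None:
        self._emergency_postnatal(mother, m_onsets, date, t, maternal=True)
        if week <= 3:
            self._emergency_postnatal(newborn, n_onsets, date, t, maternal=False)

    def _emergency_postnatal(self, person, onsets, date, t, maternal: bool) -> None:
        if person is None or not person.alive:
            return
        emergencies = [n for n in onsets if self.params.condition(n).emergency]
        if not emergencies:
            return
        p = (self.overrides.emergency_careseek_postnatal
             if self.overrides.emergency_careseek_postnatal is not None
             else self.params.emergency_careseek_prob)
        for name in emergencies:
            if not self._seeks(f"emseek:{name}", person.id, t, p):
                continue
            if maternal:
                if name in _PPH_CONDITIONS:
                    self._hsi("cemonc_postnatal", person, t,
                              self._day(date, "empn", person.id, t),
                              "district-hospital", emergency=True)
                else:
                    self._hsi("pnc_maternal", person, t,
                              self._day(date, "empn", person.id, t),
                              "health-centre", emergency=True)
            else:
                self._hsi("pnc_neonatal", person, t,
                          self._day(date, "emnn", person.id, t),
                          "district-hospital", emergency=True)

    def _end_pregnancy(self, woman) -> None:
        woman.is_pregnant = False
        woman.gestational_age = None
        woman.labour_state = "none"
        woman.delivery_setting = "none"
        woman.postnatal_week = None
        woman.active_conditions = {}
        woman.received_pnc = False
        woman._preventions = set()
        woman._detected = set()
        woman._treatments = {}
        woman._delays = {}
        woman._anc_schedule = []
        woman._death_drawn = set()
        woman.risk_flags.discard("caesarean")

    # -- main loop ---------------------------------------------------------

    def run(self) -> RunResult:
        cfg = self.config
        date = cfg.start
        while date < cfg.end:
            t = date.year * 12 + date.month
            if not self._switched and date >= self.scenario.effective_date:
                cohort = list(self.pop.women_of_reproductive_age(date))
                for w in cohort:
                    w._age_now = w.age_years(date)
                self.overrides = apply_scenario(self.scenario, self.params, date,
                                                cohort=cohort or None)
                self._switched = True
            monthly_demographic_update(self.pop, date, self.params.background_mortality,
                                       self.rs)
            newly = initiate_pregnancies(self.pop, date, self.params, self.rs)
            for w in newly:
                self._plan_pregnancy(w, date, t)
            pregnant = sorted((p for p in self.pop.alive() if p.is_pregnant),
                              key=lambda p: p.id)
            for w in pregnant:
                if w.alive:
                    self._antenatal_month(w, date, t)
            accrue_dalys(self.daly,
                         (p for p in self.pop.alive()
                          if p.is_pregnant and p.active_conditions),
                         date.year, self.params)
            date = (date.replace(day=1) + dt.timedelta(days=32)).replace(day=1)
        return self._build_result()

    def _build_result(self) -> RunResult:
        years = list(range(self.config.start.year, self.config.end.year))
        if self.config.end == dt.date(self.config.end.year, 1, 1):
            pass
        else:
            years.append(self.config.end.year)
        rows = {}
        maternal_causes = sorted({c.name for c in self.params.conditions
                                  if c.category.startswith("maternal")})
        neonatal_causes = sorted({c.name for c in self.params.conditions
                                  if c.category == "neonatal"})
        for year in years:
            g = lambda key: self.tally.get(year, key)  # noqa: E731
            row = {
                "live_births": g("live_births"),
                "stillbirths_antenatal": g("stillbirths_antenatal"),
                "stillbirths_intrapartum": g("stillbirths_intrapartum"),
                "facility_deliveries": g("facility_deliveries"),
                "home_births": g("home_births"),
                "women_delivered": g("women_delivered"),
                "women_anc4": g("women_anc4"),
                "women_pnc": g("women_pnc"),
                "newborn_pnc": g("newborn_pnc"),
                "maternal_yld": self.daly.yld[(year, "maternal")],
                "maternal_yll": self.daly.yll[(year, "maternal")],
                "neonatal_yld": self.daly.yld[(year, "neonatal")],
                "neonatal_yll": self.daly.yll[(year, "neonatal")],
            }
            row["stillbirths"] = row["stillbirths_antenatal"] + row["stillbirths_intrapartum"]
            row["total_births"] = row["live_births"] + row["stillbirths"]
            row["maternal_dalys"] = row["maternal_yld"] + row["maternal_yll"]
            row["neonatal_dalys"] = row["neonatal_yld"] + row["neonatal_yll"]
            for cause in maternal_causes:
                row[f"maternal_deaths_{cause}"] = g(f"maternal_deaths_{cause}")
            for cause in neonatal_causes:
                row[f"neonatal_deaths_{cause}"] = g(f"neonatal_deaths_{cause}")
            row["maternal_deaths"] = sum(row[f"maternal_deaths_{c}"] for c in maternal_causes)
            row["neonatal_deaths"] = sum(row[f"neonatal_deaths_{c}"] for c in neonatal_causes)
            for hsi in ("anc", "inpatient_antenatal", "pac", "delivery_bemonc",
                        "delivery_cemonc", "pnc_maternal", "pnc_neonatal",
                        "cemonc_postnatal"):
                row[f"hsi_{hsi}"] = g(f"hsi_{hsi}")
            row["anc_contacts"] = row["hsi_anc"]
            row["pnc_maternal_contacts"] = row["hsi_pnc_maternal"]
            row["pnc_neonatal_contacts"] = row["hsi_pnc_neonatal"]
            for cadre in ("nurse_midwife", "clinician"):
                row[f"minutes_{cadre}"] = g(f"minutes_{cadre}")
            rows[year] = row
        import pandas as pd

        annual = pd.DataFrame.from_dict(rows, orient="index").sort_index()
        annual.index.name = "year"
        return RunResult(scenario=self.scenario.short_name, run_index=0,
                         seed=self.rs.seed, scale_factor=self.pop.ratio,
                         annual=annual)


def simulate_run(params: ParameterSet, scenario: ScenarioConfig | str,
                 config: SimulationConfig, run_seed: int) -> RunResult:
    """Simulate one run of one scenario; deterministic in (params, config, seed)."""
    if isinstance(scenario, str):
        scenario = build_scenario(scenario)
    return _Run(params, scenario, config, run_seed).run()


def run_simulation(config: SimulationConfig, params: ParameterSet | None = None) -> list:
    """Run all paired runs of a scenario (seeds base_seed + run index).

    When ``config.output_dir`` is set, one RunResult CSV per run plus a JSON
    manifest (config, seeds, version, config hash) are written there.
    """
    config.validate()
    if params is None:
        params = generate_default_parameters(seed=0)
    results = []
    runs = []
    scenario = build_scenario(config.scenario)
    for i in range(config.runs):
        run_seed = config.base_seed + i
        run = _Run(params, scenario, config, run_seed)
        rr = run.run()
        rr.run_index = i
        results.append(rr)
        runs.append(run)
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        safe = config.scenario.replace(" ", "_").replace(".", "")
        for rr in results:
            rr.to_csv(outdir / f"run_{safe}_{rr.run_index}.csv")
        if config.write_event_logs:
            for rr, run in zip(results, runs):
                _write_event_logs(outdir, safe, rr.run_index, run)
        cfg_dict = {k: str(v) for k, v in dataclasses.asdict(config).items()}
        manifest = {
            "scenario": config.scenario,
            "seeds": [config.base_seed + i for i in range(config.runs)],
            "config": cfg_dict,
            "config_hash": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
            "version": __version__,
        }
        (outdir / f"manifest_{safe}.json").write_text(json.dumps(manifest, indent=2))
    return results


def _write_event_logs(outdir: Path, safe: str, run_index: int, run: "_Run") -> None:
    """HSI event log and deaths log as CSV (date, person, type, squeeze,
    delays, delivered interventions / cause, category, YLL)."""
    import pandas as pd

    hsi = pd.DataFrame([{
        "date": ev.date, "person_id": ev.person_id, "hsi_type": ev.hsi_type,
        "facility_level": ev.facility_level, "squeeze": ev.squeeze,
        "delay1": ev.delays[0], "delay2": ev.delays[1], "delay3": ev.delays[2],
        "delivered": ";".join(ev.delivered_interventions),
        **{f"minutes_{c}": v for c, v in ev.required_minutes.items()},
    } for ev in run.hsi_log])
    hsi.to_csv(outdir / f"hsi_log_{safe}_{run_index}.csv", index=False)
    deaths = pd.DataFrame([{
        "date": ev.date, "person_id": ev.person_id, "cause": ev.cause,
        "category": ev.category, "treated": ev.treated,
        "delay1": ev.delays[0], "delay2": ev.delays[1], "delay3": ev.delays[2],
        "age_years": ev.age_years, "yll": ev.yll,
    } for ev in run.death_log])
    deaths.to_csv(outdir / f"deaths_log_{safe}_{run_index}.csv", index=False)


def pipeline_end_to_end(scenarios, config: SimulationConfig,
                        params: ParameterSet | None = None,
                        comparator: str = "SQ") -> dict:
    """simulate -> summarise -> economics for a set of scenarios.

    The comparator (SQ) must be among the scenarios; runs are paired across
    scenarios by run index (same seed list).  Returns {"results", "summary",
    "economics"}.
    """
    from .summary import economics_summary, summarise_scenarios

    if comparator not in scenarios:
        raise ValueError(f"comparator {comparator!r} missing from scenario set")
    if params is None:
        params = generate_default_parameters(seed=0)
    results = {}
    for name in scenarios:
        cfg = dataclasses.replace(config, scenario=name)
        results[name] = run_simulation(cfg, params=params)
    summary = summarise_scenarios(results, comparator=comparator)
    economics = economics_summary(results, cet=params.cet_usd, comparator=comparator)
    return {"results": results, "summary": summary, "economics": economics}
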