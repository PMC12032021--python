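"""Synthetic parameter registry: conditions, interventions, care-seeking, system.

This module generates a complete, internally consistent synthetic parameter
set.  Values are order-of-magnitude plausible for Malawi (incidences and
untreated case-fatality risks of obstetric/neonatal complications, disability
weights in the GBD range, DHS-like coverage) and the care-seeking intercepts
are solved at generation time so population-level coverage matches the
standard targets (~51% ANC4+, ~91% facility delivery, 42% maternal PNC,
60% newborn PNC).  The defaults are a synthetic stand-in, not estimates from
any single empirical source.

Serialisation: one flat CSV per entity type plus a YAML manifest of scalars;
a merged JSON export is also provided.  Round-trips are lossless.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .cohort import PersonRecord
from .rand import RandomSource

PHASES = ("antenatal-monthly", "intrapartum", "postnatal-weekly", "neonatal")
CADRES = ("nurse_midwife", "clinician")
FACILITY_LEVELS = ("health-centre", "district-hospital", "central-hospital")
HSI_TYPES = (
    "anc",
    "inpatient_antenatal",
    "pac",
    "delivery_bemonc",
    "delivery_cemonc",
    "pnc_maternal",
    "pnc_neonatal",
    "cemonc_postnatal",
)
# service groups used for scenario quality / delay-three overrides
SERVICES = ("anc", "inpatient_antenatal", "delivery", "pnc", "inpatient_postnatal", "pac")
HSI_SERVICE = {
    "anc": "anc",
    "inpatient_antenatal": "inpatient_antenatal",
    "pac": "pac",
    "delivery_bemonc": "delivery",
    "delivery_cemonc": "delivery",
    "pnc_maternal": "pnc",
    "pnc_neonatal": "pnc",
    "cemonc_postnatal": "inpatient_postnatal",
}

BEMONC_SIGNAL_FUNCTIONS = (
    "iv_antibiotics",
    "uterotonics",
    "mgso4",
    "avd",
    "neonatal_resuscitation",
)
CEMONC_SIGNAL_FUNCTIONS = ("blood_transfusion", "caesarean_section", "surgical_repair")


class ParameterError(ValueError):
    """Raised when a parameter file or parameter set fails validation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ConditionSpec:
    """Natural-history parameters of one maternal or perinatal condition.

    ``modifiers`` are (predicate, relative-risk) pairs; predicates are small
    string expressions over person state evaluated by the natural-history
    engine (e.g. ``cond:obstructed_labour``, ``prev:iron_folic_acid``,
    ``flag:hiv``, ``week0``, ``preterm``).  ``window`` is inclusive and is in
    gestational months for antenatal conditions and in postnatal/neonatal
    weeks otherwise ((0, 0) = at birth only).
    """

    name: str
    phase: str
    baseline_risk: float
    modifiers: list = field(default_factory=list)  # [(predicate, rr)]
    progression: tuple | None = None  # (target condition, per-timestep prob)
    untreated_cfr: float = 0.0
    disability_weight: float = 0.0
    treatments: list = field(default_factory=list)
    window: tuple = (0, 0)
    phases: tuple = ()  # all phases in which onset may occur; defaults to (phase,)
    requires: str = ""  # predicate gating any risk at all (e.g. "preterm")
    ends_pregnancy: bool = False
    fetal: bool = False
    category: str = "none"
    emergency: bool = False
    treatment_resolves: bool = False

    def __post_init__(self):
        if not self.phases:
            self.phases = (self.phase,)

    def validate(self, intervention_names=None) -> None:
        if self.phase not in PHASES:
            raise ParameterError(f"condition {self.name}: unknown phase {self.phase!r}")
        for ph in self.phases:
            if ph not in PHASES:
                raise ParameterError(f"condition {self.name}: unknown phase {ph!r}")
        for fname in ("baseline_risk", "untreated_cfr", "disability_weight"):
            v = getattr(self, fname)
            if v is None or not 0.0 <= v <= 1.0:
                raise ParameterError(f"condition {self.name}: {fname} must be in [0,1], got {v}")
        for pred, rr in self.modifiers:
            if rr <= 0:
                raise ParameterError(f"condition {self.name}: relative risk for {pred!r} must be > 0")
        if self.progression is not None:
            tgt, p = self.progression
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"condition {self.name}: progression probability must be in [0,1]")
        if intervention_names is not None:
            for tname in self.treatments:
                if tname not in intervention_names:
                    raise ParameterError(
                        f"condition {self.name}: treatment {tname!r} not in intervention registry"
                    )


@dataclass
class InterventionSpec:
    """One deliverable intervention: quality factors, time demand and effect.

    Delivery requires every consumable-availability draw, the competence draw
    and (for EmONC interventions) the trained-staffing draw to succeed.
    ``treatment_rr`` multiplies the case-fatality risk (or onset/progression
    risk for prophylactics through condition modifiers) of treated conditions.
    """

    name: str
    klass: str  # screening | preventative | curative
    hsi_types: tuple
    emonc_class: str = "none"  # none | BEmONC | CEmONC
    consumable_availability: dict = field(default_factory=dict)  # item -> prob
    competence_prob: float = 0.85
    hcw_minutes: dict = field(default_factory=dict)  # cadre -> minutes
    treatment_rr: float = 1.0
    detects: tuple = ()  # screening targets (condition names)
    indication: str = "all"  # engine gate for prophylactics (all|primigravida|preterm|detected)

    def __post_init__(self):
        self.hcw_minutes = {k: float(v) for k, v in self.hcw_minutes.items()}
        self.consumable_availability = {k: float(v)
                                        for k, v in self.consumable_availability.items()}
        self.treatment_rr = float(self.treatment_rr)
        self.competence_prob = float(self.competence_prob)

    @property
    def required_consumables(self) -> list:
        return sorted(self.consumable_availability)

    def validate(self) -> None:
        if self.klass not in ("screening", "preventative", "curative"):
            raise ParameterError(f"intervention {self.name}: unknown class {self.klass!r}")
        if self.emonc_class not in ("none", "BEmONC", "CEmONC"):
            raise ParameterError(f"intervention {self.name}: unknown emonc_class {self.emonc_class!r}")
        if not 0.0 < self.treatment_rr <= 1.0:
            raise ParameterError(f"intervention {self.name}: treatment_rr must be in (0,1]")
        if not 0.0 <= self.competence_prob <= 1.0:
            raise ParameterError(f"intervention {self.name}: competence_prob must be in [0,1]")
        for item, prob in self.consumable_availability.items():
            if not 0.0 <= prob <= 1.0:
                raise ParameterError(
                    f"intervention {self.name}: consumable_availability[{item}] must be in [0,1]"
                )
        for cadre, minutes in self.hcw_minutes.items():
            if cadre not in CADRES:
                raise ParameterError(f"intervention {self.name}: unknown cadre {cadre!r}")
            if minutes < 0:
                raise ParameterError(f"intervention {self.name}: hcw_minutes must be >= 0")
        for h in self.hsi_types:
            if h not in HSI_TYPES:
                raise ParameterError(f"intervention {self.name}: unknown hsi_type {h!r}")


@dataclass
class CareSeekingModel:
    """Logistic care-seeking model for one routine maternity service."""

    service: str  # anc_start | facility_delivery | pnc_maternal | pnc_neonatal
    intercept: float
    coefficients: dict = field(default_factory=dict)

    def linear_predictor(self, person, with_intercept: bool = True) -> float:
        x = covariate_vector(person)
        lp = self.intercept if with_intercept else 0.0
        for name, beta in self.coefficients.items():
            lp += beta * x[name]
        return lp

    def validate(self) -> None:
        for name in self.coefficients:
            if name not in COVARIATE_NAMES:
                raise ParameterError(f"careseeking {self.service}: unknown covariate {name!r}")


COVARIATE_NAMES = ("wealth", "education", "young", "high_parity", "urban")


def covariate_vector(person) -> dict:
    """Sociodemographic covariates used by all care-seeking models."""
    try:
        return {
            "wealth": person.wealth_quintile - 3,
            "education": person.education_level - 1,
            "young": 1.0 if getattr(person, "_age_now", 25) < 20 else 0.0,
            "high_parity": 1.0 if person.parity >= 4 else 0.0,
            "urban": 1.0 if person.urban else 0.0,
        }
    except AttributeError as exc:  # pragma: no cover - defensive
        raise ParameterError(f"missing care-seeking covariate: {exc}") from exc


@dataclass
class ParameterSet:
    """The complete registry every other module reads from."""

    conditions: list = field(default_factory=list)
    interventions: list = field(default_factory=list)
    careseeking: dict = field(default_factory=dict)  # service -> CareSeekingModel
    emergency_careseek_prob: float = 0.7
    delay1_prob: float = 0.35
    delay2_prob: float = 0.30
    squeeze_threshold: float = 3.0
    delay_attenuation: float = 0.25
    monthly_conception_prob: dict = field(default_factory=dict)  # (lo, hi) -> prob
    background_mortality: dict = field(default_factory=dict)  # (lo, hi) -> monthly prob
    anc_minutes: float = 12.0
    pnc_minutes: float = 15.0
    cet_usd: float = 62.3
    spending_growth: float = 0.009
    model_to_real_ratio: float = 58.0
    hcw_daily_minutes_per_1000: dict = field(default_factory=dict)  # (level, cadre) -> minutes
    hsi_minutes: dict = field(default_factory=dict)  # hsi_type -> {cadre: minutes}
    disability_cap: float = 1.0
    life_table: dict = field(default_factory=dict)  # age -> remaining life expectancy
    emonc_staffing_prob: float = 0.8
    facility_hospital_share: float = 0.45
    anc_first_visit_month_dist: dict = field(default_factory=dict)  # gestational month -> prob
    anc_transition_prob: float = 0.82
    anc_truncation_factor: float = 0.97
    risk_flag_prevalence: dict = field(default_factory=dict)
    female_fraction: float = 0.505
    urban_fraction: float = 0.16
    education_dist: dict = field(default_factory=lambda: {0: 0.30, 1: 0.50, 2: 0.20})
    age_band_weights: dict = field(default_factory=dict)  # (lo, hi) -> weight
    postterm_prob: float = 0.06
    coverage_targets: dict = field(
        default_factory=lambda: {
            "anc4": 0.51,
            "facility_delivery": 0.91,
            "pnc_maternal": 0.42,
            "pnc_neonatal": 0.60,
        }
    )

    # -- lookups ----------------------------------------------------------
    def condition(self, name: str) -> ConditionSpec:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)

    def intervention(self, name: str) -> InterventionSpec:
        for iv in self.interventions:
            if iv.name == name:
                return iv
        raise KeyError(name)

    def conditions_in_phase(self, phase: str) -> list:
        return [c for c in self.conditions if phase in c.phases]

    def conception_probability(self, age: int) -> float:
        for (lo, hi), p in self.monthly_conception_prob.items():
            if lo <= age <= hi:
                return p
        return 0.0

    def remaining_life_expectancy(self, age: float) -> float:
        ages = sorted(self.life_table)
        vals = [self.life_table[a] for a in ages]
        return float(np.interp(age, ages, vals))

    def validate(self) -> None:
        names = {iv.name for iv in self.interventions}
        for c in self.conditions:
            c.validate(intervention_names=names)
        for iv in self.interventions:
            iv.validate()
        for model in self.careseeking.values():
            model.validate()
        for fname in (
            "emergency_careseek_prob",
            "delay1_prob",
            "delay2_prob",
            "delay_attenuation",
            "emonc_staffing_prob",
            "facility_hospital_share",
            "female_fraction",
            "urban_fraction",
            "postterm_prob",
        ):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{fname} must be in [0,1], got {v}")
        if not 0.0 <= self.delay_attenuation < 1.0:
            raise ParameterError("delay_attenuation must be in [0,1)")
        if self.squeeze_threshold <= 0:
            raise ParameterError("squeeze_threshold must be positive")
        if self.model_to_real_ratio <= 0:
            raise ParameterError("model_to_real_ratio must be positive")
        if self.disability_cap != 1.0:
            raise ParameterError("disability cap is fixed at 1.0")
        for d in (self.monthly_conception_prob, self.background_mortality):
            for band, p in d.items():
                if not 0.0 <= p <= 1.0:
                    raise ParameterError(f"probability for age band {band} must be in [0,1]")
        dist_total = sum(self.anc_first_visit_month_dist.values())
        if self.anc_first_visit_month_dist and abs(dist_total - 1.0) > 1e-9:
            raise ParameterError("anc_first_visit_month_dist must sum to 1")
        if not self.life_table:
            raise ParameterError("reference life table is empty")


# ---------------------------------------------------------------------------
# default registry
# ---------------------------------------------------------------------------


def _default_conditions() -> list:
    C = ConditionSpec
    return [
        # --- antenatal (monthly probabilities; window in gestational months)
        C("ectopic_pregnancy", "antenatal-monthly", 0.004, window=(1, 2),
          untreated_cfr=0.05, disability_weight=0.114, treatments=["post_abortion_care"],
          ends_pregnancy=True, category="maternal-direct", emergency=True),
        C("abortion_complications", "antenatal-monthly", 0.0035, window=(2, 6),
          untreated_cfr=0.025, disability_weight=0.114, treatments=["post_abortion_care"],
          ends_pregnancy=True, category="maternal-direct", emergency=True),
        C("maternal_anaemia", "antenatal-monthly", 0.030, window=(2, 10),
          modifiers=[("cond:malaria_in_pregnancy", 1.6), ("flag:hiv", 1.3),
                     ("prev:iron_folic_acid", 0.45)],
          untreated_cfr=0.002, disability_weight=0.052, treatments=["blood_transfusion"],
          category="maternal-indirect"),
        C("malaria_in_pregnancy", "antenatal-monthly", 0.010, window=(2, 9),
          modifiers=[("prev:iptp_malaria", 0.45)],
          untreated_cfr=0.002, disability_weight=0.051, category="maternal-indirect"),
        C("syphilis", "antenatal-monthly", 0.0015, window=(1, 9),
          disability_weight=0.035, treatments=["syphilis_treatment"], treatment_resolves=True),
        C("gestational_diabetes", "antenatal-monthly", 0.0045, window=(4, 9),
          disability_weight=0.049, treatments=["gdm_management"], treatment_resolves=True),
        C("gestational_htn_mild", "antenatal-monthly", 0.007, window=(4, 10),
          progression=("gestational_htn_severe", 0.06), treatments=["antihypertensives_oral"]),
        C("gestational_htn_severe", "antenatal-monthly", 0.001, window=(5, 10),
          untreated_cfr=0.004, disability_weight=0.049, treatments=["antihypertensives_iv"],
          category="maternal-direct"),
        C("pre_eclampsia_mild", "antenatal-monthly", 0.009, window=(5, 10),
          modifiers=[("prev:calcium_supplementation", 0.45)],
          progression=("pre_eclampsia_severe", 0.08), treatments=["antihypertensives_oral"]),
        C("pre_eclampsia_severe", "antenatal-monthly", 0.0015, window=(6, 10),
          progression=("eclampsia", 0.07), untreated_cfr=0.005, disability_weight=0.049,
          treatments=["antihypertensives_iv", "mgso4"], category="maternal-direct",
          emergency=True),
        C("eclampsia", "antenatal-monthly", 0.0004, window=(6, 10),
          phases=("antenatal-monthly", "intrapartum", "postnatal-weekly"),
          untreated_cfr=0.10, disability_weight=0.324,
          treatments=["mgso4", "caesarean_section"], category="maternal-direct",
          emergency=True),
        C("antepartum_haemorrhage", "antenatal-monthly", 0.002, window=(7, 10),
          phases=("antenatal-monthly", "intrapartum"),
          untreated_cfr=0.035, disability_weight=0.114,
          treatments=["blood_transfusion", "caesarean_section"], category="maternal-direct",
          emergency=True),
        C("antenatal_stillbirth", "antenatal-monthly", 0.0018, window=(5, 10),
          modifiers=[("cond_untreated:gestational_diabetes", 1.8),
                     ("cond:pre_eclampsia_severe", 1.8), ("cond:eclampsia", 3.0),
                     ("cond_untreated:syphilis", 2.2), ("postterm", 2.5)],
          fetal=True, ends_pregnancy=True, category="stillbirth-antenatal"),
        C("preterm_labour", "antenatal-monthly", 0.055, window=(8, 9),
          modifiers=[("cond:malaria_in_pregnancy", 1.9), ("cond:maternal_anaemia", 1.4)],
          disability_weight=0.0),
        C("post_term_pregnancy", "antenatal-monthly", 0.0, window=(10, 10)),
        # --- intrapartum (per-labour probabilities)
        C("obstructed_labour", "intrapartum", 0.055,
          untreated_cfr=0.004, disability_weight=0.324,
          treatments=["avd", "caesarean_section"], category="maternal-direct",
          emergency=True),
        C("uterine_rupture", "intrapartum", 0.004,
          modifiers=[("cond_untreated:obstructed_labour", 4.0)],
          untreated_cfr=0.22, disability_weight=0.324,
          treatments=["surgical_repair", "blood_transfusion"], category="maternal-direct",
          emergency=True),
        C("sepsis_intrapartum", "intrapartum", 0.012,
          modifiers=[("prev:clean_birth_practices", 0.6), ("flag:hiv", 1.5)],
          untreated_cfr=0.035, disability_weight=0.133, treatments=["iv_antibiotics"],
          category="maternal-direct", emergency=True),
        C("intrapartum_stillbirth", "intrapartum", 0.011,
          modifiers=[("cond:obstructed_labour", 2.0), ("cond:uterine_rupture", 6.0),
                     ("cond:antepartum_haemorrhage", 3.0), ("postterm", 2.0)],
          fetal=True, treatments=["avd", "caesarean_section"],
          category="stillbirth-intrapartum"),
        # --- postnatal (weekly; window in postnatal weeks, (0,0) = at birth)
        C("pph_primary", "postnatal-weekly", 0.050, window=(0, 0),
          modifiers=[("prev:amtsl", 0.4), ("cond:maternal_anaemia", 1.3)],
          untreated_cfr=0.04, disability_weight=0.114,
          treatments=["uterotonics", "blood_transfusion", "pph_surgery"],
          category="maternal-direct", emergency=True),
        C("pph_secondary", "postnatal-weekly", 0.0018, window=(1, 6),
          untreated_cfr=0.02, disability_weight=0.114,
          treatments=["pph_management", "pph_surgery"], category="maternal-direct",
          emergency=True),
        C("sepsis_postnatal", "postnatal-weekly", 0.0022, window=(0, 6),
          modifiers=[("week0", 3.5), ("caesarean", 2.2),
                     ("prev:clean_birth_practices", 0.6), ("flag:hiv", 1.5)],
          untreated_cfr=0.035, disability_weight=0.133, treatments=["iv_antibiotics"],
          category="maternal-direct", emergency=True),
        C("severe_htn_postnatal", "postnatal-weekly", 0.0025, window=(0, 3),
          progression=("eclampsia", 0.02), untreated_cfr=0.003, disability_weight=0.049,
          treatments=["antihypertensives_iv"], category="maternal-direct"),
        # --- neonatal (weekly; window in weeks of life, (0,0) = at birth)
        C("low_birth_weight", "neonatal", 0.10, window=(0, 0),
          modifiers=[("preterm", 6.5)], category="none"),
        C("preterm_rds", "neonatal", 0.30, window=(0, 0), requires="preterm",
          modifiers=[("prev:acs_preterm", 0.5)],
          untreated_cfr=0.32, disability_weight=0.133,
          treatments=["neonatal_full_supportive_care"], category="neonatal",
          emergency=True),
        C("prematurity_other", "neonatal", 0.22, window=(0, 0), requires="preterm",
          untreated_cfr=0.15, disability_weight=0.108,
          treatments=["kangaroo_mother_care", "neonatal_full_supportive_care"],
          category="neonatal"),
        C("neonatal_encephalopathy", "neonatal", 0.016, window=(0, 0),
          modifiers=[("mother_cond:obstructed_labour", 2.5),
                     ("mother_cond:uterine_rupture", 5.0)],
          untreated_cfr=0.32, disability_weight=0.133,
          treatments=["neonatal_resuscitation", "neonatal_full_supportive_care"],
          category="neonatal", emergency=True),
        C("neonatal_sepsis", "neonatal", 0.004, window=(0, 3),
          modifiers=[("cond:low_birth_weight", 1.8), ("week0", 2.5),
                     ("prev:clean_birth_practices", 0.7)],
          untreated_cfr=0.20, disability_weight=0.133,
          treatments=["neonatal_antibiotics", "neonatal_full_supportive_care"],
          category="neonatal", emergency=True),
    ]


def _default_interventions() -> list:
    I = InterventionSpec
    nm = lambda m: {"nurse_midwife": m}  # noqa: E731
    return [
        # --- ANC screening
        I("bp_measurement", "screening", ("anc", "inpatient_antenatal"), competence_prob=0.90,
          detects=("gestational_htn_mild", "gestational_htn_severe",
                   "pre_eclampsia_mild", "pre_eclampsia_severe")),
        I("urine_dipstick", "screening", ("anc",), competence_prob=0.85,
          consumable_availability={"urine_dipstick": 0.65},
          detects=("pre_eclampsia_mild", "pre_eclampsia_severe")),
        I("hb_test", "screening", ("anc",), competence_prob=0.85,
          consumable_availability={"haemoglobinometer": 0.60},
          detects=("maternal_anaemia",)),
        I("syphilis_test", "screening", ("anc",), competence_prob=0.85,
          consumable_availability={"rpr_test_kit": 0.60}, detects=("syphilis",)),
        I("gdm_test", "screening", ("anc",), competence_prob=0.80,
          consumable_availability={"glucose_test_kit": 0.55}, detects=("gestational_diabetes",)),
        # --- ANC preventative
        I("iron_folic_acid", "preventative", ("anc",), competence_prob=0.90,
          consumable_availability={"iron_folic_acid": 0.70}),
        I("calcium_supplementation", "preventative", ("anc",), competence_prob=0.85,
          consumable_availability={"calcium": 0.50}, indication="primigravida"),
        I("iptp_malaria", "preventative", ("anc",), competence_prob=0.90,
          consumable_availability={"sulfadoxine_pyrimethamine": 0.75}),
        I("syphilis_treatment", "preventative", ("anc",), competence_prob=0.90,
          consumable_availability={"benzathine_penicillin": 0.70}, treatment_rr=0.1,
          indication="detected"),
        # --- inpatient antenatal / emergency antenatal care
        I("gdm_management", "curative", ("inpatient_antenatal",), competence_prob=0.85,
          consumable_availability={"insulin": 0.55}, treatment_rr=0.6,
          hcw_minutes={"nurse_midwife": 15, "clinician": 10}),
        I("antihypertensives_oral", "curative", ("inpatient_antenatal", "anc"),
          competence_prob=0.85, consumable_availability={"methyldopa": 0.60},
          treatment_rr=0.50, indication="detected"),
        I("antihypertensives_iv", "curative",
          ("inpatient_antenatal", "delivery_bemonc", "delivery_cemonc", "pnc_maternal"), competence_prob=0.85,
          consumable_availability={"hydralazine": 0.55}, treatment_rr=0.50,
          hcw_minutes={"nurse_midwife": 10}),
        I("mgso4", "curative", ("inpatient_antenatal", "delivery_bemonc", "delivery_cemonc", "pnc_maternal"),
          emonc_class="BEmONC", competence_prob=0.85,
          consumable_availability={"magnesium_sulphate": 0.55}, treatment_rr=0.41,
          hcw_minutes={"nurse_midwife": 10}),
        I("post_abortion_care", "curative", ("pac",), competence_prob=0.85,
          consumable_availability={"pac_kit": 0.70}, treatment_rr=0.25,
          hcw_minutes={"nurse_midwife": 30, "clinician": 10}),
        # --- facility delivery: prophylactic
        I("clean_birth_practices", "preventative", ("delivery_bemonc", "delivery_cemonc"), competence_prob=0.90,
          consumable_availability={"clean_birth_kit": 0.70}),
        I("acs_preterm", "preventative", ("delivery_bemonc", "delivery_cemonc"), competence_prob=0.80,
          consumable_availability={"dexamethasone": 0.50}, indication="preterm"),
        I("amtsl", "preventative", ("delivery_bemonc", "delivery_cemonc"), competence_prob=0.85,
          consumable_availability={"oxytocin": 0.60}),
        # --- facility delivery: BEmONC curative
        I("avd", "curative", ("delivery_bemonc", "delivery_cemonc"), emonc_class="BEmONC", competence_prob=0.75,
          consumable_availability={"vacuum_extractor": 0.50}, treatment_rr=0.50,
          hcw_minutes={"nurse_midwife": 20}),
        I("iv_antibiotics", "curative", ("delivery_bemonc", "delivery_cemonc", "inpatient_antenatal", "pnc_maternal"),
          emonc_class="BEmONC", competence_prob=0.85,
          consumable_availability={"iv_antibiotics": 0.65}, treatment_rr=0.35,
          hcw_minutes={"nurse_midwife": 10}),
        I("uterotonics", "curative", ("delivery_bemonc", "delivery_cemonc"), emonc_class="BEmONC",
          competence_prob=0.85, consumable_availability={"oxytocin": 0.60}, treatment_rr=0.35,
          hcw_minutes={"nurse_midwife": 15}),
        I("neonatal_resuscitation", "curative", ("delivery_bemonc", "delivery_cemonc"), emonc_class="BEmONC",
          competence_prob=0.70, consumable_availability={"bag_valve_mask": 0.60},
          treatment_rr=0.45, hcw_minutes={"nurse_midwife": 15}),
        # --- facility delivery: CEmONC curative (hospital)
        I("caesarean_section", "curative", ("delivery_cemonc",), emonc_class="CEmONC",
          competence_prob=0.85, consumable_availability={"surgical_kit": 0.55},
          treatment_rr=0.40, hcw_minutes={"clinician": 60, "nurse_midwife": 30}),
        I("surgical_repair", "curative", ("delivery_cemonc",), emonc_class="CEmONC",
          competence_prob=0.85, consumable_availability={"surgical_kit": 0.55},
          treatment_rr=0.35, hcw_minutes={"clinician": 60, "nurse_midwife": 30}),
        I("blood_transfusion", "curative",
          ("delivery_cemonc", "inpatient_antenatal", "cemonc_postnatal"), emonc_class="CEmONC",
          competence_prob=0.85, consumable_availability={"blood": 0.45}, treatment_rr=0.45,
          hcw_minutes={"nurse_midwife": 15}),
        # --- postnatal care, maternal
        I("pph_management", "curative", ("pnc_maternal",), emonc_class="BEmONC",
          competence_prob=0.85, consumable_availability={"oxytocin": 0.60}, treatment_rr=0.35,
          hcw_minutes={"nurse_midwife": 15}),
        # --- postnatal care, neonatal
        I("neonatal_antibiotics", "curative", ("pnc_neonatal",), competence_prob=0.80,
          consumable_availability={"gentamicin": 0.60}, treatment_rr=0.30,
          hcw_minutes={"nurse_midwife": 10}),
        I("neonatal_full_supportive_care", "curative", ("pnc_neonatal",), emonc_class="BEmONC",
          competence_prob=0.80, consumable_availability={"neonatal_support_kit": 0.50},
          treatment_rr=0.45, hcw_minutes={"nurse_midwife": 30, "clinician": 10}),
        I("kangaroo_mother_care", "curative", ("pnc_neonatal",), competence_prob=0.70,
          treatment_rr=0.49, hcw_minutes=nm(10)),
        # --- postnatal CEmONC
        I("pph_surgery", "curative", ("cemonc_postnatal",), emonc_class="CEmONC",
          competence_prob=0.85, consumable_availability={"surgical_kit": 0.55},
          treatment_rr=0.30, hcw_minutes={"clinician": 60, "nurse_midwife": 30}),
    ]


# GBD-style reference remaining life expectancy (synthetic approximation)
_LIFE_TABLE = {
    0: 88.9, 1: 88.0, 5: 84.0, 10: 79.1, 15: 74.1, 20: 69.1, 25: 64.2,
    30: 59.2, 35: 54.3, 40: 49.3, 45: 44.4, 50: 39.5, 55: 34.6, 60: 29.8,
    65: 25.1, 70: 20.5, 75: 16.2, 80: 12.2, 85: 8.9, 90: 6.2,
}

_AGE_BAND_WEIGHTS = {
    (0, 4): 0.158, (5, 9): 0.145, (10, 14): 0.132, (15, 19): 0.115,
    (20, 24): 0.095, (25, 29): 0.077, (30, 34): 0.061, (35, 39): 0.049,
    (40, 44): 0.039, (45, 49): 0.031, (50, 54): 0.025, (55, 59): 0.020,
    (60, 64): 0.016, (65, 69): 0.013, (70, 74): 0.010, (75, 79): 0.008,
    (80, 89): 0.006,
}

_CONCEPTION = {
    (15, 19): 0.008, (20, 24): 0.016, (25, 29): 0.015, (30, 34): 0.012,
    (35, 39): 0.009, (40, 44): 0.004, (45, 49): 0.001,
}

_BACKGROUND_MORTALITY = {
    (0, 4): 0.0006, (5, 14): 0.0001, (15, 49): 0.00025, (50, 69): 0.0008,
    (70, 120): 0.006,
}

_CARESEEKING_COEFS = {
    "anc_start": {"wealth": 0.15, "education": 0.25, "young": -0.20, "high_parity": -0.25, "urban": 0.30},
    "facility_delivery": {"wealth": 0.20, "education": 0.30, "young": -0.10, "high_parity": -0.30, "urban": 0.40},
    "pnc_maternal": {"wealth": 0.15, "education": 0.20, "young": -0.15, "high_parity": -0.20, "urban": 0.25},
    "pnc_neonatal": {"wealth": 0.15, "education": 0.20, "young": -0.15, "high_parity": -0.20, "urban": 0.25},
}

_ANC_FIRST_VISIT_DIST = {2: 0.10, 3: 0.22, 4: 0.30, 5: 0.25, 6: 0.13}


def solve_logit_intercept(target: float, lps_without_intercept: np.ndarray) -> float:
    """Intercept such that mean inverse-logit over the cohort equals target."""
    if not 0.0 < target < 1.0:
        raise ParameterError(f"coverage target must be in (0,1), got {target}")
    lp = np.asarray(lps_without_intercept, dtype=float)

    def gap(b0):
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + lp))))) - target

    return float(brentq(gap, -25.0, 25.0, xtol=1e-10))


def anc4_chain_probability(first_visit_dist: dict, transition_prob: float,
                           truncation_factor: float = 1.0) -> float:
    """P(>= 4 contacts | any ANC) under the visit chain.

    Visits occur in consecutive gestational months starting at the first-visit
    month; each subsequent visit is attended with ``transition_prob``; four
    visits require three successful transitions and a start no later than
    month 6 (visits through the month of a term delivery).  The truncation
    factor absorbs pregnancy loss and preterm delivery before visit four.
    """
    q = sum(p for m, p in first_visit_dist.items() if m <= 6) * transition_prob**3
    return q * truncation_factor


def generate_default_parameters(seed: int = 0) -> ParameterSet:
    """Build the complete synthetic parameter set.

    Deterministic for a given seed: the seed only drives the synthetic
    covariate cohort used to solve care-seeking intercepts against the
    coverage targets, so repeated calls serialise byte-identically.
    """
    ps = ParameterSet(
        conditions=_default_conditions(),
        interventions=_default_interventions(),
        monthly_conception_prob=dict(_CONCEPTION),
        background_mortality=dict(_BACKGROUND_MORTALITY),
        hcw_daily_minutes_per_1000={
            ("health-centre", "nurse_midwife"): 0.45,
            ("health-centre", "clinician"): 0.08,
            ("district-hospital", "nurse_midwife"): 0.55,
            ("district-hospital", "clinician"): 0.25,
            ("central-hospital", "nurse_midwife"): 0.30,
            ("central-hospital", "clinician"): 0.15,
        },
        hsi_minutes={
            "anc": {"nurse_midwife": 12.0},
            "inpatient_antenatal": {"nurse_midwife": 30.0, "clinician": 10.0},
            "pac": {"nurse_midwife": 30.0, "clinician": 10.0},
            "delivery_bemonc": {"nurse_midwife": 60.0},
            "delivery_cemonc": {"nurse_midwife": 60.0, "clinician": 20.0},
            "pnc_maternal": {"nurse_midwife": 15.0},
            "pnc_neonatal": {"nurse_midwife": 15.0},
            "cemonc_postnatal": {"nurse_midwife": 30.0, "clinician": 40.0},
        },
        life_table=dict(_LIFE_TABLE),
        anc_first_visit_month_dist=dict(_ANC_FIRST_VISIT_DIST),
        risk_flag_prevalence={"malaria": 0.05, "hiv": 0.09, "depression": 0.05},
        age_band_weights=dict(_AGE_BAND_WEIGHTS),
    )
    # solve care-seeking intercepts against the coverage targets over a
    # synthetic cohort of women of reproductive age
    cohort = [p for p in make_fixture_population(4000, seed=seed, params=ps)
              if p.sex == "F" and 15 <= p.age_years(dt.date(2023, 1, 1)) <= 49]
    for w in cohort:
        w._age_now = w.age_years(dt.date(2023, 1, 1))
    targets = ps.coverage_targets
    q4 = anc4_chain_probability(ps.anc_first_visit_month_dist, ps.anc_transition_prob,
                                ps.anc_truncation_factor)
    service_targets = {
        "anc_start": min(targets["anc4"] / q4, 0.97),
        "facility_delivery": targets["facility_delivery"],
        "pnc_maternal": targets["pnc_maternal"],
        "pnc_neonatal": targets["pnc_neonatal"],
    }
    for service, coefs in _CARESEEKING_COEFS.items():
        model = CareSeekingModel(service=service, intercept=0.0, coefficients=dict(coefs))
        lps = np.array([model.linear_predictor(w, with_intercept=False) for w in cohort])
        model.intercept = solve_logit_intercept(service_targets[service], lps)
        ps.careseeking[service] = model
    ps.validate()
    return ps


# ---------------------------------------------------------------------------
# fixture populations
# ---------------------------------------------------------------------------


def make_fixture_population(n: int, seed: int, params: ParameterSet | None = None,
                            reference_date: dt.date = dt.date(2010, 1, 1)) -> list:
    """Draw ``n`` persons from the configured demographic marginals."""
    if n < 1:
        raise ValueError("fixture population size must be >= 1")
    female_fraction = params.female_fraction if params else 0.505
    urban_fraction = params.urban_fraction if params else 0.16
    education_dist = params.education_dist if params else {0: 0.30, 1: 0.50, 2: 0.20}
    band_weights = params.age_band_weights if params and params.age_band_weights else _AGE_BAND_WEIGHTS
    flag_prev = params.risk_flag_prevalence if params else {"malaria": 0.05, "hiv": 0.09, "depression": 0.05}

    rng = RandomSource(seed).generator("fixture-population")
    bands = list(band_weights)
    weights = np.array([band_weights[b] for b in bands], dtype=float)
    weights /= weights.sum()
    edu_levels = sorted(education_dist)
    edu_probs = np.array([education_dist[k] for k in edu_levels], dtype=float)
    edu_probs /= edu_probs.sum()

    persons = []
    band_idx = rng.choice(len(bands), size=n, p=weights)
    sexes = rng.random(n) < female_fraction
    urbans = rng.random(n) < urban_fraction
    wealth = rng.integers(1, 6, size=n)
    edu = rng.choice(edu_levels, size=n, p=edu_probs)
    for i in range(n):
        lo, hi = bands[band_idx[i]]
        age_days = int(rng.integers(lo * 365, (hi + 1) * 365))
        dob = reference_date - dt.timedelta(days=age_days)
        p = PersonRecord(
            id=i, sex="F" if sexes[i] else "M", date_of_birth=dob,
            urban=bool(urbans[i]), wealth_quintile=int(wealth[i]),
            education_level=int(edu[i]),
        )
        age = p.age_years(reference_date)
        if p.sex == "F" and age >= 15:
            # parity rises with age; crude gravidity ladder
            p.parity = int(min(rng.poisson(max(age - 17, 0) * 0.22), 9))
        for flag, prev in flag_prev.items():
            if rng.random() < prev:
                p.risk_flags.add(flag)
        p.check_invariants()
        persons.append(p)
    return persons


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------


def _enc_pairs(pairs, kv_sep="=", item_sep="|") -> str:
    return item_sep.join(f"{k}{kv_sep}{v}" for k, v in pairs)


def _dec_pairs(s: str, cast=float, kv_sep="=", item_sep="|") -> list:
    if not s or (isinstance(s, float) and math.isnan(s)):
        return []
    out = []
    for item in str(s).split(item_sep):
        k, v = item.rsplit(kv_sep, 1)
        out.append((k, cast(v)))
    return out


def _conditions_frame(conditions) -> pd.DataFrame:
    rows = []
    for c in conditions:
        rows.append({
            "name": c.name, "phase": c.phase, "phases": ";".join(c.phases),
            "baseline_risk": c.baseline_risk,
            "modifiers": _enc_pairs(c.modifiers),
            "progression_target": c.progression[0] if c.progression else "",
            "progression_prob": c.progression[1] if c.progression else "",
            "untreated_cfr": c.untreated_cfr, "disability_weight": c.disability_weight,
            "treatments": ";".join(c.treatments),
            "window_lo": c.window[0], "window_hi": c.window[1],
            "requires": c.requires, "ends_pregnancy": c.ends_pregnancy,
            "fetal": c.fetal, "category": c.category, "emergency": c.emergency,
            "treatment_resolves": c.treatment_resolves,
        })
    return pd.DataFrame(rows)


def _conditions_from_frame(df: pd.DataFrame) -> list:
    out = []
    for _, r in df.iterrows():
        for req in ("baseline_risk", "untreated_cfr", "disability_weight"):
            if r[req] == "" or pd.isna(r[req]):
                raise ParameterError(f"condition {r['name']}: missing {req}")
        prog = None
        if str(r["progression_target"]):
            prog = (str(r["progression_target"]), float(r["progression_prob"]))
        out.append(ConditionSpec(
            name=str(r["name"]), phase=str(r["phase"]),
            phases=tuple(str(r["phases"]).split(";")),
            baseline_risk=float(r["baseline_risk"]),
            modifiers=_dec_pairs(r["modifiers"]),
            progression=prog,
            untreated_cfr=float(r["untreated_cfr"]),
            disability_weight=float(r["disability_weight"]),
            treatments=[t for t in str(r["treatments"]).split(";") if t],
            window=(int(r["window_lo"]), int(r["window_hi"])),
            requires=str(r["requires"]) if str(r["requires"]) != "nan" else "",
            ends_pregnancy=bool(r["ends_pregnancy"]), fetal=bool(r["fetal"]),
            category=str(r["category"]), emergency=bool(r["emergency"]),
            treatment_resolves=bool(r["treatment_resolves"]),
        ))
    return out


def _interventions_frame(interventions) -> pd.DataFrame:
    rows = []
    for iv in interventions:
        rows.append({
            "name": iv.name, "klass": iv.klass, "hsi_types": ";".join(iv.hsi_types),
            "emonc_class": iv.emonc_class,
            "consumable_availability": _enc_pairs(iv.consumable_availability.items()),
            "competence_prob": iv.competence_prob,
            "hcw_minutes": _enc_pairs(iv.hcw_minutes.items()),
            "treatment_rr": iv.treatment_rr, "detects": ";".join(iv.detects),
            "indication": iv.indication,
        })
    return pd.DataFrame(rows)


def _interventions_from_frame(df: pd.DataFrame) -> list:
    out = []
    for _, r in df.iterrows():
        out.append(InterventionSpec(
            name=str(r["name"]), klass=str(r["klass"]),
            hsi_types=tuple(str(r["hsi_types"]).split(";")),
            emonc_class=str(r["emonc_class"]),
            consumable_availability=dict(_dec_pairs(r["consumable_availability"])),
            competence_prob=float(r["competence_prob"]),
            hcw_minutes=dict(_dec_pairs(r["hcw_minutes"])),
            treatment_rr=float(r["treatment_rr"]),
            detects=tuple(t for t in str(r["detects"]).split(";") if t and t != "nan"),
            indication=str(r["indication"]),
        ))
    return out


def _band_dict_to_list(d: dict) -> list:
    return [[int(lo), int(hi), float(v)] for (lo, hi), v in sorted(d.items())]


def _band_dict_from_list(rows) -> dict:
    return {(int(lo), int(hi)): float(v) for lo, hi, v in rows}


def write_parameters(path: str | Path, ps: ParameterSet) -> None:
    """Write a parameter set to a directory: CSVs + manifest.yaml."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _conditions_frame(ps.conditions).to_csv(path / "conditions.csv", index=False)
    _interventions_frame(ps.interventions).to_csv(path / "interventions.csv", index=False)
    cs_rows = [{"service": m.service, "intercept": repr(m.intercept),
                "coefficients": _enc_pairs(m.coefficients.items())}
               for m in ps.careseeking.values()]
    pd.DataFrame(cs_rows).to_csv(path / "careseeking.csv", index=False)
    manifest = {
        "emergency_careseek_prob": ps.emergency_careseek_prob,
        "delay1_prob": ps.delay1_prob, "delay2_prob": ps.delay2_prob,
        "squeeze_threshold": ps.squeeze_threshold,
        "delay_attenuation": ps.delay_attenuation,
        "monthly_conception_prob": _band_dict_to_list(ps.monthly_conception_prob),
        "background_mortality": _band_dict_to_list(ps.background_mortality),
        "anc_minutes": ps.anc_minutes, "pnc_minutes": ps.pnc_minutes,
        "cet_usd": ps.cet_usd, "spending_growth": ps.spending_growth,
        "model_to_real_ratio": ps.model_to_real_ratio,
        "hcw_daily_minutes_per_1000": [[lvl, cad, v] for (lvl, cad), v
                                       in sorted(ps.hcw_daily_minutes_per_1000.items())],
        "hsi_minutes": {k: dict(v) for k, v in ps.hsi_minutes.items()},
        "disability_cap": ps.disability_cap,
        "life_table": {int(k): float(v) for k, v in ps.life_table.items()},
        "emonc_staffing_prob": ps.emonc_staffing_prob,
        "facility_hospital_share": ps.facility_hospital_share,
        "anc_first_visit_month_dist": {int(k): float(v)
                                       for k, v in ps.anc_first_visit_month_dist.items()},
        "anc_transition_prob": ps.anc_transition_prob,
        "anc_truncation_factor": ps.anc_truncation_factor,
        "risk_flag_prevalence": dict(ps.risk_flag_prevalence),
        "female_fraction": ps.female_fraction, "urban_fraction": ps.urban_fraction,
        "education_dist": {int(k): float(v) for k, v in ps.education_dist.items()},
        "age_band_weights": _band_dict_to_list(ps.age_band_weights),
        "postterm_prob": ps.postterm_prob,
        "coverage_targets": dict(ps.coverage_targets),
    }
    (path / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))


def read_parameters(path: str | Path) -> ParameterSet:
    """Read a parameter set written by :func:`write_parameters`; validates."""
    path = Path(path)
    try:
        conditions = _conditions_from_frame(
            pd.read_csv(path / "conditions.csv", keep_default_na=False,
                        float_precision="round_trip"))
        interventions = _interventions_from_frame(
            pd.read_csv(path / "interventions.csv", keep_default_na=False,
                        float_precision="round_trip"))
        cs_df = pd.read_csv(path / "careseeking.csv", keep_default_na=False,
                            float_precision="round_trip")
        manifest = yaml.safe_load((path / "manifest.yaml").read_text())
    except FileNotFoundError as exc:
        raise ParameterError(f"parameter directory incomplete: {exc}") from exc
    careseeking = {}
    for _, r in cs_df.iterrows():
        careseeking[str(r["service"])] = CareSeekingModel(
            service=str(r["service"]), intercept=float(r["intercept"]),
            coefficients=dict(_dec_pairs(r["coefficients"])),
        )
    ps = ParameterSet(
        conditions=conditions, interventions=interventions, careseeking=careseeking,
        emergency_careseek_prob=manifest["emergency_careseek_prob"],
        delay1_prob=manifest["delay1_prob"], delay2_prob=manifest["delay2_prob"],
        squeeze_threshold=float(manifest["squeeze_threshold"]),
        delay_attenuation=manifest["delay_attenuation"],
        monthly_conception_prob=_band_dict_from_list(manifest["monthly_conception_prob"]),
        background_mortality=_band_dict_from_list(manifest["background_mortality"]),
        anc_minutes=manifest["anc_minutes"], pnc_minutes=manifest["pnc_minutes"],
        cet_usd=manifest["cet_usd"], spending_growth=manifest["spending_growth"],
        model_to_real_ratio=manifest["model_to_real_ratio"],
        hcw_daily_minutes_per_1000={(lvl, cad): float(v) for lvl, cad, v
                                    in manifest["hcw_daily_minutes_per_1000"]},
        hsi_minutes={k: {c: float(m) for c, m in v.items()}
                     for k, v in manifest["hsi_minutes"].items()},
        disability_cap=manifest["disability_cap"],
        life_table={int(k): float(v) for k, v in manifest["life_table"].items()},
        emonc_staffing_prob=manifest["emonc_staffing_prob"],
        facility_hospital_share=manifest["facility_hospital_share"],
        anc_first_visit_month_dist={int(k): float(v)
                                    for k, v in manifest["anc_first_visit_month_dist"].items()},
        anc_transition_prob=manifest["anc_transition_prob"],
        anc_truncation_factor=manifest["anc_truncation_factor"],
        risk_flag_prevalence=dict(manifest["risk_flag_prevalence"]),
        female_fraction=manifest["female_fraction"],
        urban_fraction=manifest["urban_fraction"],
        education_dist={int(k): float(v) for k, v in manifest["education_dist"].items()},
        age_band_weights=_band_dict_from_list(manifest["age_band_weights"]),
        postterm_prob=manifest["postterm_prob"],
        coverage_targets=dict(manifest["coverage_targets"]),
    )
    ps.validate()
    return ps


def parameters_to_json(ps: ParameterSet) -> str:
    """Merged JSON export of the full parameter set."""

    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (set, tuple)):
            return list(o)
        raise TypeError(type(o))

    merged = {
        "conditions": [dataclasses.asdict(c) for c in ps.conditions],
        "interventions": [dataclasses.asdict(iv) for iv in ps.interventions],
        "careseeking": {k: dataclasses.asdict(v) for k, v in ps.careseeking.items()},
        "scalars": {
            k: v for k, v in dataclasses.asdict(ps).items()
            if k not in ("conditions", "interventions", "careseeking")
            and not isinstance(v, dict)
        },
        "tables": {
            "monthly_conception_prob": _band_dict_to_list(ps.monthly_conception_prob),
            "background_mortality": _band_dict_to_list(ps.background_mortality),
            "life_table": ps.life_table,
            "hcw_daily_minutes_per_1000": [[l, c, v] for (l, c), v
                                           in sorted(ps.hcw_daily_minutes_per_1000.items())],
        },
    }
    return json.dumps(merged, indent=2, default=default, sort_keys=True)


def parameter_sets_equal(a: ParameterSet, b: ParameterSet) -> bool:
    return parameters_to_json(a) == parameters_to_json(b)
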