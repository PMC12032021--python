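"""The sixteen service-delivery scenarios as override bundles.

Each scenario modifies coverage (care-seeking), quality (intervention
delivery probabilities), or both, for antenatal, intrapartum and/or postnatal
services, taking effect on the intervention date (2023-01-01).  Coverage
targets are met by re-solving care-seeking intercepts against the current
covariate distribution so sociodemographic gradients persist; "max."
scenarios pin probabilities outright.  Care delivered after pregnancy loss
(post-abortion / ectopic case management) is never modified.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np

from .health_system import ServiceOverrides
from .params import ParameterSet, anc4_chain_probability, solve_logit_intercept

INTERVENTION_DATE = dt.date(2023, 1, 1)

SCENARIO_NAMES = (
    "SQ",
    "AN coverage", "AN coverage and qual.", "AN max.", "AN min.",
    "IP BEmONC", "IP CEmONC", "IP max.", "IP min.",
    "PN coverage", "PN coverage and qual.", "PN max.", "PN min.",
    "All services coverage", "All services coverage and qual.",
    "All services max.", "All services min.",
)

_PIN_ON = 30.0  # logit intercept numerically equivalent to probability 1


@dataclass
class ScenarioConfig:
    """A named bundle of coverage/quality overrides."""

    short_name: str
    effective_date: dt.date = INTERVENTION_DATE
    anc4_target: float | None = None
    anc_first_trimester_all: bool = False
    anc_transition_prob_pin: float | None = None
    anc_start_all: bool = False
    facility_delivery_coverage: float | None = None
    prophylactic_delivery_prob: float | None = None
    bemonc_delivery_prob: float | None = None
    cemonc_delivery_prob: float | None = None
    pnc_coverage_target: float | None = None
    pnc_within_48h: bool = False
    emergency_careseek_antenatal: float | None = None
    emergency_careseek_postnatal: float | None = None
    quality_max: set = field(default_factory=set)
    delay3_disabled: set = field(default_factory=set)
    service_disabled: set = field(default_factory=set)

    def is_sq(self) -> bool:
        return self == ScenarioConfig(short_name=self.short_name)


def _an_coverage() -> ScenarioConfig:
    return ScenarioConfig("AN coverage", anc4_target=0.90)


def _an_coverage_qual() -> ScenarioConfig:
    return replace(_an_coverage(), short_name="AN coverage and qual.",
                   quality_max={"anc", "inpatient_antenatal"},
                   delay3_disabled={"inpatient_antenatal"})


def _an_max() -> ScenarioConfig:
    return ScenarioConfig(
        "AN max.", anc_first_trimester_all=True, anc_transition_prob_pin=1.0,
        anc_start_all=True, emergency_careseek_antenatal=1.0,
        quality_max={"anc", "inpatient_antenatal"},
        delay3_disabled={"inpatient_antenatal"})


def _an_min() -> ScenarioConfig:
    return ScenarioConfig("AN min.", service_disabled={"anc"},
                          emergency_careseek_antenatal=0.0)


def _ip_bemonc() -> ScenarioConfig:
    return ScenarioConfig("IP BEmONC", prophylactic_delivery_prob=0.90,
                          bemonc_delivery_prob=0.90, delay3_disabled={"delivery"})


def _ip_cemonc() -> ScenarioConfig:
    return replace(_ip_bemonc(), short_name="IP CEmONC", cemonc_delivery_prob=0.90)


def _ip_max() -> ScenarioConfig:
    return ScenarioConfig(
        "IP max.", facility_delivery_coverage=1.0, prophylactic_delivery_prob=1.0,
        bemonc_delivery_prob=1.0, cemonc_delivery_prob=1.0,
        delay3_disabled={"delivery"})


def _ip_min() -> ScenarioConfig:
    # delivery-intervention probabilities zero; facility attendance unchanged
    return ScenarioConfig("IP min.", prophylactic_delivery_prob=0.0,
                          bemonc_delivery_prob=0.0, cemonc_delivery_prob=0.0)


def _pn_coverage() -> ScenarioConfig:
    return ScenarioConfig("PN coverage", pnc_coverage_target=0.90, pnc_within_48h=True)


def _pn_coverage_qual() -> ScenarioConfig:
    return replace(_pn_coverage(), short_name="PN coverage and qual.",
                   quality_max={"pnc", "inpatient_postnatal"},
                   delay3_disabled={"inpatient_postnatal"})


def _pn_max() -> ScenarioConfig:
    return ScenarioConfig(
        "PN max.", pnc_coverage_target=1.0, pnc_within_48h=True,
        emergency_careseek_postnatal=1.0,
        quality_max={"pnc", "inpatient_postnatal"},
        delay3_disabled={"pnc", "inpatient_postnatal"})


def _pn_min() -> ScenarioConfig:
    return ScenarioConfig("PN min.", service_disabled={"pnc"},
                          emergency_careseek_postnatal=0.0)


def _union(name: str, *parts: ScenarioConfig) -> ScenarioConfig:
    """Composite scenarios equal the union of their components' overrides."""
    out = ScenarioConfig(short_name=name)
    for part in parts:
        for f in (
            "anc4_target", "anc_transition_prob_pin", "facility_delivery_coverage",
            "prophylactic_delivery_prob", "bemonc_delivery_prob",
            "cemonc_delivery_prob", "pnc_coverage_target",
            "emergency_careseek_antenatal", "emergency_careseek_postnatal",
        ):
            v = getattr(part, f)
            if v is not None:
                setattr(out, f, v)
        for f in ("anc_first_trimester_all", "anc_start_all", "pnc_within_48h"):
            if getattr(part, f):
                setattr(out, f, True)
        out.quality_max |= part.quality_max
        out.delay3_disabled |= part.delay3_disabled
        out.service_disabled |= part.service_disabled
    return out


_BUILDERS = {
    "SQ": lambda: ScenarioConfig("SQ"),
    "AN coverage": _an_coverage,
    "AN coverage and qual.": _an_coverage_qual,
    "AN max.": _an_max,
    "AN min.": _an_min,
    "IP BEmONC": _ip_bemonc,
    "IP CEmONC": _ip_cemonc,
    "IP max.": _ip_max,
    "IP min.": _ip_min,
    "PN coverage": _pn_coverage,
    "PN coverage and qual.": _pn_coverage_qual,
    "PN max.": _pn_max,
    "PN min.": _pn_min,
    "All services coverage": lambda: _union(
        "All services coverage", _an_coverage(), _ip_bemonc(), _pn_coverage()),
    "All services coverage and qual.": lambda: _union(
        "All services coverage and qual.", _an_coverage_qual(), _ip_cemonc(),
        _pn_coverage_qual()),
    "All services max.": lambda: _union(
        "All services max.", _an_max(), _ip_max(), _pn_max()),
    "All services min.": lambda: _union(
        "All services min.", _an_min(), _ip_min(), _pn_min()),
}


def build_scenario(short_name: str) -> ScenarioConfig:
    """The exact override bundle for one of the sixteen scenario short names."""
    try:
        return _BUILDERS[short_name]()
    except KeyError:
        raise KeyError(f"unknown scenario {short_name!r}; known: {SCENARIO_NAMES}") from None


def apply_scenario(config: ScenarioConfig, params: ParameterSet, date: dt.date,
                   cohort=None) -> ServiceOverrides:
    """Service overrides in force on ``date`` (empty before the switch-on).

    Coverage targets are converted to re-solved care-seeking intercepts
    against the covariate distribution of ``cohort`` (women of reproductive
    age; a synthetic cohort is drawn when omitted), performed once at
    switch-on by the engine.
    """
    if date < config.effective_date:
        return ServiceOverrides()
    ov = ServiceOverrides(
        quality_max=set(config.quality_max),
        delay3_disabled=set(config.delay3_disabled),
        service_disabled=set(config.service_disabled),
        emergency_careseek_antenatal=config.emergency_careseek_antenatal,
        emergency_careseek_postnatal=config.emergency_careseek_postnatal,
        anc_first_trimester_all=config.anc_first_trimester_all,
        anc_transition_prob=config.anc_transition_prob_pin,
    )
    for key, p in (("delivery:prophylactic", config.prophylactic_delivery_prob),
                   ("delivery:BEmONC", config.bemonc_delivery_prob),
                   ("delivery:CEmONC", config.cemonc_delivery_prob)):
        if p is not None:
            ov.fixed_delivery_prob[key] = p

    needs_cohort = any(v is not None for v in (
        config.anc4_target, config.facility_delivery_coverage, config.pnc_coverage_target))
    if needs_cohort and cohort is None:
        from .params import make_fixture_population
        ref = dt.date(2023, 1, 1)
        cohort = [p for p in make_fixture_population(3000, seed=7, params=params)
                  if p.sex == "F" and 15 <= p.age_years(ref) <= 49]
        for w in cohort:
            w._age_now = w.age_years(ref)

    def solve(service: str, target: float) -> float:
        model = params.careseeking[service]
        lps = np.array([model.linear_predictor(w, with_intercept=False) for w in cohort])
        return solve_logit_intercept(target, lps)

    if config.anc_start_all:
        ov.anc_start_intercept = _PIN_ON
    elif config.anc4_target is not None:
        # the visit chain caps ANC4+ below the start probability; raise the
        # per-transition probability before re-solving the start intercept
        tp = max(params.anc_transition_prob, 0.99)
        ov.anc_transition_prob = tp
        q4 = anc4_chain_probability(params.anc_first_visit_month_dist, tp,
                                    params.anc_truncation_factor)
        ov.anc_start_intercept = solve("anc_start", min(config.anc4_target / q4, 0.99))

    if config.facility_delivery_coverage is not None:
        if config.facility_delivery_coverage >= 0.999:
            ov.facility_all = True
        else:
            ov.facility_intercept = solve("facility_delivery", config.facility_delivery_coverage)

    if config.pnc_coverage_target is not None:
        if config.pnc_coverage_target >= 0.999:
            ov.pnc_all = True
        else:
            ov.pnc_maternal_intercept = solve("pnc_maternal", config.pnc_coverage_target)
            ov.pnc_neonatal_intercept = solve("pnc_neonatal", config.pnc_coverage_target)
    return ov
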