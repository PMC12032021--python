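"""Maternity-service delivery: care-seeking, quality of care, the three delays.

A health system interaction (HSI) is a discrete event in which care is
delivered, defined by its facility level, required consumables, and required
healthcare-worker time by cadre.  An indicated intervention is delivered iff
every required consumable is available, the worker identifies the need
(clinical competence) and - for EmONC interventions - appropriately trained
staff are present.  Over-demand of worker time produces a "squeeze"
(required/available - 1); squeeze above a threshold triggers delay three,
which (like delays one and two) attenuates treatment effectiveness.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

from .cohort import PersonRecord
from .params import (
    CareSeekingModel,
    HSI_SERVICE,
    InterventionSpec,
    ParameterSet,
    covariate_vector,  # noqa: F401  (re-exported: the care-seeking covariates)
)

__all__ = [
    "CareSeekingModel", "HSIEvent", "HcwLedger", "ServiceOverrides",
    "careseeking_probability", "plan_anc_schedule", "emergency_careseeking",
    "compute_squeeze_factor", "assess_delays", "attempt_intervention_delivery",
    "execute_hsi", "indicated_interventions",
]


@dataclass
class HSIEvent:
    """Record of one executed health system interaction."""

    person_id: int
    hsi_type: str
    facility_level: str
    date: dt.date | None
    required_minutes: dict = field(default_factory=dict)  # cadre -> minutes
    squeeze: float = 0.0
    delays: tuple = (False, False, False)
    attempted_interventions: list = field(default_factory=list)
    delivered_interventions: list = field(default_factory=list)


@dataclass
class ServiceOverrides:
    """Scenario-effective modifications to quality, delays and care-seeking.

    ``fixed_delivery_prob`` replaces the whole consumables x competence x
    staffing product for a quality key ("delivery:prophylactic",
    "delivery:BEmONC", "delivery:CEmONC"); ``quality_max`` pins every factor
    of a service to 1.  ``service_disabled`` suppresses the service's HSIs
    entirely.
    """

    quality_max: set = field(default_factory=set)  # services
    fixed_delivery_prob: dict = field(default_factory=dict)  # quality key -> prob
    delay3_disabled: set = field(default_factory=set)  # services
    service_disabled: set = field(default_factory=set)  # services
    emergency_careseek_antenatal: float | None = None
    emergency_careseek_postnatal: float | None = None
    anc_start_intercept: float | None = None
    anc_first_trimester_all: bool = False
    anc_transition_prob: float | None = None
    facility_intercept: float | None = None
    facility_all: bool = False
    pnc_maternal_intercept: float | None = None
    pnc_neonatal_intercept: float | None = None
    pnc_all: bool = False


def _draw(rng, key: str) -> float:
    if hasattr(rng, "draw"):
        return rng.draw(key)
    return rng.random()


# ---------------------------------------------------------------------------
# care seeking
# ---------------------------------------------------------------------------


def careseeking_probability(model: CareSeekingModel, person: PersonRecord) -> float:
    """Inverse-logit of the model's linear predictor for this person."""
    person.require_alive()
    lp = model.linear_predictor(person)
    return 1.0 / (1.0 + math.exp(-lp))


def plan_anc_schedule(woman: PersonRecord, params: ParameterSet, rng,
                      overrides: ServiceOverrides | None = None) -> list:
    """Plan antenatal-contact timings for a newly pregnant woman.

    The first-visit gestational month is drawn from the configured
    distribution (pinned to the first trimester under maximum-coverage
    scenarios); each subsequent monthly contact is attended with the
    per-transition probability, up to 8 contacts.  The engine truncates the
    schedule when the pregnancy ends.  Returns [(visit_number, month), ...].
    """
    overrides = overrides or ServiceOverrides()
    if overrides.anc_first_trimester_all:
        first = 2
    else:
        u = _draw(rng, "anc-first-visit")
        first, acc = max(params.anc_first_visit_month_dist), 0.0
        for m in sorted(params.anc_first_visit_month_dist):
            acc += params.anc_first_visit_month_dist[m]
            if u < acc:
                first = m
                break
    tp = (overrides.anc_transition_prob if overrides.anc_transition_prob is not None
          else params.anc_transition_prob)
    schedule = [(1, first)]
    month = first
    for k in range(2, 9):  # at most 8 contacts
        month += 1
        if month > 10:
            break
        if _draw(rng, f"anc-transition-{k}") >= tp:
            break
        schedule.append((k, month))
    return schedule


def emergency_careseeking(rng, p: float) -> bool:
    """Bernoulli care-seeking decision after an emergency complication."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"care-seeking probability must be in [0,1], got {p}")
    if p >= 1.0:
        return True
    if p <= 0.0:
        return False
    return _draw(rng, "emergency-careseek") < p


# ---------------------------------------------------------------------------
# squeeze and delays
# ---------------------------------------------------------------------------


def compute_squeeze_factor(required_minutes: float, available_minutes: float) -> float:
    """required / available - 1 (over-demand of healthcare-worker time)."""
    if available_minutes <= 0:
        raise ValueError("available minutes must be positive")
    if required_minutes < 0:
        raise ValueError("required minutes must be non-negative")
    return required_minutes / available_minutes - 1.0


def assess_delays(rng, p1: float, p2: float, squeeze: float, threshold: float,
                  d3_disabled: bool = False) -> tuple:
    """The three delays: Bernoulli delays one/two; delay three iff squeeze
    strictly exceeds the threshold (boundary equality does not trigger)."""
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {p}")
    d1 = _draw(rng, "delay1") < p1 if p1 > 0 else False
    d2 = _draw(rng, "delay2") < p2 if p2 > 0 else False
    d3 = (not d3_disabled) and squeeze > threshold
    return (d1, d2, d3)


class HcwLedger:
    """Daily healthcare-worker time budgets by (facility level, cadre).

    Budgets are expressed per 1000 population and scaled to the simulated
    population; events deplete the day's remaining minutes sequentially, so
    squeeze reflects remaining availability at execution time.
    """

    def __init__(self, params: ParameterSet, population_size: int):
        self.daily_budget = {
            key: minutes * population_size / 1000.0
            for key, minutes in params.hcw_daily_minutes_per_1000.items()
        }
        self._remaining_by_day: dict = {}
        self.day = None
        self.demand_log: list = []

    def begin_day(self, day) -> None:
        self.day = day
        self._remaining_by_day[day] = dict(self.daily_budget)

    @property
    def remaining(self) -> dict:
        return self._remaining_by_day.setdefault(self.day, dict(self.daily_budget))

    def remaining_for(self, day) -> dict:
        return self._remaining_by_day.setdefault(day, dict(self.daily_budget))

    def request(self, facility_level: str, minutes_by_cadre: dict, day=None) -> float:
        """Squeeze for this request against remaining budgets, then deplete.

        Events on a day are processed in queue order against a snapshot budget
        that depletes sequentially; squeeze reflects remaining availability at
        execution time.
        """
        if day is None:
            day = self.day
        remaining = self.remaining_for(day)
        required = sum(minutes_by_cadre.values())
        available = sum(
            max(remaining.get((facility_level, cadre), 0.0), 0.0)
            for cadre in minutes_by_cadre
        )
        if required <= 0:
            squeeze = -1.0
        elif available <= 0:
            squeeze = math.inf
        else:
            squeeze = compute_squeeze_factor(required, available)
        for cadre, minutes in minutes_by_cadre.items():
            key = (facility_level, cadre)
            if key in remaining:
                remaining[key] = remaining[key] - minutes
        self.demand_log.append((day, facility_level, required, squeeze))
        return squeeze


# ---------------------------------------------------------------------------
# intervention delivery
# ---------------------------------------------------------------------------


def attempt_intervention_delivery(spec: InterventionSpec, params: ParameterSet, rng,
                                  overrides: ServiceOverrides | None = None,
                                  service: str | None = None,
                                  quality_key: str | None = None) -> bool:
    """Quality model: consumables AND competence AND (EmONC) staffing.

    A scenario may pin every factor of a service to 1 (``quality_max``) or
    replace the whole product with a fixed delivery probability for a
    quality key (e.g. BEmONC interventions in labour "set at 90%").
    """
    overrides = overrides or ServiceOverrides()
    if quality_key is not None and quality_key in overrides.fixed_delivery_prob:
        p = overrides.fixed_delivery_prob[quality_key]
        if p <= 0.0:
            return False
        if p >= 1.0:
            return True
        return _draw(rng, f"fixed:{spec.name}") < p
    if service is not None and service in overrides.quality_max:
        return True
    for item, availability in spec.consumable_availability.items():
        if _draw(rng, f"consumable:{spec.name}:{item}") >= availability:
            return False
    if _draw(rng, f"competence:{spec.name}") >= spec.competence_prob:
        return False
    if spec.emonc_class != "none":
        if _draw(rng, f"staffing:{spec.name}") >= params.emonc_staffing_prob:
            return False
    return True


def _quality_key(spec: InterventionSpec, hsi_type: str) -> str | None:
    """Scenario quality keys exist only for delivery-room interventions."""
    if hsi_type not in ("delivery_bemonc", "delivery_cemonc"):
        return None
    if spec.klass == "preventative":
        return "delivery:prophylactic"
    if spec.emonc_class == "CEmONC":
        return "delivery:CEmONC"
    return "delivery:BEmONC"


def indicated_interventions(hsi_type: str, person: PersonRecord,
                            params: ParameterSet) -> list:
    """Interventions indicated for this person at this HSI, in registry order.

    Screening is offered at every eligible contact; preventatives once per
    pregnancy subject to their gate (e.g. calcium for primigravidae,
    corticosteroids in preterm labour); curatives when an active condition
    listing them has been detected (routine antenatal care) or is clinically
    evident (labour, emergencies, postnatal complications).
    """
    out = []
    evident = hsi_type != "anc"  # outside routine ANC, conditions present are evident
    treatable = set()
    for cond in params.conditions:
        if cond.name not in person.active_conditions:
            continue
        if evident or cond.name in person._detected:
            treatable.update(cond.treatments)
    for spec in params.interventions:
        if hsi_type not in spec.hsi_types:
            continue
        if spec.klass == "screening":
            out.append(spec)
        elif spec.klass == "preventative":
            if spec.name in person._preventions:
                continue
            gate = spec.indication
            if gate == "primigravida" and person.parity != 0:
                continue
            if gate == "preterm" and person.labour_state != "preterm":
                continue
            if gate == "detected":
                if not any(spec.name in params.condition(c).treatments
                           and (evident or c in person._detected)
                           for c in person.active_conditions):
                    continue
            out.append(spec)
        else:  # curative
            if spec.name in treatable:
                out.append(spec)
    return out


def execute_hsi(hsi_type: str, person: PersonRecord, params: ParameterSet,
                ledger: HcwLedger | None, rng,
                overrides: ServiceOverrides | None = None,
                facility_level: str = "health-centre",
                date: dt.date | None = None,
                emergency: bool = False) -> HSIEvent:
    """Run one health system interaction for an eligible person.

    Computes squeeze against the day's remaining cadre budget, assesses the
    three delays (delays one/two only where the event follows a care-seeking
    decision, i.e. emergencies and facility delivery), then iterates the
    indicated interventions through the quality model.  Delivered curative
    interventions are recorded on the person (relative risk + delays) for the
    mortality stage; preventatives register as risk-modifying flags;
    screening marks conditions as detected.
    """
    if hsi_type not in HSI_SERVICE:
        raise ValueError(f"unknown hsi_type {hsi_type!r}")
    person.require_alive()
    overrides = overrides or ServiceOverrides()
    service = HSI_SERVICE[hsi_type]

    specs = indicated_interventions(hsi_type, person, params)
    required = dict(params.hsi_minutes.get(hsi_type, {}))
    for spec in specs:
        for cadre, minutes in spec.hcw_minutes.items():
            required[cadre] = required.get(cadre, 0.0) + minutes

    if ledger is not None:
        squeeze = ledger.request(facility_level, required, day=date)
    else:
        squeeze = -1.0
    with_d1d2 = emergency or hsi_type in ("delivery_bemonc", "delivery_cemonc")
    delays = assess_delays(
        rng,
        params.delay1_prob if with_d1d2 else 0.0,
        params.delay2_prob if with_d1d2 else 0.0,
        squeeze, params.squeeze_threshold,
        d3_disabled=service in overrides.delay3_disabled,
    )

    event = HSIEvent(person_id=person.id, hsi_type=hsi_type,
                     facility_level=facility_level, date=date,
                     required_minutes=required, squeeze=squeeze, delays=delays,
                     attempted_interventions=[s.name for s in specs])
    for spec in specs:
        delivered = attempt_intervention_delivery(
            spec, params, rng, overrides=overrides, service=service,
            quality_key=_quality_key(spec, hsi_type))
        if not delivered:
            continue
        event.delivered_interventions.append(spec.name)
        if spec.klass == "screening":
            for target in spec.detects:
                if target in person.active_conditions:
                    person._detected.add(target)
        elif spec.klass == "preventative":
            person._preventions.add(spec.name)
            if spec.treatment_rr < 1.0:  # e.g. syphilis treatment clears infection
                for cname in list(person.active_conditions):
                    cond = params.condition(cname)
                    if spec.name in cond.treatments and cond.treatment_resolves:
                        person.active_conditions.pop(cname)
                        person._detected.discard(cname)
        else:  # curative
            for cname in list(person.active_conditions):
                cond = params.condition(cname)
                if spec.name not in cond.treatments:
                    continue
                if hsi_type == "anc" and cname not in person._detected:
                    continue
                if cond.treatment_resolves:
                    person.active_conditions.pop(cname)
                    person._detected.discard(cname)
                    person._treatments.setdefault(cname, []).append(spec.treatment_rr)
                else:
                    person._treatments.setdefault(cname, []).append(spec.treatment_rr)
                    person._delays[cname] = delays
            if spec.name == "caesarean_section":
                person.risk_flags.add("caesarean")
    return event
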