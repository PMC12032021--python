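"""Mortality with treatment effects and delay attenuation; DALYs; headline rates.

Case fatality of an untreated complication is reduced multiplicatively by the
relative risk of each delivered treatment; each delay experienced while
obtaining that treatment shrinks the treatment effect toward null.  Disability
weights of co-occurring conditions combine additively, capped at 1.0.  DALYs
are years lived with disability (no age-weighting or discounting) plus years
of life lost against a reference life table.
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict
from dataclasses import dataclass, field

from .cohort import NEONATAL_WINDOW_DAYS, PersonRecord
from .params import ParameterSet

MATERNAL_CATEGORIES = ("maternal-direct", "maternal-indirect")
STILLBIRTH_CATEGORIES = ("stillbirth-antenatal", "stillbirth-intrapartum")


@dataclass
class DeathEvent:
    person_id: int
    date: dt.date
    cause: str
    category: str  # maternal-direct | maternal-indirect | neonatal | stillbirth-*
    treated: bool = False
    delays: tuple = (False, False, False)
    age_years: float = 0.0
    yll: float = 0.0


@dataclass
class DalyLedger:
    """Per-year YLD/YLL accumulator for the maternal and neonatal categories."""

    yld: dict = field(default_factory=lambda: defaultdict(float))  # (year, cat) -> years
    yll: dict = field(default_factory=lambda: defaultdict(float))

    def add_yld(self, year: int, category: str, years: float) -> None:
        if years < 0:
            raise ValueError("YLD increment must be non-negative")
        self.yld[(year, category)] += years

    def add_yll(self, year: int, category: str, years: float) -> None:
        if years < 0:
            raise ValueError("YLL increment must be non-negative")
        self.yll[(year, category)] += years

    def dalys(self, year: int, category: str) -> float:
        return self.yld[(year, category)] + self.yll[(year, category)]


def combine_disability_weights(weights) -> float:
    """Additive combination capped at 1.0 for multimorbidity."""
    total = 0.0
    for w in weights:
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"disability weight must be in [0,1], got {w}")
        total += w
    return min(total, 1.0)


def adjusted_death_probability(cfr: float, treatment_rrs, delays=(False, False, False),
                               attenuation: float = 0.25) -> float:
    """Case fatality after treatment effects, attenuated by delays.

    Each delivered treatment with relative risk r contributes an effective
    relative risk 1 - (1-r) * (1-attenuation)^d, where d is the number of
    delays experienced; the effects multiply.  With no treatment the
    untreated CFR is returned unchanged.
    """
    if not 0.0 <= cfr <= 1.0:
        raise ValueError(f"case fatality risk must be in [0,1], got {cfr}")
    if not 0.0 <= attenuation < 1.0:
        raise ValueError(f"attenuation must be in [0,1), got {attenuation}")
    n_delays = sum(bool(d) for d in delays)
    p = cfr
    for rr in treatment_rrs:
        if not 0.0 < rr <= 1.0:
            raise ValueError(f"treatment relative risk must be in (0,1], got {rr}")
        effective = 1.0 - (1.0 - rr) * (1.0 - attenuation) ** n_delays
        p *= effective
    return p


def death_category(params: ParameterSet, person: PersonRecord, cause: str) -> str:
    cond = params.condition(cause)
    if cond.category != "none":
        return cond.category
    return "neonatal" if person.neonatal_age_days is not None else "maternal-direct"


def apply_death(person: PersonRecord, cause: str, p: float, rng, clock: dt.date,
                params: ParameterSet | None = None,
                ledger: DalyLedger | None = None) -> DeathEvent | None:
    """Bernoulli death draw for one potentially fatal condition episode.

    On death the person is marked dead, the event is categorised (maternal
    deaths arise in pregnancy or within 42 days postpartum; neonatal deaths
    at under 28 days of life) and, when a parameter set and ledger are
    supplied, YLL accrues from the reference life table.
    """
    person.require_alive()
    if cause not in person.active_conditions:
        raise ValueError(f"person {person.id} does not have condition {cause!r}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"death probability must be in [0,1], got {p}")
    u = rng.draw(f"death:{cause}") if hasattr(rng, "draw") else rng.random()
    if u >= p:
        return None
    person.alive = False
    person.date_of_death = clock
    person.cause_of_death = cause
    category = death_category(params, person, cause) if params else "maternal-direct"
    if person.neonatal_age_days is not None and person.neonatal_age_days >= NEONATAL_WINDOW_DAYS:
        raise ValueError("neonatal death outside the 28-day window")
    age = person.age_years(clock)
    event = DeathEvent(person_id=person.id, date=clock, cause=cause, category=category,
                       treated=bool(person._treatments.get(cause)),
                       delays=person._delays.get(cause, (False, False, False)),
                       age_years=age)
    if params is not None:
        event.yll = params.remaining_life_expectancy(age)
        if ledger is not None:
            side = "neonatal" if category == "neonatal" else "maternal"
            ledger.add_yll(clock.year, side, event.yll)
    return event


def accrue_dalys(ledger: DalyLedger, persons, year: int, params: ParameterSet,
                 fraction_of_year: float = 1.0 / 12.0) -> DalyLedger:
    """Accrue YLD for one accounting step over the given persons.

    Each alive person contributes combined-capped disability weight times the
    step length in years, to the maternal or neonatal category.
    """
    for person in persons:
        if not person.alive or not person.active_conditions:
            continue
        weights = [params.condition(c).disability_weight for c in person.active_conditions]
        combined = combine_disability_weights(weights)
        if combined > 0:
            side = "neonatal" if person.neonatal_age_days is not None else "maternal"
            ledger.add_yld(year, side, combined * fraction_of_year)
    return ledger


def compute_period_rates(maternal_deaths: float, neonatal_deaths: float,
                         stillbirths: float, live_births: float,
                         sbr_denominator: str = "total") -> tuple:
    """(MMR, NMR, SBR): per 100k live births, per 1k live births, per 1k births.

    The stillbirth-rate denominator is total births by default (live births +
    stillbirths); pass ``sbr_denominator='live'`` for the live-birth variant.
    """
    if live_births <= 0:
        raise ZeroDivisionError("rates undefined with zero live births")
    mmr = maternal_deaths / live_births * 1e5
    nmr = neonatal_deaths / live_births * 1e3
    denom = live_births + stillbirths if sbr_denominator == "total" else live_births
    sbr = stillbirths / denom * 1e3
    return (mmr, nmr, sbr)
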