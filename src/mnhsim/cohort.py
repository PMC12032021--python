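"""Simulated population: person records, ageing, background mortality, conception.

The population advances on a monthly master clock.  Pregnancy, intrapartum and
postnatal/neonatal events are driven by the engine (see :mod:`mnhsim.engine`);
this module owns the demographic substrate those events act on.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterator

from .rand import RandomSource

if TYPE_CHECKING:  # pragma: no cover
    from .params import ParameterSet

REPRODUCTIVE_AGE = (15, 49)
MAX_GESTATION_DAYS = 300
POSTNATAL_WINDOW_DAYS = 42
NEONATAL_WINDOW_DAYS = 28


@dataclass
class PersonRecord:
    """State of one simulated individual.

    ``active_conditions`` maps condition name to onset date.  Fields prefixed
    with an underscore are engine bookkeeping (care plans, delivered
    treatments) rather than epidemiological state.
    """

    id: int
    sex: str  # 'F' or 'M'
    date_of_birth: dt.date
    alive: bool = True
    district: int = 0
    urban: bool = False
    wealth_quintile: int = 3  # 1 (poorest) .. 5 (richest)
    education_level: int = 1  # 0 none, 1 primary, 2 secondary+
    parity: int = 0
    is_pregnant: bool = False
    gestational_age: int | None = None  # days since conception
    labour_state: str = "none"  # none | preterm | term | post-term | in-labour
    delivery_setting: str = "none"  # none | home | health-centre | hospital
    active_conditions: dict = field(default_factory=dict)
    postnatal_week: int | None = None
    neonatal_age_days: int | None = None
    risk_flags: set = field(default_factory=set)  # malaria, hiv, depression
    anc_visits_attended: int = 0
    received_pnc: bool = False
    date_of_death: dt.date | None = None
    cause_of_death: str | None = None
    # engine bookkeeping
    _preventions: set = field(default_factory=set)
    _detected: set = field(default_factory=set)
    _treatments: dict = field(default_factory=dict)  # condition -> [effective RR]
    _delays: dict = field(default_factory=dict)  # condition -> (d1, d2, d3)
    _anc_schedule: list = field(default_factory=list)  # gestational months of planned visits
    _mother_id: int | None = None
    _preterm: bool = False

    def age_years(self, on: dt.date) -> int:
        years = on.year - self.date_of_birth.year
        if (on.month, on.day) < (self.date_of_birth.month, self.date_of_birth.day):
            years -= 1
        return max(years, 0)

    def check_invariants(self) -> None:
        if self.is_pregnant != (self.gestational_age is not None):
            raise ValueError(f"person {self.id}: gestational_age present iff pregnant")
        if self.gestational_age is not None and not (0 <= self.gestational_age <= MAX_GESTATION_DAYS):
            raise ValueError(f"person {self.id}: gestational_age {self.gestational_age} out of range")
        if self.is_pregnant and self.postnatal_week is not None:
            raise ValueError(f"person {self.id}: simultaneously pregnant and postnatal")
        if not 1 <= self.wealth_quintile <= 5:
            raise ValueError(f"person {self.id}: wealth quintile {self.wealth_quintile}")

    def require_alive(self) -> None:
        """Dead persons are never mutated further."""
        if not self.alive:
            raise ValueError(f"person {self.id} is dead and must not be mutated")


class Population:
    """Container for person records plus the model-to-real scale factor."""

    def __init__(self, ratio: float = 1.0):
        if ratio <= 0:
            raise ValueError("model-to-real ratio must be positive")
        self.ratio = float(ratio)
        self.persons: dict[int, PersonRecord] = {}
        self._next_id = 0

    def add(self, person: PersonRecord) -> None:
        self.persons[person.id] = person
        self._next_id = max(self._next_id, person.id + 1)

    def new_id(self) -> int:
        nid = self._next_id
        self._next_id += 1
        return nid

    def alive(self) -> Iterator[PersonRecord]:
        return (p for p in self.persons.values() if p.alive)

    def n_alive(self) -> int:
        return sum(1 for _ in self.alive())

    def real_count(self, model_count: float) -> float:
        """Rescale a model count to the real population it represents."""
        return model_count * self.ratio

    def women_of_reproductive_age(self, on: dt.date) -> Iterator[PersonRecord]:
        lo, hi = REPRODUCTIVE_AGE
        for p in self.alive():
            if p.sex == "F" and lo <= p.age_years(on) <= hi:
                yield p


def population_snapshot(population: Population):
    """One-row-per-person DataFrame of the core demographic/pregnancy state."""
    import pandas as pd

    rows = []
    for p in population.persons.values():
        rows.append({
            "id": p.id, "sex": p.sex, "date_of_birth": p.date_of_birth,
            "alive": p.alive, "urban": p.urban,
            "wealth_quintile": p.wealth_quintile,
            "education_level": p.education_level, "parity": p.parity,
            "is_pregnant": p.is_pregnant, "gestational_age": p.gestational_age,
            "labour_state": p.labour_state, "postnatal_week": p.postnatal_week,
            "neonatal_age_days": p.neonatal_age_days,
            "active_conditions": ";".join(sorted(p.active_conditions)),
            "date_of_death": p.date_of_death, "cause_of_death": p.cause_of_death,
        })
    return pd.DataFrame(rows)


def initialise_population(n: int, ratio: float, seed: int) -> Population:
    """Build a demographically structured population of ``n`` persons.

    ``ratio`` is the model-to-real population ratio (1:ratio), recorded for
    later rescaling of counts; it does not change the simulated dynamics.
    """
    from .params import make_fixture_population

    if n < 1:
        raise ValueError("population size must be >= 1")
    pop = Population(ratio=ratio)
    for person in make_fixture_population(n, seed):
        pop.add(person)
    return pop


def monthly_demographic_update(
    population: Population,
    month: dt.date,
    background_mortality: dict,
    rng: RandomSource,
) -> int:
    """Apply one month of background (non-maternal, non-neonatal) mortality.

    Ages are derived from date of birth so no explicit ageing step is needed.
    Pregnancy fields are never touched here.  Returns the number of deaths.
    ``background_mortality`` maps (age_lo, age_hi) to a monthly death
    probability.
    """
    t = month.year * 12 + month.month
    deaths = 0
    for p in list(population.alive()):
        # modelled maternal/neonatal mortality handles newborns in-window
        if p.neonatal_age_days is not None:
            continue
        age = p.age_years(month)
        rate = _rate_for_age(background_mortality, age)
        if rate > 0 and rng.uniform("background-mortality", p.id, t) < rate:
            p.alive = False
            p.date_of_death = month
            p.cause_of_death = "background"
            deaths += 1
    return deaths


def _rate_for_age(bands: dict, age: int) -> float:
    for (lo, hi), rate in bands.items():
        if lo <= age <= hi:
            return rate
    return 0.0


def initiate_pregnancies(
    population: Population,
    month: dt.date,
    params: "ParameterSet",
    rng: RandomSource,
) -> list[PersonRecord]:
    """Monthly conception among alive, non-pregnant women of reproductive age.

    Conception probability is an age-band constant (the stand-in for the
    contraception/fecundity model), calibrated to a plausible crude birth
    rate.  Conception sets gestational age 0 and clears postnatal state.
    Returns the list of newly pregnant women.
    """
    t = month.year * 12 + month.month
    newly = []
    for w in population.women_of_reproductive_age(month):
        if w.is_pregnant or w.postnatal_week is not None:
            continue
        p = params.conception_probability(w.age_years(month))
        if p > 0 and rng.uniform("conception", w.id, t) < p:
            w.is_pregnant = True
            w.gestational_age = 0
            w.labour_state = "none"
            w.delivery_setting = "none"
            w.postnatal_week = None
            w.anc_visits_attended = 0
            w.received_pnc = False
            w._preventions = set()
            w._detected = set()
            w._treatments = {}
            w._delays = {}
            w._anc_schedule = []
            newly.append(w)
    return newly
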