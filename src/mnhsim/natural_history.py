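"""Untreated natural history: onset, progression, labour timing, phase gating.

Risks are applied on the cadence of the master clock: monthly
time-since-conception specific risks through pregnancy, per-labour risks
intrapartum, and weekly risks through the postnatal (mother, 6 weeks) and
neonatal (newborn, 28 days) windows.  Relative-risk modifiers compose
multiplicatively on the probability scale and the product is clipped to 1.
"""

from __future__ import annotations

import datetime as dt

from .cohort import PersonRecord
from .params import ConditionSpec, ParameterSet

DAYS_PER_GESTATIONAL_MONTH = 30
TERM_LABOUR_DAYS = 270  # ~38.6 completed weeks
POSTTERM_LABOUR_DAYS = 300  # ~42.9 completed weeks
PRETERM_CUTOFF_WEEKS = 37
POSTTERM_CUTOFF_WEEKS = 42

# severity ladders are monotone non-decreasing absent treatment
SEVERITY_ORDER = {
    "gestational_htn_mild": 0, "gestational_htn_severe": 1,
    "pre_eclampsia_mild": 0, "pre_eclampsia_severe": 1, "eclampsia": 2,
}


def onset_probability(baseline: float, modifiers) -> float:
    """min(1, baseline x product of relative risks)."""
    if not 0.0 <= baseline <= 1.0:
        raise ValueError(f"baseline risk must be in [0,1], got {baseline}")
    p = baseline
    for rr in modifiers:
        if rr <= 0:
            raise ValueError(f"relative risk must be strictly positive, got {rr}")
        p *= rr
    return min(p, 1.0)


def _draw(rng, key: str) -> float:
    """Uniform from a keyed CRN source when available, else a plain rng."""
    if hasattr(rng, "draw"):
        return rng.draw(key)
    return rng.random()


def predicate_holds(pred: str, person: PersonRecord, ctx: dict | None = None) -> bool:
    """Evaluate one modifier predicate against person state and cycle context."""
    ctx = ctx or {}
    if pred.startswith("cond:"):
        return pred[5:] in person.active_conditions
    if pred.startswith("cond_untreated:"):
        name = pred[15:]
        return name in person.active_conditions and not person._treatments.get(name)
    if pred.startswith("prev:"):
        return pred[5:] in person._preventions
    if pred.startswith("flag:"):
        return pred[5:] in person.risk_flags
    if pred.startswith("mother_cond:"):
        mother = ctx.get("mother")
        return mother is not None and pred[12:] in mother.active_conditions
    if pred == "week0":
        return ctx.get("week") == 0
    if pred == "preterm":
        return person._preterm or person.labour_state == "preterm"
    if pred == "postterm":
        return person.labour_state == "post-term" or "post_term_pregnancy" in person.active_conditions
    if pred == "caesarean":
        return "caesarean" in person.risk_flags
    raise ValueError(f"unknown modifier predicate {pred!r}")


def effective_onset_probability(cond: ConditionSpec, person: PersonRecord,
                                ctx: dict | None = None) -> float:
    """Baseline risk with all satisfied modifiers applied, clipped to [0,1]."""
    if cond.requires and not predicate_holds(cond.requires, person, ctx):
        return 0.0
    rrs = [rr for pred, rr in cond.modifiers if predicate_holds(pred, person, ctx)]
    return onset_probability(cond.baseline_risk, rrs)


def gestational_month(woman: PersonRecord) -> int:
    """Current 1-based month of pregnancy."""
    return woman.gestational_age // DAYS_PER_GESTATIONAL_MONTH + 1


def determine_labour_category(gestational_age_days: int) -> str:
    """Standard obstetric cut-points: <37 weeks preterm, >=42 post-term."""
    weeks = gestational_age_days / 7.0
    if weeks < PRETERM_CUTOFF_WEEKS:
        return "preterm"
    if weeks >= POSTTERM_CUTOFF_WEEKS:
        return "post-term"
    return "term"


def apply_phase_onsets(person: PersonRecord, phase: str, params: ParameterSet,
                       rng, ctx: dict | None = None, only=None,
                       include_fetal: bool = True) -> list[str]:
    """Draw onsets for every condition of ``phase`` the person is at risk of.

    Conditions are drawn in registry order with one keyed uniform each, so
    paired scenario runs stay aligned.  Window gating: gestational month for
    antenatal conditions, postnatal/neonatal week (``ctx['week']``) otherwise.
    Returns the list of conditions that fired (not yet applied to state for
    fetal conditions: the caller decides what a fetal death means).
    """
    ctx = ctx or {}
    person.require_alive()
    fired = []
    for cond in params.conditions_in_phase(phase):
        if only is not None and cond.name not in only:
            continue
        if not include_fetal and cond.fetal:
            continue
        if cond.name in person.active_conditions:
            continue
        if phase == "antenatal-monthly":
            m = ctx.get("gestational_month", gestational_month(person))
            if not cond.window[0] <= m <= cond.window[1]:
                continue
        elif phase in ("postnatal-weekly", "neonatal"):
            wk = ctx["week"]
            if not cond.window[0] <= wk <= cond.window[1]:
                continue
        p = effective_onset_probability(cond, person, ctx)
        if p > 0 and _draw(rng, f"onset:{cond.name}") < p:
            fired.append(cond.name)
    return fired


def apply_progression(woman: PersonRecord, params: ParameterSet, rng,
                      phase: str | None = None) -> list[tuple[str, str]]:
    """Progress active conditions up their severity ladder.

    Delivered treatments against a condition scale its progression
    probability by their relative risks; untreated severity is monotone
    non-decreasing.  Returns (from, to) transitions applied.
    """
    woman.require_alive()
    transitions = []
    at_entry = set(woman.active_conditions)  # one severity step per call
    for cond in params.conditions:
        if cond.progression is None or cond.name not in at_entry or \
                cond.name not in woman.active_conditions:
            continue
        target_name, p = cond.progression
        target = params.condition(target_name)
        if phase is not None and phase not in target.phases:
            continue
        for rr in woman._treatments.get(cond.name, []):
            p *= rr
        if p > 0 and _draw(rng, f"progress:{cond.name}") < p:
            onset_date = woman.active_conditions.pop(cond.name)
            woman._treatments.pop(cond.name, None)
            woman.active_conditions[target_name] = onset_date
            transitions.append((cond.name, target_name))
    return transitions


def apply_antenatal_cycle(woman: PersonRecord, params: ParameterSet, rng,
                          date: dt.date | None = None) -> dict:
    """One monthly antenatal step: onsets, progression, possible pregnancy end.

    Returns a summary dict with ``onsets``, ``transitions``, ``ended``
    (condition name that terminated the pregnancy, or None) and
    ``labour`` ("preterm" if preterm labour fired, else None).  Advances
    gestational age by one month.
    """
    woman.require_alive()
    if not woman.is_pregnant:
        raise ValueError(f"person {woman.id} is not pregnant")
    m = gestational_month(woman)
    ctx = {"gestational_month": m}
    fired = apply_phase_onsets(woman, "antenatal-monthly", params, rng, ctx)
    ended = None
    labour = None
    for name in fired:
        cond = params.condition(name)
        if cond.fetal:
            # antenatal stillbirth: pregnancy ends, no morbidity entry
            ended = name
            continue
        woman.active_conditions[name] = date
        if name == "preterm_labour":
            labour = "preterm"
        if cond.ends_pregnancy:
            ended = ended or name
    transitions = apply_progression(woman, params, rng, phase="antenatal-monthly")
    woman.gestational_age += DAYS_PER_GESTATIONAL_MONTH
    return {"onsets": fired, "transitions": transitions, "ended": ended, "labour": labour}


def apply_intrapartum_complications(woman: PersonRecord, params: ParameterSet, rng,
                                    stage: str = "complications",
                                    date: dt.date | None = None) -> list[str]:
    """Intrapartum onset draws, staged around care delivery.

    ``complications``: obstructed labour, sepsis, eclampsia, APH - drawn at
    labour onset, before any care, so care can respond to them.
    ``sequelae``: uterine rupture - drawn after care, so treated obstructed
    labour no longer multiplies its risk.
    ``fetal``: intrapartum stillbirth - the caller applies treatment effects.
    """
    woman.require_alive()
    if woman.labour_state not in ("preterm", "term", "post-term", "in-labour"):
        raise ValueError(f"person {woman.id} is not in labour")
    ctx: dict = {}
    if stage == "complications":
        only = {"obstructed_labour", "sepsis_intrapartum", "eclampsia", "antepartum_haemorrhage"}
        fired = apply_phase_onsets(woman, "intrapartum", params, rng, ctx,
                                   only=only, include_fetal=False)
    elif stage == "sequelae":
        fired = apply_phase_onsets(woman, "intrapartum", params, rng, ctx,
                                   only={"uterine_rupture"}, include_fetal=False)
    elif stage == "fetal":
        return apply_phase_onsets(woman, "intrapartum", params, rng, ctx,
                                  only={"intrapartum_stillbirth"}, include_fetal=True)
    else:
        raise ValueError(f"unknown intrapartum stage {stage!r}")
    for name in fired:
        woman.active_conditions[name] = date
    return fired


def apply_postnatal_neonatal_cycle(record: PersonRecord, week: int,
                                   params: ParameterSet, rng,
                                   mother: PersonRecord | None = None,
                                   date: dt.date | None = None) -> list[str]:
    """One weekly postnatal (mother) or neonatal (newborn) risk step.

    Week 0 is the birth itself: birth-only conditions (primary PPH, RDS,
    encephalopathy) can fire only there.  Raises outside the 6-week
    postnatal / 28-day neonatal window.
    """
    record.require_alive()
    if record.neonatal_age_days is not None:
        phase = "neonatal"
        if not 0 <= week <= 3:
            raise ValueError(f"neonatal week {week} outside the 28-day window")
    else:
        phase = "postnatal-weekly"
        if record.postnatal_week is None or not 0 <= week <= 6:
            raise ValueError(f"postnatal week {week} outside the 42-day window")
    ctx = {"week": week, "mother": mother}
    fired = apply_phase_onsets(record, phase, params, rng, ctx)
    for name in fired:
        record.active_conditions[name] = date
    apply_progression(record, params, rng, phase=phase)
    return fired
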