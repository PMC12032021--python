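"""Automated calibration of under-specified parameters to fixed targets.

Individual-based health models of this kind are usually calibrated by
iteratively updating onset risks, untreated case-fatality risks and
care-seeking parameters until outputs visually match national estimates.
Here that loop is automated: a weighted relative-squared loss over
named targets is minimised by bounded multiplicative coordinate descent over
a declared knob set, with a reproducible reduced-population simulator
supplying the statistics.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import numpy as np

from .health_system import ServiceOverrides, careseeking_probability, plan_anc_schedule
from .params import ParameterSet, make_fixture_population
from .rand import RandomSource

COVERAGE_TARGET_VALUES = {
    "anc4": 0.51,
    "facility_delivery": 0.91,
    "pnc_maternal": 0.42,
    "pnc_neonatal": 0.60,
}


@dataclass
class CalibrationTarget:
    name: str
    statistic: str
    target: float
    tolerance: float
    weight: float = 1.0

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    def met(self, value: float) -> bool:
        return abs(value - self.target) <= self.tolerance


def default_coverage_targets(tolerance: float = 0.02) -> list:
    return [CalibrationTarget(k, k, v, tolerance)
            for k, v in COVERAGE_TARGET_VALUES.items()]


def calibration_loss(simulated_stats: dict, targets) -> float:
    """Weighted sum of squared relative deviations from the targets."""
    loss = 0.0
    for t in targets:
        if t.statistic not in simulated_stats:
            raise KeyError(f"statistic {t.statistic!r} missing from simulated stats")
        loss += t.weight * ((simulated_stats[t.statistic] - t.target) / t.target) ** 2
    return loss


# ---------------------------------------------------------------------------
# tunable knobs (multiplicative semantics; intercepts scale on the odds)
# ---------------------------------------------------------------------------


def _apply_knob(ps: ParameterSet, knob: str, factor: float) -> None:
    parts = knob.split(".")
    if parts[0] == "careseeking":
        ps.careseeking[parts[1]].intercept += math.log(factor)
    elif parts[0] == "condition":
        cond = ps.condition(parts[1])
        fname = parts[2]
        if fname not in ("baseline_risk", "untreated_cfr"):
            raise KeyError(f"condition field {fname!r} is not tunable")
        setattr(cond, fname, min(getattr(cond, fname) * factor, 1.0))
    elif knob == "anc_transition_prob":
        ps.anc_transition_prob = min(ps.anc_transition_prob * factor, 0.999)
    elif knob == "emergency_careseek_prob":
        ps.emergency_careseek_prob = min(ps.emergency_careseek_prob * factor, 1.0)
    else:
        raise KeyError(f"unknown or non-tunable knob {knob!r}")


def tune_parameters(params: ParameterSet, targets, knobs, budget: int, seed: int,
                    simulator, step: float = 2.0,
                    factor_bounds: tuple = (0.1, 10.0)) -> tuple:
    """Bounded multiplicative coordinate descent on the declared knobs.

    ``simulator(params) -> dict`` supplies the statistics (it should fix its
    own seeds so the loss surface is deterministic).  Accepted-step loss is
    monotone non-increasing; parameters outside the knob set are never
    touched.  Returns (best ParameterSet, audit log); the audit log rows are
    (evaluation index, knob, cumulative factor, loss, accepted).
    """
    if budget < 1:
        raise ValueError("evaluation budget must be >= 1")
    for k in knobs:
        _apply_knob(copy.deepcopy(params), k, 1.0)  # validates knob names
    best = copy.deepcopy(params)
    audit = []
    evals = 0

    stats0 = simulator(best)
    evals += 1
    best_loss = calibration_loss(stats0, targets)
    audit.append((evals, None, 1.0, best_loss, True))
    if all(t.met(stats0[t.statistic]) for t in targets):
        return best, audit

    cumulative = {k: 1.0 for k in knobs}
    current_step = step
    while evals < budget and current_step > 1.02:
        improved = True
        while improved and evals < budget:
            improved = False
            for knob in knobs:
                for direction in (current_step, 1.0 / current_step):
                    mult = direction
                    while evals < budget:
                        new_cum = cumulative[knob] * mult
                        if not factor_bounds[0] <= new_cum <= factor_bounds[1]:
                            break
                        trial = copy.deepcopy(best)
                        _apply_knob(trial, knob, mult)
                        stats = simulator(trial)
                        evals += 1
                        loss = calibration_loss(stats, targets)
                        accepted = loss < best_loss - 1e-12
                        audit.append((evals, knob, new_cum, loss, accepted))
                        if not accepted:
                            break
                        best, best_loss = trial, loss
                        cumulative[knob] = new_cum
                        improved = True
                        if all(t.met(stats[t.statistic]) for t in targets):
                            return best, audit
        # refine: halve the multiplicative step once coarse moves stall
        current_step = math.sqrt(current_step)
    return best, audit


# ---------------------------------------------------------------------------
# fast coverage simulator (care-seeking layer only)
# ---------------------------------------------------------------------------


def coverage_statistics(params: ParameterSet, overrides: ServiceOverrides | None = None,
                        n: int = 4000, seed: int = 11) -> dict:
    """Simulated service coverage over a synthetic cohort of pregnancies.

    Runs only the care-seeking layer (ANC initiation and visit chain with
    delivery truncation, facility delivery, early PNC) - the statistic the
    coverage calibration targets refer to.  Deterministic for a given seed.
    """
    overrides = overrides or ServiceOverrides()
    rng = RandomSource(seed).generator("coverage-sim")
    import datetime as dt

    ref = dt.date(2023, 1, 1)
    women = [p for p in make_fixture_population(max(n * 3, 100), seed=seed, params=params)
             if p.sex == "F" and 15 <= p.age_years(ref) <= 49][:n]
    for w in women:
        w._age_now = w.age_years(ref)
    # cumulative preterm-delivery probability truncates the visit chain
    preterm_cond = params.condition("preterm_labour")
    p_preterm = 1.0 - (1.0 - preterm_cond.baseline_risk) ** 2

    counts = {"anc4": 0, "facility_delivery": 0, "pnc_maternal": 0, "pnc_neonatal": 0}
    for w in women:
        if overrides.anc_start_intercept is not None and overrides.anc_start_intercept >= 29.0:
            starts = True
        else:
            model = params.careseeking["anc_start"]
            if overrides.anc_start_intercept is not None:
                import dataclasses
                model = dataclasses.replace(model, intercept=overrides.anc_start_intercept)
            starts = rng.random() < careseeking_probability(model, w)
        visits = 0
        if starts:
            schedule = plan_anc_schedule(w, params, rng, overrides)
            delivery_month = 9
            if rng.random() < p_preterm:
                delivery_month = 8 if rng.random() < 0.5 else 9
            visits = sum(1 for _, month in schedule if month <= delivery_month)
        if visits >= 4:
            counts["anc4"] += 1
        if overrides.facility_all:
            counts["facility_delivery"] += 1
        else:
            model = params.careseeking["facility_delivery"]
            if overrides.facility_intercept is not None:
                import dataclasses
                model = dataclasses.replace(model, intercept=overrides.facility_intercept)
            if rng.random() < careseeking_probability(model, w):
                counts["facility_delivery"] += 1
        for side, intercept in (("pnc_maternal", overrides.pnc_maternal_intercept),
                                ("pnc_neonatal", overrides.pnc_neonatal_intercept)):
            if overrides.pnc_all:
                counts[side] += 1
                continue
            model = params.careseeking[side]
            if intercept is not None:
                import dataclasses
                model = dataclasses.replace(model, intercept=intercept)
            if rng.random() < careseeking_probability(model, w):
                counts[side] += 1
    return {k: v / len(women) for k, v in counts.items()}


def make_coverage_simulator(n: int = 4000, seed: int = 11):
    """Simulator callable for :func:`tune_parameters` over coverage targets."""

    def simulator(ps: ParameterSet) -> dict:
        return coverage_statistics(ps, n=n, seed=seed)

    return simulator
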