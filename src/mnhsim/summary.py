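"""Across-run aggregation, confidence intervals, HCW time and economics.

The study design: each scenario is run repeatedly with the same parameters
and paired run seeds; per run, the mean outcome over the intervention years
is taken; across runs, the mean and 95% CI are reported.  Differences versus
the comparator (SQ) are computed per paired run first, then summarised; the
percentage difference is withheld whenever the difference CI contains zero.
The maximum ability to pay for a scenario is significant DALYs averted times
the cost-effectiveness threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .outcomes import compute_period_rates

DEFAULT_PERIOD = (2023, 2030)


@dataclass
class RunResult:
    """Per-run, per-year counts (model scale) plus the rescaling factor."""

    scenario: str
    run_index: int
    seed: int
    scale_factor: float
    annual: pd.DataFrame  # indexed by year

    def validate(self) -> None:
        a = self.annual
        if (a.select_dtypes("number") < -1e-9).any().any():
            raise ValueError("negative counts in run result")
        causes_m = [c for c in a.columns if c.startswith("maternal_deaths_")]
        causes_n = [c for c in a.columns if c.startswith("neonatal_deaths_")]
        if causes_m and not np.allclose(a[causes_m].sum(axis=1), a["maternal_deaths"]):
            raise ValueError("maternal deaths by cause do not sum to the total")
        if causes_n and not np.allclose(a[causes_n].sum(axis=1), a["neonatal_deaths"]):
            raise ValueError("neonatal deaths by cause do not sum to the total")

    def to_csv(self, path) -> None:
        df = self.annual.reset_index()
        df.insert(0, "scenario", self.scenario)
        df.insert(1, "run_index", self.run_index)
        df.insert(2, "seed", self.seed)
        df.insert(3, "scale_factor", self.scale_factor)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RunResult":
        df = pd.read_csv(path)
        meta = df.iloc[0]
        annual = df.drop(columns=["scenario", "run_index", "seed", "scale_factor"])
        annual = annual.set_index("year")
        return cls(scenario=str(meta["scenario"]), run_index=int(meta["run_index"]),
                   seed=int(meta["seed"]), scale_factor=float(meta["scale_factor"]),
                   annual=annual)


# ---------------------------------------------------------------------------
# core statistics
# ---------------------------------------------------------------------------


def per_run_period_mean(annual_values, years=range(2023, 2031)) -> float:
    """Arithmetic mean of an annual outcome over the intervention years."""
    years = list(years)
    if hasattr(annual_values, "get"):
        vals = []
        for y in years:
            if y not in annual_values:
                raise KeyError(f"year {y} missing from annual values")
            vals.append(annual_values[y])
    else:
        vals = list(annual_values)
        if len(vals) != len(years):
            raise KeyError("annual series does not cover the requested years")
    return float(np.mean(vals))


def across_run_summary(per_run_values, method: str = "t", level: float = 0.95) -> tuple:
    """Mean and two-sided CI across runs.

    ``method='t'`` uses Student's t on n-1 df (default); ``'normal'`` uses
    the normal approximation.
    """
    vals = np.asarray(list(per_run_values), dtype=float)
    n = len(vals)
    if n < 2:
        raise ValueError("at least two runs are required for a CI")
    mean = float(vals.mean())
    se = float(vals.std(ddof=1)) / math.sqrt(n)
    alpha = 1.0 - level
    if method == "t":
        crit = float(stats.t.ppf(1 - alpha / 2, df=n - 1))
    elif method == "normal":
        crit = float(stats.norm.ppf(1 - alpha / 2))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    half = crit * se
    return mean, (mean - half, mean + half)


def paired_difference_summary(sq_runs, scenario_runs, method: str = "t") -> tuple:
    """Per-run differences (scenario - SQ, matched by run index), then the
    across-run mean and CI of those differences."""
    sq = list(sq_runs)
    sc = list(scenario_runs)
    if len(sq) != len(sc):
        raise ValueError("paired runs require equal run counts")
    diffs = [b - a for a, b in zip(sq, sc)]
    return across_run_summary(diffs, method=method)


def gated_percentage_difference(diff: tuple, sq_mean: float) -> float | None:
    """100 x mean difference / comparator mean, or None (withheld) when the
    difference CI contains zero."""
    if sq_mean == 0:
        raise ZeroDivisionError("percentage difference undefined for zero comparator mean")
    mean, (lo, hi) = diff
    if lo <= 0.0 <= hi:
        return None
    return 100.0 * mean / sq_mean


# ---------------------------------------------------------------------------
# outcome extraction from run results
# ---------------------------------------------------------------------------

RATE_OUTCOMES = ("mmr", "nmr", "sbr")
TOTAL_OUTCOMES = {
    "maternal_deaths": "maternal_deaths",
    "neonatal_deaths": "neonatal_deaths",
    "stillbirths": "stillbirths",
    "maternal_dalys": "maternal_dalys",
    "neonatal_dalys": "neonatal_dalys",
    "anc_contacts": "anc_contacts",
    "pnc_maternal_contacts": "pnc_maternal_contacts",
    "pnc_neonatal_contacts": "pnc_neonatal_contacts",
}


def _annual_rate(row, outcome: str) -> float:
    mmr, nmr, sbr = compute_period_rates(
        row["maternal_deaths"], row["neonatal_deaths"], row["stillbirths"],
        row["live_births"])
    return {"mmr": mmr, "nmr": nmr, "sbr": sbr}[outcome]


def per_run_outcome(rr: RunResult, outcome: str, years=range(2023, 2031)) -> float:
    """One run's summary value: period mean of an annual rate, or the
    rescaled period total of a count."""
    years = [y for y in years if y in rr.annual.index]
    if not years:
        raise KeyError("run result does not cover the requested years")
    sub = rr.annual.loc[years]
    if outcome in RATE_OUTCOMES:
        if (sub["live_births"] <= 0).any():
            # degenerate desk-scale year: aggregate over the period instead
            tot = sub.sum()
            if tot["live_births"] <= 0:
                raise ZeroDivisionError("no live births in period")
            return _annual_rate(tot, outcome)
        vals = [_annual_rate(sub.loc[y], outcome) for y in years]
        return float(np.mean(vals))
    col = TOTAL_OUTCOMES[outcome]
    return float(sub[col].sum() * rr.scale_factor)


def summarise_scenarios(results: dict, comparator: str = "SQ",
                        years=range(2023, 2031), outcomes=None,
                        method: str = "t") -> pd.DataFrame:
    """Across-run summary table with gated percentage differences vs SQ.

    ``results`` maps scenario short name -> list of RunResult (paired by run
    index across scenarios).  Output rows: one per (scenario, outcome), with
    the across-run mean and CI, the paired-difference mean and CI, and the
    percentage difference (NaN when withheld, per the CI-contains-zero gate).
    """
    if comparator not in results:
        raise ValueError(f"comparator {comparator!r} missing")
    outcomes = list(outcomes or (list(RATE_OUTCOMES) + list(TOTAL_OUTCOMES)))
    sq_values = {o: [per_run_outcome(r, o, years) for r in results[comparator]]
                 for o in outcomes}
    rows = []
    for name in results:
        for o in outcomes:
            vals = (sq_values[o] if name == comparator
                    else [per_run_outcome(r, o, years) for r in results[name]])
            mean, (lo, hi) = across_run_summary(vals, method=method)
            row = {"scenario": name, "outcome": o, "mean": mean,
                   "ci_low": lo, "ci_high": hi,
                   "diff": np.nan, "diff_low": np.nan, "diff_high": np.nan,
                   "pct_diff": np.nan}
            if name != comparator:
                d_mean, (d_lo, d_hi) = paired_difference_summary(
                    sq_values[o], vals, method=method)
                sq_mean = float(np.mean(sq_values[o]))
                pct = (gated_percentage_difference((d_mean, (d_lo, d_hi)), sq_mean)
                       if sq_mean != 0 else None)
                row.update({"diff": d_mean, "diff_low": d_lo, "diff_high": d_hi,
                            "pct_diff": np.nan if pct is None else pct})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# health-service time and economics
# ---------------------------------------------------------------------------


def tally_contacts_and_hours(contacts: float, minutes_per_contact: float,
                             period_years: int = 8) -> tuple:
    """(contacts, total hours, hours per year) for routine contacts."""
    if contacts < 0 or minutes_per_contact < 0:
        raise ValueError("contacts and minutes must be non-negative")
    hours = contacts * minutes_per_contact / 60.0
    return contacts, hours, hours / period_years


def max_ability_to_pay(daly_components, cet: float) -> float:
    """Sum of significant DALYs-averted components times the CET (USD).

    Components whose difference CI contains zero contribute nothing.
    """
    if cet <= 0:
        raise ValueError("cost-effectiveness threshold must be positive")
    total = 0.0
    for dalys_averted, significant in daly_components:
        if significant:
            total += dalys_averted
    return total * cet


def project_total_health_spending(population_by_year: dict, per_capita_2015: float,
                                  growth: float = 0.009) -> float:
    """Sum over years of population x per-capita spending grown from 2015."""
    if per_capita_2015 <= 0:
        raise ValueError("per-capita spending must be positive")
    total = 0.0
    for year, pop in population_by_year.items():
        if pop < 0:
            raise ValueError("population must be non-negative")
        total += pop * per_capita_2015 * (1.0 + growth) ** (year - 2015)
    return total


def economics_summary(results: dict, cet: float, comparator: str = "SQ",
                      years=range(2023, 2031), method: str = "t") -> pd.DataFrame:
    """Maximum ability to pay per scenario from significant DALYs averted.

    Maternal and neonatal DALY components are tested separately (paired
    difference CI vs the comparator); a component only contributes when its
    CI excludes zero and DALYs were averted.
    """
    rows = []
    for name, runs in results.items():
        if name == comparator:
            continue
        components = []
        detail = {"scenario": name}
        for side in ("maternal", "neonatal"):
            outcome = f"{side}_dalys"
            sq_vals = [per_run_outcome(r, outcome, years) for r in results[comparator]]
            sc_vals = [per_run_outcome(r, outcome, years) for r in runs]
            d_mean, (d_lo, d_hi) = paired_difference_summary(sq_vals, sc_vals,
                                                             method=method)
            averted = -d_mean  # positive when the scenario reduces DALYs
            significant = not (d_lo <= 0.0 <= d_hi)
            components.append((averted if averted > 0 else 0.0,
                               significant and averted > 0))
            detail[f"{side}_dalys_averted"] = averted
            detail[f"{side}_significant"] = significant
        detail["max_ability_to_pay_usd"] = max_ability_to_pay(components, cet)
        rows.append(detail)
    return pd.DataFrame(rows)
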