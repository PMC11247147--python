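"""Scaling, burden statistics and the cross-country rollup.

The engine simulates a fixed virtual cohort; national results are obtained
by rescaling virtual counts to the national population. Burden statistics
follow the reporting conventions of multi-country CKD projections:
prevalence per 100,000, percent change 2022 -> 2027, cumulative incidence as
the sum of annual incident counts over the horizon (2022 included), and
population-weighted means across countries (weighted by each country's CKD
population in the target year).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .input_model import CountryInputBundle, N_COUNTRIES, PublishedTables
from .simulation_engine import outputs_to_frame, run_projection

logger = logging.getLogger(__name__)

HORIZON_YEARS = 6  # 2022..2027 inclusive


def scale_to_national(count_virtual: float, virtual_size: int,
                      national_pop: float) -> float:
    """Rescale a virtual-cohort count to the national population."""
    if virtual_size <= 0:
        raise ValueError("virtual_size must be positive")
    return count_virtual * national_pop / virtual_size


def per_100k(count: float, denominator: float) -> float:
    """Rate per 100,000 persons."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return count / denominator * 100_000.0


def percent_change(v2022: float, v2027: float) -> float:
    """Percent change 2022 -> 2027, reported to one decimal."""
    if v2022 <= 0:
        raise ValueError("baseline value must be positive")
    return round((v2027 - v2022) / v2022 * 100.0, 1)


def cumulative_incidence(annual_incident_counts) -> float:
    """Sum of annual incident counts over the six-year horizon."""
    counts = list(annual_incident_counts)
    if len(counts) != HORIZON_YEARS:
        raise ValueError(
            f"expected {HORIZON_YEARS} annual values (2022-2027), "
            f"got {len(counts)}")
    if any(c < 0 for c in counts):
        raise ValueError("incident counts must be non-negative")
    return float(sum(counts))


def weighted_mean(values, weights) -> float:
    """Population-weighted mean of per-country rates."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total == 0:
        raise ValueError("weights must not all be zero")
    return float((values * weights).sum() / total)


# -- rollups over the printed-table fixtures ---------------------------------

def _totals_by_country(tables: PublishedTables, year: int) -> pd.DataFrame:
    """Per-country diagnosed/undiagnosed per-100k totals and population."""
    prev = tables.prevalence
    rows = prev[prev["year"] == year].pivot_table(
        index="country", values="total", columns="status")
    demo = tables.demographics.set_index("country")
    out = rows.join(demo[f"population_{year}"].rename("population"))
    if out.isna().any().any() or len(out) != N_COUNTRIES:
        missing = sorted(set(demo.index) ^ set(rows.index))
        raise ValueError(f"country mismatch between tables: {missing}")
    return out


def rollup_total_cases(tables: PublishedTables, year: int) -> float:
    """Total persons with CKD (diagnosed + undiagnosed) across all countries."""
    t = _totals_by_country(tables, year)
    return float(((t["diagnosed"] + t["undiagnosed"]) / 1e5
                  * t["population"]).sum())


def national_ckd_population(tables: PublishedTables, year: int) -> pd.Series:
    """Per-country CKD population (diagnosed + undiagnosed), in persons."""
    t = _totals_by_country(tables, year)
    return (t["diagnosed"] + t["undiagnosed"]) / 1e5 * t["population"]


@dataclass
class UndiagnosedShare:
    """Population-weighted undiagnosed share with per-country extremes."""

    year: int
    share_pct: float
    per_country_pct: pd.Series
    min_pct: float
    min_country: str
    max_pct: float
    max_country: str


def undiagnosed_share(tables: PublishedTables, year: int) -> UndiagnosedShare:
    """Undiagnosed fraction of the CKD population, overall and per country."""
    t = _totals_by_country(tables, year)
    undiag = t["undiagnosed"] / 1e5 * t["population"]
    total = (t["diagnosed"] + t["undiagnosed"]) / 1e5 * t["population"]
    per_country = (t["undiagnosed"] / (t["diagnosed"] + t["undiagnosed"])
                   * 100.0)
    share = float(undiag.sum() / total.sum() * 100.0) if total.sum() else 0.0
    return UndiagnosedShare(
        year=year, share_pct=share, per_country_pct=per_country,
        min_pct=float(per_country.min()), min_country=per_country.idxmin(),
        max_pct=float(per_country.max()), max_country=per_country.idxmax())


def cv_weighted_means(tables: PublishedTables, year: int = 2027) -> dict:
    """Weighted means of the CV complication columns, per 100,000 CKD patients.

    Weights are the national CKD populations (diagnosed + undiagnosed) in the
    target year.
    """
    weights = national_ckd_population(tables, year)
    cv = tables.cv_complications.set_index("country")
    out = {}
    for col in ("heart_failure", "myocardial_infarction", "stroke"):
        out[col] = weighted_mean(cv[col].loc[weights.index], weights.values)
    return out


@dataclass
class AggregateReport:
    """Cross-country rollup of the headline burden statistics."""

    per_country: pd.DataFrame
    total_cases_2022: float
    total_cases_2027: float
    total_pct_change: float
    undiagnosed_2027: UndiagnosedShare
    cv_weighted_means_2027: dict = field(default_factory=dict)


def aggregate_report(tables: PublishedTables) -> AggregateReport:
    """Compute the full rollup from the country tables."""
    t22 = _totals_by_country(tables, 2022)
    t27 = _totals_by_country(tables, 2027)
    per_country = pd.DataFrame({
        "diagnosed_2022": t22["diagnosed"], "undiagnosed_2022": t22["undiagnosed"],
        "diagnosed_2027": t27["diagnosed"], "undiagnosed_2027": t27["undiagnosed"],
        "population_2022": t22["population"], "population_2027": t27["population"],
    })
    total22 = rollup_total_cases(tables, 2022)
    total27 = rollup_total_cases(tables, 2027)
    return AggregateReport(
        per_country=per_country,
        total_cases_2022=total22, total_cases_2027=total27,
        total_pct_change=percent_change(total22, total27),
        undiagnosed_2027=undiagnosed_share(tables, 2027),
        cv_weighted_means_2027=cv_weighted_means(tables, 2027))


# -- diagnosis-rate sensitivity ----------------------------------------------

def run_diagnosis_sensitivity(bundle: CountryInputBundle, n: int, seed: int,
                              delta: float = 0.10) -> dict[str, pd.DataFrame]:
    """Base / +delta / -delta diagnosis-rate scenarios with shared seeds.

    Every stage's diagnosis rate is scaled multiplicatively (capped at 1;
    caps are logged). Identical seeds across scenarios give common random
    numbers, so diagnosed prevalence is non-decreasing in the multiplier.
    Returns {"base", "increased", "decreased"} -> per-year output frame.
    """
    if not (0 <= delta < 1):
        raise ValueError("delta must be in [0, 1)")
    max_rate = max(bundle.diagnosis_rate_by_stage.values(), default=0.0)
    if max_rate * (1 + delta) > 1.0:
        logger.info("diagnosis sensitivity: +%.0f%% scenario caps rates at 1",
                    delta * 100)
    scenarios = {"base": 1.0, "increased": 1.0 + delta, "decreased": 1.0 - delta}
    out = {}
    for name, mult in scenarios.items():
        _, outputs = run_projection(bundle, n, seed,
                                    diagnosis_multiplier=mult)
        out[name] = outputs_to_frame(outputs)
    return out
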