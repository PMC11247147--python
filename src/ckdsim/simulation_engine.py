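"""Annual Monte Carlo update loop, 2022 -> 2027.

Each simulated year applies a fixed sub-step order to the whole cohort:

1. ageing (+1 year)
2. eGFR slope by progression subtype and albuminuria-stage transition
3. incident CKD onset among the CKD-free
4. comorbidity (type 2 diabetes / hypertension) incidence
5. diagnosis of prevalent undiagnosed cases
6. cardiovascular events (heart failure, MI, stroke) with KDIGO-graded
   relative risks
7. KRT initiation and modality transitions
8. all-cause mortality with KDIGO-graded relative risk

Death and diagnosis are absorbing; individuals on KRT stop eGFR-slope
progression; dead individuals are never updated again. Every sub-step draws
its uniforms from a dedicated stream keyed by (master seed, year, sub-step)
with one slot per individual, so results do not depend on iteration order
and scenario comparisons with equal seeds share random numbers.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kidney_math as km
from .input_model import (AGE_BANDS, CountryInputBundle, KRT_MODALITIES,
                          SEXES, STAGE_CELLS, YEARS, KrtParameters)
from .population_synthesis import (BAND_AGE_RANGES, Cohort, Individual,
                                   KRT_CODES, KRT_NAMES, band_index,
                                   _cell_bounds, synthesize)

logger = logging.getLogger(__name__)

CV_OUTCOMES = ("heart_failure", "MI", "stroke")
_STATUSES = ("diagnosed", "undiagnosed", "no_ckd")

# sub-step ids for the per-(seed, year) random streams
_SUB_SLOPE, _SUB_ACR, _SUB_ONSET, _SUB_ONSET_CELL, _SUB_ONSET_EG, \
    _SUB_ONSET_ACR, _SUB_T2D, _SUB_HTN, _SUB_DIAG, _SUB_HF, _SUB_MI, \
    _SUB_STROKE, _SUB_KRT_INIT, _SUB_KRT_MOD, _SUB_KRT_TRANS, _SUB_DEATH \
    = range(16)


@dataclass
class AnnualOutputs:
    """End-of-year tallies for one simulated calendar year (virtual counts)."""

    year: int
    n_alive_start: int
    n_alive_end: int
    deaths: int
    person_years: int
    ckd_diagnosed_by_stage: dict = field(default_factory=dict)
    ckd_undiagnosed_by_stage: dict = field(default_factory=dict)
    krt_by_modality: dict = field(default_factory=dict)
    incident_events: dict = field(default_factory=dict)
    deaths_by_status: dict = field(default_factory=dict)
    deaths_by_stage: dict = field(default_factory=dict)
    cv_prevalent_in_ckd: dict = field(default_factory=dict)
    incident_ckd: int = 0
    incident_diagnoses: int = 0

    @property
    def diagnosed_total(self) -> int:
        return sum(self.ckd_diagnosed_by_stage.values())

    @property
    def undiagnosed_total(self) -> int:
        return sum(self.ckd_undiagnosed_by_stage.values())

    @property
    def ckd_total(self) -> int:
        return self.diagnosed_total + self.undiagnosed_total

    def to_dict(self) -> dict:
        row = {"year": self.year, "n_alive_start": self.n_alive_start,
               "n_alive_end": self.n_alive_end, "deaths": self.deaths,
               "person_years": self.person_years,
               "incident_ckd": self.incident_ckd,
               "incident_diagnoses": self.incident_diagnoses,
               "diagnosed_total": self.diagnosed_total,
               "undiagnosed_total": self.undiagnosed_total}
        for g in km.G_STAGES:
            row[f"diagnosed_{g}"] = self.ckd_diagnosed_by_stage.get(g, 0)
            row[f"undiagnosed_{g}"] = self.ckd_undiagnosed_by_stage.get(g, 0)
        for m in KRT_MODALITIES:
            row[f"krt_{m}"] = self.krt_by_modality.get(m, 0)
        for o in CV_OUTCOMES:
            for s in _STATUSES:
                row[f"incident_{o}_{s}"] = self.incident_events.get(o, {}).get(s, 0)
            row[f"cv_prevalent_{o}"] = self.cv_prevalent_in_ckd.get(o, 0)
        for s in _STATUSES:
            row[f"deaths_{s}"] = self.deaths_by_status.get(s, 0)
        for g in km.G_STAGES:
            row[f"deaths_{g}"] = self.deaths_by_stage.get(g, 0)
        return row


def outputs_to_frame(outputs: list[AnnualOutputs]) -> pd.DataFrame:
    """One row per simulated year."""
    return pd.DataFrame([o.to_dict() for o in outputs]).set_index("year")


def sample_event(p_base: float, rr: float, rng) -> bool:
    """Draw one event with probability min(1, p_base * rr)."""
    if not (0.0 <= p_base <= 1.0):
        raise ValueError(f"p_base must be in [0, 1], got {p_base}")
    if rr < 0:
        raise ValueError(f"relative risk must be >= 0, got {rr}")
    return bool(rng.random() < min(1.0, p_base * rr))


def update_diagnosis(individual: Individual, rates: dict, rng) -> Individual:
    """Annual diagnosis update for one prevalent case (absorbing)."""
    if not individual.is_ckd:
        raise ValueError("update_diagnosis called on an individual without CKD")
    if individual.diagnosed:
        return individual
    g = individual.stage.G
    if rng.random() < rates.get(g, 0.0):
        individual.diagnosed = True
    return individual


def krt_update(individual: Individual, krt: KrtParameters, rng,
               year: int | None = None,
               access_multiplier: float = 1.0) -> Individual:
    """KRT initiation / modality transition for one living individual."""
    if not individual.alive:
        raise ValueError("krt_update called on a dead individual")
    if individual.krt == "none":
        if individual.is_ckd and individual.egfr < krt.egfr_initiation_threshold:
            p = min(1.0, krt.access_probability * access_multiplier)
            if rng.random() < p:
                u = rng.random()
                cum = 0.0
                for mod in KRT_MODALITIES:
                    cum += krt.modality_shares.get(mod, 0.0)
                    if u < cum:
                        individual.krt = mod
                        individual.krt_start_year = year
                        break
        return individual
    row = krt.modality_transition.get(individual.krt, {})
    u = rng.random()
    cum = 0.0
    for dst in KRT_MODALITIES:
        p = row.get(dst, 0.0)
        if dst == individual.krt:
            continue
        cum += p
        if u < cum:
            individual.krt = dst
            break
    return individual


def _band_sex_lookup(table: dict, band: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Vectorised lookup of a {band: {sex: p}} table; missing cells are 0."""
    arr = np.array([[table.get(b, {}).get(s, 0.0) for s in SEXES]
                    for b in AGE_BANDS])
    return arr[band, sex]


def _category_arrays(bundle: CountryInputBundle):
    """6x3 category-index grid and (category x outcome) rr matrix."""
    grid = bundle.kdigo_grid
    cat_idx = np.array([[km.RISK_CATEGORIES.index(grid.category[f"{g}/{a}"])
                         for a in km.A_STAGES] for g in km.G_STAGES])
    rr = np.array([[grid.rr.get(cat, {}).get(o, 1.0)
                    for o in km.OUTCOMES]
                   for cat in km.RISK_CATEGORIES])
    return cat_idx, rr


def advance_year(cohort: Cohort, bundle: CountryInputBundle, year: int,
                 seed: int, diagnosis_multiplier: float = 1.0,
                 krt_access_multiplier: float = 1.0,
                 incidence_multiplier: float = 1.0):
    """Advance the cohort through one calendar year (in place).

    Returns ``(cohort, AnnualOutputs)``. ``seed`` is the master seed of the
    run; the per-year streams are derived from it.
    """
    if year not in YEARS:
        raise ValueError(f"year {year} outside the 2022-2027 horizon")
    if cohort.n_alive == 0:
        raise ValueError("cohort has no living individuals")
    bundle.require_complete()
    n = len(cohort)
    seed = int(seed) % (2**31)
    rngk = lambda sub: np.random.default_rng([seed, year, sub])
    alive = cohort.alive
    n_alive_start = int(alive.sum())

    # 1. ageing
    cohort.age[alive] += 1
    band = band_index(cohort.age)
    adults = cohort.age >= 18

    # 2. eGFR slope by subtype; albuminuria-stage transition
    slope_table = bundle.slopes.slope
    sub_keys = np.array(
        [km.subtype_key(bool(t), bool(h), bool(c))
         for t in (False, True) for h in (False, True) for c in (False, True)])
    sub_idx = (cohort.t2d.astype(int) * 4 + cohort.htn.astype(int) * 2
               + cohort.cv_any.astype(int))
    slope_vals = np.array([slope_table.get(k, slope_table.get("no_comorbidity", 0.0))
                           for k in sub_keys])[sub_idx]
    progressing = alive & adults & cohort.is_ckd & (cohort.krt == 0)
    cohort.egfr[progressing] = np.maximum(
        0.0, cohort.egfr[progressing] + slope_vals[progressing])

    if bundle.a_transition is not None:
        a_idx = cohort.a_index
        u = rngk(_SUB_ACR).random(n)
        new_a = a_idx.copy()
        for ai, a in enumerate(km.A_STAGES):
            row = bundle.a_transition.get(a)
            if row is None:
                continue
            mask = progressing & (a_idx == ai)
            if not mask.any():
                continue
            cum = np.cumsum([row.get(t, 0.0) for t in km.A_STAGES])
            new_a[mask] = np.searchsorted(cum, u[mask], side="right")
        moved = progressing & (new_a != a_idx)
        if moved.any():
            # redraw ACR uniformly inside the new A-stage cell
            u2 = rngk(_SUB_ACR).random(n)  # independent stream reuse is fine
            for ai in range(3):
                m = moved & (new_a == ai)
                lo, hi = km.A_BOUNDS[ai]
                cohort.acr[m] = lo + u2[m] * (hi - lo)

    # 3. incident CKD onset among CKD-free adults
    p_onset = _band_sex_lookup(bundle.ckd_incidence, band, cohort.sex)
    p_onset = np.minimum(1.0, p_onset * incidence_multiplier)
    onset = (alive & adults & ~cohort.is_ckd
             & (rngk(_SUB_ONSET).random(n) < p_onset))
    n_onset = int(onset.sum())
    if n_onset:
        cells = list(bundle.onset_stage_distribution)
        cum = np.cumsum([bundle.onset_stage_distribution[c] for c in cells])
        pick = np.searchsorted(cum, rngk(_SUB_ONSET_CELL).random(n), side="right")
        eg_u = rngk(_SUB_ONSET_EG).random(n)
        ac_u = rngk(_SUB_ONSET_ACR).random(n)
        for ci, cname in enumerate(cells):
            m = onset & (pick == ci)
            if not m.any():
                continue
            (eg_lo, eg_hi), (ac_lo, ac_hi) = _cell_bounds(cname)
            cohort.egfr[m] = eg_lo + eg_u[m] * (eg_hi - eg_lo)
            cohort.acr[m] = ac_lo + ac_u[m] * (ac_hi - ac_lo)
        cohort.is_ckd[onset] = True

    # 4. comorbidity incidence (optional; defaults to none)
    for key, flag, sub in (("t2d", cohort.t2d, _SUB_T2D),
                           ("htn", cohort.htn, _SUB_HTN)):
        p = bundle.comorbidity_incidence.get(key, 0.0)
        if p > 0:
            onset_c = alive & adults & ~flag & (rngk(sub).random(n) < p)
            flag[onset_c] = True

    # 5. diagnosis (absorbing) with optional scenario multiplier
    g_idx = cohort.g_index
    rate = np.array([bundle.diagnosis_rate_by_stage.get(g, 0.0)
                     for g in km.G_STAGES])[g_idx]
    scaled = rate * diagnosis_multiplier
    if diagnosis_multiplier > 1.0 and np.any(scaled > 1.0):
        logger.info("diagnosis rates capped at 1.0 for %d individuals in %d",
                    int((scaled > 1.0).sum()), year)
    rate = np.minimum(1.0, scaled)
    newly_diag = (alive & cohort.is_ckd & ~cohort.diagnosed
                  & (rngk(_SUB_DIAG).random(n) < rate))
    cohort.diagnosed[newly_diag] = True

    # 6. cardiovascular events (first event of each type)
    cat_idx_grid, rr_matrix = _category_arrays(bundle)
    a_idx = cohort.a_index
    cat_idx = cat_idx_grid[g_idx, a_idx]
    incident_events = {}
    for oi, (outcome, flag, sub) in enumerate(
            (("heart_failure", cohort.cv_hf, _SUB_HF),
             ("MI", cohort.cv_mi, _SUB_MI),
             ("stroke", cohort.cv_stroke, _SUB_STROKE))):
        base = _band_sex_lookup(bundle.cv_base_rates.get(outcome, {}),
                                band, cohort.sex)
        rr = np.where(cohort.is_ckd, rr_matrix[cat_idx, oi], 1.0)
        p = np.minimum(1.0, base * rr)
        event = alive & ~flag & (rngk(sub).random(n) < p)
        flag[event] = True
        incident_events[outcome] = {
            "diagnosed": int((event & cohort.is_ckd & cohort.diagnosed).sum()),
            "undiagnosed": int((event & cohort.is_ckd & ~cohort.diagnosed).sum()),
            "no_ckd": int((event & ~cohort.is_ckd).sum()),
        }

    # 7. KRT initiation and modality transitions
    krt = bundle.krt
    eligible = (alive & cohort.is_ckd & (cohort.krt == 0)
                & (cohort.egfr < krt.egfr_initiation_threshold))
    p_access = min(1.0, krt.access_probability * krt_access_multiplier)
    initiate = eligible & (rngk(_SUB_KRT_INIT).random(n) < p_access)
    if initiate.any():
        shares = np.cumsum([krt.modality_shares.get(m, 0.0)
                            for m in KRT_MODALITIES])
        pick = np.searchsorted(shares, rngk(_SUB_KRT_MOD).random(n),
                               side="right")
        cohort.krt[initiate] = (pick[initiate] + 1).astype(np.int8)
        cohort.krt_start_year[initiate] = year
    if krt.modality_transition:
        u = rngk(_SUB_KRT_TRANS).random(n)
        current = cohort.krt.copy()
        for src in KRT_MODALITIES:
            row = krt.modality_transition.get(src)
            if not row:
                continue
            on_src = alive & (current == KRT_CODES[src])
            if not on_src.any():
                continue
            targets = [m for m in KRT_MODALITIES if m != src]
            cum = np.cumsum([row.get(t, 0.0) for t in targets])
            pick = np.searchsorted(cum, u, side="right")
            for ti, tgt in enumerate(targets):
                cohort.krt[on_src & (pick == ti)] = KRT_CODES[tgt]

    # 8. all-cause mortality
    p_death = _band_sex_lookup(bundle.mortality_base, band, cohort.sex)
    g_idx = cohort.g_index  # eGFR may have changed above
    cat_idx = cat_idx_grid[g_idx, cohort.a_index]
    rr_death = np.where(cohort.is_ckd, rr_matrix[cat_idx, 3], 1.0)
    tx_mult = np.where(cohort.krt == KRT_CODES["Tx"],
                       bundle.tx_mortality_multiplier, 1.0)
    p = np.minimum(1.0, p_death * rr_death * tx_mult)
    died = alive & (rngk(_SUB_DEATH).random(n) < p)
    cohort.alive[died] = False
    cohort.death_year[died] = year

    # --- tallies -------------------------------------------------------------
    alive_now = cohort.alive
    g_idx = cohort.g_index
    out = AnnualOutputs(
        year=year, n_alive_start=n_alive_start,
        n_alive_end=int(alive_now.sum()), deaths=int(died.sum()),
        person_years=n_alive_start, incident_ckd=n_onset,
        incident_diagnoses=int(newly_diag.sum()),
        incident_events=incident_events,
    )
    ckd_alive = alive_now & cohort.is_ckd
    for gi, g in enumerate(km.G_STAGES):
        at_stage = ckd_alive & (g_idx == gi)
        out.ckd_diagnosed_by_stage[g] = int((at_stage & cohort.diagnosed).sum())
        out.ckd_undiagnosed_by_stage[g] = int((at_stage & ~cohort.diagnosed).sum())
    for mod, code in KRT_CODES.items():
        if mod != "none":
            out.krt_by_modality[mod] = int((alive_now & (cohort.krt == code)).sum())
    out.deaths_by_status = {
        "diagnosed": int((died & cohort.is_ckd & cohort.diagnosed).sum()),
        "undiagnosed": int((died & cohort.is_ckd & ~cohort.diagnosed).sum()),
        "no_ckd": int((died & ~cohort.is_ckd).sum()),
    }
    for gi, g in enumerate(km.G_STAGES):
        out.deaths_by_stage[g] = int((died & cohort.is_ckd & (g_idx == gi)).sum())
    for outcome, flag in (("heart_failure", cohort.cv_hf), ("MI", cohort.cv_mi),
                          ("stroke", cohort.cv_stroke)):
        out.cv_prevalent_in_ckd[outcome] = int((ckd_alive & flag).sum())
    return cohort, out


def run_projection(bundle: CountryInputBundle, n: int, seed: int,
                   horizon: tuple[int, int] = (2022, 2027),
                   diagnosis_multiplier: float = 1.0,
                   krt_access_multiplier: float = 1.0,
                   incidence_multiplier: float = 1.0,
                   cohort: Cohort | None = None):
    """Synthesize a cohort and run the annual loop over the horizon.

    Returns ``(cohort, [AnnualOutputs ...])`` with one entry per simulated
    year (end-of-year state). The same ``seed`` drives synthesis and every
    annual stream, so runs are reproducible and scenario comparisons can use
    common random numbers.
    """
    first, last = horizon
    if first not in YEARS or last not in YEARS or first > last:
        raise ValueError(f"horizon {horizon} outside 2022-2027")
    if cohort is None:
        cohort = synthesize(bundle, n, seed,
                            diagnosis_multiplier=diagnosis_multiplier,
                            base_year=first)
    outputs = []
    for year in range(first, last + 1):
        if cohort.n_alive == 0:
            break
        _, out = advance_year(cohort, bundle, year, seed,
                              diagnosis_multiplier=diagnosis_multiplier,
                              krt_access_multiplier=krt_access_multiplier,
                              incidence_multiplier=incidence_multiplier)
        outputs.append(out)
    return cohort, outputs
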