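"""Baseline virtual-cohort synthesis.

A cohort of ``n`` virtual individuals is drawn so that its empirical
marginals match the country input bundle: sex and age band from the
demographic pyramid, a (G, A) stage cell (or "none") from the stage
distribution conditional on age band and sex, a concrete eGFR and ACR
uniformly within the stage cell, a diagnosed flag from the stage-specific
diagnosis rate, and comorbidities from the CKD-conditional prevalence table.
Individuals under 18 carry no CKD state (the eGFR equations are adult) and
age into eligibility during the simulation.

The cohort is stored as a struct-of-arrays for vectorised annual updates;
``Cohort.to_frame`` exports one row per individual for inspection.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kidney_math as km
from .input_model import (AGE_BANDS, COMORBIDITY_CLASSES, CountryInputBundle,
                          SEXES, STAGE_CELLS)

#: integer codes for the sex axis (array storage)
SEX_CODES = {"F": 0, "M": 1}
#: sampled age range per reporting band (inclusive)
BAND_AGE_RANGES = {"0-17": (0, 17), "18-34": (18, 34),
                   "35-64": (35, 64), "65+": (65, 90)}
#: KRT modality codes: 0 = none
KRT_CODES = {"none": 0, "HD": 1, "PD": 2, "Tx": 3}
KRT_NAMES = {v: k for k, v in KRT_CODES.items()}

#: eGFR/ACR sampling window for individuals without CKD
NO_CKD_EGFR = (60.0, 120.0)
NO_CKD_ACR = (0.0, 30.0)


def band_index(age):
    """Reporting age band index (0..3) for an age array."""
    age = np.asarray(age)
    return np.searchsorted([18, 35, 65], age, side="right").astype(np.int8)


@dataclass
class Individual:
    """One virtual person's health state (scalar view, mainly for tests)."""

    id: int
    age: int
    sex: str
    alive: bool = True
    egfr: float = 100.0
    acr: float = 5.0
    diagnosed: bool = False
    t2d: bool = False
    htn: bool = False
    is_ckd: bool = False
    cv_history: dict = field(default_factory=dict)
    krt: str = "none"
    krt_start_year: int | None = None
    death_year: int | None = None

    @property
    def stage(self) -> km.StagePair:
        pair = km.stage_from_measures(self.egfr, self.acr)
        # CKD is absorbing in the model even if ACR drifts back under 30
        if self.is_ckd and not pair.is_ckd:
            return km.StagePair(pair.G, pair.A, True)
        return pair


@dataclass
class Cohort:
    """Struct-of-arrays container for the virtual population."""

    country_code: str
    virtual_size: int
    base_year: int
    age: np.ndarray          # int16, years
    sex: np.ndarray          # int8, 0=F 1=M
    alive: np.ndarray        # bool
    egfr: np.ndarray         # float64
    acr: np.ndarray          # float64
    is_ckd: np.ndarray       # bool (absorbing)
    diagnosed: np.ndarray    # bool (absorbing)
    t2d: np.ndarray          # bool
    htn: np.ndarray          # bool
    cv_hf: np.ndarray        # bool, ever had heart failure
    cv_mi: np.ndarray
    cv_stroke: np.ndarray
    krt: np.ndarray          # int8, KRT_CODES
    krt_start_year: np.ndarray  # int16, -1 = never
    death_year: np.ndarray   # int16, -1 = alive

    def __len__(self):
        return self.age.shape[0]

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    @property
    def g_index(self) -> np.ndarray:
        return km.g_stage_index(self.egfr)

    @property
    def a_index(self) -> np.ndarray:
        return km.a_stage_index(self.acr)

    @property
    def cv_any(self) -> np.ndarray:
        return self.cv_hf | self.cv_mi | self.cv_stroke

    def to_frame(self) -> pd.DataFrame:
        """One row per individual, for debugging and CSV export."""
        sex = np.array(["F", "M"])[self.sex]
        return pd.DataFrame({
            "age": self.age, "sex": sex, "alive": self.alive,
            "egfr": self.egfr, "acr": self.acr,
            "g_stage": np.array(km.G_STAGES)[self.g_index],
            "a_stage": np.array(km.A_STAGES)[self.a_index],
            "is_ckd": self.is_ckd, "diagnosed": self.diagnosed,
            "t2d": self.t2d, "htn": self.htn,
            "cv_hf": self.cv_hf, "cv_mi": self.cv_mi,
            "cv_stroke": self.cv_stroke,
            "krt": np.array([KRT_NAMES[c] for c in self.krt]),
            "death_year": self.death_year,
        })

    def get_individual(self, i: int) -> Individual:
        return Individual(
            id=i, age=int(self.age[i]), sex="F" if self.sex[i] == 0 else "M",
            alive=bool(self.alive[i]), egfr=float(self.egfr[i]),
            acr=float(self.acr[i]), diagnosed=bool(self.diagnosed[i]),
            t2d=bool(self.t2d[i]), htn=bool(self.htn[i]),
            is_ckd=bool(self.is_ckd[i]),
            cv_history={"heart_failure": bool(self.cv_hf[i]),
                        "MI": bool(self.cv_mi[i]),
                        "stroke": bool(self.cv_stroke[i])},
            krt=KRT_NAMES[int(self.krt[i])],
            krt_start_year=(int(self.krt_start_year[i])
                            if self.krt_start_year[i] >= 0 else None),
            death_year=(int(self.death_year[i])
                        if self.death_year[i] >= 0 else None),
        )


def _cell_bounds(cell: str):
    """eGFR and ACR uniform-sampling bounds for a stage cell."""
    if cell == "none":
        return NO_CKD_EGFR, NO_CKD_ACR
    g, a = cell.split("/")
    gi, ai = km.G_STAGES.index(g), km.A_STAGES.index(a)
    lo = km.G_LOWER_BOUNDS[gi] if gi < 5 else km.G5_SAMPLING_FLOOR
    return (lo, km.G_UPPER_BOUNDS[gi]), km.A_BOUNDS[ai]


def synthesize(bundle: CountryInputBundle, n: int, seed: int,
               diagnosis_multiplier: float = 1.0,
               base_year: int = 2022) -> Cohort:
    """Draw a baseline cohort of ``n`` virtual individuals.

    Reproducible: every sampling decision uses its own stream derived from
    ``seed``, so equal seeds give byte-identical cohorts and scenario
    comparisons (e.g. diagnosis-rate multipliers) share random numbers.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    bundle.require_complete()
    rng = lambda k: np.random.default_rng([int(seed) % (2**31), k])

    # sex x age band from the joint pyramid
    cats = [(sex, band, bundle.pyramid.get(sex, {}).get(band, 0.0))
            for sex in SEXES for band in AGE_BANDS]
    probs = np.array([c[2] for c in cats])
    probs = probs / probs.sum()
    cat_idx = rng(0).choice(len(cats), size=n, p=probs)
    sex = np.array([SEX_CODES[cats[i][0]] for i in range(len(cats))],
                   dtype=np.int8)[cat_idx]
    band = np.array([AGE_BANDS.index(cats[i][1]) for i in range(len(cats))],
                    dtype=np.int8)[cat_idx]
    age_u = rng(1).random(n)
    lo = np.array([BAND_AGE_RANGES[AGE_BANDS[b]][0] for b in range(4)])[band]
    hi = np.array([BAND_AGE_RANGES[AGE_BANDS[b]][1] for b in range(4)])[band]
    age = (lo + np.floor(age_u * (hi - lo + 1))).astype(np.int16)

    # stage cell conditional on (band, sex); minors are CKD-free
    cell = np.zeros(n, dtype=np.int16)  # index into STAGE_CELLS; 0 = "none"
    stage_u = rng(2).random(n)
    adults = age >= 18
    for bi, bname in enumerate(AGE_BANDS):
        if bname == "0-17":
            continue
        for sname, scode in SEX_CODES.items():
            mask = adults & (band == bi) & (sex == scode)
            if not mask.any():
                continue
            row = bundle.stage_distribution.get(bname, {}).get(sname)
            if row is None:
                raise ValueError(
                    f"stage_distribution missing row for {bname}/{sname}")
            p = np.array([row.get(c, 0.0) for c in STAGE_CELLS])
            cum = np.cumsum(p / p.sum())
            cell[mask] = np.searchsorted(cum, stage_u[mask], side="right")

    # concrete eGFR / ACR uniformly within the assigned cell
    egfr_u, acr_u = rng(3).random(n), rng(4).random(n)
    egfr = np.empty(n)
    acr = np.empty(n)
    for ci, cname in enumerate(STAGE_CELLS):
        mask = cell == ci
        if not mask.any():
            continue
        (eg_lo, eg_hi), (ac_lo, ac_hi) = _cell_bounds(cname)
        egfr[mask] = eg_lo + egfr_u[mask] * (eg_hi - eg_lo)
        acr[mask] = ac_lo + acr_u[mask] * (ac_hi - ac_lo)
    is_ckd = cell > 0

    # diagnosis: stage-specific probability that a prevalent case is diagnosed
    g_idx = km.g_stage_index(egfr)
    diag_rate = np.array([bundle.diagnosis_rate_by_stage.get(g, 0.0)
                          for g in km.G_STAGES])[g_idx]
    diag_rate = np.minimum(1.0, diag_rate * diagnosis_multiplier)
    diagnosed = is_ckd & (rng(5).random(n) < diag_rate)

    # comorbidities conditional on CKD status
    comorb_u = rng(6).random(n)
    t2d = np.zeros(n, dtype=bool)
    htn = np.zeros(n, dtype=bool)
    for status, mask in (("ckd", is_ckd & adults),
                         ("no_ckd", ~is_ckd & adults)):
        row = bundle.comorbidity_prevalence.get(status, {})
        p_t2d = row.get("t2d_only", 0.0)
        p_htn = row.get("htn_only", 0.0)
        p_both = row.get("both", 0.0)
        u = comorb_u[mask]
        t2d[mask] = (u < p_t2d) | ((u >= p_t2d + p_htn) & (u < p_t2d + p_htn + p_both))
        htn[mask] = (u >= p_t2d) & (u < p_t2d + p_htn + p_both)

    z = lambda dtype, fill=0: np.full(n, fill, dtype=dtype)
    return Cohort(
        country_code=bundle.country_code, virtual_size=n, base_year=base_year,
        age=age, sex=sex, alive=np.ones(n, dtype=bool), egfr=egfr, acr=acr,
        is_ckd=is_ckd, diagnosed=diagnosed, t2d=t2d, htn=htn,
        cv_hf=z(bool), cv_mi=z(bool), cv_stroke=z(bool),
        krt=z(np.int8), krt_start_year=z(np.int16, -1),
        death_year=z(np.int16, -1),
    )


def baseline_summary(cohort: Cohort) -> pd.Series:
    """Empirical proportions of the cohort, mirroring the baseline tables.

    Per-G-stage proportions count individuals with CKD in that stage as a
    share of the whole cohort, so they sum to the all-stage CKD proportion.
    Comorbidity proportions are conditional on having CKD.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")
    out = {"female": float((cohort.sex == 0).mean())}
    bands = band_index(cohort.age)
    for bi, bname in enumerate(AGE_BANDS):
        out[f"age_{bname}"] = float((bands == bi).mean())
    g_idx = cohort.g_index
    for gi, g in enumerate(km.G_STAGES):
        out[f"stage_{g}"] = float((cohort.is_ckd & (g_idx == gi)).mean())
    out["ckd_all_stages"] = float(cohort.is_ckd.mean())
    out["ckd_diagnosed"] = float(cohort.diagnosed.mean())
    n_ckd = int(cohort.is_ckd.sum())
    out["t2d_in_ckd"] = (float(cohort.t2d[cohort.is_ckd].mean())
                         if n_ckd else 0.0)
    out["htn_in_ckd"] = (float(cohort.htn[cohort.is_ckd].mean())
                         if n_ckd else 0.0)
    return pd.Series(out)
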