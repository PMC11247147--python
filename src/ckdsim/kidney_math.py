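"""Deterministic kidney arithmetic.

eGFR from serum creatinine (CKD-EPI creatinine equations, 2009 and 2021
race-free versions), KDIGO G/A staging, risk-grid categorisation, and linear
eGFR slope application. Everything here is a pure function of its inputs;
all Monte Carlo behaviour lives in the simulation engine.

Staging conventions (fixed once for the whole package):

* G intervals are closed at the lower bound: eGFR 90 -> G1, 60 -> G2,
  45 -> G3a, 30 -> G3b, 15 -> G4, below 15 -> G5.
* A1 = [0, 30) mg/g, A2 = [30, 300] (closed at both ends), A3 = (300, inf).
* CKD is present iff G >= G3a, or G in {G1, G2} with albuminuria (A2/A3).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

G_STAGES = ("G1", "G2", "G3a", "G3b", "G4", "G5")
A_STAGES = ("A1", "A2", "A3")
#: lower eGFR bound of each G stage, aligned with G_STAGES
G_LOWER_BOUNDS = (90.0, 60.0, 45.0, 30.0, 15.0, 0.0)
#: upper eGFR bound used when sampling a concrete value inside a stage cell
G_UPPER_BOUNDS = (120.0, 90.0, 60.0, 45.0, 30.0, 15.0)
#: lower bound of the G5 sampling cell (eGFR of exactly 0 is not drawn)
G5_SAMPLING_FLOOR = 1.0
#: ACR sampling bounds per A stage; A3 is truncated at 3000 mg/g
A_BOUNDS = ((0.0, 30.0), (30.0, 300.0), (300.0, 3000.0))

RISK_CATEGORIES = ("low", "moderate", "high", "very_high")
OUTCOMES = ("heart_failure", "MI", "stroke", "death")


@dataclass(frozen=True)
class EgfrEquationParams:
    """Coefficients of one published CKD-EPI creatinine equation version."""

    version: int
    intercept: float
    kappa: dict  # sex -> creatinine knot (mg/dL)
    alpha: dict  # sex -> exponent below the knot
    beta: float  # exponent above the knot
    age_base: float  # per-year age multiplier base
    female_multiplier: float


CKD_EPI_2009 = EgfrEquationParams(
    version=2009,
    intercept=141.0,
    kappa={"F": 0.7, "M": 0.9},
    alpha={"F": -0.329, "M": -0.411},
    beta=-1.209,
    age_base=0.993,
    female_multiplier=1.018,
)

CKD_EPI_2021 = EgfrEquationParams(
    version=2021,
    intercept=142.0,
    kappa={"F": 0.7, "M": 0.9},
    alpha={"F": -0.241, "M": -0.302},
    beta=-1.200,
    age_base=0.9938,
    female_multiplier=1.012,
)

EQUATIONS = {2009: CKD_EPI_2009, 2021: CKD_EPI_2021}


def egfr_ckd_epi(scr, age, sex, params: EgfrEquationParams | int = 2021):
    """Estimated GFR (mL/min/1.73 m^2) from serum creatinine.

    Parameters
    ----------
    scr : float or array
        Serum creatinine, mg/dL. Must be positive.
    age : float or array
        Age in years; the equations are validated for adults (>= 18).
    sex : {"F", "M"}
        Sex used for the kappa/alpha coefficients and female multiplier.
    params : EgfrEquationParams or {2009, 2021}
        Equation version; the default is the 2021 race-free refit.
    """
    if isinstance(params, int):
        params = EQUATIONS[params]
    if sex not in ("F", "M"):
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
    scr = np.asarray(scr, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be positive")
    ratio = scr / params.kappa[sex]
    value = (
        params.intercept
        * np.minimum(ratio, 1.0) ** params.alpha[sex]
        * np.maximum(ratio, 1.0) ** params.beta
        * params.age_base ** np.asarray(age, dtype=float)
    )
    if sex == "F":
        value = value * params.female_multiplier
    return value if value.ndim else float(value)


def g_stage_index(egfr):
    """Vectorised G stage index (0=G1 .. 5=G5); lower bounds closed."""
    egfr = np.asarray(egfr, dtype=float)
    if np.any(egfr < 0) or np.any(~np.isfinite(egfr)):
        raise ValueError("eGFR must be finite and non-negative")
    # searchsorted over descending bounds: egfr >= 90 -> 0, ..., < 15 -> 5
    idx = np.zeros(egfr.shape, dtype=np.int8)
    for i, lo in enumerate(G_LOWER_BOUNDS[:-1]):
        idx = np.where(egfr < lo, i + 1, idx)
    return idx if idx.ndim else int(idx)


def a_stage_index(acr):
    """Vectorised A stage index (0=A1, 1=A2, 2=A3); A2 closed at 300."""
    acr = np.asarray(acr, dtype=float)
    if np.any(acr < 0) or np.any(~np.isfinite(acr)):
        raise ValueError("ACR must be finite and non-negative")
    idx = np.where(acr < 30.0, 0, np.where(acr <= 300.0, 1, 2)).astype(np.int8)
    return idx if idx.ndim else int(idx)


def is_ckd_from_indices(g_idx, a_idx):
    """CKD flag from stage indices: G3a+ or (G1/G2 with A2/A3)."""
    g_idx = np.asarray(g_idx)
    a_idx = np.asarray(a_idx)
    out = (g_idx >= 2) | (a_idx >= 1)
    return out if out.ndim else bool(out)


@dataclass(frozen=True)
class StagePair:
    """A (G, A) KDIGO stage assignment with the derived CKD flag."""

    G: str
    A: str
    is_ckd: bool

    @property
    def g_index(self) -> int:
        return G_STAGES.index(self.G)

    @property
    def a_index(self) -> int:
        return A_STAGES.index(self.A)


def stage_from_measures(egfr: float, acr: float) -> StagePair:
    """Stage a single (eGFR, ACR) measurement pair."""
    gi = g_stage_index(egfr)
    ai = a_stage_index(acr)
    return StagePair(G=G_STAGES[gi], A=A_STAGES[ai],
                     is_ckd=is_ckd_from_indices(gi, ai))


# -- KDIGO heat map -----------------------------------------------------------

#: published KDIGO 2012 risk heat map over the 18 (G, A) cells
DEFAULT_KDIGO_CATEGORIES = {
    ("G1", "A1"): "low", ("G1", "A2"): "moderate", ("G1", "A3"): "high",
    ("G2", "A1"): "low", ("G2", "A2"): "moderate", ("G2", "A3"): "high",
    ("G3a", "A1"): "moderate", ("G3a", "A2"): "high", ("G3a", "A3"): "very_high",
    ("G3b", "A1"): "high", ("G3b", "A2"): "very_high", ("G3b", "A3"): "very_high",
    ("G4", "A1"): "very_high", ("G4", "A2"): "very_high", ("G4", "A3"): "very_high",
    ("G5", "A1"): "very_high", ("G5", "A2"): "very_high", ("G5", "A3"): "very_high",
}


def kdigo_category(stage: StagePair, grid) -> str:
    """Risk category of a stage pair under a KdigoRiskGrid (or plain dict)."""
    categories = getattr(grid, "category", grid)
    key = (stage.G, stage.A)
    if key not in categories:
        raise KeyError(f"KDIGO grid has no cell for {key}")
    return categories[key]


# -- eGFR slopes --------------------------------------------------------------

def subtype_key(t2d: bool, htn: bool, cv: bool) -> str:
    """Canonical progression-subtype key from comorbidity/CV-history flags."""
    parts = [name for flag, name in ((t2d, "t2d"), (htn, "htn"), (cv, "cv"))
             if flag]
    return "+".join(parts) if parts else "no_comorbidity"


def apply_slope(egfr: float, subtype: str, slopes, years: int) -> float:
    """Apply ``years`` worth of annual eGFR slope, floored at zero."""
    if years < 0:
        raise ValueError("years must be non-negative")
    table = getattr(slopes, "slope", slopes)
    if subtype not in table:
        raise KeyError(f"unknown progression subtype {subtype!r}")
    return max(0.0, float(egfr) + table[subtype] * years)
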