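"""Synthetic country input bundles with known ground truth.

The study's real per-country inputs live in registries and national
statistics; this module generates bundles with the same statistical
structure (population size, sex split, four reporting age bands,
stage-specific CKD prevalence, diagnosed fraction, comorbidity prevalence)
so every pipeline stage is testable without any external data. Profiles
place the over-65 share at the extremes observed across the modelled
countries (3.6% for a large young population, 28.9% for a small aged one).

Ground-truth scenarios pair a bundle with analytically computed
expectations (constant-hazard survival, linear eGFR decline, a known
mortality relative risk) used to validate the simulation engine.
"""
from __future__ import annotations

import numpy as np

from .input_model import (AGE_BANDS, CountryInputBundle, KdigoRiskGrid,
                          KrtParameters, ProgressionSlopes, SEXES, YEARS)
from .kidney_math import A_STAGES, DEFAULT_KDIGO_CATEGORIES, G_STAGES

PROFILES = ("small_aged", "large_young", "degenerate", "custom")
SCENARIOS = ("constant_hazard", "slope_recovery", "rr_recovery", "calibration")

#: outcome relative risks per KDIGO category, representative of the
#: graded hazards reported for CKD cohorts (low category is the reference)
DEFAULT_RR = {
    "low": {"heart_failure": 1.0, "MI": 1.0, "stroke": 1.0, "death": 1.0},
    "moderate": {"heart_failure": 1.5, "MI": 1.4, "stroke": 1.4, "death": 1.5},
    "high": {"heart_failure": 2.5, "MI": 2.0, "stroke": 1.9, "death": 2.2},
    "very_high": {"heart_failure": 4.0, "MI": 3.0, "stroke": 2.8, "death": 3.5},
}

#: annual eGFR slopes (mL/min/1.73 m^2 per year) by progression subtype,
#: in the range reported by large CKD cohort slope analyses
DEFAULT_SLOPES = {
    "no_comorbidity": -1.0, "t2d": -2.5, "htn": -1.8, "t2d+htn": -3.0,
    "cv": -1.5, "t2d+cv": -3.0, "htn+cv": -2.3, "t2d+htn+cv": -3.5,
}


def default_kdigo_grid(rr: dict | None = None) -> KdigoRiskGrid:
    """The published KDIGO heat map with default (or supplied) relative risks."""
    category = {f"{g}/{a}": DEFAULT_KDIGO_CATEGORIES[(g, a)]
                for g in G_STAGES for a in A_STAGES}
    return KdigoRiskGrid(category=category, rr=rr or DEFAULT_RR)


def _stage_row(ckd_prev: float) -> dict:
    """Distribute an all-stage CKD prevalence over (G, A) cells.

    G mixture follows the typical shape of baseline stage tables (G3a the
    modal CKD stage); A mixture respects the CKD definition (G1/G2 cases
    must be albuminuric).
    """
    g_weights = {"G1": 0.25, "G2": 0.20, "G3a": 0.33, "G3b": 0.14,
                 "G4": 0.06, "G5": 0.02}
    row = {"none": 1.0 - ckd_prev}
    for g, gw in g_weights.items():
        if g in ("G1", "G2"):
            a_mix = {"A2": 0.8, "A3": 0.2}
        else:
            a_mix = {"A1": 0.6, "A2": 0.3, "A3": 0.1}
        for a, aw in a_mix.items():
            row[f"{g}/{a}"] = ckd_prev * gw * aw
    total = sum(row.values())
    return {k: v / total for k, v in row.items()}


def _flat_population(size: float, growth: float = 0.01) -> dict:
    return {y: size * (1 + growth) ** (y - 2022) for y in YEARS}


_PROFILE_PARAMS = {
    # over-65 shares at the extremes observed across modelled countries
    "small_aged": dict(
        population=5.8e6, growth=0.004,
        female=0.512, bands=(0.149, 0.165, 0.397, 0.289),
        ckd_prev_by_band=(0.0, 0.05, 0.12, 0.30)),
    "large_young": dict(
        population=112.5e6, growth=0.012,
        female=0.498, bands=(0.310, 0.298, 0.356, 0.036),
        ckd_prev_by_band=(0.0, 0.02, 0.06, 0.18)),
}

_DEFAULT_RATES = dict(
    diagnosis_rate_by_stage={"G1": 0.05, "G2": 0.08, "G3a": 0.15,
                             "G3b": 0.30, "G4": 0.50, "G5": 0.80},
    ckd_incidence_by_band=(0.0, 0.002, 0.005, 0.012),
    comorbidity_prevalence={
        "ckd": {"t2d_only": 0.12, "htn_only": 0.40, "both": 0.18},
        "no_ckd": {"t2d_only": 0.05, "htn_only": 0.20, "both": 0.04}},
    cv_base_by_band={
        "heart_failure": (0.0, 0.0005, 0.003, 0.012),
        "MI": (0.0, 0.0006, 0.004, 0.012),
        "stroke": (0.0, 0.0005, 0.003, 0.010)},
    mortality_by_band=(0.0003, 0.0008, 0.004, 0.040),
)


def _by_band_sex(values, male_factor: float = 1.0) -> dict:
    return {band: {"F": values[i], "M": min(1.0, values[i] * male_factor)}
            for i, band in enumerate(AGE_BANDS)}


def generate_bundle(profile: str, seed: int = 0,
                    **custom) -> CountryInputBundle:
    """Generate a valid country bundle for a named profile.

    ``custom`` entries override any CountryInputBundle field (profile
    "custom" requires them). The realised scalar parameters are recorded in
    ``metadata["ground_truth"]`` for recovery tests. Deterministic given
    (profile, seed).
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected {PROFILES}")

    if profile == "degenerate":
        fields = dict(
            country_code="DEGENERATE",
            population_by_year={y: 1e6 for y in YEARS},
            pyramid={"M": {"35-64": 1.0}},
            stage_distribution={b: {s: {"none": 1.0} for s in SEXES}
                                for b in AGE_BANDS},
            diagnosis_rate_by_stage={g: 0.0 for g in G_STAGES},
            ckd_incidence=_by_band_sex((0.0,) * 4),
            comorbidity_prevalence={"ckd": {}, "no_ckd": {}},
            cv_base_rates={o: _by_band_sex((0.0,) * 4)
                           for o in ("heart_failure", "MI", "stroke")},
            mortality_base=_by_band_sex((0.0,) * 4),
            kdigo_grid=default_kdigo_grid(),
            slopes=ProgressionSlopes(slope={k: 0.0 for k in DEFAULT_SLOPES}),
            krt=KrtParameters(egfr_initiation_threshold=10.0,
                              access_probability=0.0,
                              modality_shares={"HD": 1.0}),
            metadata={"profile": profile, "seed": int(seed)},
        )
        fields.update(custom)
        return CountryInputBundle(**fields)

    if profile == "custom":
        params = dict(_PROFILE_PARAMS["small_aged"])
        rng = None
    else:
        params = dict(_PROFILE_PARAMS[profile])
        rng = np.random.default_rng([int(seed) % (2**31), 97])

    # seed-jittered prevalence (+-10% relative) keeps distinct seeds distinct
    jitter = (lambda v: float(np.clip(v * (1 + 0.1 * (rng.random() * 2 - 1)),
                                      0.0, 0.97)) if rng is not None
              else (lambda v: v))
    ckd_prev = [jitter(v) for v in params["ckd_prev_by_band"]]

    female = params["female"]
    bands = params["bands"]
    pyramid = {"F": {b: female * bands[i] for i, b in enumerate(AGE_BANDS)},
               "M": {b: (1 - female) * bands[i] for i, b in enumerate(AGE_BANDS)}}

    stage_distribution = {}
    for i, band in enumerate(AGE_BANDS):
        row = {"none": 1.0} if band == "0-17" else _stage_row(ckd_prev[i])
        stage_distribution[band] = {"F": dict(row), "M": dict(row)}

    fields = dict(
        country_code=profile.upper(),
        population_by_year=_flat_population(params["population"],
                                            params["growth"]),
        pyramid=pyramid,
        stage_distribution=stage_distribution,
        diagnosis_rate_by_stage=dict(_DEFAULT_RATES["diagnosis_rate_by_stage"]),
        ckd_incidence=_by_band_sex(_DEFAULT_RATES["ckd_incidence_by_band"]),
        comorbidity_prevalence={k: dict(v) for k, v in
                                _DEFAULT_RATES["comorbidity_prevalence"].items()},
        cv_base_rates={o: _by_band_sex(v, male_factor=1.2)
                       for o, v in _DEFAULT_RATES["cv_base_by_band"].items()},
        mortality_base=_by_band_sex(_DEFAULT_RATES["mortality_by_band"],
                                    male_factor=1.3),
        kdigo_grid=default_kdigo_grid(),
        slopes=ProgressionSlopes(slope=dict(DEFAULT_SLOPES)),
        krt=KrtParameters(
            egfr_initiation_threshold=10.0, access_probability=0.7,
            modality_shares={"HD": 0.65, "PD": 0.15, "Tx": 0.20},
            modality_transition={"HD": {"Tx": 0.02},
                                 "PD": {"HD": 0.05, "Tx": 0.02}},
            historical_prevalence=[(2016, 900.0), (2018, 1000.0),
                                   (2020, 1100.0)]),
        metadata={"profile": profile, "seed": int(seed),
                  "ground_truth": {"ckd_prev_by_band": ckd_prev,
                                   "female": female,
                                   "band_shares": list(bands)}},
    )
    fields.update(custom)
    return CountryInputBundle(**fields)


def generate_ground_truth_scenario(target: str, seed: int = 0):
    """A bundle plus closed-form expectations for engine validation."""
    if target not in SCENARIOS:
        raise ValueError(f"unknown scenario {target!r}; expected {SCENARIOS}")

    if target == "constant_hazard":
        p = 0.1
        bundle = generate_bundle(
            "degenerate", seed, country_code="CONSTANT_HAZARD",
            mortality_base=_by_band_sex((p,) * 4))
        expected = {"death_probability": p,
                    "alive_fraction_after_5_years": (1 - p) ** 5}
        return bundle, expected

    if target == "slope_recovery":
        slope = -3.0
        cell_row = {b: {s: {"G2/A2": 1.0} for s in SEXES}
                    for b in AGE_BANDS if b != "0-17"}
        cell_row["0-17"] = {s: {"none": 1.0} for s in SEXES}
        bundle = generate_bundle(
            "degenerate", seed, country_code="SLOPE_RECOVERY",
            pyramid={"M": {"35-64": 1.0}},
            stage_distribution=cell_row,
            slopes=ProgressionSlopes(slope={k: slope for k in DEFAULT_SLOPES}))
        # baseline eGFR uniform on [60, 90): mean 75; no floor within 5 years
        expected = {"slope": slope, "mean_egfr_baseline": 75.0,
                    "mean_egfr_after_5_years": 75.0 + 5 * slope}
        return bundle, expected

    if target == "rr_recovery":
        p_base, rr = 0.01, 2.0
        grid_rr = {cat: dict(v) for cat, v in DEFAULT_RR.items()}
        for cat in grid_rr:
            grid_rr[cat] = {o: 1.0 for o in grid_rr[cat]}
        grid_rr["very_high"]["death"] = rr
        stage = {b: {s: {"none": 0.5, "G4/A1": 0.5} for s in SEXES}
                 for b in AGE_BANDS}
        bundle = generate_bundle(
            "degenerate", seed, country_code="RR_RECOVERY",
            stage_distribution=stage,
            mortality_base=_by_band_sex((p_base,) * 4),
            kdigo_grid=default_kdigo_grid(grid_rr))
        expected = {"death_rr": rr, "p_base": p_base,
                    "p_death_ckd": p_base * rr}
        return bundle, expected

    # calibration: a known KRT access fraction to be recovered by bisection
    access = 0.6
    stage = {b: {s: {"none": 0.7, "G5/A2": 0.3} for s in SEXES}
             for b in AGE_BANDS}
    stage["0-17"] = {s: {"none": 1.0} for s in SEXES}
    bundle = generate_bundle(
        "degenerate", seed, country_code="CALIBRATION",
        stage_distribution=stage,
        krt=KrtParameters(egfr_initiation_threshold=10.0,
                          access_probability=1.0,
                          modality_shares={"HD": 1.0},
                          historical_prevalence=[(2018, 1000.0),
                                                 (2020, 1100.0)]))
    expected = {"true_access": access}
    return bundle, expected
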