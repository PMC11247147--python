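"""Country input bundles and printed-table fixtures.

A :class:`CountryInputBundle` carries every per-country parameter the
microsimulation consumes: national population by calendar year, the sex x
age-band pyramid, the joint (G, A) stage distribution conditional on age band
and sex, stage-specific diagnosis rates, CKD onset rates, comorbidity
prevalence, cardiovascular base rates, all-cause mortality, the KDIGO risk
grid with outcome relative risks, eGFR progression slopes, and the kidney
replacement therapy (KRT) parameters. Bundles serialise to a single YAML
document with a versioned schema so that inputs are inspectable and diffable.

The module also loads the packaged CSV transcriptions of the published
country summary tables used by the aggregation layer.
"""
from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .kidney_math import A_STAGES, G_STAGES, OUTCOMES, RISK_CATEGORIES

SCHEMA_VERSION = 1
YEARS = tuple(range(2022, 2028))
AGE_BANDS = ("0-17", "18-34", "35-64", "65+")
SEXES = ("F", "M")
#: stage-cell labels used in stage distributions: "none" or "<G>/<A>"
STAGE_CELLS = ("none",) + tuple(f"{g}/{a}" for g in G_STAGES for a in A_STAGES)
KRT_MODALITIES = ("HD", "PD", "Tx")
COMORBIDITY_CLASSES = ("none", "t2d_only", "htn_only", "both")
PROB_TOL = 1e-9

#: the fields resolve_proxy may fill from a donor bundle
PROXYABLE_FIELDS = (
    "diagnosis_rate_by_stage", "ckd_incidence", "comorbidity_prevalence",
    "cv_base_rates", "mortality_base", "kdigo_grid", "slopes", "krt",
)


def _check_prob(name, value):
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")
    return value


class KdigoRiskGrid(BaseModel):
    """KDIGO heat-map categories and per-category outcome relative risks.

    ``category`` maps each of the 18 "G/A" cells (e.g. ``"G3a/A2"``) to one
    of low/moderate/high/very_high; ``rr`` maps each category to relative
    risks for heart_failure, MI, stroke and death. The low category is the
    reference and must carry rr 1 for every outcome.
    """

    model_config = ConfigDict(extra="forbid")

    category: dict[str, str]
    rr: dict[str, dict[str, float]]

    @model_validator(mode="after")
    def _complete(self):
        expected = {f"{g}/{a}" for g in G_STAGES for a in A_STAGES}
        missing = expected - set(self.category)
        if missing:
            raise ValueError(f"KDIGO grid missing cells: {sorted(missing)}")
        extra = set(self.category) - expected
        if extra:
            raise ValueError(f"KDIGO grid has unknown cells: {sorted(extra)}")
        bad = set(self.category.values()) - set(RISK_CATEGORIES)
        if bad:
            raise ValueError(f"unknown risk categories: {sorted(bad)}")
        for cat in set(self.category.values()):
            if cat not in self.rr:
                raise ValueError(f"no relative risks for category {cat!r}")
            for outcome in OUTCOMES:
                if outcome not in self.rr[cat]:
                    raise ValueError(f"rr[{cat!r}] missing outcome {outcome!r}")
                if self.rr[cat][outcome] < 0:
                    raise ValueError("relative risks must be >= 0")
        if "low" in self.rr:
            for outcome, v in self.rr["low"].items():
                if outcome in OUTCOMES and v != 1.0:
                    raise ValueError("rr(low, .) must be 1 by convention")
        return self

    def category_at(self, g: str, a: str) -> str:
        return self.category[f"{g}/{a}"]

    def relative_risk(self, g: str, a: str, outcome: str) -> float:
        return self.rr[self.category_at(g, a)][outcome]


class ProgressionSlopes(BaseModel):
    """Annual eGFR change (mL/min/1.73 m^2 per year) by patient subtype.

    Subtypes are keyed by the presence of type 2 diabetes, hypertension and
    prior cardiovascular events (see :func:`ckdsim.kidney_math.subtype_key`).
    Slopes are assumed identical across countries in a multi-country run.
    """

    model_config = ConfigDict(extra="forbid")

    slope: dict[str, float]

    @model_validator(mode="after")
    def _finite(self):
        for key, v in self.slope.items():
            if not (v == v and abs(v) < 1e6):
                raise ValueError(f"slope[{key!r}] must be finite")
        return self


class KrtParameters(BaseModel):
    """Kidney replacement therapy initiation, access and modality dynamics."""

    model_config = ConfigDict(extra="forbid")

    egfr_initiation_threshold: float = Field(gt=0)
    access_probability: float
    modality_shares: dict[str, float]
    modality_transition: dict[str, dict[str, float]] = Field(default_factory=dict)
    historical_prevalence: list[tuple[int, float]] = Field(default_factory=list)

    @model_validator(mode="after")
    def _shares(self):
        _check_prob("access_probability", self.access_probability)
        unknown = set(self.modality_shares) - set(KRT_MODALITIES)
        if unknown:
            raise ValueError(f"unknown KRT modalities: {sorted(unknown)}")
        total = sum(self.modality_shares.values())
        if abs(total - 1.0) > PROB_TOL:
            raise ValueError(f"modality_shares must sum to 1, got {total}")
        for src, row in self.modality_transition.items():
            if src not in KRT_MODALITIES:
                raise ValueError(f"unknown transition source {src!r}")
            for dst, p in row.items():
                if dst not in KRT_MODALITIES:
                    raise ValueError(f"unknown transition target {dst!r}")
                _check_prob(f"modality_transition[{src}][{dst}]", p)
            if sum(row.values()) > 1.0 + PROB_TOL:
                raise ValueError(f"transition probabilities out of {src} exceed 1")
        return self


class CountryInputBundle(BaseModel):
    """All per-country inputs consumed by the simulation engine.

    The fields listed in :data:`PROXYABLE_FIELDS` are optional at load time
    so that gaps can be filled from donor countries via
    :func:`resolve_proxy`; :meth:`require_complete` asserts none are missing
    before a simulation run.
    """

    model_config = ConfigDict(extra="forbid")

    schema_version: int = SCHEMA_VERSION
    country_code: str
    population_by_year: dict[int, float]
    pyramid: dict[str, dict[str, float]]
    stage_distribution: dict[str, dict[str, dict[str, float]]]
    diagnosis_rate_by_stage: Optional[dict[str, float]] = None
    ckd_incidence: Optional[dict[str, dict[str, float]]] = None
    comorbidity_prevalence: Optional[dict[str, dict[str, float]]] = None
    cv_base_rates: Optional[dict[str, dict[str, dict[str, float]]]] = None
    mortality_base: Optional[dict[str, dict[str, float]]] = None
    kdigo_grid: Optional[KdigoRiskGrid] = None
    slopes: Optional[ProgressionSlopes] = None
    krt: Optional[KrtParameters] = None
    # engine options with conservative defaults
    onset_stage_distribution: dict[str, float] = Field(
        default_factory=lambda: {"G2/A2": 0.5, "G3a/A1": 0.5})
    a_transition: Optional[dict[str, dict[str, float]]] = None
    comorbidity_incidence: dict[str, float] = Field(
        default_factory=lambda: {"t2d": 0.0, "htn": 0.0})
    tx_mortality_multiplier: float = 1.0
    egfr_equation_version: int = 2021
    metadata: dict = Field(default_factory=dict)

    @field_validator("population_by_year")
    @classmethod
    def _years(cls, v):
        missing = [y for y in YEARS if y not in v]
        if missing:
            raise ValueError(f"population_by_year missing years: {missing}")
        for y, p in v.items():
            if p <= 0:
                raise ValueError(f"population in {y} must be strictly positive")
        return v

    @model_validator(mode="after")
    def _distributions(self):
        total = 0.0
        for sex, row in self.pyramid.items():
            if sex not in SEXES:
                raise ValueError(f"pyramid: unknown sex {sex!r}")
            for band, p in row.items():
                if band not in AGE_BANDS:
                    raise ValueError(f"pyramid: unknown age band {band!r}")
                total += _check_prob(f"pyramid[{sex}][{band}]", p)
        if abs(total - 1.0) > PROB_TOL:
            raise ValueError(f"pyramid proportions must sum to 1, got {total}")

        for band, by_sex in self.stage_distribution.items():
            if band not in AGE_BANDS:
                raise ValueError(f"stage_distribution: unknown band {band!r}")
            for sex, cells in by_sex.items():
                if sex not in SEXES:
                    raise ValueError(f"stage_distribution: unknown sex {sex!r}")
                row_sum = 0.0
                for cell, p in cells.items():
                    if cell not in STAGE_CELLS:
                        raise ValueError(f"unknown stage cell {cell!r}")
                    row_sum += _check_prob(
                        f"stage_distribution[{band}][{sex}][{cell}]", p)
                if abs(row_sum - 1.0) > PROB_TOL:
                    raise ValueError(
                        f"stage_distribution[{band}][{sex}] sums to {row_sum}, "
                        "expected 1")

        if self.diagnosis_rate_by_stage is not None:
            for g, p in self.diagnosis_rate_by_stage.items():
                if g not in G_STAGES:
                    raise ValueError(f"diagnosis rate for unknown stage {g!r}")
                _check_prob(f"diagnosis_rate_by_stage[{g}]", p)

        if self.comorbidity_prevalence is not None:
            for status, row in self.comorbidity_prevalence.items():
                if status not in ("ckd", "no_ckd"):
                    raise ValueError(f"unknown CKD status {status!r}")
                s = sum(_check_prob(f"comorbidity_prevalence[{status}][{k}]", p)
                        for k, p in row.items())
                if s > 1.0 + PROB_TOL:
                    raise ValueError(
                        f"comorbidity_prevalence[{status}] exceeds 1")

        for name in ("ckd_incidence", "mortality_base"):
            table = getattr(self, name)
            if table is not None:
                for band, by_sex in table.items():
                    for sex, p in by_sex.items():
                        _check_prob(f"{name}[{band}][{sex}]", p)

        if self.cv_base_rates is not None:
            for outcome, by_band in self.cv_base_rates.items():
                if outcome not in ("heart_failure", "MI", "stroke"):
                    raise ValueError(f"unknown CV outcome {outcome!r}")
                for band, by_sex in by_band.items():
                    for sex, p in by_sex.items():
                        _check_prob(f"cv_base_rates[{outcome}][{band}][{sex}]", p)

        onset_sum = sum(self.onset_stage_distribution.values())
        if abs(onset_sum - 1.0) > PROB_TOL:
            raise ValueError("onset_stage_distribution must sum to 1")
        for cell in self.onset_stage_distribution:
            if cell not in STAGE_CELLS or cell == "none":
                raise ValueError(f"invalid onset stage cell {cell!r}")

        if self.a_transition is not None:
            for a, row in self.a_transition.items():
                if a not in A_STAGES:
                    raise ValueError(f"unknown A stage {a!r}")
                if abs(sum(row.values()) - 1.0) > PROB_TOL:
                    raise ValueError(f"a_transition[{a}] must sum to 1")
        return self

    def require_complete(self):
        """Raise if any engine-required optional field is still missing."""
        missing = [f for f in PROXYABLE_FIELDS if getattr(self, f) is None]
        if missing:
            raise ValueError(
                f"bundle {self.country_code!r} incomplete; missing: {missing}. "
                "Fill the fields or use resolve_proxy().")
        return self


# -- serialisation ------------------------------------------------------------

def save_country_bundle(bundle: CountryInputBundle, path) -> None:
    """Write a bundle as a single YAML document."""
    payload = bundle.model_dump(mode="json")
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)


def load_country_bundle(path) -> CountryInputBundle:
    """Load and fully validate a YAML country bundle."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ValueError(f"{path} does not contain a mapping document")
    # YAML round-trips the year keys and historical datapoints as plain types
    if "population_by_year" in payload and payload["population_by_year"]:
        payload["population_by_year"] = {
            int(k): v for k, v in payload["population_by_year"].items()}
    return CountryInputBundle.model_validate(payload)


def resolve_proxy(bundle: CountryInputBundle, field: str,
                  donor_bundles: list[CountryInputBundle],
                  priority: list[str]) -> CountryInputBundle:
    """Fill a missing field from the first donor country that has it.

    The donor search follows ``priority`` (a list of country codes); the
    substitution is recorded under ``metadata["proxy_sources"]`` so the
    provenance of every proxied input stays visible in the saved bundle.
    A field already present is never overwritten.
    """
    if field not in PROXYABLE_FIELDS:
        raise ValueError(f"field {field!r} is not proxyable "
                         f"(expected one of {PROXYABLE_FIELDS})")
    if getattr(bundle, field) is not None:
        raise ValueError(f"field {field!r} is already present in bundle "
                         f"{bundle.country_code!r}; refusing to overwrite")
    if not priority:
        raise ValueError("priority list must be non-empty")
    by_code = {b.country_code: b for b in donor_bundles}
    tried = []
    for code in priority:
        donor = by_code.get(code)
        tried.append(code)
        if donor is None or getattr(donor, field) is None:
            continue
        value = getattr(donor, field)
        update = {field: value.model_copy(deep=True)
                  if isinstance(value, BaseModel) else value}
        new = bundle.model_copy(update=update, deep=True)
        provenance = dict(new.metadata.get("proxy_sources", {}))
        provenance[field] = code
        new.metadata = {**new.metadata, "proxy_sources": provenance}
        return new
    raise LookupError(
        f"no donor provides {field!r}; tried in order: {tried}")


# -- printed-table fixtures ---------------------------------------------------

N_COUNTRIES = 31


class PublishedTables:
    """The packaged transcriptions of the published country summary tables.

    Attributes
    ----------
    demographics : DataFrame
        National population 2022/2027, sex split and reporting age bands.
    baseline_ckd : DataFrame
        Baseline (2022) per-stage CKD prevalence %, diagnosed %, comorbidity %.
    prevalence : DataFrame
        Diagnosed/undiagnosed CKD prevalence per 100,000, by G stage and year.
    cv_complications : DataFrame
        Projected 2027 cardiovascular complication prevalence per 100,000
        patients with CKD.
    """

    def __init__(self, demographics, baseline_ckd, prevalence, cv_complications):
        self.demographics = demographics
        self.baseline_ckd = baseline_ckd
        self.prevalence = prevalence
        self.cv_complications = cv_complications

    @property
    def countries(self) -> list[str]:
        return list(self.demographics["country"])


def fixture_dir() -> Path:
    """Directory holding the packaged fixture CSVs."""
    return Path(importlib.resources.files("ckdsim") / "fixtures")


def load_published_tables(directory=None) -> PublishedTables:
    """Load the fixture CSVs (defaults to the packaged copies).

    Every table must contain exactly 31 country/region rows (the UAE enters
    through its Emirati rows only); a mismatch raises.
    """
    directory = Path(directory) if directory is not None else fixture_dir()
    read = lambda name: pd.read_csv(directory / name, comment="#")
    demographics = read("demographics.csv")
    baseline = read("baseline_ckd.csv")
    prevalence = read("prevalence_per_100k.csv")
    cv = read("cv_complications_per_100k.csv")

    for name, frame, expected in (
        ("demographics", demographics, N_COUNTRIES),
        ("baseline_ckd", baseline, N_COUNTRIES),
        ("prevalence_per_100k", prevalence, N_COUNTRIES * 4),
        ("cv_complications_per_100k", cv, N_COUNTRIES),
    ):
        if len(frame) != expected:
            raise ValueError(
                f"{name}: expected {expected} rows, found {len(frame)}")
    return PublishedTables(demographics, baseline, prevalence, cv)
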