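"""Virtual subjects: renal staging, body size, and population sampling.

Renal function is staged on the glomerular filtration rate normalized to
1.73 m2 of body surface area (mL/min/1.73 m2), using the conventional
chronic-kidney-disease bands: healthy >= 90, mild impairment [60, 90),
moderate [30, 60), severe [15, 30), end-stage renal disease (ESRD) [0, 15).
A subject carries both the normalized GFR and the absolute GFR
(``gfr_abs = gfr_norm * bsa / 1.73``), because glomerular filtration of a
drug scales with the absolute filtration rate while staging is done on the
normalized one.

The unbound plasma fraction ``fup`` is what links renal physiology to drug
clearance: only unbound daptomycin is filtered at the glomerulus. fup rises
slightly with declining renal function (hypoalbuminemia and competition by
uremic solutes): 8% in healthy subjects, 9% in mild impairment, 10% from
moderate impairment to ESRD. In the elderly renal-impairment cohort the
healthy-status fup is 9% (serum albumin is lower in older adults).

Pediatric renal maturation is represented by a sigmoid (Hill) function of
postmenstrual age; normalized GFR is essentially adult by age 2. The curve
parameters are exposed as keyword arguments so an alternative maturation
model can be substituted without touching callers.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import DomainError, UnsupportedPopulationError

__all__ = [
    "RenalFunctionCategory",
    "Population",
    "Sex",
    "Subject",
    "PopulationSample",
    "REPRESENTATIVE_GFR_NORM",
    "FUP_BY_CATEGORY",
    "classify_gfr",
    "fup_for",
    "healthy_gfr_norm",
    "derive_height_from_bmi",
    "body_surface_area",
    "make_subject",
    "sample_virtual_population",
]


class RenalFunctionCategory(enum.Enum):
    """Renal-function stage on normalized GFR (mL/min/1.73 m2)."""

    HEALTHY = "healthy"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"
    ESRD = "esrd"

    @property
    def gfr_band(self) -> tuple[float, float]:
        """Half-open band [lo, hi) of normalized GFR for this stage."""
        return _GFR_BANDS[self]

    @property
    def gfr_band_lo(self) -> float:
        return _GFR_BANDS[self][0]

    @property
    def gfr_band_hi(self) -> float:
        return _GFR_BANDS[self][1]

    @property
    def representative_gfr_norm(self) -> float:
        """Default representative normalized GFR (band midpoint; 120 for healthy)."""
        return REPRESENTATIVE_GFR_NORM[self]


_C = RenalFunctionCategory

#: Band edges, healthy at the top; bands partition [0, inf) with no gaps.
_GFR_BANDS: dict[RenalFunctionCategory, tuple[float, float]] = {
    _C.HEALTHY: (90.0, math.inf),
    _C.MILD: (60.0, 90.0),
    _C.MODERATE: (30.0, 60.0),
    _C.SEVERE: (15.0, 30.0),
    _C.ESRD: (0.0, 15.0),
}

#: Category order from best to worst renal function.
CATEGORY_ORDER: tuple[RenalFunctionCategory, ...] = (
    _C.HEALTHY,
    _C.MILD,
    _C.MODERATE,
    _C.SEVERE,
    _C.ESRD,
)

#: Representative normalized GFR per stage: band midpoints for the impaired
#: stages, 120 mL/min/1.73 m2 for healthy adults. Exposed as module config;
#: ``make_subject`` also accepts a per-call override.
REPRESENTATIVE_GFR_NORM: dict[RenalFunctionCategory, float] = {
    _C.HEALTHY: 120.0,
    _C.MILD: 75.0,
    _C.MODERATE: 45.0,
    _C.SEVERE: 22.5,
    _C.ESRD: 7.5,
}

#: Unbound plasma fraction per renal stage (fraction, not percent).
FUP_BY_CATEGORY: dict[RenalFunctionCategory, float] = {
    _C.HEALTHY: 0.08,
    _C.MILD: 0.09,
    _C.MODERATE: 0.10,
    _C.SEVERE: 0.10,
    _C.ESRD: 0.10,
}

#: fup of the healthy elderly (renal-impairment study) cohort.
FUP_ELDERLY_HEALTHY = 0.09


class Population(enum.Enum):
    ADULT = "adult"
    CHILD = "child"
    ELDERLY_RI_COHORT = "elderly_ri_cohort"


class Sex(enum.Enum):
    M = "M"
    F = "F"


def classify_gfr(gfr_norm: float) -> RenalFunctionCategory:
    """Return the renal stage whose band contains ``gfr_norm``."""
    if gfr_norm < 0 or not math.isfinite(gfr_norm):
        raise DomainError(f"normalized GFR must be finite and >= 0, got {gfr_norm}")
    for cat, (lo, hi) in _GFR_BANDS.items():
        if lo <= gfr_norm < hi:
            return cat
    raise AssertionError("unreachable: bands partition [0, inf)")


def fup_for(category: RenalFunctionCategory, population: Population = Population.ADULT) -> float:
    """Unbound plasma fraction for a renal stage.

    The elderly renal-impairment cohort uses 0.09 rather than 0.08 in the
    healthy state; all other stage assignments are population-independent.
    """
    if population is Population.ELDERLY_RI_COHORT and category is _C.HEALTHY:
        return FUP_ELDERLY_HEALTHY
    return FUP_BY_CATEGORY[category]


def healthy_gfr_norm(
    age_years: float,
    *,
    adult_gfr_norm: float = REPRESENTATIVE_GFR_NORM[_C.HEALTHY],
    tm50_pma_weeks: float = 47.7,
    hill: float = 3.4,
) -> float:
    """Age-appropriate normalized GFR for healthy subjects.

    Sigmoid maturation on postmenstrual age (term birth taken as 40 weeks;
    one year ~ 52.14 weeks): half of adult function is reached at
    ``tm50_pma_weeks`` with Hill coefficient ``hill``. By age 1 the curve
    gives ~90% of the adult value, by age 2 ~98%; for adults it is
    indistinguishable from ``adult_gfr_norm``.
    """
    if age_years < 0:
        raise DomainError("age must be >= 0")
    pma_weeks = 40.0 + age_years * 52.1429
    frac = pma_weeks**hill / (pma_weeks**hill + tm50_pma_weeks**hill)
    return adult_gfr_norm * frac


def derive_height_from_bmi(weight_kg: float, bmi: float) -> float:
    """Height (m) from weight and BMI: ``sqrt(weight / bmi)``.

    The study tables print weight and BMI but not height, which is needed
    for the body-surface-area step.
    """
    if weight_kg <= 0 or bmi <= 0:
        raise DomainError("weight and BMI must be positive")
    return math.sqrt(weight_kg / bmi)


def body_surface_area(weight_kg: float, height_m: float, formula: str = "dubois") -> float:
    """Body surface area (m2).

    ``dubois`` (default): 0.007184 * W^0.425 * (100 H)^0.725.
    ``haycock``: 0.024265 * W^0.5378 * (100 H)^0.3964.
    """
    if weight_kg <= 0 or height_m <= 0:
        raise DomainError("weight and height must be positive")
    height_cm = 100.0 * height_m
    if formula == "dubois":
        return 0.007184 * weight_kg**0.425 * height_cm**0.725
    if formula == "haycock":
        return 0.024265 * weight_kg**0.5378 * height_cm**0.3964
    raise DomainError(f"unknown BSA formula: {formula!r}")


@dataclass(frozen=True)
class Subject:
    """One virtual individual.

    ``gfr_norm`` is in mL/min/1.73 m2 and must lie within the band of
    ``category``; ``gfr_abs`` (mL/min) equals ``gfr_norm * bsa_m2 / 1.73``
    by construction. ``fup`` is the unbound plasma fraction in (0, 1].
    """

    age_years: float
    weight_kg: float
    height_m: float
    bsa_m2: float
    gfr_norm: float
    gfr_abs: float
    fup: float
    category: RenalFunctionCategory
    population: Population = Population.ADULT
    sex: Sex = Sex.M

    def __post_init__(self) -> None:
        if self.weight_kg <= 0 or self.height_m <= 0 or self.bsa_m2 <= 0:
            raise DomainError("weight, height and BSA must be positive")
        if not 0 < self.fup <= 1:
            raise DomainError(f"fup must be in (0, 1], got {self.fup}")
        if self.gfr_abs < 0:
            raise DomainError("absolute GFR must be >= 0")
        lo, hi = self.category.gfr_band
        if not lo <= self.gfr_norm < hi:
            raise DomainError(
                f"gfr_norm {self.gfr_norm} outside {self.category.value} band [{lo}, {hi})"
            )
        expected_abs = self.gfr_norm * self.bsa_m2 / 1.73
        if abs(self.gfr_abs - expected_abs) > 1e-9 * max(1.0, expected_abs):
            raise DomainError("gfr_abs must equal gfr_norm * bsa / 1.73")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "age_years", "weight_kg", "height_m", "bsa_m2",
            "gfr_norm", "gfr_abs", "fup",
        )}
        d["category"] = self.category.value
        d["population"] = self.population.value
        d["sex"] = self.sex.value
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def make_subject(
    age_years: float,
    weight_kg: float,
    bmi: float,
    category: RenalFunctionCategory,
    population: Population = Population.ADULT,
    *,
    sex: Sex = Sex.M,
    representative_gfr: dict[RenalFunctionCategory, float] | None = None,
    bsa_formula: str = "dubois",
) -> Subject:
    """Construct a subject with derived height, BSA, GFR and fup.

    Healthy subjects get the age-appropriate normalized GFR from the
    maturation curve (equal to the adult representative value for adults);
    impaired subjects get the representative value of their stage.
    Children younger than one year are not supported (the drug's label
    excludes them), raising :class:`UnsupportedPopulationError`.
    """
    if age_years < 1:
        raise UnsupportedPopulationError(
            "subjects younger than 1 year are outside the supported population"
        )
    rep = dict(REPRESENTATIVE_GFR_NORM)
    if representative_gfr:
        rep.update(representative_gfr)
    height = derive_height_from_bmi(weight_kg, bmi)
    bsa = body_surface_area(weight_kg, height, formula=bsa_formula)
    gfr_norm = _healthy_or_representative_gfr(age_years, category, population, rep)
    lo, hi = category.gfr_band
    if not lo <= gfr_norm < hi:
        raise DomainError(
            f"representative GFR {gfr_norm} outside {category.value} band [{lo}, {hi})"
        )
    return Subject(
        age_years=age_years,
        weight_kg=weight_kg,
        height_m=height,
        bsa_m2=bsa,
        gfr_norm=gfr_norm,
        gfr_abs=gfr_norm * bsa / 1.73,
        fup=fup_for(category, population),
        category=category,
        population=population,
        sex=sex,
    )


def _healthy_or_representative_gfr(
    age_years: float,
    category: RenalFunctionCategory,
    population: Population,
    rep: dict[RenalFunctionCategory, float],
) -> float:
    """Healthy children follow the maturation curve; everyone else uses the stage value."""
    if category is _C.HEALTHY and population is Population.CHILD:
        return healthy_gfr_norm(age_years, adult_gfr_norm=rep[_C.HEALTHY])
    return rep[category]


def with_category(
    subject: Subject,
    category: RenalFunctionCategory,
    *,
    representative_gfr: dict[RenalFunctionCategory, float] | None = None,
) -> Subject:
    """Same individual re-staged to another renal category (GFR and fup move)."""
    rep = dict(REPRESENTATIVE_GFR_NORM)
    if representative_gfr:
        rep.update(representative_gfr)
    gfr_norm = _healthy_or_representative_gfr(
        subject.age_years, category, subject.population, rep
    )
    return replace(
        subject,
        category=category,
        gfr_norm=gfr_norm,
        gfr_abs=gfr_norm * subject.bsa_m2 / 1.73,
        fup=fup_for(category, subject.population),
    )


@dataclass(frozen=True)
class PopulationSample:
    """Monte-Carlo sample of inter-individual variability around a base subject.

    Subjects share the base covariates; between-subject variability enters
    through multiplicative log-normal factors on clearance and volume
    (median 1 by construction). Regenerating with the same seed reproduces
    the sample bit for bit.
    """

    base_subject: Subject
    n: int
    cl_multipliers: np.ndarray
    v_multipliers: np.ndarray
    seed: int | None = None
    cv_cl: float = 0.0
    cv_v: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError("population size must be >= 1")
        for name in ("cl_multipliers", "v_multipliers"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (self.n,):
                raise DomainError(f"{name} must have length n={self.n}")
            if not np.all(arr > 0):
                raise DomainError(f"{name} must be strictly positive")

    @property
    def subjects(self) -> list[Subject]:
        """The n subjects (shared covariates; variability is in the multipliers)."""
        return [self.base_subject] * self.n

    def to_frame(self) -> pd.DataFrame:
        base = self.base_subject.to_dict()
        df = pd.DataFrame({
            "subject_id": np.arange(self.n),
            "cl_multiplier": self.cl_multipliers,
            "v_multiplier": self.v_multipliers,
        })
        for key, val in base.items():
            df[key] = val
        return df


def _lognormal_sigma(cv: float) -> float:
    # CV of a log-normal with log-scale sigma: sqrt(exp(sigma^2) - 1)
    return math.sqrt(math.log1p(cv * cv))


def sample_virtual_population(
    base_subject: Subject,
    n: int,
    cv_cl: float = 0.25,
    cv_v: float = 0.15,
    seed: int | None = None,
) -> PopulationSample:
    """Draw n log-normal clearance/volume multipliers (median 1) around a subject."""
    if n < 1:
        raise DomainError("n must be >= 1")
    if cv_cl < 0 or cv_v < 0:
        raise DomainError("coefficients of variation must be >= 0")
    rng = np.random.default_rng(seed)
    cl_mult = rng.lognormal(mean=0.0, sigma=_lognormal_sigma(cv_cl), size=n)
    v_mult = rng.lognormal(mean=0.0, sigma=_lognormal_sigma(cv_v), size=n)
    return PopulationSample(
        base_subject=base_subject,
        n=n,
        cl_multipliers=cl_mult,
        v_multipliers=v_mult,
        seed=seed,
        cv_cl=cv_cl,
        cv_v=cv_v,
    )
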