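"""Daptomycin parameters and the clearance decomposition.

Total clearance is split into a renal and a non-renal route::

    CL_renal = CL_filt + CL_sec - CL_reabs          (renal decomposition)
    CL_total = CL_renal + CL_hepatic                (route sum)
    CL_total = fup * GFR + CL_H                     (filtration-only renal term)

Daptomycin's renal elimination is treated as pure glomerular filtration of
the unbound drug (no evidence for tubular secretion or reabsorption), so
``CL_sec`` and ``CL_reabs`` are structurally present but fixed at zero. The
non-renal route is treated as constant biliary excretion booked as hepatic
clearance; it is obtained once, by subtracting the renal clearance from a
reference total clearance in the healthy calibration subject, and is then
frozen: renal impairment changes only the fup * GFR term.

Scaling to children keeps the renal term mechanistic (child fup x child
absolute GFR) and scales the hepatic term by the adult hepatic-to-renal
clearance ratio applied to the child's healthy renal clearance, after which
it is again frozen across renal-impairment stages.

Units: GFR in mL/min, clearances in L/h (1 mL/min = 0.06 L/h).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources

from .exceptions import CalibrationError, DomainError, PopulationMismatchError, UnsupportedPopulationError
from .physiology import (
    Population,
    RenalFunctionCategory,
    Subject,
    fup_for,
    healthy_gfr_norm,
)

__all__ = [
    "DrugParameters",
    "ClearanceModel",
    "ML_PER_MIN_TO_L_PER_H",
    "renal_filtration_clearance",
    "cl_from_dose_auc",
    "calibrate_hepatic_clearance",
    "build_clearance_model",
    "apply_renal_impairment",
    "scale_to_pediatric",
]

ML_PER_MIN_TO_L_PER_H = 0.06


@dataclass(frozen=True)
class DrugParameters:
    """Physicochemical and disposition constants for daptomycin.

    ``vss_per_kg`` (0.1 L/kg) and the protein binding data drive the reduced
    disposition model; molecular weight, logP, solubility, pKa and the
    blood-to-plasma ratio are carried as validated metadata (they document
    the compound but do not enter the reduced model equations).
    """

    molecular_weight: float = 1620.7       # g/mol
    log_p: float = 1.2                     # optimized oil-water partition
    solubility_mg_ml: float = 17.89
    pka_acid: float = 2.98
    pka_base: float = 9.59
    blood_to_plasma_ratio: float = 0.2     # optimized
    vss_per_kg: float = 0.1                # L/kg, steady-state volume
    binding_protein: str = "human serum albumin"

    def __post_init__(self) -> None:
        if self.vss_per_kg <= 0:
            raise DomainError("vss_per_kg must be positive")

    @classmethod
    def default(cls) -> "DrugParameters":
        """Packaged daptomycin defaults."""
        text = resources.files("daptopk.data").joinpath("daptomycin_parameters.json").read_text()
        return cls.from_json(text)

    @classmethod
    def from_json(cls, text: str) -> "DrugParameters":
        return cls(**json.loads(text))

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


@dataclass(frozen=True)
class ClearanceModel:
    """The renal/hepatic clearance split for one subject, in L/h.

    ``cl_renal = cl_filt + cl_sec - cl_reabs`` and
    ``cl_total = cl_renal + cl_hepatic`` hold exactly by construction.
    """

    cl_filt: float
    cl_hepatic: float
    cl_sec: float = 0.0
    cl_reabs: float = 0.0
    population: Population = Population.ADULT

    def __post_init__(self) -> None:
        for name in ("cl_filt", "cl_hepatic", "cl_sec", "cl_reabs"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.cl_reabs > self.cl_filt + self.cl_sec:
            raise DomainError("reabsorption cannot exceed filtration + secretion")

    @property
    def cl_renal(self) -> float:
        return self.cl_filt + self.cl_sec - self.cl_reabs

    @property
    def cl_total(self) -> float:
        return self.cl_renal + self.cl_hepatic

    def to_dict(self) -> dict:
        return {
            "cl_filt_l_h": self.cl_filt,
            "cl_sec_l_h": self.cl_sec,
            "cl_reabs_l_h": self.cl_reabs,
            "cl_renal_l_h": self.cl_renal,
            "cl_hepatic_l_h": self.cl_hepatic,
            "cl_total_l_h": self.cl_total,
            "population": self.population.value,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def renal_filtration_clearance(subject: Subject) -> float:
    """Renal (filtration-only) clearance in L/h: fup x absolute GFR."""
    return subject.fup * subject.gfr_abs * ML_PER_MIN_TO_L_PER_H


def cl_from_dose_auc(dose_mg: float, auc_ug_h_ml: float) -> float:
    """Total clearance (L/h) implied by a dose and its interval AUC (ug.h/mL)."""
    if dose_mg <= 0 or auc_ug_h_ml <= 0:
        raise DomainError("dose and AUC must be positive")
    return dose_mg / auc_ug_h_ml


def calibrate_hepatic_clearance(cl_total_ref: float, cl_renal: float) -> float:
    """Non-renal (hepatic/biliary) clearance = reference total - renal.

    Raises :class:`CalibrationError` when the reference total clearance is
    below the renal clearance, which would imply a negative non-renal route.
    """
    if cl_total_ref < 0 or cl_renal < 0:
        raise DomainError("clearances must be >= 0")
    if cl_total_ref < cl_renal:
        raise CalibrationError(
            f"reference total clearance {cl_total_ref:.4f} L/h is below the renal "
            f"clearance {cl_renal:.4f} L/h"
        )
    return cl_total_ref - cl_renal


def build_clearance_model(subject: Subject, cl_total_ref: float) -> ClearanceModel:
    """Calibrate a clearance model for a (healthy) subject from a reference CL.

    The renal term comes from the subject's fup x GFR; the hepatic term is
    whatever remains of ``cl_total_ref``.
    """
    cl_renal = renal_filtration_clearance(subject)
    cl_hepatic = calibrate_hepatic_clearance(cl_total_ref, cl_renal)
    return ClearanceModel(
        cl_filt=cl_renal,
        cl_hepatic=cl_hepatic,
        population=subject.population,
    )


def apply_renal_impairment(model: ClearanceModel, subject_impaired: Subject) -> ClearanceModel:
    """Re-derive the renal term for an impaired subject; hepatic stays frozen.

    The model must come from the same population as the impaired subject
    (an adult calibration cannot be recycled for a child directly; use
    :func:`scale_to_pediatric` first).
    """
    if model.population is not subject_impaired.population:
        raise PopulationMismatchError(
            f"clearance model for population {model.population.value!r} cannot be "
            f"applied to a {subject_impaired.population.value!r} subject"
        )
    return replace(model, cl_filt=renal_filtration_clearance(subject_impaired))


def scale_to_pediatric(
    adult_model: ClearanceModel,
    adult_subject: Subject,
    child_subject: Subject,
) -> ClearanceModel:
    """Scale a calibrated healthy-adult clearance model to a child.

    Renal: child fup x child absolute GFR (age-dependent through the GFR
    maturation of the child's covariates). Non-renal: the adult
    hepatic-to-renal clearance ratio applied to the child's *healthy* renal
    clearance; the resulting hepatic clearance is frozen across the child's
    renal-impairment stages.
    """
    if child_subject.age_years < 1:
        raise UnsupportedPopulationError("pediatric scaling supports ages >= 1 year")
    if adult_subject.category is not RenalFunctionCategory.HEALTHY:
        raise CalibrationError("the adult reference model must be calibrated on a healthy subject")
    if adult_model.cl_renal <= 0:
        raise CalibrationError("adult renal clearance must be positive for ratio scaling")
    ratio = adult_model.cl_hepatic / adult_model.cl_renal
    healthy_fup = fup_for(RenalFunctionCategory.HEALTHY, child_subject.population)
    healthy_gfr_abs = (
        healthy_gfr_norm(child_subject.age_years) * child_subject.bsa_m2 / 1.73
    )
    child_healthy_renal = healthy_fup * healthy_gfr_abs * ML_PER_MIN_TO_L_PER_H
    return ClearanceModel(
        cl_filt=renal_filtration_clearance(child_subject),
        cl_hepatic=ratio * child_healthy_renal,
        population=child_subject.population,
    )
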