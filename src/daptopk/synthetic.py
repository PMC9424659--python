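"""Synthetic inputs: noisy virtual trials and stand-in MIC distributions.

Two generators make the pipeline testable end to end without external data:

* :func:`generate_virtual_trial` draws concentration-time observations from
  the simulator under a proportional-plus-additive residual error model
  (the standard PK residual structure), paired with
  :func:`recover_clearance`, a non-compartmental dose/AUC estimator, for
  parameter-recovery studies.
* :func:`generate_mic_distribution` builds synthetic MIC frequency
  distributions on the doubling-dilution grid. They emulate the *shape* of
  surveillance distributions for daptomycin-susceptible populations — mass
  concentrated at MIC <= 0.5 mg/L for the MRSA-like preset, shifted one to
  two dilutions higher for the E. faecium-like preset — but are synthetic
  stand-ins, not surveillance data, so CFR values computed from them are
  qualitative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drug import ClearanceModel, DrugParameters
from .exceptions import DomainError, InsufficientSamplingError
from .physiology import Subject
from .pkpd import DEFAULT_MIC_GRID, MICDistribution
from .pksim import DosingRegimen, predict_concentrations

__all__ = [
    "VirtualTrial",
    "generate_virtual_trial",
    "recover_clearance",
    "generate_mic_distribution",
    "MIC_PRESETS",
]


@dataclass(frozen=True)
class VirtualTrial:
    """Simulated observations around the model prediction for one regimen."""

    subject: Subject
    regimen: DosingRegimen
    sampling_times: np.ndarray
    observed_concentrations: np.ndarray
    predicted_concentrations: np.ndarray
    prop_cv: float
    add_sd: float
    seed: int | None

    def __post_init__(self) -> None:
        for name in ("sampling_times", "observed_concentrations", "predicted_concentrations"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if np.any(self.observed_concentrations < 0):
            raise DomainError("observations must be >= 0")

    def to_frame(self, replicate_id: int = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.sampling_times,
                "conc_mg_L": self.observed_concentrations,
                "replicate_id": replicate_id,
            }
        )


def generate_virtual_trial(
    subject: Subject,
    clearance: ClearanceModel | float,
    regimen: DosingRegimen,
    times: np.ndarray,
    prop_cv: float = 0.15,
    add_sd: float = 0.5,
    seed: int | None = None,
    *,
    drug: DrugParameters | None = None,
    **dispo_kwargs,
) -> VirtualTrial:
    """Noisy observations: prediction * exp(eps_prop) + eps_add, floored at 0.

    ``eps_prop`` is normal on the log scale with a sigma chosen so the
    multiplicative factor has coefficient of variation ``prop_cv`` (median
    1; the mean exceeds the prediction by the half-sigma-squared log-normal
    offset, ~0.5% at cv 0.1). ``eps_add`` is additive normal noise with SD
    ``add_sd`` mg/L. Sampling times must lie within the simulated span.
    """
    if prop_cv < 0 or add_sd < 0:
        raise DomainError("error magnitudes must be >= 0")
    drug = drug or DrugParameters.default()
    times = np.asarray(times, float)
    pred = predict_concentrations(subject, drug, clearance, regimen, times, **dispo_kwargs)
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(prop_cv**2))
    eps_prop = rng.normal(0.0, sigma, size=times.shape) if prop_cv > 0 else np.zeros_like(times)
    eps_add = rng.normal(0.0, add_sd, size=times.shape) if add_sd > 0 else np.zeros_like(times)
    obs = np.maximum(pred * np.exp(eps_prop) + eps_add, 0.0)
    return VirtualTrial(
        subject=subject,
        regimen=regimen,
        sampling_times=times,
        observed_concentrations=obs,
        predicted_concentrations=pred,
        prop_cv=prop_cv,
        add_sd=add_sd,
        seed=seed,
    )


def recover_clearance(trial: VirtualTrial) -> float:
    """Non-compartmental clearance estimate: dose / trapezoid-AUC of the last interval.

    Requires observations covering the final dosing interval (at steady
    state for an unbiased estimate); at least four samples spanning at least
    90% of the interval, starting within its first 5%.
    """
    reg = trial.regimen
    start = (reg.n_doses - 1) * reg.interval_h
    end = reg.n_doses * reg.interval_h
    mask = (trial.sampling_times >= start - 1e-9) & (trial.sampling_times <= end + 1e-9)
    t = trial.sampling_times[mask]
    c = trial.observed_concentrations[mask]
    if len(t) < 4:
        raise InsufficientSamplingError("need at least 4 samples within the last dosing interval")
    if t[0] > start + 0.05 * reg.interval_h or t[-1] < end - 0.10 * reg.interval_h:
        raise InsufficientSamplingError(
            "samples must span the last dosing interval (start within 5%, end within 10%)"
        )
    auc = float(np.trapezoid(c, t))
    if auc <= 0:
        raise InsufficientSamplingError("non-positive AUC; cannot recover clearance")
    return reg.dose_mg(trial.subject.weight_kg) / auc


#: Base frequencies (before seeded jitter) on the default MIC grid.
MIC_PRESETS: dict[str, tuple[float, ...]] = {
    # MRSA-like: >= 90% of isolates at MIC <= 0.5 mg/L.
    "MRSA_LIKE": (0.10, 0.45, 0.38, 0.05, 0.015, 0.004, 0.001),
    # E. faecium-like: modal MIC one-to-two dilutions higher.
    "EFAECIUM_LIKE": (0.02, 0.10, 0.30, 0.40, 0.15, 0.02, 0.01),
}


def generate_mic_distribution(preset: str, seed: int | None = None) -> MICDistribution:
    """Synthetic MIC distribution for a preset pathogen shape.

    With ``seed=None`` the exact base frequencies are returned; a seed adds
    reproducible Dirichlet jitter around them (concentration 400, i.e. a few
    percent relative wobble) while preserving the preset's shape.
    """
    try:
        base = np.asarray(MIC_PRESETS[preset], float)
    except KeyError:
        raise DomainError(f"unknown MIC preset {preset!r}; available: {sorted(MIC_PRESETS)}") from None
    if seed is None:
        freqs = base
    else:
        rng = np.random.default_rng(seed)
        freqs = rng.dirichlet(base * 400.0)
    freqs = freqs / freqs.sum()
    return MICDistribution(DEFAULT_MIC_GRID, tuple(freqs), pathogen=preset)
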