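"""Fold-error model validation against published observed/predicted exposures.

The acceptance rule of the field: a prediction is successful when the fold
error — the larger of observed/predicted and predicted/observed — is below
2. The module computes per-record fold errors, pass flags, and the mean
fold error over a comparison table, and ships the published adult and
pediatric observed/predicted AUC and Cmax pairs as packaged CSV fixtures
(transcribed from the source tables; the adult table mixes multiple-dose
and dose-escalation study arms, the pediatric table single-dose literature
values and label regimens).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import DomainError

__all__ = [
    "FOLD_ERROR_THRESHOLD",
    "Metric",
    "ValidationRecord",
    "ValidationReport",
    "fold_error",
    "validate_table",
    "load_reference_table",
    "validate_reference",
]

#: Conventional acceptance threshold on the fold error.
FOLD_ERROR_THRESHOLD = 2.0


class Metric(enum.Enum):
    AUC = "AUC"
    CMAX = "CMAX"


def fold_error(observed: float, predicted: float) -> float:
    """max(observed, predicted) / min(observed, predicted); always >= 1."""
    if observed <= 0 or predicted <= 0:
        raise DomainError("observed and predicted values must be positive")
    return max(observed, predicted) / min(observed, predicted)


@dataclass(frozen=True)
class ValidationRecord:
    """One observed/predicted comparison with its fold error and pass flag."""

    label: str
    metric: Metric
    observed: float
    predicted: float
    fold_error: float
    passed: bool

    @classmethod
    def evaluate(
        cls,
        observed: float,
        predicted: float,
        label: str = "",
        metric: Metric = Metric.AUC,
        threshold: float = FOLD_ERROR_THRESHOLD,
    ) -> "ValidationRecord":
        fe = fold_error(observed, predicted)
        return cls(
            label=label,
            metric=metric,
            observed=observed,
            predicted=predicted,
            fold_error=fe,
            passed=fe < threshold,
        )


@dataclass(frozen=True)
class ValidationReport:
    """Per-record fold errors (input order preserved) and their arithmetic mean."""

    records: tuple[ValidationRecord, ...]
    mean_fold_error: float
    all_passed: bool
    threshold: float = FOLD_ERROR_THRESHOLD

    def to_frame(self, decimals: int | None = 2) -> pd.DataFrame:
        """Tabular report; fold errors rounded only at rendering time."""
        df = pd.DataFrame(
            {
                "label": [r.label for r in self.records],
                "metric": [r.metric.value for r in self.records],
                "observed": [r.observed for r in self.records],
                "predicted": [r.predicted for r in self.records],
                "fold_error": [r.fold_error for r in self.records],
                "passed": [r.passed for r in self.records],
            }
        )
        if decimals is not None:
            df["fold_error"] = df["fold_error"].round(decimals)
        return df

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean_fold_error": self.mean_fold_error,
                "all_passed": self.all_passed,
                "threshold": self.threshold,
                "records": self.to_frame(decimals=None).to_dict(orient="records"),
            },
            indent=2,
        )


def validate_table(
    records: Iterable[tuple[float, float]] | pd.DataFrame,
    threshold: float = FOLD_ERROR_THRESHOLD,
) -> ValidationReport:
    """Fold-error report over (observed, predicted) pairs.

    Accepts an iterable of pairs or a DataFrame with ``observed`` and
    ``predicted`` columns (``label``/``metric`` carried through if present).
    The mean is the arithmetic mean of the fold errors; empty input is an
    error.
    """
    evaluated: list[ValidationRecord] = []
    if isinstance(records, pd.DataFrame):
        for _, row in records.iterrows():
            evaluated.append(
                ValidationRecord.evaluate(
                    float(row["observed"]),
                    float(row["predicted"]),
                    label=str(row.get("label", "")),
                    metric=Metric(row["metric"]) if "metric" in row else Metric.AUC,
                    threshold=threshold,
                )
            )
    else:
        for pair in records:
            obs, pred = pair
            evaluated.append(ValidationRecord.evaluate(float(obs), float(pred), threshold=threshold))
    if not evaluated:
        raise DomainError("validation requires at least one (observed, predicted) pair")
    mean_fe = sum(r.fold_error for r in evaluated) / len(evaluated)
    return ValidationReport(
        records=tuple(evaluated),
        mean_fold_error=mean_fe,
        all_passed=all(r.passed for r in evaluated),
        threshold=threshold,
    )


_REFERENCE_FILES = {
    "adult": "adult_pk_reference.csv",
    "pediatric": "pediatric_pk_reference.csv",
    "pediatric_ri_exposure": "pediatric_ri_exposure.csv",
    "recommended_doses": "recommended_doses_reference.csv",
}


def load_reference_table(name: str) -> pd.DataFrame:
    """Load a packaged published-values fixture: 'adult', 'pediatric', etc."""
    try:
        fname = _REFERENCE_FILES[name]
    except KeyError:
        raise DomainError(
            f"unknown reference table {name!r}; available: {sorted(_REFERENCE_FILES)}"
        ) from None
    with resources.files("daptopk.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh)


def validate_reference(name: str = "pediatric", threshold: float = FOLD_ERROR_THRESHOLD) -> ValidationReport:
    """Fold-error report over a packaged observed/predicted reference table."""
    return validate_table(load_reference_table(name), threshold=threshold)
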