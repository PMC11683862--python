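"""LFER prediction of log10 phase-water partition coefficients.

Three model families are supported:

* ``1p`` — one-parameter LFER, an affine function of logKow only;
* ``2p`` — two-parameter LFER, lambda1*logKow + lambda2*logKaw + lambda3;
* ``pp`` — poly-parameter (Abraham) LFER over the six solute descriptors.

Batch prediction over a :class:`~lfer2p.tables.ChemicalTable` reports
per-record residuals against observed values plus RMSE/MAE summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .tables import (
    AbrahamSystem,
    ChemicalTable,
    PhaseCoefficients2p,
    get_2p_coefficients,
)

__all__ = [
    "PredictionResult",
    "BatchSummary",
    "predict_1p",
    "predict_2p",
    "predict_pp",
    "batch_predict",
]


@dataclass(frozen=True)
class PredictionResult:
    id: str
    phase: str
    predicted: float
    observed: float | None = None
    model_tag: str = "2p"

    @property
    def residual(self) -> float | None:
        """Observed minus predicted; absent when no observation exists."""
        if self.observed is None:
            return None
        return self.observed - self.predicted


@dataclass(frozen=True)
class BatchSummary:
    n: int
    n_observed: int
    n_skipped: int
    rmse: float | None
    mae: float | None


def _require_finite(**values: float) -> None:
    for label, value in values.items():
        if not (isinstance(value, (int, float)) and math.isfinite(value)):
            raise ValueError(f"{label} must be finite, got {value!r}")


def predict_2p(logKow: float, logKaw: float, coeffs: PhaseCoefficients2p) -> float:
    """Evaluate the 2p-LFER: lambda1*logKow + lambda2*logKaw + lambda3."""
    _require_finite(logKow=logKow, logKaw=logKaw)
    return coeffs.lambda1 * logKow + coeffs.lambda2 * logKaw + coeffs.lambda3


def predict_1p(logKow: float, slope: float, intercept: float) -> float:
    """Evaluate a one-parameter (octanol-only) LFER: slope*logKow + intercept."""
    _require_finite(logKow=logKow, slope=slope, intercept=intercept)
    return slope * logKow + intercept


def predict_pp(descriptors: Mapping[str, float], system: AbrahamSystem) -> float:
    """Evaluate an Abraham-model pp-LFER for one chemical.

    v-form systems need descriptors E, S, A, B, V; l-form systems need
    E, S, A, B, L.  A missing required descriptor raises with its name.
    """
    required = ["E", "S", "A", "B", "V" if system.form == "v" else "L"]
    for key in required:
        if key not in descriptors:
            raise ValueError(f"missing Abraham descriptor {key!r} "
                             f"required by the {system.form}-form system")
        _require_finite(**{key: descriptors[key]})
    total = (system.c
             + system.e * descriptors["E"]
             + system.s * descriptors["S"]
             + system.a * descriptors["A"]
             + system.b * descriptors["B"])
    if system.form == "v":
        total += system.v * descriptors["V"]  # type: ignore[operator]
    else:
        total += system.l * descriptors["L"]  # type: ignore[operator]
    return total


def _predict_record(record, model_tag, coeffs):
    if model_tag == "2p":
        if record.logKow is None or record.logKaw is None:
            return None
        return predict_2p(record.logKow, record.logKaw, coeffs)
    if model_tag == "1p":
        slope, intercept = coeffs
        if record.logKow is None:
            return None
        return predict_1p(record.logKow, slope, intercept)
    if model_tag == "pp":
        required = {"E", "S", "A", "B", "V" if coeffs.form == "v" else "L"}
        if not required.issubset(record.descriptors):
            return None
        return predict_pp(record.descriptors, coeffs)
    raise ValueError(f"unknown model tag {model_tag!r}")


def batch_predict(
    table: ChemicalTable,
    phase: str,
    model_tag: str = "2p",
    coeffs: PhaseCoefficients2p | AbrahamSystem | tuple[float, float] | None = None,
    observed_phase: str | None = None,
    strict: bool = False,
) -> tuple[list[PredictionResult], BatchSummary]:
    """Predict a phase-water log K for every record in a table.

    Records lacking the required inputs are skipped and counted
    (``strict=True`` raises instead).  The summary RMSE/MAE cover only
    records with an observation in ``observed_phase`` (default: ``phase``).
    """
    if coeffs is None:
        if model_tag != "2p":
            raise ValueError("coeffs must be supplied for 1p and pp models")
        coeffs = get_2p_coefficients(phase)
    observed_phase = observed_phase or phase

    results: list[PredictionResult] = []
    n_skipped = 0
    for record in table:
        predicted = _predict_record(record, model_tag, coeffs)
        if predicted is None:
            if strict:
                raise ValueError(f"record {record.id!r} lacks inputs for "
                                 f"the {model_tag} model")
            n_skipped += 1
            continue
        results.append(
            PredictionResult(
                id=record.id, phase=phase, predicted=predicted,
                observed=record.observed.get(observed_phase),
                model_tag=model_tag,
            )
        )
    if not results:
        raise ValueError("no predictable records in table")

    residuals = np.array([r.residual for r in results if r.residual is not None])
    rmse = float(np.sqrt(np.mean(residuals**2))) if residuals.size else None
    mae = float(np.mean(np.abs(residuals))) if residuals.size else None
    summary = BatchSummary(
        n=len(results), n_observed=int(residuals.size),
        n_skipped=n_skipped, rmse=rmse, mae=mae,
    )
    return results, summary
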