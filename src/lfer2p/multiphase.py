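"""Multiphase equilibrium partitioning of chemicals into tissues and milk.

A tissue is modelled as a mixture of five sorptive phases — water, storage
lipid, phospholipid, structural protein and albumin — each occupying a
fraction f_i of the tissue.  At equilibrium the tissue-water partition
coefficient is the fraction-weighted sum of the phase capacities,

    K_tissue-water = f_water * 1 + sum_i f_i * K_i-water,

with water's own capacity fixed at 1.  The per-phase chemical load is
f_i*K_i normalised by that sum, the organ:reference (e.g. organ:plasma)
distribution ratio is the difference of the two tissue log Ks, and milk
is handled as just another composition.

Phase log Ks can come from any LFER flavour; :func:`phase_logk_from_2p`
builds the map from the built-in 2p-LFER coefficient registry.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from .predict import predict_2p
from .tables import get_2p_coefficients

__all__ = [
    "TissueComposition",
    "PhaseLoad",
    "SORPTIVE_PHASES",
    "load_tissue_compositions",
    "builtin_tissue_compositions",
    "tissue_k",
    "distribution_ratio",
    "phase_loads",
    "milk_k",
    "phase_logk_from_2p",
]

#: non-water sorptive phases, keyed as in phase_logK maps
SORPTIVE_PHASES = ("storage_lipid", "phospholipid", "structural_protein", "albumin")


@dataclass(frozen=True)
class TissueComposition:
    """Mass fractions of the five sorptive phases in one tissue.

    Fractions must be non-negative and sum to 1 within a +/-2% band that
    tolerates literature rounding; outside-but-close sums are renormalized
    on construction with a warning.
    """

    tissue: str
    f_water: float
    f_storage_lipid: float = 0.0
    f_phospholipid: float = 0.0
    f_structural_protein: float = 0.0
    f_albumin: float = 0.0

    def __post_init__(self) -> None:
        fractions = self.as_dict()
        for phase, f in fractions.items():
            if f < 0 or not math.isfinite(f):
                raise ValueError(f"{self.tissue}: fraction {phase} = {f} invalid")
        total = sum(fractions.values())
        if not 0.98 <= total <= 1.02:
            raise ValueError(
                f"{self.tissue}: fractions sum to {total:.4f}, outside [0.98, 1.02]"
            )
        if abs(total - 1.0) > 1e-9:
            warnings.warn(
                f"{self.tissue}: fractions sum to {total:.4f}; renormalizing"
            )
            for name, f in fractions.items():
                object.__setattr__(self, f"f_{name}" if name != "water" else "f_water",
                                   f / total)

    def as_dict(self) -> dict[str, float]:
        return {
            "water": self.f_water,
            "storage_lipid": self.f_storage_lipid,
            "phospholipid": self.f_phospholipid,
            "structural_protein": self.f_structural_protein,
            "albumin": self.f_albumin,
        }


@dataclass(frozen=True)
class PhaseLoad:
    """Fraction of the total chemical amount residing in each phase."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        assert abs(total - 1.0) < 1e-9, "phase loads must sum to 1"

    def __getitem__(self, phase: str) -> float:
        return self.fractions[phase]


def load_tissue_compositions(path: str | Path) -> dict[str, TissueComposition]:
    """Load a tissue-composition JSON file (tissue -> fraction map)."""
    payload = json.loads(Path(path).read_text())
    tissues = payload.get("tissues", payload)
    out = {}
    for name, fractions in tissues.items():
        if name.startswith("_"):
            continue
        out[name] = TissueComposition(tissue=name, **fractions)
    return out


def builtin_tissue_compositions() -> dict[str, TissueComposition]:
    """Representative mammalian tissue compositions shipped with the package.

    These are synthetic stand-in values assembled from typical
    physiological compositions (see the data file header); replace them
    with source-specific tables for study reproduction.
    """
    with resources.as_file(
        resources.files("lfer2p.data").joinpath("synthetic_tissue_compositions.json")
    ) as path:
        return load_tissue_compositions(path)


def _phase_capacities(
    composition: TissueComposition, phase_logK: Mapping[str, float]
) -> dict[str, float]:
    capacities = {"water": composition.f_water * 1.0}
    for phase in SORPTIVE_PHASES:
        f = composition.as_dict()[phase]
        if f > 0:
            if phase not in phase_logK:
                raise ValueError(
                    f"{composition.tissue}: no log K supplied for phase "
                    f"{phase!r} with fraction {f}"
                )
            capacities[phase] = f * 10.0 ** phase_logK[phase]
    return capacities


def tissue_k(
    composition: TissueComposition, phase_logK: Mapping[str, float]
) -> float:
    """log10 tissue-water partition coefficient of a mixed tissue.

    ``phase_logK`` maps each non-water phase with positive fraction to its
    log10 phase-water partition coefficient.
    """
    return math.log10(sum(_phase_capacities(composition, phase_logK).values()))


def distribution_ratio(
    organ: TissueComposition,
    reference: TissueComposition,
    phase_logK: Mapping[str, float],
) -> float:
    """log10 organ:reference (typically organ:plasma) distribution ratio."""
    return tissue_k(organ, phase_logK) - tissue_k(reference, phase_logK)


def phase_loads(
    composition: TissueComposition, phase_logK: Mapping[str, float]
) -> PhaseLoad:
    """Relative distribution of the chemical amount across the phases."""
    capacities = _phase_capacities(composition, phase_logK)
    total = sum(capacities.values())
    return PhaseLoad(fractions={p: c / total for p, c in capacities.items()})


def milk_k(
    milk_composition: TissueComposition, phase_logK: Mapping[str, float]
) -> float:
    """log10 milk-water partition coefficient (milk as a phase mixture)."""
    return tissue_k(milk_composition, phase_logK)


def phase_logk_from_2p(
    logKow: float,
    logKaw: float,
    protein_phase: str = "combined_structural_protein",
) -> dict[str, float]:
    """Build the phase log K map for one chemical from 2p-LFER predictions.

    Uses the registry coefficient sets for storage lipid, phospholipid,
    structural protein (``protein_phase``) and albumin (BSA surrogate).
    """
    return {
        "storage_lipid": predict_2p(logKow, logKaw, get_2p_coefficients("storage_lipid")),
        "phospholipid": predict_2p(logKow, logKaw, get_2p_coefficients("phospholipid")),
        "structural_protein": predict_2p(logKow, logKaw, get_2p_coefficients(protein_phase)),
        "albumin": predict_2p(logKow, logKaw, get_2p_coefficients("bsa")),
    }
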