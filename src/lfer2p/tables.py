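"""Chemical property tables and partition-system coefficient registries.

The central container is :class:`ChemicalTable`, an ordered collection of
:class:`ChemicalRecord` objects.  Each record carries the two macroscopic
descriptors used by the two-parameter linear free energy relationship
(2p-LFER) — the log10 octanol-water partition coefficient (``logKow``) and
the log10 air-water partition coefficient (``logKaw``) — plus the optional
six Abraham solute descriptors (E, S, A, B, V, L) and any number of observed
log10 phase-water partition coefficients.

Coefficient sets for 2p-LFER phase-water systems (lambda1 on logKow,
lambda2 on logKaw, intercept lambda3) ship in a built-in JSON registry;
users may register their own sets or overlay a JSON/YAML-exported file.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "ChemicalRecord",
    "ChemicalTable",
    "PhaseCoefficients2p",
    "AbrahamSystem",
    "CoefficientRegistry",
    "get_2p_coefficients",
    "register_2p_coefficients",
    "registered_phases",
    "read_chemical_table",
    "write_chemical_table",
    "average_protein_datasets",
    "TableFormatError",
]

DESCRIPTOR_NAMES = ("E", "S", "A", "B", "V", "L")

#: canonical column -> accepted lowercase spellings in CSV headers
_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "id": ("id", "chemical_id", "cas", "cas_rn"),
    "name": ("name", "chemical", "chemical_name", "compound"),
    "logKow": ("logkow", "log_kow", "log kow", "logp", "log_p"),
    "logKaw": ("logkaw", "log_kaw", "log kaw", "logkh", "log_kaw_exp"),
}


class TableFormatError(ValueError):
    """Raised for malformed chemical tables (missing id, duplicates, bad cells)."""


@dataclass
class ChemicalRecord:
    """One chemical: identifiers, descriptors and observed partition data.

    ``observed`` maps a phase name (e.g. ``"structural_protein"``) to the
    observed log10 phase-water partition coefficient.  ``provenance``
    optionally records, per field, whether a value is experimental or
    estimated.
    """

    id: str
    name: str = ""
    logKow: float | None = None
    logKaw: float | None = None
    descriptors: dict[str, float] = field(default_factory=dict)
    observed: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise TableFormatError("chemical id must be non-empty")
        for label, value in (("logKow", self.logKow), ("logKaw", self.logKaw)):
            if value is not None and not math.isfinite(value):
                raise TableFormatError(f"{label} for {self.id!r} is not finite")
        for key, value in self.descriptors.items():
            if not math.isfinite(value):
                raise TableFormatError(
                    f"descriptor {key} for {self.id!r} is not finite"
                )
        for phase, value in self.observed.items():
            if not math.isfinite(value):
                raise TableFormatError(
                    f"observed log K ({phase}) for {self.id!r} is not finite"
                )


class ChemicalTable:
    """Ordered, id-unique collection of :class:`ChemicalRecord`."""

    def __init__(self, records: Iterable[ChemicalRecord] = ()) -> None:
        self._records: list[ChemicalRecord] = []
        self._index: dict[str, int] = {}
        for record in records:
            self.append(record)

    def append(self, record: ChemicalRecord) -> None:
        if record.id in self._index:
            raise TableFormatError(f"duplicate chemical id: {record.id!r}")
        self._index[record.id] = len(self._records)
        self._records.append(record)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ChemicalRecord]:
        return iter(self._records)

    def __getitem__(self, chem_id: str) -> ChemicalRecord:
        return self._records[self._index[chem_id]]

    def __contains__(self, chem_id: str) -> bool:
        return chem_id in self._index

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self._records]

    @property
    def phase_columns(self) -> set[str]:
        cols: set[str] = set()
        for record in self._records:
            cols.update(record.observed)
        return cols

    def subset(self, ids: Iterable[str]) -> "ChemicalTable":
        return ChemicalTable(self[i] for i in ids)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a DataFrame with observed columns named ``logK_<phase>``."""
        rows = []
        for r in self._records:
            row: dict[str, object] = {"id": r.id, "name": r.name,
                                      "logKow": r.logKow, "logKaw": r.logKaw}
            for d in DESCRIPTOR_NAMES:
                if d in r.descriptors:
                    row[d] = r.descriptors[d]
            for phase, value in r.observed.items():
                row[f"logK_{phase}"] = value
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ChemicalTable":
        return _table_from_frame(frame)


def _canonical_column(raw: str) -> str:
    """Map a raw CSV header (case-insensitive) onto the canonical column name."""
    stripped = raw.strip()
    low = stripped.lower()
    for canonical, aliases in _COLUMN_ALIASES.items():
        if low in aliases:
            return canonical
    if stripped.upper() in DESCRIPTOR_NAMES and len(stripped) == 1:
        return stripped.upper()
    if low.startswith("logk_"):
        return "logK_" + stripped[5:]
    return stripped


def _parse_cell(value: object, row: int, column: str) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    try:
        parsed = float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise TableFormatError(
            f"non-numeric value {value!r} in column {column!r}, row {row}"
        ) from None
    if not math.isfinite(parsed):
        raise TableFormatError(
            f"non-finite value {value!r} in column {column!r}, row {row}"
        )
    return parsed


def _table_from_frame(frame: pd.DataFrame) -> ChemicalTable:
    frame = frame.rename(columns={c: _canonical_column(str(c)) for c in frame.columns})
    if "id" not in frame.columns:
        raise TableFormatError("table has no id column")
    ids = frame["id"].astype(str)
    duplicates = sorted(ids[ids.duplicated()].unique())
    if duplicates:
        raise TableFormatError(f"duplicate chemical ids: {', '.join(duplicates)}")

    records = []
    for row_number, (_, row) in enumerate(frame.iterrows(), start=1):
        descriptors = {}
        for d in DESCRIPTOR_NAMES:
            if d in frame.columns:
                value = _parse_cell(row[d], row_number, d)
                if value is not None:
                    descriptors[d] = value
        observed = {}
        for column in frame.columns:
            if column.startswith("logK_"):
                value = _parse_cell(row[column], row_number, column)
                if value is not None:
                    observed[column[5:]] = value
        records.append(
            ChemicalRecord(
                id=str(row["id"]),
                name=str(row["name"]) if "name" in frame.columns and not pd.isna(row["name"]) else "",
                logKow=_parse_cell(row.get("logKow"), row_number, "logKow") if "logKow" in frame.columns else None,
                logKaw=_parse_cell(row.get("logKaw"), row_number, "logKaw") if "logKaw" in frame.columns else None,
                descriptors=descriptors,
                observed=observed,
            )
        )
    return ChemicalTable(records)


def read_chemical_table(path: str | Path) -> ChemicalTable:
    """Read a UTF-8 comma-separated chemical table.

    The header row is required; column names are matched case-insensitively
    against the documented alias map; empty cells denote missing values.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame = frame.replace("", None)
    return _table_from_frame(frame)


def write_chemical_table(table: ChemicalTable, path: str | Path) -> None:
    """Write a table back to CSV (empty cells for missing values)."""
    frame = table.to_frame()
    # repr round-trips doubles bit-exactly
    frame.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# coefficient sets


@dataclass(frozen=True)
class PhaseCoefficients2p:
    """2p-LFER coefficients for one phase-water system.

    The model is ``logK_phase-water = lambda1*logKow + lambda2*logKaw +
    lambda3``.  ``lambda3 == 0.0`` exactly with ``intercept_dropped=True``
    means the intercept was statistically indistinguishable from zero and
    the fit was repeated without it.
    """

    phase: str
    lambda1: float
    lambda2: float
    lambda3: float = 0.0
    se1: float | None = None
    se2: float | None = None
    se3: float | None = None
    intercept_dropped: bool = False
    n: int | None = None
    r2: float | None = None
    adj_r2: float | None = None
    rmse: float | None = None
    f_stat: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.intercept_dropped and self.lambda3 != 0.0:
            raise ValueError("dropped intercept must be recorded as exactly 0.0")
        if self.n is not None and self.n < 3:
            raise ValueError("a fitted coefficient set needs n >= 3")


@dataclass(frozen=True)
class AbrahamSystem:
    """Abraham-model (pp-LFER) system coefficients for one phase pair.

    Two equation forms exist: the *v*-form ``c + eE + sS + aA + bB + vV``
    (condensed-phase systems) and the *l*-form ``c + eE + sS + aA + bB + lL``
    (systems involving air).  Exactly one of ``v``/``l`` is set, matching
    ``form``.
    """

    phase: str
    c: float
    e: float
    s: float
    a: float
    b: float
    v: float | None = None
    l: float | None = None
    form: str = "v"

    def __post_init__(self) -> None:
        if self.form not in ("v", "l"):
            raise ValueError("form must be 'v' or 'l'")
        if self.form == "v" and (self.v is None or self.l is not None):
            raise ValueError("v-form system must set v and leave l unset")
        if self.form == "l" and (self.l is None or self.v is not None):
            raise ValueError("l-form system must set l and leave v unset")
        for label, value in (("c", self.c), ("e", self.e), ("s", self.s),
                             ("a", self.a), ("b", self.b),
                             ("v", self.v), ("l", self.l)):
            if value is not None and not math.isfinite(value):
                raise ValueError(f"system coefficient {label} is not finite")


class CoefficientRegistry:
    """Registry of named 2p-LFER coefficient sets with synonym resolution."""

    def __init__(self) -> None:
        self._sets: dict[str, PhaseCoefficients2p] = {}
        self._synonyms: dict[str, str] = {}

    @classmethod
    def builtin(cls) -> "CoefficientRegistry":
        registry = cls()
        payload = json.loads(
            resources.files("lfer2p.data").joinpath("coefficients_2p.json").read_text()
        )
        for phase, row in payload["phases"].items():
            registry.register(
                PhaseCoefficients2p(
                    phase=phase,
                    lambda1=row["lambda1"], se1=row["se1"],
                    lambda2=row["lambda2"], se2=row["se2"],
                    lambda3=row["lambda3"], se3=row["se3"],
                    intercept_dropped=row["intercept_dropped"],
                    n=row["n"], r2=row["r2"], adj_r2=row["adj_r2"],
                    rmse=row["rmse"], f_stat=row["f_stat"],
                    source=row["source"],
                )
            )
        for synonym, target in payload["synonyms"].items():
            registry.add_synonym(synonym, target)
        return registry

    def register(self, coeffs: PhaseCoefficients2p) -> None:
        self._sets[coeffs.phase] = coeffs

    def add_synonym(self, synonym: str, target: str) -> None:
        self._synonyms[synonym.lower()] = target

    def resolve(self, phase: str) -> str:
        key = phase.strip().lower().replace(" ", "_")
        if key in self._sets:
            return key
        if phase.strip().lower() in self._synonyms:
            return self._synonyms[phase.strip().lower()]
        if key in self._synonyms:
            return self._synonyms[key]
        raise KeyError(
            f"unknown phase {phase!r}; registered: {', '.join(sorted(self._sets))}"
        )

    def get(self, phase: str) -> PhaseCoefficients2p:
        return self._sets[self.resolve(phase)]

    @property
    def phases(self) -> list[str]:
        return sorted(self._sets)


_DEFAULT_REGISTRY = CoefficientRegistry.builtin()


def get_2p_coefficients(phase: str) -> PhaseCoefficients2p:
    """Look up a published (or user-registered) 2p-LFER coefficient set."""
    return _DEFAULT_REGISTRY.get(phase)


def register_2p_coefficients(coeffs: PhaseCoefficients2p) -> None:
    """Add a user coefficient set to the default registry."""
    _DEFAULT_REGISTRY.register(coeffs)


def registered_phases() -> list[str]:
    return _DEFAULT_REGISTRY.phases


# ---------------------------------------------------------------------------
# dataset merging


def _merge_scalar(a: float | None, b: float | None, what: str, chem_id: str,
                  tol: float = 1e-6) -> float | None:
    if a is None:
        return b
    if b is None:
        return a
    if abs(a - b) > tol:
        raise TableFormatError(
            f"conflicting {what} for {chem_id!r}: {a} vs {b}"
        )
    return a


def average_protein_datasets(
    chicken: ChemicalTable,
    fish: ChemicalTable,
    chicken_phase: str = "chicken_structural_protein",
    fish_phase: str = "fish_structural_protein",
    out_phase: str = "structural_protein",
) -> ChemicalTable:
    """Merge chicken and fish muscle-protein datasets into one table.

    Chemicals present in both tables get the arithmetic mean of the two
    observed log K values as the combined structural-protein value;
    chemicals present in only one table keep their single value (union
    policy, maximising training size).  Descriptors must agree to 1e-6
    where both tables carry them.
    """
    merged_ids = list(chicken.ids) + [i for i in fish.ids if i not in chicken]
    records = []
    for chem_id in merged_ids:
        in_chicken = chem_id in chicken
        in_fish = chem_id in fish
        base = chicken[chem_id] if in_chicken else fish[chem_id]
        other = fish[chem_id] if (in_chicken and in_fish) else None

        logKow, logKaw = base.logKow, base.logKaw
        descriptors = dict(base.descriptors)
        observed = dict(base.observed)
        name = base.name
        if other is not None:
            logKow = _merge_scalar(logKow, other.logKow, "logKow", chem_id)
            logKaw = _merge_scalar(logKaw, other.logKaw, "logKaw", chem_id)
            for key, value in other.descriptors.items():
                descriptors[key] = _merge_scalar(
                    descriptors.get(key), value, f"descriptor {key}", chem_id
                )
            for phase, value in other.observed.items():
                if phase in observed:
                    observed[phase] = _merge_scalar(
                        observed[phase], value, f"observed {phase}", chem_id
                    )
                else:
                    observed[phase] = value
            name = name or other.name

        values = [
            v for phase, v in (
                (chicken_phase, chicken[chem_id].observed.get(chicken_phase) if in_chicken else None),
                (fish_phase, fish[chem_id].observed.get(fish_phase) if in_fish else None),
            ) if v is not None
        ]
        if values:
            observed[out_phase] = sum(values) / len(values)
        records.append(
            ChemicalRecord(id=chem_id, name=name, logKow=logKow, logKaw=logKaw,
                           descriptors=descriptors, observed=observed)
        )
    return ChemicalTable(records)
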