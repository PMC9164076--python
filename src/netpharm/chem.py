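"""Drug-likeness screening: Lipinski rules, violation counts, TPSA filter.

The rule bounds are the ones used for orally administered small molecules:
molecular weight < 500 g/mol, hydrogen-bond acceptors < 10, hydrogen-bond
donors ≤ 5, Moriguchi logP ≤ 4.15, and topological polar surface area
< 140 Å².  Boundary semantics are deliberately mixed (strict for MW and HBA,
inclusive for HBD and MLogP) — that is how screening tables in this field
count violations, and a compound sitting exactly on an inclusive bound passes.

Descriptors are taken from the input table (typically a SwissADME export);
recomputation from SMILES is a separate, optional code path because different
toolkits disagree in the third decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import IncompleteRecordError, MalformedRecordError, SchemaError
from .ingest import ascii_minus, read_table

#: Default rule bounds, overridable per call.
LIPINSKI_BOUNDS = {"mw": 500.0, "hba": 10, "hbd": 5, "mlogp": 4.15}
TPSA_THRESHOLD = 140.0  # Å²; oral-drug membrane-permeability cutoff


@dataclass(frozen=True)
class Compound:
    """One compound with the physicochemical descriptors screening needs."""

    name: str
    molecular_weight: float | None  # g/mol
    hba: int | None  # H-bond acceptors
    hbd: int | None  # H-bond donors
    mlogp: float | None  # Moriguchi logP
    tpsa: float | None  # Å²
    bioavailability_score: float | None = None
    smiles: str | None = None

    def __post_init__(self):
        if not str(self.name).strip():
            raise MalformedRecordError("compound with empty name")
        if self.molecular_weight is not None and self.molecular_weight <= 0:
            raise MalformedRecordError(f"{self.name}: molecular weight must be positive")
        for fld in ("hba", "hbd", "tpsa"):
            value = getattr(self, fld)
            if value is not None and value < 0:
                raise MalformedRecordError(f"{self.name}: {fld} must be non-negative")


@dataclass(frozen=True)
class LipinskiResult:
    violations: int  # 0..4
    violated_rules: tuple[str, ...]


@dataclass(frozen=True)
class CompoundScreen:
    name: str
    violations: int
    violated_rules: tuple[str, ...]
    tpsa: float
    tpsa_pass: bool
    bioavailability_score: float | None = None


@dataclass(frozen=True)
class ScreenReport:
    records: tuple[CompoundScreen, ...]
    tpsa_threshold: float
    summary: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [r.name for r in self.records],
                "lipinski_violations": [r.violations for r in self.records],
                "violated_rules": [";".join(r.violated_rules) for r in self.records],
                "tpsa": [r.tpsa for r in self.records],
                "tpsa_pass": [r.tpsa_pass for r in self.records],
            }
        )


def _require(compound: Compound, fields: Sequence[str]) -> None:
    for fld in fields:
        value = getattr(compound, fld)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise IncompleteRecordError(f"{compound.name}: missing descriptor '{fld}'")


def lipinski_violations(compound: Compound, bounds: dict | None = None) -> LipinskiResult:
    """Count failed Lipinski rules.

    MW and HBA must be *strictly* below their bounds; HBD and MLogP may equal
    theirs.  Returns the count (0–4) and the names of the violated rules.
    """
    _require(compound, ("molecular_weight", "hba", "hbd", "mlogp"))
    b = {**LIPINSKI_BOUNDS, **(bounds or {})}
    violated = []
    if not compound.molecular_weight < b["mw"]:
        violated.append("MW")
    if not compound.hba < b["hba"]:
        violated.append("HBA")
    if not compound.hbd <= b["hbd"]:
        violated.append("HBD")
    if not compound.mlogp <= b["mlogp"]:
        violated.append("MLOGP")
    return LipinskiResult(violations=len(violated), violated_rules=tuple(violated))


def tpsa_filter(roster: Iterable[Compound], threshold: float = TPSA_THRESHOLD) -> list[Compound]:
    """Compounds with TPSA strictly below the threshold, input order preserved."""
    passing = []
    for compound in roster:
        _require(compound, ("tpsa",))
        if compound.tpsa < threshold:
            passing.append(compound)
    return passing


def screen(
    roster: Sequence[Compound],
    tpsa_threshold: float = TPSA_THRESHOLD,
    bounds: dict | None = None,
) -> ScreenReport:
    """Annotate a compound roster with rule violations and the TPSA flag.

    Screening is annotative: nothing is removed.  Callers wanting a hard
    filter combine ``tpsa_pass`` / ``violations`` themselves (or use
    :func:`tpsa_filter`).
    """
    if not roster:
        raise MalformedRecordError("screen() requires a non-empty roster")
    records = []
    for compound in roster:
        _require(compound, ("tpsa",))
        lip = lipinski_violations(compound, bounds)
        records.append(
            CompoundScreen(
                name=compound.name,
                violations=lip.violations,
                violated_rules=lip.violated_rules,
                tpsa=compound.tpsa,
                tpsa_pass=compound.tpsa < tpsa_threshold,
                bioavailability_score=compound.bioavailability_score,
            )
        )
    rule_counts = {rule: sum(1 for r in records if rule not in r.violated_rules) for rule in ("MW", "HBA", "HBD", "MLOGP")}
    summary = {
        "n_compounds": len(records),
        "n_zero_violations": sum(1 for r in records if r.violations == 0),
        "n_tpsa_pass": sum(1 for r in records if r.tpsa_pass),
        "passing_each_rule": rule_counts,
        "total_violations": sum(r.violations for r in records),
    }
    return ScreenReport(records=tuple(records), tpsa_threshold=tpsa_threshold, summary=summary)


_COLUMN_MAP = {
    "name": "name",
    "mw": "molecular_weight",
    "hba": "hba",
    "hbd": "hbd",
    "mlogp": "mlogp",
    "tpsa": "tpsa",
}


def read_compound_table(path: str | Path, delimiter: str | None = None) -> list[Compound]:
    """Read a compound roster CSV/TSV.

    Required columns (case-insensitive): name, MW, HBA, HBD, MLOGP, TPSA.
    Optional: BA_SCORE, SMILES.
    """
    path = Path(path)
    frame = read_table(path, delimiter)
    lookup = {c.lower(): c for c in frame.columns}
    for col in _COLUMN_MAP:
        if col not in lookup:
            raise SchemaError(f"{path}: missing required column '{col.upper()}'")

    def _num(row, col, cast=float):
        raw = ascii_minus(row[lookup[col]]).strip()
        return cast(raw) if raw else None

    compounds = []
    for _, row in frame.iterrows():
        compounds.append(
            Compound(
                name=str(row[lookup["name"]]).strip(),
                molecular_weight=_num(row, "mw"),
                hba=_num(row, "hba", int),
                hbd=_num(row, "hbd", int),
                mlogp=_num(row, "mlogp"),
                tpsa=_num(row, "tpsa"),
                bioavailability_score=_num(row, "ba_score") if "ba_score" in lookup else None,
                smiles=str(row[lookup["smiles"]]).strip() or None if "smiles" in lookup else None,
            )
        )
    return compounds
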