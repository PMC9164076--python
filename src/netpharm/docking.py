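"""Docking configuration and docking-score triage.

The package never runs a docking engine.  It prepares a deterministic
Vina-style grid-box configuration for a receptor, parses score tables
exported from a docking run, and classifies ligands against the activity
threshold used for AutoDock-style scores: a binding energy strictly below
−6.0 kcal/mol marks a stable (active) binder.  More negative energies are
more favorable, so the best binder is the minimum-energy record.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import FormatError, NoResultError, SchemaError
from .ingest import ascii_minus, read_table

log = logging.getLogger(__name__)

ACTIVITY_THRESHOLD = -6.0  # kcal/mol; energy < threshold => active

#: residue labels like Trp391: 3-letter amino-acid code + position
_RESIDUE_RE = re.compile(r"^[A-Z][a-z]{2}\d+$")


@dataclass(frozen=True)
class GridBox:
    """Search-box center and extents, in Å."""

    center_x: float
    center_y: float
    center_z: float
    size_x: float = 40.0
    size_y: float = 40.0
    size_z: float = 40.0

    def __post_init__(self):
        for axis in ("x", "y", "z"):
            if getattr(self, f"size_{axis}") <= 0:
                raise FormatError(f"grid box size_{axis} must be strictly positive")


def _fmt(value: float) -> str:
    """Render a number with the precision it was given (40 -> '40')."""
    return format(value, "g")


def make_grid_config(
    box: GridBox,
    receptor_file: str,
    ligand_file: str,
    exhaustiveness: int = 8,
    num_modes: int = 10,
    energy_range: float = 4,
) -> str:
    """Deterministic, line-ordered ``key = value`` text for a Vina-style engine."""
    lines = [
        f"receptor = {receptor_file}",
        f"ligand = {ligand_file}",
        f"center_x = {_fmt(box.center_x)}",
        f"center_y = {_fmt(box.center_y)}",
        f"center_z = {_fmt(box.center_z)}",
        f"size_x = {_fmt(box.size_x)}",
        f"size_y = {_fmt(box.size_y)}",
        f"size_z = {_fmt(box.size_z)}",
        f"exhaustiveness = {exhaustiveness}",
        f"num_modes = {num_modes}",
        f"energy_range = {_fmt(energy_range)}",
    ]
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class DockingRecord:
    ligand: str
    binding_energy: float  # kcal/mol; negative = favorable
    receptor: str = ""
    pubchem_id: str | None = None
    hbond_residues: tuple[str, ...] = ()
    hydrophobic_residues: tuple[str, ...] = ()

    def __post_init__(self):
        if not math.isfinite(self.binding_energy):
            raise FormatError(f"{self.ligand}: binding energy must be finite")


def parse_residues(cell: str) -> tuple[tuple[str, ...], list[str]]:
    """Split a comma-separated residue cell into valid labels and rejects.

    'N/A' and empty cells mean no residues.  Labels must look like Trp391;
    malformed tokens are returned separately (callers log, not fail).
    """
    cell = str(cell).strip()
    if not cell or cell.upper() in {"N/A", "NA", "NONE"}:
        return (), []
    valid, malformed = [], []
    for token in re.split(r"[,;]", cell):
        token = token.strip()
        if not token:
            continue
        (valid if _RESIDUE_RE.match(token) else malformed).append(token)
    return tuple(valid), malformed


def parse_scores(path: str | Path, delimiter: str | None = None) -> list[DockingRecord]:
    """Read a docking score TSV into records.

    Required columns: ligand, binding_energy (or energy).  Optional:
    receptor, pubchem_id, hbond_residues, hydrophobic_residues.  Unicode
    minus signs in energies are normalized; non-numeric energies are format
    errors naming the row.
    """
    path = Path(path)
    frame = read_table(path, delimiter)
    lookup = {c.lower(): c for c in frame.columns}
    if "ligand" not in lookup:
        raise SchemaError(f"{path}: missing required column 'ligand'")
    energy_col = lookup.get("binding_energy") or lookup.get("energy")
    if energy_col is None:
        raise SchemaError(f"{path}: missing required column 'binding_energy'")

    records = []
    for idx, row in frame.iterrows():
        raw = ascii_minus(row[energy_col]).strip()
        try:
            energy = float(raw)
        except ValueError:
            raise FormatError(f"{path}: non-numeric binding energy {raw!r} on data row {idx + 1}") from None

        def _residues(key: str) -> tuple[str, ...]:
            if key not in lookup:
                return ()
            valid, malformed = parse_residues(row[lookup[key]])
            if malformed:
                log.warning("%s row %d: malformed residue label(s) %s", path, idx + 1, malformed)
            return valid

        records.append(
            DockingRecord(
                ligand=str(row[lookup["ligand"]]).strip(),
                binding_energy=energy,
                receptor=str(row[lookup["receptor"]]).strip() if "receptor" in lookup else "",
                pubchem_id=str(row[lookup["pubchem_id"]]).strip() if "pubchem_id" in lookup else None,
                hbond_residues=_residues("hbond_residues"),
                hydrophobic_residues=_residues("hydrophobic_residues"),
            )
        )
    return records


@dataclass(frozen=True)
class TriageReport:
    records: tuple[DockingRecord, ...]
    threshold: float
    actives: tuple[DockingRecord, ...]
    inactives: tuple[DockingRecord, ...]
    ranking: tuple[DockingRecord, ...]  # ascending energy (best first)
    best: "DockingRecord"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ligand": [r.ligand for r in self.ranking],
                "binding_energy": [r.binding_energy for r in self.ranking],
                "active": [r.binding_energy < self.threshold for r in self.ranking],
            }
        )


def classify_binders(records: Sequence[DockingRecord], threshold: float = ACTIVITY_THRESHOLD) -> TriageReport:
    """Partition records into actives (energy strictly below threshold) and inactives.

    A record sitting exactly on the threshold is inactive.
    """
    if not records:
        raise NoResultError("classify_binders() on empty record list")
    ranking = tuple(sorted(records, key=lambda r: (r.binding_energy, r.ligand)))
    actives = tuple(r for r in ranking if r.binding_energy < threshold)
    inactives = tuple(r for r in ranking if not r.binding_energy < threshold)
    return TriageReport(
        records=tuple(records),
        threshold=threshold,
        actives=actives,
        inactives=inactives,
        ranking=ranking,
        best=ranking[0],
    )


def best_binder(records: Sequence[DockingRecord]) -> DockingRecord:
    """Minimum-energy record; ties break lexicographically by ligand name."""
    if not records:
        raise NoResultError("best_binder() on empty record list")
    return min(records, key=lambda r: (r.binding_energy, r.ligand))
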