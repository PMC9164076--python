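"""Two-stage target-set intersection.

Drug-target predictions from two independent sources are intersected first
(keeping only targets both predictors agree on), and that consensus set is
then intersected with a disease-associated target list.  The surviving
symbols are the candidate therapeutic targets carried into enrichment and
network analysis.  All counts needed for a two-set Venn diagram are reported
at each stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .ingest import normalize_symbol


@dataclass(frozen=True)
class TargetSet:
    """A named collection of normalized gene symbols."""

    label: str
    members: frozenset[str]

    @classmethod
    def from_iterable(cls, label: str, symbols: Iterable[str]) -> "TargetSet":
        return cls(label=label, members=frozenset(normalize_symbol(s) for s in symbols))

    def __len__(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass(frozen=True)
class VennResult:
    """Two-set Venn decomposition; intersection members kept, sorted."""

    label_a: str
    label_b: str
    a_only: int
    b_only: int
    intersection: tuple[str, ...]

    @property
    def intersection_size(self) -> int:
        return len(self.intersection)

    @property
    def size_a(self) -> int:
        return self.a_only + self.intersection_size

    @property
    def size_b(self) -> int:
        return self.b_only + self.intersection_size

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "size_a": self.size_a,
            "size_b": self.size_b,
            "a_only": self.a_only,
            "b_only": self.b_only,
            "intersection_size": self.intersection_size,
        }


def intersect(a: TargetSet, b: TargetSet) -> VennResult:
    """Exact set intersection with Venn bookkeeping."""
    common = a.members & b.members
    return VennResult(
        label_a=a.label,
        label_b=b.label,
        a_only=len(a.members - common),
        b_only=len(b.members - common),
        intersection=tuple(sorted(common)),
    )


@dataclass(frozen=True)
class TwoStageResult:
    stage1: VennResult  # source A × source B
    stage2: VennResult  # (A ∩ B) × disease
    final_targets: TargetSet
    union_size: int  # |A ∪ B|, reported for roster-level sanity checks

    def to_dict(self) -> dict:
        return {
            "stage1": self.stage1.to_dict(),
            "stage2": self.stage2.to_dict(),
            "final_targets": self.final_targets.sorted_members(),
            "union_size": self.union_size,
        }


def two_stage_overlap(source_a: TargetSet, source_b: TargetSet, disease: TargetSet) -> TwoStageResult:
    """Intersect the two prediction sources, then the result with the disease set.

    The final member list is emitted in lexicographic order so reports diff
    deterministically.
    """
    stage1 = intersect(source_a, source_b)
    consensus = TargetSet(
        label=f"{source_a.label}∩{source_b.label}",
        members=frozenset(stage1.intersection),
    )
    stage2 = intersect(consensus, disease)
    final = TargetSet(label="final", members=frozenset(stage2.intersection))
    return TwoStageResult(
        stage1=stage1,
        stage2=stage2,
        final_targets=final,
        union_size=len(source_a.members | source_b.members),
    )


def write_venn_json(result: TwoStageResult, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(result.to_dict(), handle, indent=2, sort_keys=True)
        handle.write("\n")
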