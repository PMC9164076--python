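"""Seeded synthetic study generator.

The study's upstream inputs — SEA- and SwissTargetPrediction-style drug→
target exports, a disease-associated target list, pathway annotations, a
target PPI network and a docking score table — were produced by web-database
queries that cannot be replayed.  This module generates inputs with the same
*statistical structure*, with every planted quantity controlled: the two
prediction sources intersect in exactly ``overlap_ab`` targets, the disease
set overlaps that consensus in exactly ``overlap_final`` targets, each
pathway contains exactly its planted number of final targets out of K
annotated genes, the PPI graph has one bridge node that dominates both
degree and betweenness, and the docking table has exact active/inactive
counts around the −6 kcal/mol threshold.

Default cardinalities are the study's: 32 drugs, 332 and 660 predicted
targets overlapping in 198, a 622-gene disease set overlapping in 15, and
seven pathways whose (K, hits) pairs reproduce the published rich-factor
spread.  Every generator is a pure function of (config, seed): rerunning
with the same config is byte-identical.  The synthetic gene vocabulary is
zero-padded sequential (G000001…) so diffs and sort orders are stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .chem import Compound
from .docking import DockingRecord
from .errors import ConfigError
from .ingest import EdgeList, PathwayDB, PathwayEntry, PredictionTable, write_edge_list, write_gmt, write_symbol_list
from .overlap import TargetSet

log = logging.getLogger(__name__)

_AMINO = ("Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
          "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val")


@dataclass(frozen=True)
class SynthConfig:
    """Shape parameters for one synthetic study.

    Defaults mirror the case study's printed cardinalities and rich-factor
    spread; ``pathways`` is a tuple of (K, planted hit count) pairs.
    """

    seed: int = 0
    n_drugs: int = 32
    n_targets_a: int = 332
    n_targets_b: int = 660
    overlap_ab: int = 198
    n_disease: int = 622
    overlap_final: int = 15
    pathways: tuple[tuple[int, int], ...] = (
        (21, 2), (64, 3), (48, 2), (107, 4), (116, 4), (229, 3), (330, 4),
    )
    clique_sizes: tuple[int, ...] = (5, 5)
    n_isolated: int = 4
    energy_low: float = -8.0  # kcal/mol
    energy_high: float = -4.0
    n_active: int = 6
    n_inactive: int = 2

    def __post_init__(self):
        if min(self.n_drugs, self.n_targets_a, self.n_targets_b, self.n_disease) < 0:
            raise ConfigError("counts must be non-negative")
        if self.overlap_ab > min(self.n_targets_a, self.n_targets_b):
            raise ConfigError(
                f"overlap_ab={self.overlap_ab} exceeds min(n_targets_a, n_targets_b)"
            )
        if self.overlap_final > min(self.overlap_ab, self.n_disease):
            raise ConfigError(
                f"overlap_final={self.overlap_final} exceeds min(overlap_ab, n_disease)"
            )
        for K, k in self.pathways:
            if k > K:
                raise ConfigError(f"planted hits {k} exceed pathway size {K}")
            if k > self.overlap_final:
                raise ConfigError(f"planted hits {k} exceed the {self.overlap_final} final targets")


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    """Independent deterministic stream per generator stage."""
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed) % (2**31), stream]))


def _symbols(start: int, count: int, prefix: str = "G") -> list[str]:
    return [f"{prefix}{i:06d}" for i in range(start, start + count)]


def drug_names(cfg: SynthConfig) -> list[str]:
    return [f"DRUG{i:03d}" for i in range(1, cfg.n_drugs + 1)]


def gen_compounds(cfg: SynthConfig) -> list[Compound]:
    """Synthetic physicochemical descriptors for the drug roster.

    Values are drawn uniformly from small-molecule drug-like ranges; the
    roster names match the drug identifiers in the prediction tables.
    """
    rng = _rng(cfg, 0)
    compounds = []
    for name in drug_names(cfg):
        compounds.append(
            Compound(
                name=name,
                molecular_weight=float(np.round(rng.uniform(200, 520), 2)),
                hba=int(rng.integers(0, 8)),
                hbd=int(rng.integers(0, 4)),
                mlogp=float(np.round(rng.uniform(0.5, 5.5), 2)),
                tpsa=float(np.round(rng.uniform(3, 120), 2)),
                bioavailability_score=0.55,
            )
        )
    return compounds


def gen_prediction_sources(cfg: SynthConfig) -> tuple[PredictionTable, PredictionTable]:
    """Two drug→target sources intersecting in exactly ``overlap_ab`` targets."""
    rng = _rng(cfg, 1)
    shared = _symbols(1, cfg.overlap_ab)
    a_only = _symbols(1 + cfg.overlap_ab, cfg.n_targets_a - cfg.overlap_ab)
    b_only = _symbols(1 + cfg.n_targets_a, cfg.n_targets_b - cfg.overlap_ab)
    drugs = drug_names(cfg)

    def _pairs(targets: Sequence[str]) -> frozenset[tuple[str, str]]:
        pairs = set()
        for target in targets:
            for drug in rng.choice(drugs, size=int(rng.integers(1, 4)), replace=False):
                pairs.add((str(drug), target))
        return frozenset(pairs)

    table_a = PredictionTable("sourceA", _pairs(shared + a_only))
    table_b = PredictionTable("sourceB", _pairs(shared + b_only))
    return table_a, table_b


def gen_disease_set(cfg: SynthConfig, stage1: TargetSet) -> TargetSet:
    """Disease set of size ``n_disease`` meeting stage1 in exactly ``overlap_final``."""
    if cfg.overlap_final > len(stage1):
        raise ConfigError(
            f"overlap_final={cfg.overlap_final} exceeds stage-1 consensus size {len(stage1)}"
        )
    rng = _rng(cfg, 2)
    chosen = rng.choice(stage1.sorted_members(), size=cfg.overlap_final, replace=False)
    filler = _symbols(1, cfg.n_disease - cfg.overlap_final, prefix="C")
    return TargetSet(label="disease", members=frozenset(map(str, chosen)) | frozenset(filler))


def gen_pathway_db(cfg: SynthConfig, final_targets: TargetSet) -> PathwayDB:
    """Pathways containing exactly the planted hit counts plus filler genes.

    Filler symbols use a distinct prefix, so they can never collide with the
    query and the planted k is recovered exactly by enrichment.
    """
    for K, k in cfg.pathways:
        if k > len(final_targets):
            raise ConfigError(f"planted hits {k} exceed final target count {len(final_targets)}")
    rng = _rng(cfg, 3)
    entries = {}
    filler_start = 1
    for i, (K, k) in enumerate(cfg.pathways, start=1):
        pid = f"syn{i:05d}"
        hits = [str(s) for s in rng.choice(final_targets.sorted_members(), size=k, replace=False)]
        filler = _symbols(filler_start, K - k, prefix="F")
        filler_start += K - k
        entries[pid] = PathwayEntry(pid, f"Synthetic pathway {i}", frozenset(hits) | frozenset(filler), K)
    return PathwayDB(entries=entries)


def gen_hub_graph(cfg: SynthConfig) -> tuple[EdgeList, str]:
    """PPI graph of disjoint cliques joined only through one bridge node.

    The bridge attaches to every clique member, so it has both the maximal
    degree (it survives the DC stage) and all inter-clique shortest paths (it
    dominates BC in the subnetwork).  Optional isolated nodes emulate
    disconnected targets carried with DC = BC = 0.  Returns the edge list and
    the planted hub's identity.

    Recovery by the double filter is guaranteed when the cliques are equal in
    size: boundary ties then pull every clique member through the degree
    stage, leaving the bridge as the only positive-betweenness node.  With
    unequal cliques the degree filter can keep only the largest clique, whose
    induced subnetwork is complete (all betweenness zero), and the hub is
    lost — deliberately representable, but not the default shape.
    """
    if len(cfg.clique_sizes) < 2 or min(cfg.clique_sizes) < 3:
        raise ConfigError("hub graph needs at least 2 cliques of size >= 3")
    rng = _rng(cfg, 4)
    n_members = sum(cfg.clique_sizes)
    labels = [f"G{i:06d}" for i in rng.choice(
        np.arange(1, 10 * (n_members + cfg.n_isolated + 1)),
        size=n_members + cfg.n_isolated + 1,
        replace=False,
    )]
    hub, labels = labels[0], labels[1:]
    edges = {}
    offset = 0
    for size in cfg.clique_sizes:
        members = labels[offset:offset + size]
        offset += size
        for i in range(size):
            for j in range(i + 1, size):
                a, b = sorted((members[i], members[j]))
                edges[(a, b)] = 1.0
        for member in members:
            a, b = sorted((hub, member))
            edges[(a, b)] = 1.0
    isolated = frozenset(labels[offset:offset + cfg.n_isolated])
    return EdgeList(edges=frozenset(edges), confidence=edges, isolated_nodes=isolated), hub


def gen_docking_table(
    cfg: SynthConfig,
    n_active: int | None = None,
    n_inactive: int | None = None,
    threshold: float = -6.0,
) -> list[DockingRecord]:
    """Docking records with exact active/inactive counts around the threshold."""
    n_active = cfg.n_active if n_active is None else n_active
    n_inactive = cfg.n_inactive if n_inactive is None else n_inactive
    if n_active < 0 or n_inactive < 0:
        raise ConfigError("active/inactive counts must be non-negative")
    if n_active > 0 and not cfg.energy_low < threshold:
        raise ConfigError(f"energy range [{cfg.energy_low}, {cfg.energy_high}] has no room below {threshold}")
    if n_inactive > 0 and not cfg.energy_high >= threshold:
        raise ConfigError(f"energy range [{cfg.energy_low}, {cfg.energy_high}] has no room at/above {threshold}")
    rng = _rng(cfg, 5)
    actives = np.round(rng.uniform(cfg.energy_low, threshold, size=n_active), 1)
    # rounding to table precision must not push an active onto the boundary
    actives[actives >= threshold] = np.round(threshold - 0.1, 1)
    inactives = np.round(rng.uniform(threshold, cfg.energy_high, size=n_inactive), 1)
    inactives[inactives < threshold] = np.round(threshold, 1)
    energies = np.concatenate([actives, inactives])
    records = []
    for i, energy in enumerate(energies, start=1):
        residues = tuple(
            f"{_AMINO[int(r)]}{int(p)}"
            for r, p in zip(rng.integers(0, len(_AMINO), size=3), rng.integers(100, 800, size=3))
        )
        records.append(
            DockingRecord(
                ligand=f"LIG{i:03d}",
                binding_energy=float(energy),
                receptor="SYNTHETIC_RECEPTOR",
                hydrophobic_residues=residues,
            )
        )
    return records


def write_study(cfg: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit a complete synthetic study directory in the dialects the readers expect.

    Files: compounds.csv, predictions_a.tsv, predictions_b.tsv,
    disease_targets.txt, pathways.gmt, ppi_edges.tsv, docking_scores.tsv,
    config.yaml (the config actually used).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("compounds", "compounds.csv"),
        ("predictions_a", "predictions_a.tsv"),
        ("predictions_b", "predictions_b.tsv"),
        ("disease_targets", "disease_targets.txt"),
        ("pathways", "pathways.gmt"),
        ("ppi_edges", "ppi_edges.tsv"),
        ("docking_scores", "docking_scores.tsv"),
        ("config", "config.yaml"),
    ]}

    compounds = gen_compounds(cfg)
    with open(paths["compounds"], "w", encoding="utf-8") as handle:
        handle.write("name,MW,HBA,HBD,MLOGP,TPSA,BA_SCORE\n")
        for c in compounds:
            handle.write(
                f"{c.name},{c.molecular_weight},{c.hba},{c.hbd},{c.mlogp},{c.tpsa},{c.bioavailability_score}\n"
            )

    table_a, table_b = gen_prediction_sources(cfg)
    for table, key in ((table_a, "predictions_a"), (table_b, "predictions_b")):
        table.to_frame().to_csv(paths[key], sep="\t", index=False)

    stage1 = TargetSet(label="consensus", members=table_a.targets & table_b.targets)
    disease = gen_disease_set(cfg, stage1)
    write_symbol_list(disease.sorted_members(), paths["disease_targets"])

    final = TargetSet(label="final", members=stage1.members & disease.members)
    write_gmt(gen_pathway_db(cfg, final), paths["pathways"])

    edge_list, hub = gen_hub_graph(cfg)
    write_edge_list(edge_list, paths["ppi_edges"])

    records = gen_docking_table(cfg)
    with open(paths["docking_scores"], "w", encoding="utf-8") as handle:
        handle.write("ligand\treceptor\tbinding_energy\thydrophobic_residues\n")
        for r in records:
            handle.write(
                f"{r.ligand}\t{r.receptor}\t{r.binding_energy}\t{','.join(r.hydrophobic_residues)}\n"
            )

    meta = asdict(cfg)
    meta["planted_hub"] = hub
    with open(paths["config"], "w", encoding="utf-8") as handle:
        yaml.safe_dump(meta, handle, sort_keys=True)
    log.info("synthetic study written to %s (planted hub %s)", outdir, hub)
    return paths


def gen_pta_mappings(
    n_pathways: int = 7,
    n_targets: int = 11,
    n_drugs: int = 30,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Random pathway–target and target–drug pairs covering every node.

    Each pathway annotates at least one target, every target belongs to at
    least one pathway and at least one drug hits it, so the tripartite
    network built from these pairs has exactly
    ``n_pathways + n_targets + n_drugs`` nodes.
    """
    rng = np.random.default_rng(seed)
    pathways = [f"PW{i:02d}" for i in range(1, n_pathways + 1)]
    targets = [f"T{i:03d}" for i in range(1, n_targets + 1)]
    drugs = [f"DRUG{i:03d}" for i in range(1, n_drugs + 1)]
    pt = {(str(rng.choice(pathways)), t) for t in targets}
    for p in pathways:
        pt.add((p, str(rng.choice(targets))))
    td = {(str(rng.choice(targets)), d) for d in drugs}
    for t in targets:
        td.add((t, str(rng.choice(drugs))))
    # a few extra cross links for realistic degree spread
    for _ in range(n_drugs):
        td.add((str(rng.choice(targets)), str(rng.choice(drugs))))
    for _ in range(n_targets):
        pt.add((str(rng.choice(pathways)), str(rng.choice(targets))))
    return sorted(pt), sorted(td)
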