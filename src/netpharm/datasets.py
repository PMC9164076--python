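"""Bundled reference tables from the antihistamine–COVID-19 case study.

These are the printed desk-scale tables of the study this pipeline
reproduces: the 32-antihistamine physicochemical roster, the 7-row pathway
enrichment table, the PPI and subnetwork centrality tables, and the
GRIN2B docking scores with the grid box used.  They serve as fixtures and as
worked-example inputs; the upstream web-database exports behind them (SEA,
SwissTargetPrediction, PubChem, STRING) were never published, which is what
:mod:`netpharm.simulate` emulates.

Known quirks preserved verbatim from the printed enrichment table: the
long-term potentiation row spells one gene "GRRIN2B" and lists "RPS6KA2"
twice, and the insulin-resistance rich factor 0.0374 is not k/K for any
integer K at k = 3.  Background sizes (K) are therefore stored only for the
four rows where the printed rich factor is integer-recoverable
(hsa00220 2/21, hsa04720 3/64, hsa00330 2/48, hsa04080 4/330).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .chem import Compound
from .docking import DockingRecord, GridBox, parse_scores
from .enrichment import EnrichmentRow, EnrichmentTable, make_table
from .graphs import FilterOutcome  # noqa: F401  (re-exported convenience)
from .ingest import read_table

#: Grid box centered on the GRIN2B (PDB 7EU8) active site, 40 Å cube.
GRIN2B_GRID_BOX = GridBox(
    center_x=128.688, center_y=128.088, center_z=133.365,
    size_x=40, size_y=40, size_z=40,
)


def _data_path(filename: str):
    return resources.files("netpharm.data").joinpath(filename)


def _load(filename: str) -> pd.DataFrame:
    with resources.as_file(_data_path(filename)) as path:
        return read_table(path, delimiter="\t")


def antihistamine_descriptors() -> pd.DataFrame:
    """The 32-antihistamine roster with printed descriptors and violation counts.

    Columns: name, mw, hba, hbd, mlogp, violations (as printed, for
    cross-checking), ba_score, tpsa.
    """
    frame = _load("antihistamines.tsv")
    for col in ("mw", "mlogp", "ba_score", "tpsa"):
        frame[col] = frame[col].astype(float)
    for col in ("hba", "hbd", "violations"):
        frame[col] = frame[col].astype(int)
    return frame


def antihistamine_compounds() -> list[Compound]:
    """The roster as :class:`~netpharm.chem.Compound` objects."""
    return [
        Compound(
            name=row.name_,
            molecular_weight=row.mw,
            hba=row.hba,
            hbd=row.hbd,
            mlogp=row.mlogp,
            tpsa=row.tpsa,
            bioavailability_score=row.ba_score,
        )
        for row in antihistamine_descriptors().rename(columns={"name": "name_"}).itertuples()
    ]


def pathway_enrichment_frame() -> pd.DataFrame:
    """The printed 7-row enrichment table (rich factor and FDR as published)."""
    frame = _load("pathway_enrichment.tsv")
    frame["rich_factor"] = frame["rich_factor"].astype(float)
    frame["fdr"] = frame["fdr"].astype(float)
    frame["background_size"] = pd.to_numeric(frame["background_size"], errors="coerce").astype("Int64")
    return frame


def pathway_enrichment_table() -> EnrichmentTable:
    """The enrichment fixture as an :class:`EnrichmentTable`.

    Rich factors and FDRs are the published values; k is the listed gene
    count and K is stored only where integer-recoverable (None otherwise).
    p-values were not published and are None.
    """
    rows = []
    for row in pathway_enrichment_frame().itertuples():
        genes = tuple(g.strip() for g in row.genes.split(","))
        K = int(row.background_size) if pd.notna(row.background_size) else None
        rows.append(
            EnrichmentRow(
                pathway_id=row.pathway_id,
                name=row.name,
                hit_genes=genes,
                k=len(genes),
                K=K,
                rich_factor=row.rich_factor,
                p_value=None,
                fdr=row.fdr,
                significant=row.fdr < 0.05,
            )
        )
    return make_table(rows, background_size=None, query_size=15)


def ppi_centrality() -> pd.DataFrame:
    """Published DC/BC table of the 13-node target PPI network."""
    frame = _load("ppi_centrality.tsv")
    frame["dc"] = frame["dc"].astype(int)
    frame["bc"] = frame["bc"].astype(float)
    return frame


def subnetwork_centrality() -> pd.DataFrame:
    """Published DC/BC table of the 5-node degree-filtered subnetwork."""
    frame = _load("subnetwork_centrality.tsv")
    frame["dc"] = frame["dc"].astype(int)
    frame["bc"] = frame["bc"].astype(float)
    return frame


def docking_records() -> list[DockingRecord]:
    """The eight GRIN2B docking scores with interacting residues."""
    with resources.as_file(_data_path("docking_scores.tsv")) as path:
        return parse_scores(path)
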