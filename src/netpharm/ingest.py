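"""Readers and writers for the external formats the pipeline touches.

All gene identity in netpharm is uppercase-symbol equality: symbols are
trimmed and uppercased on the way in, and set operations downstream assume
that normalization has happened here.  Text IO is UTF-8 throughout, and
typographic minus/dash variants in numeric fields are normalized to the ASCII
hyphen-minus before parsing (published tables frequently print U+2212).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import FormatError, MalformedRecordError, SchemaError

log = logging.getLogger(__name__)

_DASHES = str.maketrans({"−": "-", "–": "-", "—": "-"})

#: Delimiters tried, in order, when none is given explicitly.
_DELIMITERS = ("\t", ",", ";")


def ascii_minus(text: str) -> str:
    """Replace Unicode minus / en-dash / em-dash with ASCII ``-``."""
    return str(text).translate(_DASHES)


def normalize_symbol(raw: str) -> str:
    """Trim and uppercase a gene symbol.

    Raises :class:`MalformedRecordError` if the symbol is empty after
    trimming.  Idempotent by construction.
    """
    symbol = str(raw).strip().upper()
    if not symbol:
        raise MalformedRecordError(f"empty gene symbol in record: {raw!r}")
    return symbol


def _sniff_delimiter(path: Path) -> str:
    with open(path, encoding="utf-8") as handle:
        header = handle.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters="".join(_DELIMITERS)).delimiter
    except csv.Error:
        for delim in _DELIMITERS:
            if delim in header:
                return delim
        return "\t"


def read_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a delimited text table, auto-detecting tab/comma/semicolon."""
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")


def _require_columns(frame: pd.DataFrame, columns: Iterable[str], path: Path) -> dict[str, str]:
    """Case-insensitive column lookup; raises SchemaError naming the column."""
    lookup = {c.lower(): c for c in frame.columns}
    resolved = {}
    for col in columns:
        if col.lower() not in lookup:
            raise SchemaError(f"{path}: missing required column '{col}'")
        resolved[col] = lookup[col.lower()]
    return resolved


# ---------------------------------------------------------------------------
# drug -> target prediction tables (SEA / SwissTargetPrediction style exports)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictionTable:
    """Deduplicated (drug, target) pairs from one prediction source."""

    source_name: str
    pairs: frozenset[tuple[str, str]]

    @property
    def drugs(self) -> frozenset[str]:
        return frozenset(d for d, _ in self.pairs)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(t for _, t in self.pairs)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.pairs)
        return pd.DataFrame(rows, columns=["drug", "target"])


def read_prediction_table(
    path: str | Path,
    source_name: str,
    drug_col: str = "drug",
    target_col: str = "target",
    probability_col: str | None = None,
    min_probability: float | None = None,
    delimiter: str | None = None,
    roster: Iterable[str] | None = None,
) -> PredictionTable:
    """Read a drug→target prediction export into a deduplicated pair set.

    Target symbols are normalized, so case/whitespace variants of the same
    pair collapse.  ``probability_col``/``min_probability`` optionally filter
    rows the way SwissTargetPrediction exports can be thresholded; when no
    threshold is given every row is kept.  If ``roster`` is supplied, drugs
    outside it raise :class:`MalformedRecordError`.
    """
    path = Path(path)
    frame = read_table(path, delimiter)
    wanted = [drug_col, target_col] + ([probability_col] if probability_col else [])
    cols = _require_columns(frame, wanted, path)

    if probability_col and min_probability is not None:
        prob = pd.to_numeric(frame[cols[probability_col]].map(ascii_minus), errors="coerce")
        frame = frame[prob >= min_probability]

    roster_set = {str(d).strip() for d in roster} if roster is not None else None
    pairs: set[tuple[str, str]] = set()
    n_rows = 0
    for drug, target in zip(frame[cols[drug_col]], frame[cols[target_col]]):
        n_rows += 1
        drug = str(drug).strip()
        if not drug:
            raise MalformedRecordError(f"{path}: empty drug identifier on data row {n_rows}")
        if roster_set is not None and drug not in roster_set:
            raise MalformedRecordError(f"{path}: drug '{drug}' not in supplied compound roster")
        pairs.add((drug, normalize_symbol(target)))

    n_dup = n_rows - len(pairs)
    if n_rows == 0:
        log.warning("%s: prediction table '%s' is empty", path, source_name)
    log.info("%s: read %d rows, %d unique pairs (%d duplicates dropped)", path, n_rows, len(pairs), n_dup)
    return PredictionTable(source_name=source_name, pairs=frozenset(pairs))


# ---------------------------------------------------------------------------
# pathway annotation (GMT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PathwayEntry:
    pathway_id: str
    name: str
    genes: frozenset[str]
    background_size: int  # K: total genes annotated to the pathway

    def __post_init__(self):
        if self.background_size < len(self.genes):
            raise FormatError(
                f"pathway '{self.pathway_id}': background size {self.background_size} "
                f"smaller than stored gene set ({len(self.genes)})"
            )


@dataclass(frozen=True)
class PathwayDB:
    """Pathway id → (name, gene set, background size K)."""

    entries: Mapping[str, PathwayEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def __getitem__(self, pathway_id: str) -> PathwayEntry:
        return self.entries[pathway_id]


def read_gmt(path: str | Path, size_overrides: Mapping[str, int] | None = None) -> PathwayDB:
    """Read a Broad-dialect GMT file (name, description, tab-separated members).

    The background size K defaults to the member count; ``size_overrides``
    (pathway id → K) replaces it when the annotation is wider than the stored
    gene list.  Lines with fewer than 3 fields and duplicate pathway ids are
    format errors.
    """
    path = Path(path)
    entries: dict[str, PathwayEntry] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need at least 3")
            pathway_id, name = fields[0].strip(), fields[1].strip()
            if pathway_id in entries:
                raise FormatError(f"{path}:{lineno}: duplicate pathway id '{pathway_id}'")
            genes = frozenset(normalize_symbol(g) for g in fields[2:] if g.strip())
            size = len(genes)
            if size_overrides and pathway_id in size_overrides:
                size = int(size_overrides[pathway_id])
            entries[pathway_id] = PathwayEntry(pathway_id, name, genes, size)
    return PathwayDB(entries=entries)


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for entry in sorted(db, key=lambda e: e.pathway_id):
            members = "\t".join(sorted(entry.genes))
            handle.write(f"{entry.pathway_id}\t{entry.name}\t{members}\n")


# ---------------------------------------------------------------------------
# protein-protein interaction edge lists (STRING-style TSV)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EdgeList:
    """Undirected, deduplicated PPI edges with per-edge confidence in [0, 1]."""

    edges: frozenset[tuple[str, str]]  # each stored as a sorted pair
    confidence: Mapping[tuple[str, str], float] = field(default_factory=dict)
    isolated_nodes: frozenset[str] = frozenset()

    @property
    def nodes(self) -> frozenset[str]:
        connected = frozenset(n for edge in self.edges for n in edge)
        return connected | self.isolated_nodes

    def to_graph(self) -> nx.Graph:
        graph = nx.Graph()
        graph.add_nodes_from(sorted(self.nodes), role="target")
        for a, b in sorted(self.edges):
            graph.add_edge(a, b, confidence=self.confidence.get((a, b), 1.0))
        return graph


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def read_edge_list(
    path: str | Path,
    min_confidence: float = 0.0,
    node_cols: tuple[str, str] = ("node1", "node2"),
    score_col: str = "combined_score",
    delimiter: str | None = None,
) -> EdgeList:
    """Read a STRING-style edge TSV into an undirected, deduplicated edge set.

    Self-loops are dropped (and counted in the log); duplicate unordered pairs
    keep the maximum confidence.  A missing score column means confidence 1.0
    for every edge; scores above 1 are taken to be on STRING's 0–1000 scale
    and divided by 1000.
    """
    path = Path(path)
    frame = read_table(path, delimiter)
    cols = _require_columns(frame, list(node_cols), path)
    score_lookup = {c.lower(): c for c in frame.columns}
    score_actual = score_lookup.get(score_col.lower())

    edges: dict[tuple[str, str], float] = {}
    n_self = 0
    for idx, row in frame.iterrows():
        a = normalize_symbol(row[cols[node_cols[0]]])
        b = normalize_symbol(row[cols[node_cols[1]]])
        if a == b:
            n_self += 1
            continue
        if score_actual is not None:
            raw = ascii_minus(row[score_actual])
            try:
                conf = float(raw)
            except ValueError:
                raise FormatError(f"{path}: non-numeric score {raw!r} on data row {idx + 1}") from None
            if conf > 1.0:
                conf = conf / 1000.0
        else:
            conf = 1.0
        key = _edge_key(a, b)
        edges[key] = max(edges.get(key, 0.0), conf)

    if n_self:
        log.info("%s: dropped %d self-loop(s)", path, n_self)
    kept = {k: v for k, v in edges.items() if v >= min_confidence}
    return EdgeList(edges=frozenset(kept), confidence=kept)


def write_edge_list(edge_list: EdgeList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("node1\tnode2\tcombined_score\n")
        for a, b in sorted(edge_list.edges):
            handle.write(f"{a}\t{b}\t{edge_list.confidence.get((a, b), 1.0):g}\n")


# ---------------------------------------------------------------------------
# graphs and symbol lists
# ---------------------------------------------------------------------------

_VALID_ROLES = {"pathway", "target", "drug"}


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """Write an attributed graph as GraphML; every node must carry a role."""
    for node, data in graph.nodes(data=True):
        role = data.get("role")
        if role not in _VALID_ROLES:
            raise SchemaError(
                f"node {node!r} has invalid role {role!r}; expected one of {sorted(_VALID_ROLES)}"
            )
    nx.write_graphml(graph, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def read_symbol_list(path: str | Path) -> list[str]:
    """Read one gene symbol per line (or first CSV column), normalized."""
    symbols: list[str] = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            token = line.split(",")[0].strip()
            if token:
                symbols.append(normalize_symbol(token))
    return symbols


def write_symbol_list(symbols: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for symbol in symbols:
            handle.write(f"{symbol}\n")
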