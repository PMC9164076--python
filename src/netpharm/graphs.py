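"""Tripartite pathway–target–drug networks and centrality-based hub isolation.

Two graph families live here:

* the **PTA network**: pathways, targets and drugs as three layers, with
  edges only between adjacent layers (pathway–target annotation edges and
  target–drug prediction edges).  Degree in this graph measures how widely
  connected each entity is across layers.
* the **PPI network** over the final target set, on which a two-stage
  topological filter isolates a hub: first keep targets in the top 30% by
  degree centrality (DC), then, within the induced subnetwork, keep targets
  in the top 30% by betweenness centrality (BC).

The filter rule used at both stages: drop zero-metric nodes, rank the rest,
and select the top ``ceil(fraction · n)`` where ``n`` is the *original*
table size, including every node tied with the boundary value.  Dropping
zeros first matters because disconnected targets are retained in centrality
tables with DC = BC = 0 and should never be "selected".  Betweenness is
normalized by (n−1)(n−2)/2 so that a node lying on every shortest path
between all other pairs scores exactly 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import StructureError
from .ingest import EdgeList

log = logging.getLogger(__name__)

DEFAULT_FRACTION = 0.30

LAYERS = ("pathway", "target", "drug")


def build_pta(
    pt_pairs: Iterable[tuple[str, str]],
    td_pairs: Iterable[tuple[str, str]],
) -> nx.Graph:
    """Build the tripartite Pathways–Targets–Drugs network.

    ``pt_pairs`` are (pathway, target) edges, ``td_pairs`` are
    (target, drug) edges.  Nodes are exactly the entities referenced by at
    least one pair, so candidates without any surviving link (a drug whose
    predicted targets all dropped out upstream) are excluded by construction.
    An identifier appearing in two different layers is a structure error.
    """
    pt_pairs = list(pt_pairs)
    td_pairs = list(td_pairs)
    pathways = {p for p, _ in pt_pairs}
    targets = {t for _, t in pt_pairs} | {t for t, _ in td_pairs}
    drugs = {d for _, d in td_pairs}

    for a, b, la, lb in (
        (pathways, targets, "pathway", "target"),
        (targets, drugs, "target", "drug"),
        (pathways, drugs, "pathway", "drug"),
    ):
        clash = a & b
        if clash:
            raise StructureError(f"identifier(s) {sorted(clash)} appear in both '{la}' and '{lb}' layers")

    graph = nx.Graph()
    for layer, nodes in zip(LAYERS, (pathways, targets, drugs)):
        graph.add_nodes_from(sorted(nodes), role=layer)
    graph.add_edges_from(pt_pairs)
    graph.add_edges_from(td_pairs)
    return graph


def _as_graph(net: EdgeList | nx.Graph) -> nx.Graph:
    return net.to_graph() if isinstance(net, EdgeList) else net


def degree_table(net: EdgeList | nx.Graph) -> pd.DataFrame:
    """Raw degree (DC) per node, sorted by descending degree then node id."""
    graph = _as_graph(net)
    rows = sorted(graph.degree(), key=lambda item: (-item[1], item[0]))
    frame = pd.DataFrame(rows, columns=["node", "dc"])
    if graph.number_of_nodes():
        roles = nx.get_node_attributes(graph, "role")
        if roles:
            frame["layer"] = [roles.get(n, "") for n in frame["node"]]
    return frame


def layer_degree_summary(graph: nx.Graph) -> dict[str, dict]:
    """Per-layer degree maxima and breakdowns for a PTA network.

    For targets, pathway-side and drug-side neighbor counts are reported
    separately on top of the total degree.
    """
    roles = nx.get_node_attributes(graph, "role")
    summary: dict[str, dict] = {}
    for layer in LAYERS:
        nodes = [n for n in graph if roles.get(n) == layer]
        if not nodes:
            continue
        degrees = {n: graph.degree(n) for n in nodes}
        top = max(degrees.items(), key=lambda item: (item[1], item[0]))
        summary[layer] = {"n_nodes": len(nodes), "max_degree_node": top[0], "max_degree": top[1]}
    # target-layer breakdown: pathway neighbors vs drug neighbors
    targets = [n for n in graph if roles.get(n) == "target"]
    breakdown = {}
    for t in targets:
        neigh_roles = [roles.get(m) for m in graph.neighbors(t)]
        breakdown[t] = {
            "pathway_degree": sum(1 for r in neigh_roles if r == "pathway"),
            "drug_degree": sum(1 for r in neigh_roles if r == "drug"),
        }
    if targets:
        summary["target"]["breakdown"] = breakdown
    return summary


def betweenness_table(net: EdgeList | nx.Graph) -> pd.DataFrame:
    """Normalized shortest-path betweenness (BC) per node.

    Normalization divides by (n−1)(n−2)/2, so BC ∈ [0, 1]; pair dependencies
    split equally among multiple shortest paths.
    """
    graph = _as_graph(net)
    bc = nx.betweenness_centrality(graph, normalized=True)
    rows = sorted(bc.items(), key=lambda item: (-item[1], item[0]))
    return pd.DataFrame(rows, columns=["node", "bc"])


def centrality_table(net: EdgeList | nx.Graph) -> pd.DataFrame:
    """Combined per-node DC and BC table, sorted by descending DC."""
    graph = _as_graph(net)
    bc = nx.betweenness_centrality(graph, normalized=True)
    rows = [(node, graph.degree(node), bc[node]) for node in graph]
    rows.sort(key=lambda item: (-item[1], -item[2], item[0]))
    return pd.DataFrame(rows, columns=["node", "dc", "bc"])


@dataclass(frozen=True)
class FilterOutcome:
    """Result of one top-fraction centrality filter stage."""

    selected: tuple[str, ...]  # metric-descending, ties by node id
    metric: str
    fraction: float
    n_input: int  # original table size, zeros included
    cutoff: int  # ceil(fraction * n_input)
    boundary_value: float | None  # metric value at the cutoff rank
    n_zero_excluded: int
    tied_at_boundary: tuple[str, ...]

    @property
    def selected_set(self) -> frozenset[str]:
        return frozenset(self.selected)


def top_fraction_filter(
    table: pd.DataFrame,
    metric: str,
    fraction: float = DEFAULT_FRACTION,
    keep_zeros: bool = False,
    include_ties: bool = True,
) -> FilterOutcome:
    """Select the top ``ceil(fraction·n)`` nodes by a centrality metric.

    ``n`` is the size of the input table *before* zero-metric nodes are
    excluded; nodes tied with the boundary value are all included (the
    default policy).  ``keep_zeros``/``include_ties`` expose the alternative
    conventions.
    """
    if table.empty:
        raise StructureError("top_fraction_filter() on an empty centrality table")
    if not 0 < fraction <= 1:
        raise StructureError(f"fraction must lie in (0, 1], got {fraction}")
    if metric not in table.columns:
        raise StructureError(f"metric '{metric}' not in table columns {list(table.columns)}")

    n_input = len(table)
    values = list(zip(table["node"], pd.to_numeric(table[metric])))
    if keep_zeros:
        candidates = values
        n_zero = 0
    else:
        candidates = [(node, v) for node, v in values if v > 0]
        n_zero = n_input - len(candidates)

    cutoff = math.ceil(fraction * n_input)
    if not candidates:
        log.warning("all %s values are zero; empty selection", metric)
        return FilterOutcome((), metric, fraction, n_input, cutoff, None, n_zero, ())

    candidates.sort(key=lambda item: (-item[1], item[0]))
    if cutoff >= len(candidates):
        selected = candidates
        boundary = candidates[-1][1]
    else:
        boundary = candidates[cutoff - 1][1]
        if include_ties:
            selected = [(node, v) for node, v in candidates if v >= boundary]
        else:
            selected = candidates[:cutoff]
    tied = tuple(node for node, v in candidates if v == boundary)
    return FilterOutcome(
        selected=tuple(node for node, _ in selected),
        metric=metric,
        fraction=fraction,
        n_input=n_input,
        cutoff=cutoff,
        boundary_value=boundary,
        n_zero_excluded=n_zero,
        tied_at_boundary=tied,
    )


@dataclass(frozen=True)
class HubResult:
    """Everything the two-stage filter produced, for reporting."""

    hub: tuple[str, ...]
    stage1: FilterOutcome
    stage2: FilterOutcome | None
    full_table: pd.DataFrame
    sub_table: pd.DataFrame | None
    subgraph: nx.Graph | None = None


def isolate_hub(
    ppi: EdgeList | nx.Graph,
    fraction: float = DEFAULT_FRACTION,
    keep_zeros: bool = False,
    include_ties: bool = True,
) -> HubResult:
    """Run the DC-then-BC double filter on a PPI network.

    Stage 1 filters the full graph on degree; the induced subgraph on the
    survivors is rebuilt and both centralities are *recomputed* inside it;
    stage 2 filters that subnetwork on betweenness.  The stage-2 survivors
    are the hub target(s).
    """
    graph = _as_graph(ppi)
    if graph.number_of_nodes() == 0:
        raise StructureError("isolate_hub() on an empty PPI network")
    full = centrality_table(graph)
    stage1 = top_fraction_filter(full, "dc", fraction, keep_zeros, include_ties)
    if not stage1.selected:
        return HubResult((), stage1, None, full, None, None)
    subgraph = graph.subgraph(stage1.selected).copy()
    sub = centrality_table(subgraph)
    stage2 = top_fraction_filter(sub, "bc", fraction, keep_zeros, include_ties)
    return HubResult(tuple(stage2.selected), stage1, stage2, full, sub, subgraph)


def hub_from_centrality_tables(
    full_table: pd.DataFrame,
    subnetwork_table: pd.DataFrame,
    fraction: float = DEFAULT_FRACTION,
) -> HubResult:
    """Double filter driven by precomputed centrality tables.

    Used when the underlying edge list is unavailable but published DC/BC
    tables are: stage 1 filters ``full_table`` on DC, stage 2 filters
    ``subnetwork_table`` (the recomputed subnetwork centralities) on BC.
    The subnetwork table must cover exactly the stage-1 survivors.
    """
    stage1 = top_fraction_filter(full_table, "dc", fraction)
    sub_nodes = set(subnetwork_table["node"])
    if sub_nodes != stage1.selected_set:
        raise StructureError(
            f"subnetwork table nodes {sorted(sub_nodes)} do not match "
            f"stage-1 survivors {sorted(stage1.selected_set)}"
        )
    stage2 = top_fraction_filter(subnetwork_table, "bc", fraction)
    return HubResult(tuple(stage2.selected), stage1, stage2, full_table, subnetwork_table, None)
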