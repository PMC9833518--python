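"""Annotation-overlap network: gene sets as nodes, shared genes as edges.

Nodes are the gene sets of the selected datasets (grouped by dataset via a
node attribute); an undirected edge joins two sets whose similarity
exceeds a minimum-weight threshold.  Edge weight is the Jaccard index
|A∩B| / |A∪B| by default (the overlap coefficient |A∩B| / min(|A|,|B|) is
available behind a flag).  Enrichment significance for one named query can
be overlaid as a per-node -log10(p) score; the underlying graph stays
constant across queries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import IO, Sequence

import networkx as nx

from .annotations import AnnotationDataset
from .enrichment import EnrichmentResult
from .errors import ParameterError, UnknownFormatError, UnknownQueryError

DEFAULT_MIN_WEIGHT = 0.05

EDGE_METRICS = ("jaccard", "overlap")


def _node_id(dataset_id: str, set_id: str) -> str:
    return f"{dataset_id}::{set_id}"


@dataclass
class AnnotationGraph:
    """A weighted, undirected gene-set overlap graph with optional overlay.

    Thin wrapper over a :class:`networkx.Graph`; node ids are
    ``"<dataset_id>::<set_id>"`` strings carrying ``dataset``, ``set_id``
    and ``size`` attributes, edges carry ``weight``.  ``overlay_query``
    holds the query name whose -log10(p) scores are currently stored in
    the ``score`` node attribute.
    """

    graph: nx.Graph
    min_weight: float
    edge_metric: str = "jaccard"
    overlay_query: str | None = field(default=None)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_weight(self, a: str, b: str) -> float | None:
        if self.graph.has_edge(a, b):
            return self.graph.edges[a, b]["weight"]
        return None


def _similarity(a: frozenset, b: frozenset, metric: str) -> float:
    inter = len(a & b)
    if inter == 0:
        return 0.0
    if metric == "jaccard":
        return inter / len(a | b)
    return inter / min(len(a), len(b))  # overlap coefficient


def build_graph(
    datasets: Sequence[AnnotationDataset],
    min_weight: float = DEFAULT_MIN_WEIGHT,
    edge_metric: str = "jaccard",
) -> AnnotationGraph:
    """Build the overlap graph for all gene sets across the given datasets.

    One node per gene set (cross-dataset edges included); edges with
    weight <= ``min_weight`` are omitted.  Nodes and edges are inserted in
    sorted order so repeated calls yield identical graphs.
    """
    if not datasets:
        raise ParameterError("build_graph requires at least one dataset")
    if not (0.0 <= min_weight < 1.0):
        raise ParameterError(
            f"min_weight must lie in [0, 1), got {min_weight}"
        )
    if edge_metric not in EDGE_METRICS:
        raise ParameterError(
            f"edge_metric must be one of {EDGE_METRICS}, got {edge_metric!r}"
        )
    graph = nx.Graph()
    members: dict[str, frozenset] = {}
    entries = []
    for ds in datasets:
        for gs in ds.gene_sets:
            entries.append((ds.dataset_id, gs.set_id, gs))
    entries.sort(key=lambda e: (e[0], e[1]))
    for dataset_id, set_id, gs in entries:
        node = _node_id(dataset_id, set_id)
        graph.add_node(
            node, dataset=dataset_id, set_id=set_id, size=len(gs.members)
        )
        members[node] = gs.members
    nodes = sorted(members)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            w = _similarity(members[a], members[b], edge_metric)
            if w > min_weight:
                graph.add_edge(a, b, weight=w)
    return AnnotationGraph(
        graph=graph, min_weight=min_weight, edge_metric=edge_metric
    )


def overlay_query(
    graph: AnnotationGraph,
    results: Sequence[EnrichmentResult],
    query_name: str,
) -> AnnotationGraph:
    """Store -log10(p_enrich) of one query as the ``score`` node attribute.

    Only nodes actually tested for that query receive a score; a previous
    overlay is fully replaced.  Topology is never touched.
    """
    available = sorted({r.query_name for r in results})
    if query_name not in available:
        raise UnknownQueryError(
            f"query {query_name!r} not found; available: "
            f"{', '.join(available)}"
        )
    for node in graph.graph.nodes:
        graph.graph.nodes[node].pop("score", None)
    for r in results:
        if r.query_name != query_name:
            continue
        node = _node_id(r.dataset_id, r.set_id)
        if node in graph.graph:
            graph.graph.nodes[node]["score"] = -math.log10(r.p_enrich)
    graph.overlay_query = query_name
    return graph


GRAPH_FORMATS = ("graphml", "cytoscape_json")


def export_graph(graph: AnnotationGraph, format: str, sink: IO) -> None:
    """Serialize the graph as GraphML or Cytoscape-compatible JSON.

    Node/edge order is already sorted at build time, so the output is
    deterministic; JSON keys are additionally sorted.
    """
    if format == "graphml":
        for line in nx.generate_graphml(graph.graph):
            sink.write(line + "\n")
    elif format == "cytoscape_json":
        payload = nx.cytoscape_data(graph.graph)
        json.dump(payload, sink, indent=1, sort_keys=True)
    else:
        raise UnknownFormatError(
            f"unknown graph format {format!r}; use one of {GRAPH_FORMATS}"
        )


def import_graph(source: IO, format: str) -> nx.Graph:
    """Re-read an exported graph (round-trip counterpart of export_graph)."""
    if format == "graphml":
        return nx.parse_graphml(source.read())
    if format == "cytoscape_json":
        return nx.cytoscape_graph(json.load(source))
    raise UnknownFormatError(
        f"unknown graph format {format!r}; use one of {GRAPH_FORMATS}"
    )
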