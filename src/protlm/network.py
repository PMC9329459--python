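"""Sequence-space similarity networks from all-against-all hit tables.

Nodes are sequences; an undirected edge joins two sequences whenever some
alignment between them is at least ``min_aln`` residues long with a search
probability of at least ``min_prob`` percent.  A query with qualifying
alignments in two (or more) non-overlapping query regions describes distinct
sequence segments, so it is duplicated into one suffixed node per region
(``id#1``, ``id#2``, ...) rather than conflating the regions in one node.
Connected components ("islands") and their size statistics summarize how a
generated set bridges otherwise separate regions of sequence space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .evalstats import AlignmentHit

__all__ = ["SimilarityGraph", "build_graph", "components", "bridge_report"]


@dataclass
class SimilarityGraph:
    """An undirected similarity graph with per-node class labels."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    node_class: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def write_edge_list(self, path: str | PathLike) -> None:
        with open(path, "w") as fh:
            for a, b in sorted(self.edges):
                fh.write(f"{a}\t{b}\n")

    def write_node_attributes(self, path: str | PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("node\tclass\n")
            for node in sorted(self.graph.nodes):
                fh.write(f"{node}\t{self.node_class.get(node, '')}\n")


def _interval_overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap length divided by the shorter interval's length."""
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    if hi < lo:
        return 0.0
    shorter = min(a[1] - a[0] + 1, b[1] - b[0] + 1)
    return (hi - lo + 1) / shorter


def _group_regions(
    hits: Sequence[AlignmentHit], max_overlap: float
) -> list[list[AlignmentHit]]:
    """Cluster a query's hits into regions of mutually overlapping intervals.

    Two hits belong to the same region when their query intervals overlap by
    more than ``max_overlap`` of the shorter interval (single-linkage).
    """
    ordered = sorted(hits, key=lambda h: (h.qstart, h.qend))
    regions: list[list[AlignmentHit]] = []
    spans: list[tuple[int, int]] = []
    for h in ordered:
        placed = False
        for i, span in enumerate(spans):
            if _interval_overlap_fraction((h.qstart, h.qend), span) > max_overlap:
                regions[i].append(h)
                spans[i] = (min(span[0], h.qstart), max(span[1], h.qend))
                placed = True
                break
        if not placed:
            regions.append([h])
            spans.append((h.qstart, h.qend))
    return regions


def build_graph(
    hits: Iterable[AlignmentHit],
    min_aln: int = 20,
    min_prob: float = 70.0,
    node_class: Mapping[str, str] | None = None,
    max_overlap: float = 0.10,
) -> SimilarityGraph:
    """Threshold hits into an undirected similarity graph.

    An edge joins query and target when the alignment spans at least
    ``min_aln`` residues with probability at least ``min_prob`` percent.
    Queries with qualifying alignments in multiple non-overlapping regions
    (pairwise query-interval overlap ≤ ``max_overlap`` of the shorter
    alignment) become one suffixed node per region.  Both directions of an
    asymmetric table induce the same undirected edge; self-hits are ignored.
    """
    if min_aln < 1:
        raise ValueError("min_aln must be >= 1")
    if not (0.0 <= min_prob <= 100.0):
        raise ValueError("min_prob must be a percentage")
    node_class = dict(node_class or {})

    qualifying: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        if h.aln_length >= min_aln and h.probability >= min_prob and h.query_id != h.target_id:
            qualifying.setdefault(h.query_id, []).append(h)

    sg = SimilarityGraph()
    for query in sorted(qualifying):
        regions = _group_regions(qualifying[query], max_overlap)
        multi = len(regions) > 1
        for r, region in enumerate(regions, start=1):
            qnode = f"{query}#{r}" if multi else query
            sg.graph.add_node(qnode)
            sg.node_class[qnode] = node_class.get(query, "")
            for h in region:
                tnode = h.target_id
                if tnode == qnode:
                    continue
                sg.graph.add_node(tnode)
                sg.node_class.setdefault(tnode, node_class.get(h.target_id, ""))
                sg.graph.add_edge(*sorted((qnode, tnode)))
    return sg


def components(graph: SimilarityGraph) -> list[set[str]]:
    """Connected components, largest first; ties by smallest member id."""
    comps = [set(c) for c in nx.connected_components(graph.graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def bridge_report(
    graph_with: SimilarityGraph, graph_without: SimilarityGraph
) -> dict[str, int]:
    """Compare component structure with and without a bridging sequence set.

    ``graph_without``'s nodes must be a subset of ``graph_with``'s.  Reports
    both graphs' component counts and largest-component sizes so the
    island-merging effect of the extra sequences is explicit.
    """
    if not graph_without.nodes <= graph_with.nodes:
        raise ValueError("graph_without nodes must be a subset of graph_with nodes")
    comps_with = components(graph_with) or [set()]
    comps_without = components(graph_without) or [set()]
    return {
        "n_components_with": len([c for c in comps_with if c]),
        "n_components_without": len([c for c in comps_without if c]),
        "largest_with": len(comps_with[0]),
        "largest_without": len(comps_without[0]),
    }
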