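"""Three-tier concept knowledge base with shortest-path queries.

Vertices are terms, concepts (CUIs), and semantic types; typed edges
connect concepts.  Path queries run over the concept tier only: the
distance between two concepts is the length of the shortest path over
undirected edges (concept-relation tables store each relation together
with its inverse, so undirected traversal is the faithful reading).
There may be multiple shortest paths but only one shortest path length;
the enumerator lists them in deterministic (lexicographic neighbor)
order up to a cap, recording per hop the set of relation-type labels of
all parallel edges on that hop.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Iterator, TextIO

import networkx as nx

INFINITE = math.inf


@dataclass(frozen=True)
class TypedEdge:
    cui_a: str
    cui_b: str
    relation_type: str


@dataclass
class PathSummary:
    """All shortest paths between one concept pair.

    ``paths`` holds one entry per shortest path: a sequence of
    relation-type label sets, one set per hop (collecting parallel
    edges).  ``truncated`` is set when more shortest paths exist than
    the cap allowed to enumerate.
    """

    distance: float  # nonnegative integer, or INFINITE
    paths: list[tuple[frozenset[str], ...]] = field(default_factory=list)
    truncated: bool = False


@dataclass
class ConceptGraph:
    """Typed, undirected concept graph plus the term and semantic-type
    tiers (stored for completeness; unused by path queries)."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    term_tier: dict[str, str] = field(default_factory=dict)  # term -> cui
    type_tier: dict[str, frozenset[str]] = field(default_factory=dict)  # cui -> semantic types

    @property
    def concepts(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def add_concept(self, cui: str) -> None:
        self.graph.add_node(cui)

    def add_edge(self, cui_a: str, cui_b: str, relation_type: str) -> None:
        """Add a typed edge; (a, b) and (b, a) are the same edge, self
        relations are dropped, duplicate triples collapse."""
        if cui_a == cui_b:
            return
        if self.graph.has_edge(cui_a, cui_b):
            self.graph[cui_a][cui_b]["types"].add(relation_type)
        else:
            self.graph.add_edge(cui_a, cui_b, types={relation_type})

    def edge_types(self, cui_a: str, cui_b: str) -> frozenset[str]:
        return frozenset(self.graph[cui_a][cui_b]["types"])

    def edges(self) -> Iterator[TypedEdge]:
        for a, b, data in self.graph.edges(data=True):
            x, y = sorted((a, b))
            for t in sorted(data["types"]):
                yield TypedEdge(x, y, t)

    def semantic_types_of(self, cui: str) -> frozenset[str]:
        return self.type_tier.get(cui, frozenset())

    def _neighbors(self, cui: str) -> list[str]:
        return sorted(self.graph.neighbors(cui))

    def distance(self, cui_a: str, cui_b: str, horizon: float = INFINITE) -> float:
        """Shortest-path length by breadth-first search; 0 for a == b,
        INFINITE for unknown or disconnected concepts or when the search
        exceeds *horizon*."""
        if cui_a not in self.graph or cui_b not in self.graph:
            return INFINITE
        if cui_a == cui_b:
            return 0
        frontier = {cui_a}
        seen = {cui_a}
        depth = 0
        while frontier and depth < horizon:
            depth += 1
            nxt = set()
            for node in frontier:
                for nb in self.graph.neighbors(node):
                    if nb == cui_b:
                        return depth
                    if nb not in seen:
                        seen.add(nb)
                        nxt.add(nb)
            frontier = nxt
        return INFINITE

    def shortest_path_summary(
        self, cui_a: str, cui_b: str, horizon: float = INFINITE, path_cap: int = 64
    ) -> PathSummary:
        """Enumerate all shortest paths (up to *path_cap*) between two
        concepts, visiting neighbors in lexicographic CUI order."""
        if path_cap < 1:
            raise ValueError("path_cap must be >= 1")
        dist = self.distance(cui_a, cui_b, horizon)
        if dist == 0 or dist == INFINITE:
            return PathSummary(dist)
        # BFS layering from the target to get exact distances-to-target
        dist_to_b: dict[str, int] = {cui_b: 0}
        frontier = [cui_b]
        d = 0
        while frontier and d < dist:
            d += 1
            nxt = []
            for node in frontier:
                for nb in self.graph.neighbors(node):
                    if nb not in dist_to_b:
                        dist_to_b[nb] = d
                        nxt.append(nb)
            frontier = nxt
        # DFS along strictly-decreasing distance-to-target, lexicographic
        paths: list[tuple[frozenset[str], ...]] = []
        truncated = False
        stack: list[tuple[str, tuple[frozenset[str], ...]]] = [(cui_a, ())]
        while stack:
            node, hops = stack.pop()
            if node == cui_b:
                if len(paths) < path_cap:
                    paths.append(hops)
                else:
                    truncated = True
                continue
            remaining = dist_to_b[node]
            succ = [
                nb
                for nb in self._neighbors(node)
                if dist_to_b.get(nb, INFINITE) == remaining - 1
            ]
            for nb in reversed(succ):  # stack order -> lexicographic output
                stack.append((nb, hops + (self.edge_types(node, nb),)))
        return PathSummary(dist, paths, truncated)

    def summary(self) -> dict:
        degrees = [d for _, d in self.graph.degree()]
        return {
            "concepts": self.graph.number_of_nodes(),
            "edges": self.graph.number_of_edges(),
            "isolated_concepts": sum(1 for d in degrees if d == 0),
            "degree_median": float(median(degrees)) if degrees else 0.0,
        }

    def write_summary(self, stream: TextIO) -> None:
        json.dump(self.summary(), stream, indent=2)


def load_graph(
    stream: Iterable[str],
    *,
    rrf: bool = False,
    cui1_col: int = 0,
    rel_col: int = 7,
    cui2_col: int = 4,
    concept_list: Iterable[str] = (),
    exclude_hubs: Iterable[str] = (),
    warnings: list[str] | None = None,
) -> ConceptGraph:
    """Load typed concept-concept relations from a
    `cui_a TAB cui_b TAB type` TSV or an RRF-style pipe-delimited
    relations table (column positions configurable).

    *concept_list* declares concepts that may have no edges (so isolated
    concepts are counted); *exclude_hubs* drops all edges touching very
    general, highly connected concepts.
    """
    graph = ConceptGraph()
    hubs = set(exclude_hubs)
    for cui in concept_list:
        graph.add_concept(cui)
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        if rrf:
            cols = line.split("|")
            try:
                a, b, t = cols[cui1_col], cols[cui2_col], cols[rel_col]
            except IndexError:
                if warnings is not None:
                    warnings.append(f"line {lineno}: too few columns")
                continue
        else:
            cols = line.split("\t")
            if len(cols) < 3:
                if warnings is not None:
                    warnings.append(f"line {lineno}: expected 3 tab-separated fields")
                continue
            a, b, t = cols[0], cols[1], cols[2]
        if not a or not b or not t:
            if warnings is not None:
                warnings.append(f"line {lineno}: empty field")
            continue
        if a in hubs or b in hubs:
            continue
        graph.add_edge(a, b, t)
    return graph
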