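"""Adjacency graph and the family-based DCJ distance.

For two genomes A and B over the same gene set, without duplicates, the
adjacency graph AG(A, B) is the bipartite multigraph whose two vertex
classes are the adjacencies of A and of B, with one edge per gene extremity
joining the two adjacencies that contain it.  Every vertex has degree one
(telomeric adjacency) or two, so the graph decomposes into paths and
cycles, and the DCJ distance is

    d_DCJ(A, B) = n - c - i/2,

with n genes, c cycles and i odd-length paths.  Equivalently each component
C contributes d(C) independently: |C|/2 - 1 for a cycle, (|C|-1)/2 for an
odd path, |C|/2 for an even path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .genomes import (
    Extremity,
    Genome,
    GenomeFormatError,
    TOL,
    genome_adjacencies,
)

CYCLE = "cycle"
ODD_PATH = "odd_path"
EVEN_PATH = "even_path"


@dataclass
class Component:
    """A connected component of an (optionally weighted) adjacency graph."""

    kind: str  # CYCLE, ODD_PATH or EVEN_PATH
    length: int  # |C|, number of edges
    weight: float = 0.0  # w(C), sum of edge weights (0 when unweighted)
    extremities: tuple[Extremity, ...] = field(default_factory=tuple)


@dataclass
class AdjacencyGraph:
    """Adjacency graph of two genomes plus its component decomposition."""

    graph: nx.MultiGraph
    n_genes: int
    components: list[Component]
    total_weight: float

    @property
    def n_cycles(self) -> int:
        return sum(1 for c in self.components if c.kind == CYCLE)

    @property
    def n_odd_paths(self) -> int:
        return sum(1 for c in self.components if c.kind == ODD_PATH)

    @property
    def n_even_paths(self) -> int:
        return sum(1 for c in self.components if c.kind == EVEN_PATH)


def build_adjacency_graph(
    genome_a: Genome,
    genome_b: Genome,
    edge_weights: dict[str, float] | None = None,
) -> AdjacencyGraph:
    """Build AG(A, B); with ``edge_weights`` (per gene name) the weighted
    variant AG_sigma, where both extremity edges of gene i carry the weight
    of its matching edge."""
    set_a, set_b = genome_a.gene_set, genome_b.gene_set
    if set_a != set_b:
        raise GenomeFormatError(
            "adjacency graph requires identical gene sets "
            f"({len(set_a)} vs {len(set_b)} genes, "
            f"symmetric difference {sorted(set_a ^ set_b)[:5]})"
        )
    adj_a = genome_adjacencies(genome_a)
    adj_b = genome_adjacencies(genome_b)
    locate_a = {ext: adj for adj in adj_a for ext in adj}
    locate_b = {ext: adj for adj in adj_b for ext in adj}

    graph = nx.MultiGraph()
    for adj in adj_a:
        graph.add_node(("A", adj))
    for adj in adj_b:
        graph.add_node(("B", adj))
    total_weight = 0.0
    for ext in sorted(locate_a, key=str):
        w = edge_weights.get(ext.gene, 0.0) if edge_weights else 0.0
        graph.add_edge(("A", locate_a[ext]), ("B", locate_b[ext]), key=ext, weight=w)
        total_weight += w

    components = _decompose(graph)
    return AdjacencyGraph(graph, genome_a.n_genes, components, total_weight)


def _decompose(graph: nx.MultiGraph) -> list[Component]:
    components: list[Component] = []
    for nodes in nx.connected_components(graph):
        sub = graph.subgraph(nodes)
        length = sub.number_of_edges()
        weight = sum(d.get("weight", 0.0) for _, _, d in sub.edges(data=True))
        is_cycle = all(deg == 2 for _, deg in sub.degree())
        if is_cycle:
            kind = CYCLE
        else:
            kind = ODD_PATH if length % 2 == 1 else EVEN_PATH
        exts = tuple(sorted((k for _, _, k in sub.edges(keys=True)), key=str))
        components.append(Component(kind, length, weight, exts))
    # deterministic order: by smallest extremity label, telomere-first kinds
    components.sort(key=lambda c: str(c.extremities[0]) if c.extremities else "")
    return components


def decompose_components(ag: AdjacencyGraph) -> list[Component]:
    return ag.components


def component_contribution(component: Component) -> float:
    """Distance contribution d(C) of an unweighted component."""
    length = component.length
    if component.kind == CYCLE:
        return length / 2 - 1
    if component.kind == ODD_PATH:
        return (length - 1) / 2
    return length / 2


def dcj_census(genome_a: Genome, genome_b: Genome) -> tuple[int, int, int]:
    """(n, c, i): genes, cycles, odd paths of AG(A, B)."""
    ag = build_adjacency_graph(genome_a, genome_b)
    return ag.n_genes, ag.n_cycles, ag.n_odd_paths


def dcj_distance(genome_a: Genome, genome_b: Genome) -> float:
    """Family-based DCJ distance n - c - i/2 (duplicate-free genomes).

    Computed both via the closed formula and via per-component
    contributions; the two routes must agree and the result must be a
    non-negative integer.
    """
    ag = build_adjacency_graph(genome_a, genome_b)
    n, c, i = ag.n_genes, ag.n_cycles, ag.n_odd_paths
    dist = n - c - i / 2
    by_components = sum(component_contribution(comp) for comp in ag.components)
    if abs(dist - by_components) > TOL:
        raise AssertionError(
            f"internal inconsistency: n-c-i/2 = {dist} but sum d(C) = {by_components}"
        )
    if dist < -TOL or abs(dist - round(dist)) > TOL:
        raise AssertionError(f"DCJ distance {dist} is not a non-negative integer")
    return float(round(dist)) if not math.isnan(dist) else dist
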