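"""Family-free core: gene similarity graph, matchings, reduced genomes,
the weighted adjacency graph, and the measures d_sigma, s_sigma, F_alpha.

In the family-free setting the two genomes have disjoint gene symbol sets
and are related only through pairwise normalized similarities sigma in
(0, 1].  A matching M in the gene similarity graph selects putative
ortholog pairs; deleting unsaturated genes and renaming each matched pair
to a common label 1..|M| yields the reduced genomes A^M, B^M, whose
adjacency graph inherits sigma as edge weights (both extremity edges of
pair i carry sigma(e_i), so the graph weighs exactly 2 w(M)).

The weighted distance uses f(C) = 2|C| - w(C) in place of |C|:

    d_sigma(C) = f(C)/2 - 1         (cycle)
                 (f(C) - 1)/2       (odd path)
                 f(C)/2             (even path)

and summing over components gives d_sigma(A^M, B^M) =
d_DCJ(A^M, B^M) + |M| - w(M).  When every matched edge has sigma = 1 this
reduces to the family-based distance.  The similarity s_sigma is the
normalized total component weight: w(C)/|C| for cycles, w(C)/(|C|+1) for
odd paths, w(C)/(|C|+2) for even paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .adjacency import (
    CYCLE,
    ODD_PATH,
    AdjacencyGraph,
    Component,
    build_adjacency_graph,
    dcj_distance,
)
from .genomes import (
    Chromosome,
    Genome,
    GenomeFormatError,
    SignedGene,
    SimilarityTable,
    TOL,
)


@dataclass
class GeneSimilarityGraph:
    """Weighted bipartite graph GS_sigma(A, B) over the two gene sets."""

    part_a: tuple[str, ...]  # genes of A, genome order
    part_b: tuple[str, ...]
    edges: dict[tuple[str, str], float]

    def degree_a(self, gene: str) -> int:
        return sum(1 for (a, _b) in self.edges if a == gene)

    def degree_b(self, gene: str) -> int:
        return sum(1 for (_a, b) in self.edges if b == gene)


def build_gs_graph(
    genome_a: Genome, genome_b: Genome, table: SimilarityTable
) -> GeneSimilarityGraph:
    """One edge per positive similarity entry; validates gene membership
    and the family-free disjointness of the two gene sets."""
    set_a, set_b = genome_a.gene_set, genome_b.gene_set
    if set_a & set_b:
        raise GenomeFormatError("family-free genomes must have disjoint gene sets")
    for (a, b), _s in table.items():
        if a not in set_a:
            raise GenomeFormatError(f"similarity table references unknown gene {a!r}")
        if b not in set_b:
            raise GenomeFormatError(f"similarity table references unknown gene {b!r}")
    part_a = tuple(g.name for g in genome_a.genes())
    part_b = tuple(g.name for g in genome_b.genes())
    return GeneSimilarityGraph(part_a, part_b, dict(table.entries))


@dataclass(frozen=True)
class Matching:
    """A matching in the gene similarity graph.

    ``edges`` holds (gene_a, gene_b, sigma) triples, pairwise vertex-disjoint.
    """

    edges: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        sat_a = [a for a, _b, _s in self.edges]
        sat_b = [b for _a, b, _s in self.edges]
        if len(set(sat_a)) != len(sat_a) or len(set(sat_b)) != len(sat_b):
            raise GenomeFormatError("edge set is not a matching (shared endpoint)")

    @classmethod
    def from_pairs(
        cls, pairs, graph: GeneSimilarityGraph | None = None, table: SimilarityTable | None = None
    ) -> "Matching":
        edges = []
        for a, b in pairs:
            if graph is not None:
                if (a, b) not in graph.edges:
                    raise GenomeFormatError(f"pair ({a}, {b}) is not a similarity edge")
                edges.append((a, b, graph.edges[(a, b)]))
            elif table is not None:
                s = table.get(a, b)
                if s <= 0:
                    raise GenomeFormatError(f"pair ({a}, {b}) is not a similarity edge")
                edges.append((a, b, s))
            else:
                raise ValueError("need a graph or a table to look up sigma")
        return cls(tuple(edges))

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def weight(self) -> float:
        return sum(s for _a, _b, s in self.edges)

    @property
    def saturated_a(self) -> frozenset[str]:
        return frozenset(a for a, _b, _s in self.edges)

    @property
    def saturated_b(self) -> frozenset[str]:
        return frozenset(b for _a, b, _s in self.edges)

    def pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset((a, b) for a, b, _s in self.edges)


EMPTY_MATCHING = Matching(())


def is_maximal_matching(graph: GeneSimilarityGraph, matching: Matching) -> bool:
    """True iff every similarity edge has at least one saturated endpoint."""
    for a, b, _s in matching.edges:
        if (a, b) not in graph.edges:
            raise GenomeFormatError(f"matching edge ({a}, {b}) not in the graph")
    sat_a, sat_b = matching.saturated_a, matching.saturated_b
    return all(a in sat_a or b in sat_b for (a, b) in graph.edges)


@dataclass
class ReducedGenomePair:
    """Reduced genomes A^M, B^M over the common label set {1..|M|}.

    ``label_sigma`` maps each label to the sigma of its matching edge;
    these become the edge weights of the weighted adjacency graph.
    """

    genome_a: Genome
    genome_b: Genome
    matching: Matching
    labels: dict[str, int]  # source gene name -> label
    label_sigma: dict[str, float]  # label (as gene name string) -> sigma


def reduce_genomes(genome_a: Genome, genome_b: Genome, matching: Matching) -> ReducedGenomePair:
    """Delete unsaturated genes (joining their neighbors), rename matched
    pairs to labels 1..|M| assigned in order of first occurrence along A."""
    sat_a, sat_b = matching.saturated_a, matching.saturated_b
    b_for_a = {a: b for a, b, _s in matching.edges}
    sigma_for_a = {a: s for a, _b, s in matching.edges}

    labels: dict[str, int] = {}
    label_sigma: dict[str, float] = {}
    next_label = 1
    for gene in genome_a.genes():
        if gene.name in sat_a:
            labels[gene.name] = next_label
            labels[b_for_a[gene.name]] = next_label
            label_sigma[str(next_label)] = sigma_for_a[gene.name]
            next_label += 1

    def reduce_one(genome: Genome, saturated: frozenset[str]) -> Genome:
        chroms = []
        for chrom in genome.chromosomes:
            kept = tuple(
                SignedGene(str(labels[g.name]), g.forward)
                for g in chrom.genes
                if g.name in saturated
            )
            if kept:
                chroms.append(Chromosome(kept, chrom.circular))
        return Genome(genome.name + "^M", tuple(chroms))

    return ReducedGenomePair(
        reduce_one(genome_a, sat_a),
        reduce_one(genome_b, sat_b),
        matching,
        labels,
        label_sigma,
    )


def build_weighted_adjacency_graph(reduced: ReducedGenomePair) -> AdjacencyGraph:
    """AG_sigma(A^M, B^M); its total weight is exactly 2 w(M)."""
    ag = build_adjacency_graph(reduced.genome_a, reduced.genome_b, reduced.label_sigma)
    expected = 2 * reduced.matching.weight
    if abs(ag.total_weight - expected) > TOL:
        raise AssertionError(
            f"weighted adjacency graph weighs {ag.total_weight}, expected 2 w(M) = {expected}"
        )
    return ag


def weighted_component_contribution(component: Component) -> float:
    """d_sigma(C) with f(C) = 2|C| - w(C)."""
    f = 2 * component.length - component.weight
    if component.kind == CYCLE:
        return f / 2 - 1
    if component.kind == ODD_PATH:
        return (f - 1) / 2
    return f / 2


def dsigma(reduced: ReducedGenomePair) -> float:
    """Weighted DCJ distance of the reduced genomes.

    Computed as the sum of component contributions and cross-checked
    against d_DCJ(A^M, B^M) + |M| - w(M); a disagreement beyond tolerance
    indicates a component-classification bug and raises.
    """
    matching = reduced.matching
    if len(matching) == 0:
        return 0.0
    ag = build_weighted_adjacency_graph(reduced)
    by_components = sum(weighted_component_contribution(c) for c in ag.components)
    direct = (
        dcj_distance(reduced.genome_a, reduced.genome_b)
        + len(matching)
        - matching.weight
    )
    if abs(by_components - direct) > TOL:
        raise AssertionError(
            f"d_sigma routes disagree: component sum {by_components} vs "
            f"d_DCJ + |M| - w(M) = {direct}"
        )
    return by_components


def dsigma_from_counts(size: int, weight: float, cycles: int, odd_paths: int) -> float:
    """d_sigma from matching-level aggregates:
    (|M| - c - i/2) + |M| - w(M).  Useful when only the census of the
    weighted adjacency graph is known, not the individual edges."""
    return (size - cycles - odd_paths / 2) + size - weight


def ssigma(reduced: ReducedGenomePair) -> float:
    """Family-free DCJ similarity s_sigma: normalized total component weight."""
    if len(reduced.matching) == 0:
        return 0.0
    ag = build_weighted_adjacency_graph(reduced)
    total = 0.0
    for comp in ag.components:
        if comp.kind == CYCLE:
            total += comp.weight / comp.length
        elif comp.kind == ODD_PATH:
            total += comp.weight / (comp.length + 1)
        else:
            total += comp.weight / (comp.length + 2)
    return total


def f_alpha(reduced: ReducedGenomePair, alpha: float) -> float:
    """Parameterized similarity F_alpha = alpha * s_sigma + (1 - alpha) * w(M)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return alpha * ssigma(reduced) + (1 - alpha) * reduced.matching.weight
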