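"""Synthetic instances: a DCJ-evolution simulator with duplications and
losses, the hardness-construction gadgets, and worked-example fixtures.

The simulator produces a pair of genomes where B is derived from A by a
configurable number of random inversions/translocations plus gene
duplications and losses, together with a noisy similarity table whose
ground-truth orthology is returned as a matching.  It emulates the shape
of simulated-evolution benchmarks (structural events only; no sequence
evolution — similarities are drawn directly).

The gadgets are constructive reductions: ``exemplar_to_ff_instance`` maps
an exemplar-distance instance to a family-free instance with unit
similarities, and ``counterexample_instance`` builds the family showing
that the maximum-weight matching can be arbitrarily far from the optimal
one (ratio 2/epsilon between the all-weight-1 and all-weight-(1-eps)
matchings).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .family_free import Matching
from .genomes import (
    Chromosome,
    Genome,
    GenomeFormatError,
    SignedGene,
    SimilarityTable,
)

LINEAR = "linear"
CIRCULAR = "circular"


# ---------------------------------------------------------------------------
# Simulator


@dataclass
class SimulationConfig:
    """Conditions for one simulated genome pair.

    Rates are per gene: the number of duplications (losses) is drawn
    binomially over the gene count.  True ortholog pairs get sigma drawn
    from 1 - U(0, weight_noise); paralog edges (to duplicated copies) and
    spurious edges get sigma uniform over ``paralog_weight_range``.
    """

    n_genes: int = 100
    n_chromosomes: int = 1
    topology: str = LINEAR
    n_rearrangements: int = 3
    dup_rate: float = 0.01
    loss_rate: float = 0.01
    weight_noise: float = 0.1
    spurious_edge_rate: float = 0.02
    paralog_weight_range: tuple[float, float] = (0.2, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("need at least one gene and one chromosome")
        if self.dup_rate < 0 or self.loss_rate < 0 or self.spurious_edge_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.weight_noise < 1:
            raise ValueError("weight_noise must be in [0, 1)")
        lo, hi = self.paralog_weight_range
        if not (0 < lo <= hi < 1):
            raise ValueError("paralog_weight_range must lie inside (0, 1)")
        if self.topology not in (LINEAR, CIRCULAR):
            raise ValueError(f"unknown topology {self.topology!r}")


def preset(r: int, n_genes: int = 100, seed: int = 0) -> SimulationConfig:
    """Rate presets r in {1, 2, 5}: duplication/loss and rearrangement
    per-gene rates scaled r-fold from the base setting (0.01 and 0.025
    expected events per gene at desk scale)."""
    if r not in (1, 2, 5):
        raise ValueError("preset r must be 1, 2 or 5")
    return SimulationConfig(
        n_genes=n_genes,
        n_rearrangements=max(1, round(0.025 * r * n_genes)),
        dup_rate=0.01 * r,
        loss_rate=0.01 * r,
        seed=seed,
    )


def simulate_pair(
    cfg: SimulationConfig,
) -> tuple[Genome, Genome, SimilarityTable, Matching]:
    """Simulate (A, B, sigma, ground-truth matching); reproducible from seed."""
    rng = np.random.default_rng(cfg.seed)
    circular = cfg.topology == CIRCULAR

    a_names = [f"a{i}" for i in range(1, cfg.n_genes + 1)]
    signs = rng.random(cfg.n_genes) < 0.5
    # partition genes over chromosomes
    bounds = sorted(
        rng.choice(np.arange(1, cfg.n_genes), size=cfg.n_chromosomes - 1, replace=False)
    ) if cfg.n_chromosomes > 1 else []
    pieces = np.split(np.arange(cfg.n_genes), bounds)
    a_chroms = tuple(
        Chromosome(
            tuple(SignedGene(a_names[i], bool(signs[i])) for i in piece), circular
        )
        for piece in pieces
        if len(piece)
    )
    genome_a = Genome("A", a_chroms)

    # B starts as a copy of A with renamed genes; truth maps a<i> -> b<i>
    twin = {f"a{i}": f"b{i}" for i in range(1, cfg.n_genes + 1)}
    b_chroms = [
        [SignedGene(twin[g.name], g.forward) for g in chrom.genes]
        for chrom in a_chroms
    ]

    for _ in range(cfg.n_rearrangements):
        _random_rearrangement(b_chroms, circular, rng)

    # losses
    n_loss = rng.binomial(cfg.n_genes, cfg.loss_rate)
    lost: set[str] = set()
    for _ in range(n_loss):
        flat = [(ci, gi) for ci, ch in enumerate(b_chroms) for gi in range(len(ch))]
        if len(flat) <= 1:
            break
        ci, gi = flat[rng.integers(len(flat))]
        lost.add(b_chroms[ci][gi].name)
        del b_chroms[ci][gi]
        if not b_chroms[ci]:
            del b_chroms[ci]

    # duplications: copies get fresh names and paralog edges to the ortholog
    paralog_of: dict[str, str] = {}
    n_dup = rng.binomial(cfg.n_genes, cfg.dup_rate)
    for d in range(n_dup):
        flat = [(ci, gi) for ci, ch in enumerate(b_chroms) for gi in range(len(ch))]
        if not flat:
            break
        ci, gi = flat[rng.integers(len(flat))]
        src = b_chroms[ci][gi]
        if src.name in paralog_of:  # copy of a copy: same ancestor
            ancestor = paralog_of[src.name]
        elif src.name in twin.values():
            ancestor = src.name
        else:
            ancestor = src.name
        copy = SignedGene(f"{src.name}.d{d + 1}", bool(rng.random() < 0.5))
        paralog_of[copy.name] = ancestor
        tc, tg = flat[rng.integers(len(flat))]
        b_chroms[tc].insert(tg, copy)

    genome_b = Genome(
        "B", tuple(Chromosome(tuple(ch), circular) for ch in b_chroms if ch)
    )

    # similarity table
    entries: dict[tuple[str, str], float] = {}
    true_edges = []
    back = {v: k for k, v in twin.items()}
    surviving = {g.name for g in genome_b.genes()}
    for b_name in sorted(surviving & set(twin.values())):
        a_name = back[b_name]
        s = 1.0 - rng.random() * cfg.weight_noise if cfg.weight_noise > 0 else 1.0
        entries[(a_name, b_name)] = s
        true_edges.append((a_name, b_name, s))
    lo, hi = cfg.paralog_weight_range
    for copy_name, ancestor in sorted(paralog_of.items()):
        root = ancestor.split(".")[0]
        a_name = back.get(root)
        if a_name is None:
            continue
        entries[(a_name, copy_name)] = float(rng.uniform(lo, hi))
    if cfg.spurious_edge_rate > 0:
        b_all = sorted(surviving)
        for a_name in a_names:
            for b_name in b_all:
                if (a_name, b_name) in entries:
                    continue
                if rng.random() < cfg.spurious_edge_rate:
                    entries[(a_name, b_name)] = float(rng.uniform(lo, hi))
    table = SimilarityTable(entries)
    return genome_a, genome_b, table, Matching(tuple(true_edges))


def _random_rearrangement(
    chroms: list[list[SignedGene]], circular: bool, rng: np.random.Generator
) -> None:
    """Apply one random inversion or (between linear chromosomes) translocation."""
    sizes = [len(c) for c in chroms]
    can_translocate = not circular and len(chroms) >= 2
    if can_translocate and rng.random() < 0.3:
        ci, cj = rng.choice(len(chroms), size=2, replace=False)
        pi = int(rng.integers(0, sizes[ci] + 1))
        pj = int(rng.integers(0, sizes[cj] + 1))
        tail_i, tail_j = chroms[ci][pi:], chroms[cj][pj:]
        chroms[ci][pi:], chroms[cj][pj:] = tail_j, tail_i
        # drop emptied chromosomes (a translocation may be a fusion)
        for idx in sorted((ci, cj), reverse=True):
            if not chroms[idx]:
                del chroms[idx]
    else:
        weights = np.array(sizes, dtype=float) / sum(sizes)
        ci = int(rng.choice(len(chroms), p=weights))
        m = sizes[ci]
        i = int(rng.integers(0, m))
        j = int(rng.integers(i, m)) + 1
        segment = [g.reverse() for g in reversed(chroms[ci][i:j])]
        chroms[ci][i:j] = segment


# ---------------------------------------------------------------------------
# Hardness gadgets


@dataclass(frozen=True)
class GadgetParams:
    k: int
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must be in [0, 1)")


def counterexample_instance(
    params: GadgetParams,
) -> tuple[Genome, Genome, SimilarityTable]:
    """Instance family on which the maximum-weight matching is unboundedly
    suboptimal.

    A has 2k genes 1, -2, ..., (2k-1), -2k on one linear chromosome; B has
    genes -(2k+1), (2k+2), ..., with alternating orientation.  sigma is 1
    on the 2k parallel pairs (i, 2k+i) and 1 - epsilon on the k pairs
    (i, 2k+i+1) for odd i.
    """
    k, eps = params.k, params.epsilon
    genes_a = tuple(
        SignedGene(str(i), forward=(i % 2 == 1)) for i in range(1, 2 * k + 1)
    )
    genes_b = tuple(
        SignedGene(str(2 * k + i), forward=(i % 2 == 0)) for i in range(1, 2 * k + 1)
    )
    genome_a = Genome("A", (Chromosome(genes_a),))
    genome_b = Genome("B", (Chromosome(genes_b),))
    entries = {(str(i), str(2 * k + i)): 1.0 for i in range(1, 2 * k + 1)}
    if eps > 0:
        for i in range(1, 2 * k, 2):
            entries[(str(i), str(2 * k + i + 1))] = 1.0 - eps
    return genome_a, genome_b, SimilarityTable(entries)


def counterexample_matchings(
    params: GadgetParams, table: SimilarityTable
) -> tuple[Matching, Matching]:
    """(M, M*): the maximum-weight all-1 matching and the all-(1-eps) one."""
    k = params.k
    m_full = Matching(
        tuple((str(i), str(2 * k + i), 1.0) for i in range(1, 2 * k + 1))
    )
    m_star = Matching(
        tuple(
            (str(i), str(2 * k + i + 1), table.get(str(i), str(2 * k + i + 1)))
            for i in range(1, 2 * k, 2)
        )
    )
    return m_full, m_star


def exemplar_to_ff_instance(
    genome_a: Genome, genome_b: Genome
) -> tuple[Genome, Genome, SimilarityTable]:
    """Relabel an exemplar-distance instance into a family-free one.

    The i-th gene of A becomes ``i`` and the j-th gene of B becomes
    ``j + |A|`` (orientations preserved); sigma = 1 exactly between genes
    of the same family.  A must be duplicate-free and every family of
    either genome must occur in the other.
    """
    if genome_a.has_duplicates():
        raise GenomeFormatError("A must have at most one copy per family")
    fams_a = {g.name for g in genome_a.genes()}
    fams_b = {g.name for g in genome_b.genes()}
    if fams_a != fams_b:
        raise GenomeFormatError(
            f"families not shared by both genomes: {sorted(fams_a ^ fams_b)[:5]}"
        )
    n_a = genome_a.n_genes

    def relabel(genome: Genome, offset: int, suffix: str) -> tuple[Genome, list[str]]:
        idx = offset
        fams: list[str] = []
        chroms = []
        for chrom in genome.chromosomes:
            genes = []
            for g in chrom.genes:
                idx += 1
                genes.append(SignedGene(str(idx), g.forward))
                fams.append(g.name)
            chroms.append(Chromosome(tuple(genes), chrom.circular))
        return Genome(genome.name + suffix, tuple(chroms)), fams

    ff_a, fam_of_a = relabel(genome_a, 0, "_F")
    ff_b, fam_of_b = relabel(genome_b, n_a, "_F")
    entries = {
        (str(i + 1), str(n_a + j + 1)): 1.0
        for i, fa in enumerate(fam_of_a)
        for j, fb in enumerate(fam_of_b)
        if fa == fb
    }
    return ff_a, ff_b, SimilarityTable(entries)


def ff_matching_to_exemplar(
    matching: Matching, genome_a: Genome, genome_b: Genome
) -> tuple[Genome, Genome]:
    """Map a matching of the transformed instance back to exemplar genomes.

    Edge (i, k) keeps the i-th gene occurrence of A and the (k - |A|)-th of
    B; everything else is excised, order and orientation preserved.
    """
    n_a = genome_a.n_genes
    keep_a = set()
    keep_b = set()
    for a, b, _s in matching.edges:
        i, k = int(a), int(b)
        if not (1 <= i <= n_a and n_a < k <= n_a + genome_b.n_genes):
            raise GenomeFormatError(
                f"matching edge ({a}, {b}) is not over the transformed instance"
            )
        keep_a.add(i)
        keep_b.add(k - n_a)

    def project(genome: Genome, keep: set[int], suffix: str) -> Genome:
        idx = 0
        chroms = []
        for chrom in genome.chromosomes:
            genes = []
            for g in chrom.genes:
                idx += 1
                if idx in keep:
                    genes.append(g)
            if genes:
                chroms.append(Chromosome(tuple(genes), chrom.circular))
        return Genome(genome.name + suffix, tuple(chroms), allow_duplicates=True)

    return project(genome_a, keep_a, "_X"), project(genome_b, keep_b, "_X")


# ---------------------------------------------------------------------------
# Worked-example fixtures


@dataclass
class MatchingSummary:
    """Aggregates of a matching whose individual edges are not known."""

    size: int
    weight: float
    cycles: int
    odd_paths: int


@dataclass
class FixtureBundle:
    genome_a: Genome
    genome_b: Genome
    similarities: SimilarityTable | None = None
    matching_summaries: dict[str, MatchingSummary] = field(default_factory=dict)
    source_a: Genome | None = None  # pre-relabeling genomes, for gadget fixtures
    source_b: Genome | None = None


def load_fixture(name: str) -> FixtureBundle:
    """Worked examples used throughout: ``fig1``, ``fig2``, ``fig4``,
    ``fig5_k3``."""
    if name == "fig1":
        a, b = parse_pair(">A\n-1 3 4 2 |\n>B\n-2 1 4 3 |")
        return FixtureBundle(a, b)
    if name == "fig2":
        a, b = parse_pair(">A\n1 2 3 4 5 |\n>B\n6 -7 -8 -9 10 11 |")
        return FixtureBundle(
            a,
            b,
            matching_summaries={
                "M1": MatchingSummary(size=5, weight=2.7, cycles=3, odd_paths=2),
                "M2": MatchingSummary(size=5, weight=3.9, cycles=2, odd_paths=2),
            },
        )
    if name == "fig4":
        src_a, src_b = parse_pair(
            ">A\na c -b d |\n>B\n-c d a c b -b |", allow_duplicates=True
        )
        ff_a, ff_b, table = exemplar_to_ff_instance(src_a, src_b)
        return FixtureBundle(ff_a, ff_b, table, source_a=src_a, source_b=src_b)
    if name == "fig5_k3":
        a, b, table = counterexample_instance(GadgetParams(k=3))
        return FixtureBundle(a, b, table)
    raise KeyError(f"unknown fixture {name!r}")


def parse_pair(text: str, allow_duplicates: bool = False) -> tuple[Genome, Genome]:
    from .genomes import parse_genomes

    genomes = parse_genomes(text, allow_duplicates=allow_duplicates)
    if len(genomes) != 2:
        raise GenomeFormatError(f"expected exactly 2 genomes, got {len(genomes)}")
    return genomes[0], genomes[1]


# ---------------------------------------------------------------------------
# Random test instances


def random_instance(
    rng: np.random.Generator,
    max_genes: int = 6,
    max_edges: int = 12,
    allow_circular: bool = True,
) -> tuple[Genome, Genome, SimilarityTable]:
    """Small random family-free instance with random weights, mixed
    chromosome counts and topologies; used for oracle cross-checks."""
    def random_genome(tag: str) -> Genome:
        n = int(rng.integers(1, max_genes + 1))
        names = [f"{tag}{i}" for i in range(1, n + 1)]
        n_chrom = int(rng.integers(1, min(3, n) + 1))
        cut_points = sorted(
            rng.choice(np.arange(1, n), size=n_chrom - 1, replace=False)
        ) if n_chrom > 1 else []
        pieces = np.split(np.arange(n), cut_points)
        chroms = []
        for piece in pieces:
            if not len(piece):
                continue
            genes = tuple(
                SignedGene(names[i], bool(rng.random() < 0.5)) for i in piece
            )
            circ = allow_circular and bool(rng.random() < 0.3)
            chroms.append(Chromosome(genes, circ))
        return Genome(tag.upper(), tuple(chroms))

    genome_a = random_genome("a")
    genome_b = random_genome("b")
    pairs = [(a, b) for a in genome_a.gene_set for b in genome_b.gene_set]
    order = rng.permutation(len(pairs))
    n_edges = int(rng.integers(0, min(max_edges, len(pairs)) + 1))
    entries = {}
    for idx in order[:n_edges]:
        a, b = pairs[idx]
        entries[(a, b)] = float(np.round(rng.uniform(0.05, 1.0), 3))
    return genome_a, genome_b, SimilarityTable(entries)


def random_exemplar_instance(
    rng: np.random.Generator,
    max_families: int = 6,
    topology: str = LINEAR,
) -> tuple[Genome, Genome]:
    """Random (1,2)-exemplar instance: each family once in A, once or twice
    in B, arranged on one chromosome per genome."""
    n = int(rng.integers(1, max_families + 1))
    fams = [f"f{i}" for i in range(1, n + 1)]
    circ = topology == CIRCULAR
    order_a = rng.permutation(n)
    genes_a = tuple(
        SignedGene(fams[i], bool(rng.random() < 0.5)) for i in order_a
    )
    copies = []
    for fam in fams:
        copies.append(fam)
        if rng.random() < 0.5:
            copies.append(fam)
    order_b = rng.permutation(len(copies))
    genes_b = tuple(
        SignedGene(copies[i], bool(rng.random() < 0.5)) for i in order_b
    )
    genome_a = Genome("A", (Chromosome(genes_a, circ),))
    genome_b = Genome("B", (Chromosome(genes_b, circ),), allow_duplicates=True)
    return genome_a, genome_b
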