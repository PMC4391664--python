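"""Genome data model and plain-text I/O.

Genomes are sequences of chromosomes; a chromosome is an oriented sequence
of signed genes and is either linear or circular.  The file dialect follows
the UniMoG convention used by DCJ tools: a ``>name`` header starts a genome,
chromosomes are whitespace-separated signed gene tokens terminated by ``|``
(linear) or ``)`` (circular), and ``#`` starts a comment.

Gene similarities are read from a three-column TSV (gene_a, gene_b, sigma)
with sigma in (0, 1]; a pair absent from the table has similarity 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

TOL = 1e-9

_GENE_RE = re.compile(r"^-?[A-Za-z0-9_.]+$")

HEAD = "h"
TAIL = "t"


class GenomeFormatError(ValueError):
    """Raised on malformed genome or similarity input."""


@dataclass(frozen=True, order=True)
class SignedGene:
    """An oriented gene: ``name`` plus reading direction."""

    name: str
    forward: bool = True

    def __post_init__(self) -> None:
        if not self.name or not _GENE_RE.match(self.name) or self.name.startswith("-"):
            raise GenomeFormatError(f"malformed gene token: {self.name!r}")

    def reverse(self) -> "SignedGene":
        return SignedGene(self.name, not self.forward)

    def __str__(self) -> str:
        return self.name if self.forward else "-" + self.name

    @classmethod
    def from_token(cls, token: str) -> "SignedGene":
        if not _GENE_RE.match(token):
            raise GenomeFormatError(f"malformed gene token: {token!r}")
        if token.startswith("-"):
            return cls(token[1:], False)
        return cls(token, True)

    # Extremities: a forward gene reads tail -> head along the chromosome.
    @property
    def left_side(self) -> str:
        return TAIL if self.forward else HEAD

    @property
    def right_side(self) -> str:
        return HEAD if self.forward else TAIL


@dataclass(frozen=True)
class Extremity:
    """One of the two ends (head/tail) of a gene."""

    gene: str
    side: str  # HEAD or TAIL

    def __str__(self) -> str:
        return f"{self.gene}{self.side}"


# An adjacency is a frozenset of one (telomeric) or two extremities.
Adjacency = frozenset


@dataclass(frozen=True)
class Chromosome:
    genes: tuple[SignedGene, ...]
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.genes:
            raise GenomeFormatError("empty chromosome")

    def __len__(self) -> int:
        return len(self.genes)

    def reversed_(self) -> "Chromosome":
        return Chromosome(tuple(g.reverse() for g in reversed(self.genes)), self.circular)

    def __str__(self) -> str:
        term = ")" if self.circular else "|"
        return " ".join(str(g) for g in self.genes) + " " + term


@dataclass(frozen=True)
class Genome:
    """A named set of chromosomes.

    ``allow_duplicates`` relaxes the usual requirement that a gene name occur
    at most once per genome; it is needed only for exemplar-problem inputs,
    where a gene family may have several copies.
    """

    name: str
    chromosomes: tuple[Chromosome, ...]
    allow_duplicates: bool = False

    def __post_init__(self) -> None:
        if not self.name or any(c.isspace() for c in self.name):
            raise GenomeFormatError(f"invalid genome name: {self.name!r}")
        if not self.allow_duplicates:
            seen: set[str] = set()
            for g in self.genes():
                if g.name in seen:
                    raise GenomeFormatError(
                        f"duplicate gene {g.name!r} in genome {self.name!r}"
                    )
                seen.add(g.name)

    def genes(self) -> Iterator[SignedGene]:
        for chrom in self.chromosomes:
            yield from chrom.genes

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(g.name for g in self.genes())

    @property
    def n_genes(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    @property
    def n_linear(self) -> int:
        return sum(1 for c in self.chromosomes if not c.circular)

    def has_duplicates(self) -> bool:
        names = [g.name for g in self.genes()]
        return len(names) != len(set(names))


# ---------------------------------------------------------------------------
# Parsing and writing


def parse_genomes(text: str, allow_duplicates: bool = False) -> list[Genome]:
    """Parse a UniMoG-style document into a list of genomes.

    ``allow_duplicates`` admits repeated gene names within a genome, as
    needed for exemplar-problem inputs.
    """
    genomes: list[Genome] = []
    names: set[str] = set()
    current_name: str | None = None
    chromosomes: list[Chromosome] = []
    pending: list[SignedGene] = []
    allow_dups = allow_duplicates

    def flush_genome() -> None:
        nonlocal chromosomes, pending
        if current_name is None:
            return
        if pending:
            raise GenomeFormatError(
                f"unterminated chromosome in genome {current_name!r}"
            )
        genomes.append(
            Genome(current_name, tuple(chromosomes), allow_duplicates=allow_dups)
        )
        chromosomes = []

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            flush_genome()
            current_name = line[1:].strip()
            if not current_name:
                raise GenomeFormatError("empty genome name")
            if current_name in names:
                raise GenomeFormatError(f"duplicate genome name {current_name!r}")
            names.add(current_name)
            continue
        if current_name is None:
            raise GenomeFormatError(f"gene data before genome header: {line!r}")
        for token in line.split():
            if token in ("|", ")"):
                if not pending:
                    raise GenomeFormatError("empty chromosome")
                chromosomes.append(Chromosome(tuple(pending), circular=token == ")"))
                pending = []
            else:
                pending.append(SignedGene.from_token(token))
    flush_genome()
    if not genomes:
        raise GenomeFormatError("no genome header found")
    return genomes


def _dups_ok(genomes: Iterable[Genome]) -> bool:
    return any(g.allow_duplicates for g in genomes)


def write_genomes(genomes: Iterable[Genome]) -> str:
    """Serialize genomes; inverse of :func:`parse_genomes` up to whitespace."""
    lines: list[str] = []
    for genome in genomes:
        if not genome.chromosomes:
            raise GenomeFormatError(f"genome {genome.name!r} has no chromosomes")
        lines.append(f">{genome.name}")
        for chrom in genome.chromosomes:
            lines.append(str(chrom))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Adjacencies


def chromosome_adjacencies(chrom: Chromosome) -> list[Adjacency]:
    """Adjacencies of one chromosome, in order along the chromosome.

    A linear chromosome of m genes yields m+1 adjacencies, the first and
    last of which are telomeric singletons; a circular one yields m.
    """
    ext_pairs = [
        (Extremity(g.name, g.left_side), Extremity(g.name, g.right_side))
        for g in chrom.genes
    ]
    adjacencies: list[Adjacency] = []
    if chrom.circular:
        for i, (left, _right) in enumerate(ext_pairs):
            prev_right = ext_pairs[i - 1][1]
            adjacencies.append(frozenset({prev_right, left}))
    else:
        adjacencies.append(frozenset({ext_pairs[0][0]}))
        for i in range(len(ext_pairs) - 1):
            adjacencies.append(frozenset({ext_pairs[i][1], ext_pairs[i + 1][0]}))
        adjacencies.append(frozenset({ext_pairs[-1][1]}))
    return adjacencies


def genome_adjacencies(genome: Genome) -> list[Adjacency]:
    """All adjacencies of a genome (requires unique gene names)."""
    if genome.has_duplicates():
        raise GenomeFormatError(
            f"genome {genome.name!r} has duplicate genes; adjacencies are ambiguous"
        )
    out: list[Adjacency] = []
    for chrom in genome.chromosomes:
        out.extend(chromosome_adjacencies(chrom))
    return out


# ---------------------------------------------------------------------------
# Canonical form


def _gene_key(g: SignedGene) -> tuple[str, bool]:
    return (g.name, not g.forward)


def _canonical_chromosome(chrom: Chromosome) -> Chromosome:
    if not chrom.circular:
        fwd = chrom.genes
        rev = chrom.reversed_().genes
        best = min(fwd, rev, key=lambda gs: [_gene_key(g) for g in gs])
        return Chromosome(best, False)
    candidates: list[tuple[SignedGene, ...]] = []
    for genes in (chrom.genes, chrom.reversed_().genes):
        n = len(genes)
        for shift in range(n):
            candidates.append(genes[shift:] + genes[:shift])
    best = min(candidates, key=lambda gs: [_gene_key(g) for g in gs])
    return Chromosome(best, True)


def canonicalize(genome: Genome) -> Genome:
    """Canonical representative of a genome.

    Linear chromosomes and their reversals map to one representative;
    circular chromosomes are invariant under rotation and reversal;
    chromosomes are sorted.  Idempotent.
    """
    chroms = sorted(
        (_canonical_chromosome(c) for c in genome.chromosomes),
        key=lambda c: (c.circular, [_gene_key(g) for g in c.genes]),
    )
    return Genome(genome.name, tuple(chroms), allow_duplicates=genome.allow_duplicates)


# ---------------------------------------------------------------------------
# Similarity table


@dataclass
class SimilarityTable:
    """Pairwise normalized gene similarities sigma(a, b) in (0, 1].

    Keys are (gene-of-A, gene-of-B) name pairs; absence means sigma = 0.
    """

    entries: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b), s in self.entries.items():
            _check_sigma(a, b, s)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, a: str, b: str) -> float:
        return self.entries.get((a, b), 0.0)

    def items(self) -> Iterable[tuple[tuple[str, str], float]]:
        return self.entries.items()


def _check_sigma(a: str, b: str, sigma: float) -> None:
    if not (0.0 < sigma <= 1.0 + TOL):
        raise GenomeFormatError(f"sigma({a},{b}) = {sigma} outside (0, 1]")


def parse_similarities(text: str, genome_a: Genome, genome_b: Genome) -> SimilarityTable:
    """Parse a 3-column TSV into a validated similarity table.

    Gene names must belong to the respective genome, and the two genomes
    must have disjoint gene sets (the family-free setting assumes every
    gene symbol is unique across both genomes).
    """
    set_a, set_b = genome_a.gene_set, genome_b.gene_set
    common = set_a & set_b
    if common:
        raise GenomeFormatError(
            f"gene names shared between genomes (family-free input requires "
            f"disjoint gene sets): {sorted(common)[:5]}"
        )
    entries: dict[tuple[str, str], float] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 3:
            raise GenomeFormatError(f"line {lineno}: expected 3 columns, got {len(parts)}")
        a, b, sigma_str = parts
        try:
            sigma = float(sigma_str)
        except ValueError as exc:
            raise GenomeFormatError(f"line {lineno}: bad sigma {sigma_str!r}") from exc
        if a not in set_a:
            raise GenomeFormatError(f"line {lineno}: gene {a!r} not in genome {genome_a.name!r}")
        if b not in set_b:
            raise GenomeFormatError(f"line {lineno}: gene {b!r} not in genome {genome_b.name!r}")
        if sigma == 0.0:
            continue  # sigma = 0 means no edge
        _check_sigma(a, b, sigma)
        if (a, b) in entries:
            raise GenomeFormatError(f"line {lineno}: duplicate pair ({a}, {b})")
        entries[(a, b)] = sigma
    return SimilarityTable(entries)


def write_similarities(table: SimilarityTable) -> str:
    lines = [f"{a}\t{b}\t{s:.9g}" for (a, b), s in sorted(table.items())]
    return "\n".join(lines) + ("\n" if lines else "")
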