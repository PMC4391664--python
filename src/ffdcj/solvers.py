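"""Exact optimization for the family-free DCJ distance and similarity.

Two routes are provided and kept mutually checkable:

* brute-force enumeration of all maximal matchings of the gene similarity
  graph (the reference oracle, exponential, for small instances), and
* an integer linear program over the extremity graph H, solved with the
  HiGHS backend shipped with scipy.

The H graph has one vertex per gene extremity.  *Matching edges* join the
two heads (and the two tails) of a similarity pair, *adjacency edges*
(always chosen) join consecutive extremities within a genome, and *self
edges* join the two extremities of one gene, modelling its exclusion from
the matching.  Cycles of the chosen subgraph are counted with the
label/upper-bound scheme: every vertex gets a continuous label forced
equal along chosen edges, and a binary per vertex that may be 1 only when
the label reaches the vertex index, which happens for exactly one vertex
per cycle.

Linear chromosomes are handled without cap genes: every telomeric
extremity must pick exactly one *closure edge* to another telomeric
extremity, turning every path into a cycle.  A closure edge costs 1/2
between genomes and 1 within a genome, so a closed odd path nets the
correct credit 1/2, an even path nets 0, and no multi-path closure can do
better.  A circular chromosome whose genes are all unsaturated would form
a cycle that exists only in H, not in the reduced adjacency graph; a
penalty variable per circular chromosome cancels that credit.
"""

from __future__ import annotations

import contextlib
import itertools
import os
import sys
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .adjacency import dcj_distance
from .family_free import (
    GeneSimilarityGraph,
    Matching,
    build_gs_graph,
    dsigma,
    is_maximal_matching,
    reduce_genomes,
    ssigma,
)
from .genomes import (
    Chromosome,
    Genome,
    GenomeFormatError,
    SimilarityTable,
    TOL,
)

DEFAULT_ENUMERATION_CAP = 2**20

OPTIMAL = "optimal"
FEASIBLE_TIME_LIMIT = "feasible_time_limit"
INFEASIBLE_ERROR = "infeasible_error"


class EnumerationCapExceeded(RuntimeError):
    """The search space exceeded the configured cap; use the ILP instead."""


class SolverBackendMissing(RuntimeError):
    """No MILP backend is importable."""


# ---------------------------------------------------------------------------
# Brute force over maximal matchings


def enumerate_maximal_matchings(
    graph: GeneSimilarityGraph, cap: int = DEFAULT_ENUMERATION_CAP
) -> Iterator[Matching]:
    """Yield every maximal matching of the gene similarity graph exactly once.

    Walks the binary include/exclude tree over the (sorted) edge list and
    keeps only leaves where no edge has two unsaturated endpoints.  Raises
    :class:`EnumerationCapExceeded` after ``cap`` visited states.
    """
    edges = sorted(graph.edges.items())
    states = 0

    def rec(i: int, used_a: frozenset, used_b: frozenset, chosen: list) -> Iterator[Matching]:
        nonlocal states
        states += 1
        if states > cap:
            raise EnumerationCapExceeded(
                f"more than {cap} enumeration states; use the ILP solver"
            )
        if i == len(edges):
            for (a, b), _s in edges:
                if a not in used_a and b not in used_b:
                    return  # not maximal
            yield Matching(tuple(chosen))
            return
        (a, b), s = edges[i]
        if a in used_a or b in used_b:
            yield from rec(i + 1, used_a, used_b, chosen)
            return
        chosen.append((a, b, s))
        yield from rec(i + 1, used_a | {a}, used_b | {b}, chosen)
        chosen.pop()
        yield from rec(i + 1, used_a, used_b, chosen)

    yield from rec(0, frozenset(), frozenset(), [])


def ffdcj_distance_bruteforce(
    genome_a: Genome,
    genome_b: Genome,
    table: SimilarityTable,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> tuple[float, Matching]:
    """Minimum d_sigma over all maximal matchings, with one argmin."""
    graph = build_gs_graph(genome_a, genome_b, table)
    best: tuple[float, Matching] | None = None
    for matching in enumerate_maximal_matchings(graph, cap=cap):
        value = dsigma(reduce_genomes(genome_a, genome_b, matching))
        if best is None or value < best[0] - TOL:
            best = (value, matching)
    assert best is not None  # the empty matching is maximal on edgeless graphs
    return best


def ffdcj_similarity_bruteforce(
    genome_a: Genome,
    genome_b: Genome,
    table: SimilarityTable,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> tuple[float, Matching]:
    """Maximum s_sigma over all maximal matchings, with one argmax."""
    graph = build_gs_graph(genome_a, genome_b, table)
    best: tuple[float, Matching] | None = None
    for matching in enumerate_maximal_matchings(graph, cap=cap):
        value = ssigma(reduce_genomes(genome_a, genome_b, matching))
        if best is None or value > best[0] + TOL:
            best = (value, matching)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Brute-force exemplar DCJ distance


def exemplar_dcj_bruteforce(
    genome_a: Genome, genome_b: Genome, cap: int = DEFAULT_ENUMERATION_CAP
) -> tuple[float, Genome, Genome]:
    """Minimum DCJ distance over all exemplar pairs.

    An exemplar genome keeps exactly one occurrence of each gene family;
    all combinations of kept occurrences are enumerated (product of family
    multiplicities, bounded by ``cap``).
    """
    occ_a = _occurrences(genome_a)
    occ_b = _occurrences(genome_b)
    if set(occ_a) != set(occ_b):
        missing = sorted(set(occ_a) ^ set(occ_b))
        raise GenomeFormatError(
            f"families not shared by both genomes: {missing[:5]}"
        )
    families = sorted(occ_a)
    n_combos = 1
    for fam in families:
        n_combos *= len(occ_a[fam]) * len(occ_b[fam])
        if n_combos > cap:
            raise EnumerationCapExceeded(
                f"more than {cap} exemplar combinations"
            )
    best: tuple[float, Genome, Genome] | None = None
    choices_a = [occ_a[f] for f in families]
    choices_b = [occ_b[f] for f in families]
    for keep_a in itertools.product(*choices_a):
        ex_a = _exemplar(genome_a, set(keep_a))
        for keep_b in itertools.product(*choices_b):
            ex_b = _exemplar(genome_b, set(keep_b))
            dist = dcj_distance(ex_a, ex_b)
            if best is None or dist < best[0] - TOL:
                best = (dist, ex_a, ex_b)
    assert best is not None
    return best


def _occurrences(genome: Genome) -> dict[str, list[tuple[int, int]]]:
    occ: dict[str, list[tuple[int, int]]] = {}
    for ci, chrom in enumerate(genome.chromosomes):
        for gi, gene in enumerate(chrom.genes):
            occ.setdefault(gene.name, []).append((ci, gi))
    return occ


def _exemplar(genome: Genome, keep: set[tuple[int, int]]) -> Genome:
    chroms = []
    for ci, chrom in enumerate(genome.chromosomes):
        kept = tuple(g for gi, g in enumerate(chrom.genes) if (ci, gi) in keep)
        if kept:
            chroms.append(Chromosome(kept, chrom.circular))
    return Genome(genome.name + "_X", tuple(chroms))


# ---------------------------------------------------------------------------
# ILP


@dataclass
class HGraph:
    """Extremity graph underlying the ILP.

    ``vertices`` are (genome_tag, gene, side) triples, genome A first (the
    1-based position in this list is the label upper bound).  Matching
    edges come in pairs (head-head and tail-tail images of one similarity
    edge), adjacency edges are fixed, self edges model unsaturated genes,
    and closure edges pair telomeric extremities.
    """

    vertices: list[tuple[str, str, str]]
    n_vertices_a: int
    gs_edges: list[tuple[str, str, float]]
    matching_edges: list[tuple[int, int, int]]  # (vi, vj, gs index); 2 per GS edge
    adjacency_edges: list[tuple[int, int]]
    self_edges: list[tuple[int, int, str, str]]  # (vi, vj, genome_tag, gene)
    closure_edges: list[tuple[int, int, float]]  # (vi, vj, cost)
    circular_chromosomes: list[list[str]]  # gene names per circular chromosome (with tag)

    @property
    def n_matching_edges(self) -> int:
        return len(self.matching_edges)


def build_h_graph(
    genome_a: Genome, genome_b: Genome, table: SimilarityTable
) -> HGraph:
    graph = build_gs_graph(genome_a, genome_b, table)
    vertices: list[tuple[str, str, str]] = []
    index: dict[tuple[str, str, str], int] = {}
    telomeric: list[int] = []
    adjacency_edges: list[tuple[int, int]] = []
    self_edges: list[tuple[int, int, str, str]] = []
    circular_chromosomes: list[list[str]] = []

    for tag, genome in (("A", genome_a), ("B", genome_b)):
        for chrom in genome.chromosomes:
            first = len(vertices)
            for g in chrom.genes:
                for side in (g.left_side, g.right_side):
                    index[(tag, g.name, side)] = len(vertices)
                    vertices.append((tag, g.name, side))
            last = len(vertices) - 1
            # adjacency edges between consecutive extremities of the chromosome
            for v in range(first + 1, last, 2):
                adjacency_edges.append((v, v + 1))
            if chrom.circular:
                adjacency_edges.append((last, first))
                circular_chromosomes.append([tag + ":" + g.name for g in chrom.genes])
            else:
                telomeric.extend([first, last])
            for g in chrom.genes:
                vi = index[(tag, g.name, "t")]
                vj = index[(tag, g.name, "h")]
                self_edges.append((vi, vj, tag, g.name))
        if tag == "A":
            n_vertices_a = len(vertices)

    gs_edges = [(a, b, s) for (a, b), s in sorted(graph.edges.items())]
    matching_edges: list[tuple[int, int, int]] = []
    for ei, (a, b, _s) in enumerate(gs_edges):
        for side in ("h", "t"):
            matching_edges.append((index[("A", a, side)], index[("B", b, side)], ei))

    closure_edges = [
        (u, v, 0.5 if vertices[u][0] != vertices[v][0] else 1.0)
        for u, v in itertools.combinations(sorted(telomeric), 2)
    ]
    return HGraph(
        vertices,
        n_vertices_a,
        gs_edges,
        matching_edges,
        adjacency_edges,
        self_edges,
        closure_edges,
        circular_chromosomes,
    )


@dataclass
class IlpModel:
    """Explicit MILP: minimize c @ x subject to lb <= A x <= ub.

    Variable blocks: one binary per similarity edge (it stands for both of
    its matching-edge images in H), one binary self variable per gene, one
    binary per closure edge, one continuous label per vertex, one binary
    cycle-counting variable per vertex, one continuous penalty per
    circular chromosome.
    """

    h: HGraph
    genome_a: Genome
    genome_b: Genome
    var_names: list[str]
    objective: np.ndarray
    integrality: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    rows: list[tuple[dict[int, float], float, float]]  # (coefs, lb, ub)
    match_vars: dict[int, int]  # gs edge index -> variable index

    @property
    def n_variables(self) -> int:
        return len(self.var_names)

    @property
    def n_constraints(self) -> int:
        return len(self.rows)


def build_distance_ilp(
    genome_a: Genome, genome_b: Genome, table: SimilarityTable
) -> IlpModel:
    """Build the FFDCJ-DISTANCE MILP for two genomes and their similarities."""
    h = build_h_graph(genome_a, genome_b, table)
    k = len(h.vertices)

    var_names: list[str] = []
    obj: list[float] = []
    integ: list[int] = []
    lo: list[float] = []
    hi: list[float] = []

    def add_var(name: str, cost: float, integer: bool, lb: float, ub: float) -> int:
        var_names.append(name)
        obj.append(cost)
        integ.append(1 if integer else 0)
        lo.append(lb)
        hi.append(ub)
        return len(var_names) - 1

    # each similarity edge contributes two matching edges of weight sigma to
    # H; choosing it adds 2 - sigma to 2|M| - w(M)
    match_vars = {
        ei: add_var(f"m_{a}_{b}", 2.0 - s, True, 0, 1)
        for ei, (a, b, s) in enumerate(h.gs_edges)
    }
    self_vars = {
        (tag, gene): add_var(f"s_{tag}_{gene}", 0.0, True, 0, 1)
        for _vi, _vj, tag, gene in h.self_edges
    }
    closure_vars = [
        add_var(f"t_{u}_{v}", cost, True, 0, 1) for u, v, cost in h.closure_edges
    ]
    y_vars = [add_var(f"y_{i}", 0.0, False, 0, i + 1) for i in range(k)]
    z_vars = [add_var(f"z_{i}", -1.0, True, 0, 1) for i in range(k)]
    pen_vars = [
        add_var(f"p_{j}", 1.0, False, 0, 1)
        for j in range(len(h.circular_chromosomes))
    ]

    rows: list[tuple[dict[int, float], float, float]] = []

    # degree: each gene takes exactly one of its matching/self options;
    # stating it per gene also enforces head/tail consistency
    incident_a: dict[str, list[int]] = {}
    incident_b: dict[str, list[int]] = {}
    for ei, (a, b, _s) in enumerate(h.gs_edges):
        incident_a.setdefault(a, []).append(match_vars[ei])
        incident_b.setdefault(b, []).append(match_vars[ei])
    for _vi, _vj, tag, gene in h.self_edges:
        incident = incident_a if tag == "A" else incident_b
        coefs = {v: 1.0 for v in incident.get(gene, [])}
        coefs[self_vars[(tag, gene)]] = 1.0
        rows.append((coefs, 1.0, 1.0))

    # maximality: a similarity edge may not have both genes unsaturated
    for a, b, _s in h.gs_edges:
        rows.append(({self_vars[("A", a)]: 1.0, self_vars[("B", b)]: 1.0}, -np.inf, 1.0))

    # closure: every telomeric extremity is paired with exactly one other
    closure_incident: dict[int, list[int]] = {}
    for var, (u, v, _cost) in zip(closure_vars, h.closure_edges):
        closure_incident.setdefault(u, []).append(var)
        closure_incident.setdefault(v, []).append(var)
    for u, vars_ in sorted(closure_incident.items()):
        rows.append(({v: 1.0 for v in vars_}, 1.0, 1.0))

    # labels equal along chosen edges (1-based upper bounds i+1, j+1)
    def label_rows(vi: int, vj: int, xvar: int | None) -> None:
        bi, bj = vi + 1, vj + 1
        if xvar is None:  # fixed edge
            rows.append(({y_vars[vi]: 1.0, y_vars[vj]: -1.0}, 0.0, 0.0))
        else:
            rows.append(({y_vars[vi]: 1.0, y_vars[vj]: -1.0, xvar: bi}, -np.inf, bi))
            rows.append(({y_vars[vj]: 1.0, y_vars[vi]: -1.0, xvar: bj}, -np.inf, bj))

    for vi, vj in h.adjacency_edges:
        label_rows(vi, vj, None)
    for vi, vj, ei in h.matching_edges:
        label_rows(vi, vj, match_vars[ei])
    for vi, vj, tag, gene in h.self_edges:
        label_rows(vi, vj, self_vars[(tag, gene)])
    for var, (u, v, _cost) in zip(closure_vars, h.closure_edges):
        label_rows(u, v, var)

    # z_i may be 1 only when y_i reaches its upper bound i
    for i in range(k):
        rows.append(({z_vars[i]: i + 1.0, y_vars[i]: -1.0}, -np.inf, 0.0))

    # cancel the credit of an entirely-unsaturated circular chromosome
    for j, genes in enumerate(h.circular_chromosomes):
        coefs = {}
        for tagged in genes:
            tag, gene = tagged.split(":", 1)
            coefs[self_vars[(tag, gene)]] = 1.0
        coefs[pen_vars[j]] = -1.0
        rows.append((coefs, -np.inf, len(genes) - 1.0))

    return IlpModel(
        h,
        genome_a,
        genome_b,
        var_names,
        np.array(obj),
        np.array(integ),
        np.array(lo),
        np.array(hi),
        rows,
        match_vars,
    )


@dataclass
class SolverOptions:
    time_limit: float = 3600.0  # seconds
    mip_rel_gap: float = 0.0


@dataclass
class SolveResult:
    matching: Matching
    distance: float  # recomputed from the matching via d_sigma
    objective_value: float
    status: str
    gap: float


@contextlib.contextmanager
def _quiet_fd1():
    """Mute file descriptor 1 for the duration of a HiGHS solve.

    HiGHS occasionally writes progress lines straight to the C-level
    stdout even with display off, which would corrupt JSON reports.
    """
    try:
        fd = sys.stdout.fileno()
    except (OSError, ValueError, AttributeError):
        yield
        return
    sys.stdout.flush()
    saved = os.dup(fd)
    devnull = os.open(os.devnull, os.O_WRONLY)
    try:
        os.dup2(devnull, fd)
        yield
    finally:
        sys.stdout.flush()
        try:  # flush C-level stdio while fd 1 still points at devnull
            import ctypes

            ctypes.CDLL(None).fflush(None)
        except Exception:  # pragma: no cover
            pass
        os.dup2(saved, fd)
        os.close(saved)
        os.close(devnull)


def solve_distance(model: IlpModel, opts: SolverOptions | None = None) -> SolveResult:
    """Solve the FFDCJ-DISTANCE MILP with HiGHS (via scipy).

    The reported distance is always recomputed from the returned matching
    through the reduced genomes, never read off the raw objective.
    """
    opts = opts or SolverOptions()
    if not model.h.gs_edges:
        return SolveResult(Matching(()), 0.0, 0.0, OPTIMAL, 0.0)
    try:
        from scipy.optimize import LinearConstraint, Bounds, milp
        from scipy.sparse import csr_matrix
    except ImportError as exc:  # pragma: no cover
        raise SolverBackendMissing("scipy.optimize.milp unavailable") from exc

    n = model.n_variables
    data, indices, indptr, lbs, ubs = [], [], [0], [], []
    for coefs, lb, ub in model.rows:
        for idx, coef in coefs.items():
            indices.append(idx)
            data.append(coef)
        indptr.append(len(indices))
        lbs.append(lb)
        ubs.append(ub)
    a_matrix = csr_matrix((data, indices, indptr), shape=(len(model.rows), n))
    with _quiet_fd1():
        res = milp(
            c=model.objective,
            constraints=LinearConstraint(a_matrix, np.array(lbs), np.array(ubs)),
            integrality=model.integrality,
            bounds=Bounds(model.lower, model.upper),
            options={
                "time_limit": opts.time_limit,
                "mip_rel_gap": opts.mip_rel_gap,
                "disp": False,
            },
        )
    if res.x is None:
        return SolveResult(Matching(()), float("nan"), float("nan"), INFEASIBLE_ERROR, float("inf"))
    status = OPTIMAL if res.status == 0 else FEASIBLE_TIME_LIMIT
    chosen = [
        model.h.gs_edges[ei]
        for ei, var in sorted(model.match_vars.items())
        if res.x[var] > 0.5
    ]
    matching = Matching(tuple(chosen))
    distance = dsigma(reduce_genomes(model.genome_a, model.genome_b, matching))
    gap = float(getattr(res, "mip_gap", 0.0) or 0.0)
    return SolveResult(matching, distance, float(res.fun), status, gap)


def ffdcj_distance_ilp(
    genome_a: Genome,
    genome_b: Genome,
    table: SimilarityTable,
    opts: SolverOptions | None = None,
) -> SolveResult:
    """Convenience wrapper: build and solve the distance MILP."""
    model = build_distance_ilp(genome_a, genome_b, table)
    return solve_distance(model, opts)


# ---------------------------------------------------------------------------
# LP-format export


def write_lp(model: IlpModel) -> str:
    """Serialize the model in CPLEX LP format for external solvers."""

    def term(coef: float, name: str) -> str:
        sign = "+" if coef >= 0 else "-"
        return f"{sign} {abs(coef):.12g} {name}"

    lines = ["Minimize", " obj: " + " ".join(
        term(c, model.var_names[i])
        for i, c in enumerate(model.objective)
        if c != 0
    )]
    lines.append("Subject To")
    for r, (coefs, lb, ub) in enumerate(model.rows):
        expr = " ".join(term(c, model.var_names[i]) for i, c in sorted(coefs.items()))
        if lb == ub:
            lines.append(f" c{r}: {expr} = {lb:.12g}")
        else:
            if np.isfinite(ub):
                lines.append(f" c{r}: {expr} <= {ub:.12g}")
            if np.isfinite(lb):
                lines.append(f" c{r}_l: {expr} >= {lb:.12g}")
    lines.append("Bounds")
    for i, name in enumerate(model.var_names):
        lines.append(f" {model.lower[i]:.12g} <= {name} <= {model.upper[i]:.12g}")
    binaries = [
        model.var_names[i] for i in range(model.n_variables) if model.integrality[i]
    ]
    if binaries:
        lines.append("Binaries")
        for i in range(0, len(binaries), 8):
            lines.append(" " + " ".join(binaries[i : i + 8]))
    lines.append("End")
    return "\n".join(lines) + "\n"
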