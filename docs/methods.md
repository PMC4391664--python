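# Methods

## Model

A genome is a set of chromosomes, each a sequence of oriented genes,
linear or circular.  Each gene `g` has two extremities, tail `g^t` and
head `g^h`; an adjacency is either a pair of consecutive extremities or a
single extremity next to a telomere.  For duplicate-free genomes with
equal gene content, the adjacency graph `AG(A,B)` (one edge per
extremity) decomposes into cycles and paths and yields the DCJ distance
`d_DCJ = n − c − i/2`, equivalently the sum of per-component
contributions `|C|/2 − 1` (cycle), `(|C|−1)/2` (odd path), `|C|/2` (even
path).  The implementation always computes both routes and asserts they
agree; the final distance must be a non-negative integer.

In the family-free setting the two gene sets are disjoint and carry
pairwise normalized similarities σ ∈ (0,1] (σ = 0 means no edge; the
similarity table is an *input* — computing σ from sequences is out of
scope).  A matching `M` of the gene similarity graph induces reduced
genomes `A^M, B^M`: unsaturated genes are excised (their neighbors
joined; a chromosome losing all genes disappears) and each matched pair
is renamed to a label in `1..|M|`.  The label bijection is arbitrary in
the model; for reproducibility we number pairs by first occurrence along
genome A (chromosome order, then position).

The weighted adjacency graph gives both extremity edges of pair `i` the
weight σ(e_i), so its total weight is exactly `2 w(M)` (asserted at
construction).  With `f(C) = 2|C| − w(C)` the weighted contributions are
`f/2 − 1`, `(f−1)/2`, `f/2` for cycles, odd and even paths, and summing
gives `d_σ = d_DCJ(A^M,B^M) + |M| − w(M)`.  `dsigma()` computes the
component sum and the closed form and raises on disagreement beyond
1e-9 — this guards against component-classification bugs.  The distance
problem minimizes `d_σ` over *maximal* matchings; the similarity problem
maximizes `s_σ = Σ w(C)/|C| (cycles) + Σ w(C)/(|C|+1) (odd paths) +
Σ w(C)/(|C|+2) (even paths)`, implemented literally as printed (the path
denominators count the "missing" telomeric edges; those carry no weight).
`F_α = α·s_σ + (1−α)·w(M)` is provided for a user-chosen α ∈ [0,1]; no
attempt is made to pick a "best" α.

## Exact solvers

**Enumeration.**  All maximal matchings are generated by walking the
include/exclude tree over the sorted edge list and keeping leaves where
no edge has two unsaturated endpoints; each maximal matching appears
exactly once.  A state cap (default 2^20 visited nodes) turns runaway
instances into an explicit error recommending the ILP.  The brute-force
distance/similarity minimizes/maximizes over this stream and is the
reference oracle throughout the test suite.  The exemplar DCJ solver
enumerates the product of per-family occurrence choices in both genomes
(same cap) and minimizes `d_DCJ` over the resulting exemplar pairs.

**MILP.**  The extremity graph `H` has one vertex per gene extremity.
Adjacency edges (consecutive extremities) are always chosen; every gene
has a self edge (weight 0) modelling exclusion from the matching; every
similarity edge contributes two matching-edge images (head–head and
tail–tail) sharing one binary variable, which both enforces head/tail
consistency and fixes the objective scale: choosing edge `e` adds
`2 − σ(e)` (i.e. `2|M| − w(M)` in total).  Per gene, exactly one of
{incident matching variables, self variable} is chosen; maximality is
`s_a + s_b ≤ 1` per similarity edge `ab`.  Cycles are counted by the
label scheme: continuous `y_v ∈ [0, idx(v)]` forced equal across chosen
edges, plus a binary `z_v` with `idx(v)·z_v ≤ y_v`, so each cycle can
credit exactly one `z` (at its minimum-index vertex).  `z` variables are
kept for the vertices of both genomes.

Linear chromosomes are handled without cap genes.  Every telomeric
extremity must choose exactly one *closure edge* to another telomeric
extremity (a perfect matching over all telomeric extremities, which
always exists since each genome has an even number); closure edges cost
½ across genomes and 1 within a genome and participate in the label
constraints, so every component of the chosen subgraph is a cycle.  A
closed cycle built from `a` odd paths and `k−a` even paths with `k`
closure edges of which `s` join same-genome telomeres earns
`1 − k/2 − s/2 ≤ a/2`, with equality when each path is closed by its own
telomere pair; hence the optimum over closures credits exactly
`c + i/2`, and the objective value equals `d_σ`.  One subtlety remains: a
circular chromosome whose genes are all unsaturated forms an
all-self-edge cycle in `H` that does not exist in the reduced adjacency
graph; one penalty variable per circular chromosome
(`p_K ≥ Σ self_g − |K| + 1`, objective `+p_K`) cancels that credit.
This also means genes without any similarity edge need no special
preprocessing.

The backend is HiGHS through `scipy.optimize.milp` (single-threaded,
deterministic).  Defaults: time limit 3600 s, relative gap 0.  The
solver result reports status (`optimal` / `feasible_time_limit` /
`infeasible_error`) and gap; the distance field is always recomputed
from the returned matching via `dsigma`, never taken from the raw
objective.  The model can be exported in CPLEX LP format for external
solvers.  Correctness is pinned by oracle equivalence: the suite checks
the MILP against enumeration on hundreds of seeded random instances with
mixed topologies, multiple chromosomes and random weights.

## Synthetic instances

`simulate_pair` emulates pairwise divergence under structural evolution
only: genome B starts as a renamed copy of A, then undergoes a
configurable number of random inversions (segment reversal with sign
flip) and, between linear chromosomes, translocations (suffix exchange;
emptied chromosomes are dropped), followed by per-gene binomial losses
and duplications (copies get fresh names, random position and
orientation).  The similarity table gives true ortholog pairs
σ = 1 − U(0, `weight_noise`), paralog edges (A-ortholog to duplicated
copy) and spurious edges σ ~ U over `paralog_weight_range`; the returned
ground-truth matching covers surviving originals.  Everything is driven
by one seeded generator, so identical configurations reproduce bit-for-bit.

Desk-scale defaults: 100 genes, 1 linear chromosome, weight noise 0.1,
spurious edge probability 0.02 per non-true pair, paralog weights in
(0.2, 0.8).  Presets `r ∈ {1, 2, 5}` scale per-gene duplication/loss
(base 0.01) and rearrangement (base 0.025) rates r-fold, mirroring the
relative event-rate ratios of published simulation benchmarks at sizes a
brute-force oracle can still certify; sequence-level parameters
(substitution models, indels, gene lengths) are deliberately not
modelled, since the method consumes σ directly.  Consequently, passing
tests show the optimization recovers planted structure under this noise
model — they say nothing about how well any particular σ estimator
(alignment scores etc.) approximates orthology on real data.

The hardness gadgets are generated exactly: `exemplar_to_ff_instance`
relabels an exemplar instance (gene `i` of A → `i`, gene `j` of B →
`j + |A|`, σ = 1 within families) and `ff_matching_to_exemplar` maps a
matching back to exemplar genomes; their optima coincide, which the
suite verifies by brute-forcing both sides.  `counterexample_instance`
builds, for `k ≥ 1` and ε ∈ [0,1), the pair of 2k-gene linear genomes
with alternating orientations, 2k unit edges and k weight-(1−ε) edges in
which the maximum-weight matching costs `|M|` while the light matching
costs `ε|M*|` (ratio exactly `2/ε`).  The narrative accompanying this
construction elsewhere states `|M*| = k/2`; the printed σ definition
yields `|M*| = k`, which is what this package implements — the relations
`|M| = 2|M*|` and ratio `2/ε` hold either way.  Worked-example fixtures
are generated programmatically; for the weighted five-gene example only
matching-level aggregates are known (sizes, weights, component census),
so its fixture carries those aggregates and `dsigma_from_counts`
evaluates the census form `(|M| − c − i/2) + |M| − w(M)`.

## Numerical choices and degenerate inputs

* All σ and derived weights are floats with absolute tolerance 1e-9
  (every quantity of interest is a short decimal or a small sum of
  them); family-based distances additionally assert integrality.
* Deterministic ordering everywhere: edges sorted lexicographically,
  components ordered by smallest extremity label, labels assigned along
  genome A.  Among equally optimal matchings the brute force keeps the
  first found in enumeration order and the MILP reports the solver's
  incumbent; tests compare distances, never matchings.
* Empty matching ⇒ both reduced genomes empty ⇒ d_σ = 0, s_σ = 0 (the
  reason the problems are restricted to maximal matchings).
* An edgeless similarity graph short-circuits the MILP (distance 0,
  empty matching, status optimal).
* σ = 0 rows are dropped on input; σ outside (0,1], duplicate pairs,
  unknown gene names, and gene names shared across the two genomes are
  errors.  Duplicate gene names within a genome are allowed only on
  inputs explicitly flagged for the exemplar problem.

## Limitations

* Enumeration and the exemplar solver are exponential and capped; the
  MILP is exact but NP-hard in general — worst-case instances can hit
  the time limit, in which case the incumbent matching and gap are
  reported.
* No ILP is provided for the similarity problem (brute force only), and
  no approximation algorithm is offered: the maximum-weight-matching
  heuristic is provably unbounded, and the distance is APX-hard.
* No insertion/deletion (indel) distance model and no sorting-scenario
  reconstruction; distances only.
* The test-suite problem sizes (≤ 6 genes per genome for oracle
  equivalence, ≤ 6 families for the reductions, desk-scale simulator
  presets) are chosen so that every optimization result can be certified
  against an independent brute-force oracle.
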