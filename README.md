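# ffdcj — family-free DCJ distance and similarity

`ffdcj` computes rearrangement distances between two gene-order genomes
**without prior gene-family assignment**.  It is aimed at comparative
genomicists who have two annotated genomes and a table of pairwise gene
similarities (e.g. normalized alignment scores) and want a
double-cut-and-join (DCJ) distance that selects the gene matching itself,
instead of relying on a precomputed orthology.

## The model

In the classical family-based setting, two duplicate-free genomes *A*, *B*
over the same *n* genes define the adjacency graph *AG(A,B)* — one vertex
per adjacency, one edge per gene extremity — which decomposes into cycles
and paths, giving the linear-time distance

```
d_DCJ(A, B) = n − c − i/2
```

with *c* cycles and *i* odd paths.

In the family-free setting the gene sets are disjoint and related only by
a similarity σ(a,b) ∈ (0,1].  A matching *M* in the gene similarity graph
induces *reduced genomes* A^M, B^M (unsaturated genes deleted, matched
pairs renamed to a common label), whose weighted adjacency graph carries
σ(e) on both extremity edges of each matched pair.  Each component *C*
contributes through f(C) = 2|C| − w(C), and the weighted distance satisfies

```
d_σ(A^M, B^M) = d_DCJ(A^M, B^M) + |M| − w(M)
```

The **family-free DCJ distance** is the minimum of d_σ over all *maximal*
matchings (the empty matching would trivially give 0); the companion
**family-free DCJ similarity** maximizes the normalized component weight
s_σ.  Both problems are NP-hard, so the package provides:

* a brute-force enumerator over maximal matchings (exact reference oracle
  for small instances),
* an integer linear program solved with HiGHS (via scipy) that scales
  beyond enumeration: binary variables select similarity edges and
  self-edges (unmatched genes), label variables count cycles, and
  telomere-closure edges with costs ½ / 1 account for odd and even paths
  exactly — the returned distance is always recomputed from the matching,
  never read off the objective,
* a brute-force exemplar DCJ solver and the constructive reductions
  linking exemplar and family-free optima,
* a simulator producing genome pairs diverged by inversions,
  translocations, duplications and losses, with a noisy similarity table
  and ground-truth orthology.

## Worked example

Genome files use the UniMoG-style dialect: `>name` headers, chromosomes as
signed gene tokens ending in `|` (linear) or `)` (circular).

```
$ cat fig1.txt
>A
-1 3 4 2 |
>B
-2 1 4 3 |
$ ffdcj dcj --genomes fig1.txt
{
  "schema": "ffdcj-report/1",
  "command": "dcj",
  "genomes": ["A", "B"],
  "n": 4,
  "cycles": 1,
  "odd_paths": 2,
  "distance": 2.0
}
```

The adjacency graph of these two genomes has one cycle and two odd paths,
so d_DCJ = 4 − 1 − 2/2 = 2: two DCJ operations (e.g. two inversions)
transform one genome into the other.

A family-free run on a generated gadget instance (two genomes of four
genes, six similarity edges):

```
$ ffdcj gadget counterexample --k 2 --eps 0.1 --out-prefix cx
$ ffdcj distance --genomes cx.genomes.txt --sim cx.sim.tsv --solver ilp
{
  ...
  "matching_size": 2,
  "matching_weight": 1.8,
  "distance": 0.2,
  "solver": {"name": "ilp", "status": "optimal", "objective": 0.2, ...}
}
```

Here the optimizer rejects the maximum-weight matching (4 edges of weight
1, distance 4) in favour of two edges of weight 0.9 whose reduced genomes
are already sorted — distance ε·|M*| = 0.2.  This gadget family shows the
maximum-weight heuristic can be arbitrarily far (factor 2/ε) from optimal.

Other subcommands: `similarity` (maximize s_σ), `evaluate` (score one
given matching, including F_α = α·s_σ + (1−α)·w(M)), `simulate`
(synthetic pairs with ground truth), `gadget exemplar` (relabel an
exemplar-distance instance into a family-free one).

## Documentation

See `docs/methods.md` for the model details, the ILP formulation
(including how linear chromosomes are handled without cap genes), the
simulator's event model, numerical choices and known limitations.
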