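# orbeq

Equation-based counting of graphlet degrees (automorphism-orbit counts per
node) of arbitrary order, with automatic, density-driven selection among
the redundant counting equations.

## The problem

Graphlets — small connected induced subgraphs — are a standard lens on the
local structure of biological networks: the *graphlet degree* o_i(v) of a
node v counts the induced instances of orbit representative Ω_i (a graphlet
with one marked node) in which v sits on the marked position, and the
vector of all o_i(v) (the graphlet degree signature, and in aggregate the
graphlet degree distribution, GDD) is widely used to compare
protein-interaction networks and to characterise node function.

Counting order-k degrees does not require finding order-k graphlets.  For
every order-k orbit there are linear *counting equations*

    Σ_j lhs_j · o_j(x)  =  Σ_{instances I of Ω at x} Σ_{S' ∈ A} [ c(I(S')) − adj(S') ]

whose right-hand side runs over instances of a single (k−1)-node
representative Ω and sums common-neighbour counts c(...) of up to k−2
nodes.  Searching only (k−1)-node instances and solving the (automatically
upper-triangular) system per node yields every order-k degree exactly.
`orbeq` generates all structures involved — orbit representatives of any
order with an edge-monotone canonical numbering, the orbit tree that drives
instance search, and the full family of candidate equations per orbit — and
lets you pick which equation to use per orbit.

All candidate equations are correct; they differ only in cost.  The number
of arguments |S'| of the RHS terms equals the edge difference between the
target orbit and Ω, so equations with few arguments sum over *dense*
(k−1)-representatives, which are rare in sparse graphs — and vice versa.
`orbeq` instruments the common-neighbour table lookups that dominate the
running cost and, with the `auto` strategy, chooses per graph: density
below 0.7 → fewest arguments per term, at or above 0.7 → most arguments.

## Worked example

A 5-node, 6-edge graph (a triangle a–b–c, with d adjacent to b and c, and a
pendant e on b):

    $ cat example.tsv
    a	b
    a	c
    b	c
    b	d
    c	d
    b	e
    $ orbeq count --input example.tsv --order 4 --equations auto \
        --output degrees.tsv --stats stats.tsv --header
    $ cat degrees.tsv
    node	1	2	3	4	5	6	7	8	9	10	11	12	13	14	15
    a	2	0	3	1	0	0	1	0	0	1	0	0	0	1	0
    b	4	4	0	2	1	0	0	0	2	0	0	0	1	0	0
    c	3	1	1	2	0	0	0	0	0	2	0	0	1	0	0
    d	2	0	3	1	0	0	1	0	0	1	0	0	0	1	0
    e	1	0	3	0	0	0	1	0	0	0	0	2	0	0	0

One line per node: the node name, then its graphlet degrees in ascending
catalog index (orbits of orders 2..4; the header lists the indices).
Column 1 is the order-2 orbit, i.e. the ordinary degree (b has degree 4);
column 2 is the centre of a 3-path, column 3 a 3-path end, column 4 the
triangle; the remaining 11 columns are the 4-node orbits.  For the pendant
node e every connected 4-set must pass through b: {e,b,a,d} induces a
4-star with e on a leaf (degree 1 in column 7), while {e,b,a,c} and
{e,b,c,d} induce a triangle with e pendant on it (degree 2 in column 12).

    $ cat stats.tsv
    k	4
    n	5
    m	6
    density	0.6
    strategy	auto
    resolved_strategy	fewest_args
    seed	0
    lookups	86
    intersections	2

Density 0.6 < 0.7, so `auto` resolved to `fewest_args`; the run retrieved
86 common-neighbour table entries.  Other subcommands: `orbeq random`
(seeded ER / BA / geometric generators), `orbeq generate-files` (catalog
and orbit-tree serialization), `orbeq benchmark` (lookup/time grids over
families × orders × densities × strategies).

The same pipeline as a library:

```python
from orbeq import build_graph, count_orbits

g = build_graph([("a", "b"), ("a", "c"), ("b", "c"),
                 ("b", "d"), ("c", "d"), ("b", "e")])
matrix, stats = count_orbits(g, k=4, strategy="auto")
print(matrix.to_dataframe())     # node × orbit degrees
print(stats.lookups)             # 86
```

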