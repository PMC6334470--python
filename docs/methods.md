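# Methods

## Scope and model

`orbeq` computes, for every node v of an undirected simple graph G, the
graphlet degrees o_i(v): the number of connected induced subgraphs of G of
order 2..k in which v occupies the automorphism orbit i.  Orbits are
represented by *orbit representatives* — a connected graphlet with one
marked node — and two representatives are identified when a
marked-preserving isomorphism exists between them.  Directed, weighted and
multi-edge graphs are out of scope; self-loops and duplicate edges in the
input are collapsed (with a warning, or rejected in strict mode).

## Certificates and numbering

Representative identity is decided by a canonical certificate: the minimum,
over all vertex orderings that place the marked node first, of the
upper-triangular adjacency encoding.  This is brute force over (k−1)!
orderings, deliberately dependency-free and exact; it is the right tool up
to the supported order 8, beyond which the factorial cost (and the sheer
number of orbits) makes the whole approach impractical anyway.

The catalog orders representatives by (order, edge count, certificate).
Any ordering that is monotone in order and, within an order, in edge count
guarantees that every counting equation links its target only to
higher-indexed (denser) orbits, so a one-equation-per-orbit system is
upper triangular without any decomposition.  The catalog therefore does
not — and does not try to — reproduce any historically used label values;
everything downstream is phrased in terms of structure, not labels.

Unlabelled connected graphs per order are grown by attaching a new vertex
to every non-empty subset of a smaller graph's vertices (complete, since
every connected graph has a removable non-cut vertex) and deduplicated with
Weisfeiler–Lehman hash buckets plus an exact isomorphism check (networkx);
marking and marked-class dedup then use the certificate.

## Orbit tree and instance search

The orbit tree links every representative to a parent by one action:
adding an edge (preferred, smallest-index parent whose edge-removal
remainder stays connected) or, for trees, adding a degree-1 vertex.
`match_instances` walks this tree from a root host node: node arcs extend
the partial assignment through host neighbours of the attachment vertex,
edge arcs test presence.  An assignment is emitted only when (a) the
induced host edges equal the representative exactly (all required
non-edges hold) and (b) it is lexicographically minimal under the
representative's automorphisms.  Each (node set, marked node) pair is
therefore produced exactly once; this contract — not any particular arc
choice, which is not unique — is the tested property.

## Counting equations

Removing a non-marked node a (remainder connected) from an order-k
representative leaves a (k−1)-representative Ω and an argument set
S = N(a) in Ω's labels, with |S| = e(target) − e(Ω).  The resulting
identity sums, over all instances of Ω at x, the terms c(S') − adj(S')
for S' in the Aut(Ω)-orbit A of S, where adj(S') is the number of common
neighbours of S' inside Ω itself, so each term counts extensions by one
*outside* node.  LHS coefficients are obtained by evaluating this RHS on
each order-k representative as its own host graph (where exactly one
order-k degree is 1 and the rest are 0) — a few hundred tiny evaluations
rather than a closed combinatorial formula, and self-validating: the
target must receive the minimal index and a positive coefficient.

Candidates are deduplicated per (Ω, A) class and restricted to |S| ≤ k−2,
the bound of the common-neighbour table.  Under that restriction exactly
one orbit per order is left without a candidate — the complete graphlet
K_k, whose unique decomposition needs k−1 arguments — and it is counted
directly instead (below).  The per-orbit candidate counts then multiply to
16 possible systems for k=4, ≈1.5×10^15 for k=5 and ≈3.5×10^182 for k=6,
which is the census the acceptance tests pin down.

## Selection strategies

One equation per orbit: `first` (smallest RHS representative index),
`random` (uniform per orbit, explicit seed required), `fewest_terms` /
`most_terms` (extreme |A|), `fewest_args` / `most_args` (extreme |S|), and
`auto`.  Ties prefer fewer terms, then fewer arguments, then the smaller Ω
index — fewer of either never increases lookups.  `auto` uses whole-graph
density with threshold 0.7: below → `fewest_args`, at or above →
`most_args`.  The boundary value 0.7 itself goes to `most_args` (the rule
is stated as an open interval on either side; the choice at a measure-zero
point is arbitrary and fixed here once).  For disconnected graphs whose
components are much denser than the whole, resolving `auto` per component
and selecting manually is the intended escape hatch.

All selections produce identical degree matrices — only the instrumented
cost differs.  This is asserted directly in the tests.

## Engine

1. **Common-neighbour table.** For every node w and every subset
   S ⊆ N(w) with 1 ≤ |S| ≤ k−2, the entry for S is incremented once.
   Only positive counts are stored (a sparse graph would otherwise force
   Θ(n^(k−2)) zeros); a miss reads as 0 and still counts as a lookup.
   A single table serves all tuple sizes.
2. **Subset scan.** Every connected subset of sizes 2..k−1 is enumerated
   exactly once globally (extension enumeration over bitmask adjacency,
   each subset grown from its minimum node through exclusive neighbours).
   Each subset is classified per marked node through a memoized
   edge-pattern table, giving the direct degrees of orders 2..k−1; each
   (k−1)-subset additionally feeds the RHS accumulators of the selected
   equations whose Ω matches, one table lookup per c(...) term.  Because A
   is Aut(Ω)-closed, the accumulated value is independent of which
   embedding the classifier returns.  (Walking the orbit tree once per
   root node is equivalent in output and in lookup count, but revisits
   every subset once per member; the global scan is the cheaper route and
   the tree walk is validated separately.)
3. **Densest orbit.** K_k is counted from complete (k−1)-subsets: the
   intersection of the members' adjacency sets counts its extensions, and
   each K_k at x is seen once per K_{k−1} ⊂ it containing x, i.e. k−1
   times.  These intersections (and any term with k−1 arguments, possible
   only for hand-built equations) are tallied separately from lookups.
4. **Solve.** Back-substitution in descending orbit index with exact
   integer division; a fractional or negative quotient raises rather than
   returning a silently wrong count (it can only mean an equation or
   search bug).

The lookup count is deterministic given (graph, k, system); wall-clock
times are recorded per phase but treated as informational and excluded
from reproducible outputs by default.

## Random graphs

- **ER(n, m):** edges added one by one, uniform over unconnected pairs
  (distribution-identical to a uniform m-subset of pairs); exact size.
- **BA(n, δ):** grown from K_δ; each new node attaches to δ distinct
  nodes drawn sequentially with degree-proportional probability,
  renormalised without replacement (uniform fallback while all degrees
  are 0, which only happens for δ=1).  Size is exactly
  C(δ,2) + (n−δ)δ.
- **GEO(n; D, r | m):** uniform points in the unit D-cube (default D=3),
  edges within distance r; on the torus each axis distance is
  min(|Δ|, 1−|Δ|).  Target-size mode sets the threshold at the m-th
  smallest pairwise distance (ties broken by pair order), making
  density-controlled comparisons exact — a deliberate exactness device,
  flagged as such, where a fixed a-priori radius would only approximate a
  target density.

These families emulate the regimes that matter for equation selection —
homogeneous sparse/dense (ER), heavy-tailed degrees (BA), spatially
clustered (GEO) — not any particular biological network: real interaction
networks have correlated motif abundances that no generator here models,
so passing tests show correctness of the counts and the cost mechanism,
not that `auto` is optimal for every real network's small-scale structure.

## Expected instance counts in ER graphs

For a representative with k nodes, e edges and marked-fixing automorphism
group Aut(Ω), the expected instance count in an exact-size ER(n, m) graph
is

    Π_{i<e} (m−i)/(N−i) · Π_{j<C(k,2)−e} (N−m−j)/(N−e−j) · C(n,k) · S,

with N = C(n,2) and S = k!/|Aut(Ω)| (S counts ordered placements per
k-subset, hence marked placements; the k=2 edge case gives exactly 2m).
The two products are the without-replacement probability that a fixed
k-subset realises the e edges and then the C(k,2)−e non-edges; note the
non-edge denominators continue from N−e, which is what makes the product
telescope correctly — this is re-derived here from first principles and
verified by Monte Carlo (200 seeded ER(30, 90) graphs, three 4-node
representatives, agreement within 3 standard errors).  For k ≪ n, m it
reduces to D^e (1−D)^(C(k,2)−e) C(n,k) S.  The consecutive-e ratio
D/(1−D) makes dense representatives rare below density 0.5 and common
above it — the mechanism behind the lookup asymmetry.  The cost crossover
observed between the argument-count strategies sits near density 0.7, not
0.5; the gap is not resolved here: the package reproduces both the
analytic 0.5 symmetry of the expectation and the instrumented lookup
ordering (fewest_args cheaper at density 0.2, most_args at 0.9), and the
0.7 threshold is adopted for `auto` as the empirically motivated rule.

## Problem sizes and numerical choices

Tests validate the engine entry-for-entry against a brute-force oracle on
ER graphs of order 14 for k ∈ {3,4,5} under every strategy, with a spot
check at k=6 on order 12; candidate-equation validity is checked node-wise
on ten ER(12, 30) graphs for k ∈ {4,5}; the lookup crossover uses ER
graphs of order 60 at densities 0.2 and 0.9 with five seeds per point.
These sizes keep the brute-force oracle exact and the full suite
comfortably fast while exercising every code path; the engine itself
handles graphs of a few thousand nodes at k=5 in ordinary use.  All
randomness flows through explicit integer seeds (Python's Mersenne
Twister); there are no floating-point tolerances anywhere in the counting
path — every degree is computed in exact integer arithmetic.

## Known limitations

- Single-threaded; no incremental recount on graph edits.
- Certificates, automorphism groups and embeddings are factorial in k;
  orders beyond 8 are rejected.
- Memory for the common-neighbour table grows with Σ_w C(deg(w), k−2),
  which is the binding constraint on dense graphs at large k.
- Per-node equation tailoring (choosing equations after inspecting a
  node's neighbourhood) is out of scope.
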