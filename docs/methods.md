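# Methods

## Model

A weighted rooted phylogenetic network is a rooted DAG whose leaves are
bijectively labelled with taxa and whose every edge *e* carries a finite,
non-empty set Λ(*e*) of strictly positive branch lengths, measured in
divergence units (e.g. expected substitutions per site — no molecular clock
is assumed). Multi-valued length sets are the normalized form of parallel
edges: two parallel edges of lengths 1 and 2 and one edge with Λ = {1, 2}
describe the same pair of evolutionary paths, and the parser merges the
former into the latter on input. A weighted tree is the reticulation-free,
single-length special case. A root of outdegree 1 is allowed in both
(it encodes the stub of an omitted outgroup lineage), and nodes may have
indegree and outdegree both above one (canonical forms produce them when
consecutive reticulate and speciation events collapse).

All lengths are exact rationals. This is a correctness requirement, not a
style choice: funnel suppression adds lengths (Minkowski set-sums), and both
the no-equally-long-paths check and displayed-tree deduplication test
*equality* of such sums, which floating point would corrupt. Decimal input
text like `0.1` is parsed as 1/10 exactly; values whose denominator is not
of the form 2ᵃ5ᵇ are written back as fractions (`1/3`) so that
serialization round-trips bit-exactly.

## Displayed trees

A switching keeps one in-edge per reticulation and one length per retained
edge; the resulting contained tree is pruned of unlabeled dead ends and its
indegree-1/outdegree-1 nodes are suppressed (lengths summing along the
chain). Enumeration proceeds per reticulation switching: the suppressed
topology is computed once, each compressed edge accumulating the Minkowski
sum of its constituent length sets, and the per-edge choices are expanded
afterwards. Trees are deduplicated by an exact canonical code (sorted child
subtrees plus length text), so two length choices that produce the same
summed tree count once — deduplication is by isomorphism of the *result*,
not by provenance of the switching. The total switching count
(∏ reticulation indegrees × ∏ |Λ(e)|) is checked against a cap (default
10⁶) before enumeration; exceeding it raises an error rather than silently
truncating.

## Canonicalization

Two rewrite rules are applied until neither fires: funnel suppression (R1)
removes a node with indegree ≥ 1 and outdegree 1, replacing each in-edge
(*u*, *v*) and the out-edge (*v*, *w*) by (*u*, *w*) with lengths
Λ(*u*,*v*) + Λ(*v*,*w*); multiedge merging (R2) unions parallel edges' sets.
R1 can transiently create parallel edges, so intermediates carry a
`multiedge_mode` flag and are not valid public networks; outputs always are.
Each step removes at least one edge, bounding the step count by the initial
edge count. Suppressing a funnel never creates one (its child's outdegree
is unchanged), so the number of R1 steps equals the input's funnel count.

The default scheduler is deterministic — R2 eagerly on the smallest
endpoint pair, else R1 on the smallest-id funnel — so traces are
reproducible. Order-independence of the *result* is treated as a tested
property, not an assumption: a seeded random scheduler exists solely so the
test suite can compare rule orders. The trace records every step
(rule, subject, length sets before/after) and can be replayed against the
input to reproduce the output exactly.

The inverse moves are `unzip` (slide δ of length from a reticulation's
out-edge onto its in-edges; defined on single-valued edges, merging the node
into its child at full δ) and `zip_insert_funnel` (redirect chosen in-edges
of a node through a fresh funnel, subtracting δ from every affected length
value — the exact constructive inverse of R1, and therefore canonical-form
preserving for multi-valued edges too).

## NELP, wishbones, cracks

A weighted path pairs a directed path with one length choice per edge;
paths over the same edges with different choices are distinct. NELP fails
iff some endpoint pair admits two distinct equally long weighted paths; the
checker enumerates all endpoint pairs exactly and returns a concrete witness
pair on failure. NELP is generic for divergence-style lengths (the
generator's continuous-flavoured sampler essentially never violates it) and
systematically broken by strict-clock lengths, which is why the unit-length
example family has non-unique canonical forms.

Wishbones (cracks) are unions of two root-leaf weighted paths sharing only a
prefix (only a prefix and a suffix). Classification computes the maximal
common weighted prefix and suffix and demands that the shared node set be
exactly the prefix (prefix ∪ suffix) nodes; an edge traversed by both paths
with *different* chosen lengths is not common, which is what makes a single
path with one doubly-valued edge a crack. Every root-leaf path is
degenerately both. Enumerations are deduplicated by canonical code and
guarded by a pair cap; the equality test over both enumerations is the
(exponential, small-instance) certificate that two NELP networks are
isomorphic.

## Canonical codes and isomorphism

Isomorphism means an edge-, length-set- and leaf-label-preserving bijection;
internal node identifiers are opaque. The code of a network is the
lexicographically smallest faithful serialization: children are ordered by
an isomorphism-invariant bottom-up key (length-set text plus subtree
shape), all orderings of tied children are enumerated, reticulations are
indexed in first-visit order and re-emitted as references. Because the
string determines the graph, equal codes imply isomorphism; because ties
are exhausted, isomorphic networks get equal codes. Bottom-up signatures
alone are *not* complete for DAGs (distinct nodes can share descendant
structure), hence the explicit minimization. The tie-permutation search is
capped (4 × 10⁵ candidates); at the package's working scale (tens of nodes,
few symmetric children) the search is effectively linear. A brute-force
bijection search (≤ 12 nodes) serves as the independent oracle in tests.

## Scoring

Network parsimony follows the displayed-tree formulation: unit-cost small
parsimony per tree (Sankoff dynamic programming, correct for multifurcating
trees, restricted to observed states — optimal under unit cost), minimized
per alignment and summed. Network likelihood mixes per-tree Jukes–Cantor
likelihoods (Felsenstein pruning, uniform base frequencies) with the
displayed-tree distribution induced by per-reticulation inheritance
probabilities: a tree's probability is the total probability of the
switchings yielding it, including reticulations pruned as dead ends, so the
distribution always sums to one. Jukes–Cantor is deliberate: the module
exists to demonstrate that indistinguishable networks score equally, not to
do inference. Likelihood requires single-valued length sets (one length per
tree edge) and refuses otherwise.

## Synthetic data and the example corpus

`random_network` grows a random rooted binary tree on n taxa and adds each
reticulation by subdividing two edges and bridging them (rejecting bridges
into an ancestor), then samples every edge length. The default sampler
draws k/10¹² with k uniform — an exact-rational surrogate for a continuous
draw, under which path-sum ties (NELP violations) have probability ≈ 10⁻¹²
per pair and effectively never occur; a unit-length sampler is provided to
emulate clock-like data where ties are systematic. `random_funnelize`
composes random `zip_insert_funnel` moves (random target, random in-edge
subset, δ a random fraction of the smallest affected length), which is how
indistinguishable non-isomorphic pairs are generated. What the generator
does *not* emulate: realistic birth–death branching, non-independent
lengths, inheritance-probability heterogeneity, or sequence evolution —
passing tests show the combinatorial theory holds, not that any inference
method works on real data.

The bundled corpus (`load_fixture`) provides small hand-built networks
exercising each structural regime: the nested-funnel pair fig3_N1/fig3_N2
with canonical form fig4_Nprime (the N2 lengths sit at x = 1/2, y = 1
inside the admissible family −y < x < min{λ₆, λ₅+λ₈}, 0 < y < λ₇; its
transcription is self-checked by the weighted-path sums ℓ₁ = λ₁+λ₆,
ℓ₂ = λ₂+λ₃+λ₅+λ₈, ℓ₃ = λ₂+λ₁₀+λ₉+λ₈, ℓ₄ = λ₃+λ₅, ℓ₅ = λ₁₀+λ₉ under the
default assignment λᵢ = i, chosen because distinct integers keep the
network NELP); the three-funnel network fig5_N whose funnel out-lengths
x = y = z = 0.05 are unidentifiable within (0, 0.1) and which displays 7
trees; the outgroup-omission trio fig7 (0.5-length root stub); the
unit-length family fig10_a–d (pairwise indistinguishable, pairwise
non-isomorphic, NELP-violating, extensible by adding more copies of its
repeated cherry unit); the four-step reduction example fig13; and the
wishbone/crack examples fig14.

## Numerical and design choices

- Caps: 10⁶ switchings, 10⁵ weighted paths per endpoint pair, 10⁵ path
  pairs for wishbone/crack enumeration; all overridable, all fail loudly.
- Degenerate inputs: a single labelled node is a valid network (and
  displays itself); the root survives suppression even at outdegree 1.
- Deterministic order everywhere: children sorted by invariant keys,
  funnels by node id, so repeated runs produce identical traces and
  serializations.
- Problem sizes in the test and acceptance suites (networks of 2–6 taxa
  with up to 4 reticulations; 300–500 repetitions per property) keep every
  enumeration well inside the caps while covering all rule interactions,
  including transient multiedges and funnel chains.
- CLI exit codes separate negative findings (1) from parse errors (3),
  cap violations (4) and precondition failures (5).

## Known limitations

Displayed-tree enumeration, wishbone/crack comparison and the path-based
NELP check are exponential in reticulation count and multi-valued edges by
nature; the library targets desk-scale analysis and certification, not
genome-scale networks. Whether a funnel-free NELP network can be
indistinguishable from a funnel-free NELP-violating one is an open
question; `indistinguishable(..., mode="canonical")` therefore *requires*
NELP of both inputs rather than assuming the stronger claim, and the direct
mode is the fallback. Likelihood scoring is single-model (Jukes–Cantor)
and unoptimized by design.
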