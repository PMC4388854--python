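# phylocanon

Canonical forms, displayed trees, and identifiability tests for weighted
rooted phylogenetic networks.

## The problem

Explicit phylogenetic networks describe evolution with reticulate events —
hybrid speciation, horizontal gene transfer, recombination — as rooted DAGs
whose reticulation nodes have more than one parent. Most inference criteria
evaluate a network *N* only through the set 𝒯(*N*) of weighted trees it
*displays* (the possible single-character histories): parsimony takes

Ps(*N* | *A*₁,…,*A*ₘ) = Σᵢ min_{T ∈ 𝒯(N)} Ps(*T* | *A*ᵢ),

and likelihood with inheritance probabilities takes

Pr(*A*₁,…,*A*ₘ | *N*) = Πᵢ Σ_{T ∈ 𝒯(N)} Pr(*A*ᵢ | *T*) Pr(*T* | *N*).

Distinct networks can display *exactly the same* weighted trees. Such
networks are **indistinguishable**: every criterion of the form above scores
them identically on any data, so no amount of data can separate them. The
resolution is to reconstruct only what is identifiable: the **canonical
form** of a network — a funnel-free network displaying the same trees —
which, under a mild genericity condition on branch lengths (**NELP**, "no
equally long paths"), is unique. This package implements that machinery for
networks whose edges carry finite *sets* of exact-rational branch lengths
(the normalized representation of parallel edges).

Core operations:

- **Displayed trees** — enumerate 𝒯(*N*) by switching reticulation in-edges
  and per-edge length choices, pruning dead ends, and suppressing
  degree-two nodes (summing lengths); deduplicated up to isomorphism.
- **Canonicalization** — exhaustively apply *funnel suppression* (R1:
  remove an indegree-≥1/outdegree-1 node, replacing in/out edge pairs by
  edges with Minkowski set-sums Λ(u,v) + Λ(v,w)) and *multiedge merging*
  (R2: union the length sets of parallel edges). The result is funnel-free,
  displays the same trees, and is order-independent.
- **NELP checking** — exact-rational search for two distinct weighted paths
  with equal endpoints and equal total length, with a concrete witness.
- **Wishbones and cracks** — unions of two root-leaf weighted paths sharing
  only a prefix (wishbone) or only a prefix and a suffix (crack); for NELP
  networks these characterize the network up to isomorphism.
- **Isomorphism** — canonical codes for leaf-labelled weighted DAGs, exact
  for length sets, cross-checked against brute-force search.
- **Scoring** — network parsimony (unit-cost small parsimony per displayed
  tree) and network likelihood (Jukes–Cantor mixture over the displayed-tree
  distribution), demonstrating score equality across indistinguishable
  networks.

All arithmetic on branch lengths is exact (`fractions.Fraction`); equality
of path lengths and length sets is never subject to floating-point error.

## Worked example

`fig3_N1` (bundled) is a four-taxon network in which leaf *b* descends from
two stacked reticulations, each a *funnel* (outdegree 1). Its three
displayed trees, canonical form, and NELP status:

```sh
$ phylocanon display --in fig3_N1.enwk
((d:22,(c:11,b:20):3):2,a:5);
(((d:12,b:24):10,c:14):2,a:5);
((b:13,a:4):1,(c:14,d:22):2);

$ phylocanon canonicalize --in fig3_N1.enwk --out canon.enwk --trace trace.json
$ cat canon.enwk
((b#H1:13,a:4):1,((d:12,#H1:24):10,(c:11,#H1:20):3):2);

$ phylocanon nelp --in fig3_N1.enwk
NELP holds
```

The three trees differ in where *b* attaches (to *a*'s lineage at distance
13, or below *c* or *d* at distances 20 and 24) — these three numbers are
all that is recoverable about *b*'s reticulate ancestry. The canonical form
makes that explicit: both funnels are suppressed and *b* becomes a
reticulation leaf with in-edge lengths {13, 20, 24}. The variant network
`fig3_N2`, with the two reticulations stacked in the opposite order, has the
same canonical form:

```python
>>> import phylocanon as pc
>>> n1, n2 = pc.load_fixture("fig3_N1"), pc.load_fixture("fig3_N2")
>>> pc.indistinguishable(n1, n2, mode="canonical")
True
>>> pc.are_isomorphic(n1, n2)
False
```

Indistinguishable but non-isomorphic: no displayed-tree-based method can
ever prefer one over the other, and only their shared canonical form is
reconstructible.

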