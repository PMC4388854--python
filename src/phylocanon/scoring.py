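"""Parsimony and likelihood of networks, computed through displayed trees.

This module demonstrates the identifiability problem that motivates canonical
forms.  Both scores evaluate a network *indirectly*, through the trees it
displays:

* parsimony:   Ps(N | A_1..A_m) = sum_i  min_{T in T(N)}  Ps(T | A_i)
* likelihood:  Pr(A_1..A_m | N) = prod_i sum_{T in T(N)} Pr(A_i | T) Pr(T | N)

where Pr(T | N) is induced by per-reticulation inheritance probabilities.
Networks displaying the same trees (with the same lengths and probabilities)
therefore receive identical scores on *any* data — they are indistinguishable
to every method built on these criteria.

The substitution model is deliberately the simplest equal-rates model
(Jukes-Cantor): the point of this module is score equality across
indistinguishable networks, not realistic inference.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

from .core import (CanonicalCode, Node, PhyloNetwork, WeightedTree,
                   require_valid, reticulation_nodes, tree_canonical_code)
from .display import (DEFAULT_SWITCHING_CAP, Switching, contained_tree,
                      displayed_trees, suppress_all)
from .errors import PreconditionError

DNA = "ACGT"


class Alignment:
    """Equal-length character sequences, one per taxon (DNA by default)."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("alignment must contain at least one sequence")
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {lengths}")
        if lengths == {0}:
            raise ValueError("alignment must have length >= 1")
        self.sequences = {taxon: seq.upper() for taxon, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(records)

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.sequences)

    def __len__(self) -> int:
        return len(next(iter(self.sequences.values())))

    def column(self, i: int) -> dict[str, str]:
        return {taxon: seq[i] for taxon, seq in self.sequences.items()}


def _check_taxa(phylo: PhyloNetwork, alignment: Alignment) -> None:
    if phylo.taxa() != alignment.taxa:
        raise PreconditionError(
            f"taxon mismatch: tree/network has {sorted(phylo.taxa())}, "
            f"alignment has {sorted(alignment.taxa)}")


def tree_parsimony(tree: WeightedTree, alignment: Alignment) -> int:
    """Small-parsimony score: minimal substitution count, summed per column.

    Unit-cost Sankoff dynamic programming over the (possibly multifurcating)
    rooted tree; branch lengths are ignored.  The score is 0 exactly when
    every column is constant, and is additive over columns.
    """
    _check_taxa(tree, alignment)
    g = tree.graph
    root = tree.root()
    order = list(reversed(list(_topo(tree))))  # leaves before ancestors
    total = 0
    for i in range(len(alignment)):
        column = alignment.column(i)
        states = sorted(set(column.values()) & set(DNA + "U")) or ["A"]
        cost: dict[Node, dict[str, float]] = {}
        for node in order:
            if g.out_degree(node) == 0:
                observed = column[tree.labels[node]]
                cost[node] = {s: (0 if (s == observed or observed not in states)
                                  else math.inf)
                              for s in states}
            else:
                cost[node] = {
                    s: sum(min(cost[c][t] + (s != t) for t in states)
                           for c in g.successors(node))
                    for s in states}
        total += int(min(cost[root].values()))
    return total


def _topo(phylo: PhyloNetwork):
    import networkx as nx
    return nx.topological_sort(phylo.graph)


def network_parsimony(network: PhyloNetwork, alignments: list[Alignment],
                      cap: int = DEFAULT_SWITCHING_CAP) -> int:
    """Per-alignment minimum over all displayed trees, summed."""
    require_valid(network)
    trees = displayed_trees(network, cap=cap)
    # Length choices never change a parsimony score; one tree per topology
    # would suffice, but the displayed set is small enough at this scale.
    return sum(min(tree_parsimony(t, a) for t in trees) for a in alignments)


# ---------------------------------------------------------------------------
# likelihood


class TreeDistribution(dict):
    """Mapping tree canonical code -> (tree, probability); sums to 1."""


def tree_distribution(network: PhyloNetwork,
                      inheritance_probs: dict[tuple[Node, Node], float] | None
                      ) -> TreeDistribution:
    """Distribution over displayed trees induced by inheritance probabilities.

    ``inheritance_probs`` maps each reticulation in-edge ``(parent, ret)`` to
    the probability that a character lineage follows that edge; per
    reticulation they must sum to 1 (uniform when ``None``).  The probability
    of a displayed tree is the total probability of the switchings that yield
    it.  Requires single-valued length sets.
    """
    require_valid(network)
    for u, v, lengths in network.edges():
        if len(lengths) != 1:
            raise PreconditionError(
                f"edge {u!r}->{v!r} carries {len(lengths)} lengths; the "
                "likelihood framework assigns one length per tree edge — "
                "resolve multi-valued length sets before scoring")
    rets = sorted(reticulation_nodes(network), key=str)
    probs: dict[tuple[Node, Node], float] = {}
    for ret in rets:
        parents = network.parents(ret)
        if inheritance_probs is None:
            for u in parents:
                probs[(u, ret)] = 1.0 / len(parents)
        else:
            values = []
            for u in parents:
                if (u, ret) not in inheritance_probs:
                    raise PreconditionError(
                        f"missing inheritance probability for edge "
                        f"{u!r}->{ret!r}")
                values.append(float(inheritance_probs[(u, ret)]))
            if any(p < 0 for p in values) or abs(sum(values) - 1.0) > 1e-9:
                raise PreconditionError(
                    f"inheritance probabilities of reticulation {ret!r} must "
                    f"be non-negative and sum to 1, got {values}")
            for u, p in zip(parents, values):
                probs[(u, ret)] = p

    dist = TreeDistribution()
    for combo in itertools.product(*(network.parents(r) for r in rets)):
        weight = 1.0
        for ret, parent in zip(rets, combo):
            weight *= probs[(parent, ret)]
        if weight == 0.0:
            continue
        switching = Switching(ret_in_edge=dict(zip(rets, combo)))
        tree = suppress_all(contained_tree(network, switching))
        code = tree_canonical_code(tree)
        if code in dist:
            dist[code] = (dist[code][0], dist[code][1] + weight)
        else:
            dist[code] = (tree, weight)
    return dist


def tree_log_likelihood(tree: WeightedTree, alignment: Alignment) -> float:
    """ln Pr(A | T) under Jukes-Cantor via Felsenstein pruning."""
    _check_taxa(tree, alignment)
    g = tree.graph
    root = tree.root()
    order = list(reversed(list(_topo(tree))))

    def transition(t: float):
        e = math.exp(-4.0 * t / 3.0)
        same, diff = 0.25 + 0.75 * e, 0.25 - 0.25 * e
        return same, diff

    edge_p = {}
    for u, v, lengths in tree.edges():
        edge_p[(u, v)] = transition(float(lengths.single()))

    loglik = 0.0
    for i in range(len(alignment)):
        column = alignment.column(i)
        partial: dict[Node, list[float]] = {}
        for node in order:
            if g.out_degree(node) == 0:
                state = column[tree.labels[node]]
                partial[node] = [1.0 if (state not in DNA or DNA[k] == state)
                                 else 0.0 for k in range(4)]
            else:
                vec = [1.0] * 4
                for child in g.successors(node):
                    same, diff = edge_p[(node, child)]
                    cp = partial[child]
                    s = sum(cp)
                    for k in range(4):
                        vec[k] *= diff * (s - cp[k]) + same * cp[k]
                partial[node] = vec
        site = 0.25 * sum(partial[root])
        if site <= 0.0:
            return -math.inf
        loglik += math.log(site)
    return loglik


def network_likelihood(network: PhyloNetwork,
                       inheritance_probs: dict | None,
                       alignments: list[Alignment]) -> float:
    """Pr(A_1..A_m | N): per alignment, the displayed-tree mixture likelihood.

    Networks with identical tree distributions (same trees, same lengths,
    same probabilities) receive identical likelihoods on any data.
    """
    dist = tree_distribution(network, inheritance_probs)
    result = 1.0
    for alignment in alignments:
        result *= sum(prob * math.exp(tree_log_likelihood(tree, alignment))
                      for tree, prob in dist.values())
    return result
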