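"""Random networks, random funnel insertion, and random alignments.

The generator grows a random rooted binary tree and then adds reticulations
by subdividing two edges and connecting them; every edge finally receives a
length drawn by a pluggable sampler.  The default sampler draws exact
rationals with denominator 10^12 — a fine enough grid that, like independent
continuous draws, two distinct path sums essentially never tie, so generated
networks satisfy the no-equally-long-paths property with overwhelming
empirical frequency.

``random_funnelize`` is the engine for generating indistinguishable network
pairs: it re-inserts funnels above randomly chosen nodes (the constructive
inverse of funnel suppression), which changes the graph without changing the
canonical form or the displayed trees.
"""

from __future__ import annotations

import random
from fractions import Fraction
from typing import Callable

import networkx as nx

from .canonical import zip_insert_funnel
from .core import (LengthSet, PhyloNetwork, funnel_nodes, is_funnel_free,
                   require_valid)
from .errors import PreconditionError
from .scoring import DNA, Alignment

LengthSampler = Callable[[random.Random], Fraction]

_DENOM = 10**12


def continuous_length_sampler(rng: random.Random) -> Fraction:
    """Exact-rational stand-in for a continuous draw on (0, 1]."""
    return Fraction(rng.randint(1, _DENOM), _DENOM)


def unit_length_sampler(rng: random.Random) -> Fraction:
    """Strict-clock-flavoured sampler: every edge gets length 1."""
    return Fraction(1)


def _rng(seed, rng):
    if rng is not None:
        return rng
    return random.Random(seed)


def random_network(n_taxa: int, n_reticulations: int,
                   seed: int | None = None,
                   rng: random.Random | None = None,
                   length_sampler: LengthSampler = continuous_length_sampler,
                   ) -> PhyloNetwork:
    """A random valid network, reproducible under ``seed``.

    With ``n_reticulations=0`` the result is a tree.  Each reticulation is a
    new indegree-2 node bridging two subdivided tree edges (acyclicity is
    enforced by rejecting bridges into an ancestor).
    """
    if n_taxa < 1:
        raise PreconditionError("n_taxa must be >= 1")
    if n_reticulations < 0:
        raise PreconditionError("n_reticulations must be >= 0")
    if n_taxa == 1 and n_reticulations > 0:
        raise PreconditionError(
            "reticulations require at least two tree edges (n_taxa >= 2)")
    rand = _rng(seed, rng)

    net = PhyloNetwork()
    counter = [0]

    def fresh() -> str:
        counter[0] += 1
        return f"v{counter[0]}"

    root = fresh()
    net.add_node(root)
    taxa = [f"t{i + 1}" for i in range(n_taxa)]
    if n_taxa == 1:
        leaf = fresh()
        net.add_node(leaf, taxa[0])
        net.graph.add_edge(root, leaf)
    else:
        for taxon in taxa[:2]:
            leaf = fresh()
            net.add_node(leaf, taxon)
            net.graph.add_edge(root, leaf)
        for taxon in taxa[2:]:
            u, v = _pick_edge(net, rand)
            mid = _subdivide(net, u, v, fresh())
            leaf = fresh()
            net.add_node(leaf, taxon)
            net.graph.add_edge(mid, leaf)

    for _ in range(n_reticulations):
        for _attempt in range(200):
            e1 = _pick_edge(net, rand)
            e2 = _pick_edge(net, rand)
            if e1 == e2:
                continue
            # the bridge s -> t must not close a cycle: t's side may not
            # reach e1's tail
            if nx.has_path(net.graph, e2[1], e1[0]) or e2[1] == e1[0]:
                continue
            s = _subdivide(net, *e1, fresh())
            t = _subdivide(net, *e2, fresh())
            net.graph.add_edge(s, t)
            break
        else:
            raise PreconditionError(
                "could not place a reticulation without creating a cycle")

    for u, v in list(net.graph.edges()):
        net.graph[u][v][0]["lengths"] = LengthSet([length_sampler(rand)])
    require_valid(net)
    return net


def _pick_edge(net: PhyloNetwork, rand: random.Random):
    edges = sorted(net.graph.edges(keys=False),
                   key=lambda e: (str(e[0]), str(e[1])))
    return edges[rand.randrange(len(edges))]


def _subdivide(net: PhyloNetwork, u, v, mid):
    net.graph.remove_edge(u, v)
    net.add_node(mid)
    net.graph.add_edge(u, mid)
    net.graph.add_edge(mid, v)
    return mid


def random_funnelize(network: PhyloNetwork, k: int,
                     seed: int | None = None,
                     rng: random.Random | None = None) -> PhyloNetwork:
    """Insert ``k`` random funnels; the canonical form is unchanged.

    Requires a funnel-free input.  Different seeds typically yield
    indistinguishable but non-isomorphic variants of the same network.
    """
    if k < 1:
        raise PreconditionError("k must be >= 1")
    if not is_funnel_free(network):
        raise PreconditionError("random_funnelize requires a funnel-free input")
    rand = _rng(seed, rng)
    current = network.copy()
    for _ in range(k):
        candidates = sorted(
            (n for n in current.graph.nodes if current.graph.in_degree(n) >= 1),
            key=str)
        if not candidates:
            raise PreconditionError("no feasible funnel-insertion site")
        target = candidates[rand.randrange(len(candidates))]
        parents = current.parents(target)
        subset = [u for u in parents if rand.random() < 0.5]
        if not subset:
            subset = [parents[rand.randrange(len(parents))]]
        min_value = min(min(current.edge_lengths(u, target).values)
                        for u in subset)
        delta = min_value * Fraction(rand.randint(1, 99), 100)
        current = zip_insert_funnel(current, target, subset, delta)
    assert funnel_nodes(current)
    return current


def randomize_lengths(network: PhyloNetwork,
                      seed: int | None = None,
                      rng: random.Random | None = None,
                      length_sampler: LengthSampler = continuous_length_sampler,
                      ) -> PhyloNetwork:
    """Copy of the network with a freshly sampled single length per edge."""
    rand = _rng(seed, rng)
    out = network.copy()
    for u, v in list(out.graph.edges(keys=False)):
        key = next(iter(out.graph[u][v]))
        out.graph[u][v][key]["lengths"] = LengthSet([length_sampler(rand)])
    return out


def random_alignment(taxa, length: int,
                     seed: int | None = None,
                     rng: random.Random | None = None) -> Alignment:
    """IID uniform DNA columns; no phylogenetic signal, for score demos."""
    rand = _rng(seed, rng)
    return Alignment({taxon: "".join(rand.choice(DNA) for _ in range(length))
                      for taxon in sorted(taxa)})
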