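"""Trees displayed by a network, and indistinguishability.

A *switching* jointly picks one in-edge per reticulation and one length per
retained edge.  The corresponding *contained tree* keeps the chosen edges,
prunes unlabeled dead ends, and is rooted at the network's root; suppressing
its indegree-1/outdegree-1 nodes (summing lengths) yields a *displayed tree*.
Two networks are indistinguishable when they display exactly the same set of
weighted trees — no inference criterion that scores a network through its
displayed trees can tell them apart.

Enumeration is exponential in the number of reticulations and multi-valued
edges, so every enumerating operation takes a cap and refuses loudly (never
truncates silently) when the switching count exceeds it.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

from .core import (CanonicalCode, LengthSet, Node, PhyloNetwork, WeightedTree,
                   require_valid, reticulation_nodes, tree_canonical_code)
from .errors import CapExceededError, PreconditionError

DEFAULT_SWITCHING_CAP = 10**6


@dataclass(frozen=True)
class Switching:
    """One in-edge per reticulation plus one length per retained edge."""

    ret_in_edge: dict[Node, Node] = field(default_factory=dict)  # ret -> parent
    edge_length: dict[tuple[Node, Node], Fraction] = field(default_factory=dict)


def _validate_switching(network: PhyloNetwork, switching: Switching) -> None:
    rets = reticulation_nodes(network)
    if set(switching.ret_in_edge) != rets:
        raise PreconditionError(
            f"switching must choose one in-edge for each reticulation {rets}")
    for ret, parent in switching.ret_in_edge.items():
        if parent not in network.parents(ret):
            raise PreconditionError(
                f"{parent!r} is not a parent of reticulation {ret!r}")


def _retained_edges(network: PhyloNetwork,
                    ret_choice: dict[Node, Node]) -> set[tuple[Node, Node]]:
    rets = set(ret_choice)
    retained = set()
    for u, v, _ in network.edges():
        if v in rets and ret_choice[v] != u:
            continue
        retained.add((u, v))
    return retained


def _pruned_subtree(network: PhyloNetwork,
                    retained: set[tuple[Node, Node]]) -> dict[Node, list[Node]]:
    """Children map after iteratively deleting unlabeled dead-end nodes."""
    children: dict[Node, list[Node]] = {}
    for u, v in retained:
        children.setdefault(u, []).append(v)
        children.setdefault(v, [])
    alive = set(children) | {network.root()}
    changed = True
    while changed:
        changed = False
        for node in list(alive):
            kids = [c for c in children.get(node, []) if c in alive]
            if not kids and node not in network.labels:
                alive.discard(node)
                changed = True
    return {n: sorted((c for c in children.get(n, []) if c in alive), key=str)
            for n in alive}


def contained_tree(network: PhyloNetwork, switching: Switching) -> WeightedTree:
    """The tree selected by a switching (suppressible nodes allowed).

    Every switching yields a tree on the full taxon set: after dropping the
    unchosen reticulation in-edges each non-root node keeps exactly one
    in-edge, so the structure reachable from the root is a tree, and pruning
    unlabeled outdegree-0 nodes removes branches cut off from all leaves.
    """
    require_valid(network)
    _validate_switching(network, switching)
    retained = _retained_edges(network, switching.ret_in_edge)
    children = _pruned_subtree(network, retained)

    tree = WeightedTree()
    for node in children:
        tree.add_node(node, network.labels.get(node))
    for u, kids in children.items():
        for v in kids:
            lengths = network.edge_lengths(u, v)
            if (u, v) in switching.edge_length:
                chosen = switching.edge_length[(u, v)]
                if chosen not in lengths:
                    raise PreconditionError(
                        f"chosen length {chosen} not in edge set "
                        f"{lengths.text()} of {u!r}->{v!r}")
            else:
                chosen = lengths.single()
            tree.add_edge(u, v, LengthSet([chosen]))
    return tree


def suppress_all(tree: WeightedTree) -> WeightedTree:
    """Suppress every indegree-1/outdegree-1 node, summing edge lengths.

    The result is independent of the suppression order, root-to-leaf path
    lengths are preserved, and the root is never suppressed even when its
    outdegree is 1.
    """
    out = tree.copy()
    g = out.graph
    root = out.root()
    again = True
    while again:
        again = False
        for v in list(g.nodes):
            if v == root or g.in_degree(v) != 1 or g.out_degree(v) != 1:
                continue
            (u, _, d_in), = g.in_edges(v, data=True)
            (_, w, d_out), = g.out_edges(v, data=True)
            g.remove_node(v)
            # Minkowski sum: for single-valued tree edges this is plain
            # addition lambda(e) + lambda(f)
            out.add_edge(u, w, d_in["lengths"] + d_out["lengths"])
            again = True
    return out


def count_switchings(network: PhyloNetwork) -> int:
    """Upper bound on contained trees: prod(indegrees) * prod(|length sets|)."""
    total = 1
    for ret in reticulation_nodes(network):
        total *= network.graph.in_degree(ret)
    for _, _, lengths in network.edges():
        total *= len(lengths)
    return total


def displayed_trees(network: PhyloNetwork,
                    cap: int = DEFAULT_SWITCHING_CAP) -> list[WeightedTree]:
    """All trees displayed by the network, deduplicated up to isomorphism.

    Enumerates reticulation switchings, compresses suppressible chains (each
    compressed edge accumulates the Minkowski sum of its constituent length
    sets), then expands the per-edge length choices.  Results are deduplicated
    by exact tree canonical codes, so topologically identical trees whose
    different length choices happen to produce the same summed edge lengths
    count once.
    """
    require_valid(network)
    n_switchings = count_switchings(network)
    if n_switchings > cap:
        raise CapExceededError(
            f"{n_switchings} switchings exceed the cap of {cap}")

    rets = sorted(reticulation_nodes(network), key=str)
    found: dict[CanonicalCode, WeightedTree] = {}
    for combo in itertools.product(*(network.parents(r) for r in rets)):
        ret_choice = dict(zip(rets, combo))
        retained = _retained_edges(network, ret_choice)
        children = _pruned_subtree(network, retained)
        compressed = _compress(network, children)
        for tree in _expand_lengths(compressed, network):
            found.setdefault(tree_canonical_code(tree), tree)
    return [found[code] for code in sorted(found, key=str)]


def _compress(network: PhyloNetwork, children: dict[Node, list[Node]]):
    """Suppress chains in a pruned subtree; edges carry summed LengthSets."""
    root = network.root()
    edges: list[tuple[Node, Node, LengthSet]] = []

    def walk(node: Node):
        for child in children[node]:
            lengths = network.edge_lengths(node, child)
            current = child
            while (current not in network.labels
                   and len(children[current]) == 1):
                nxt = children[current][0]
                lengths = lengths + network.edge_lengths(current, nxt)
                current = nxt
            edges.append((node, current, lengths))
            walk(current)

    walk(root)
    return root, edges


def _expand_lengths(compressed, network: PhyloNetwork):
    root, edges = compressed
    choice_lists = [sorted(lengths.values) for _, _, lengths in edges]
    for combo in itertools.product(*choice_lists):
        tree = WeightedTree()
        tree.add_node(root)
        for (u, v, _), value in zip(edges, combo):
            tree.add_node(u, network.labels.get(u))
            tree.add_node(v, network.labels.get(v))
            tree.add_edge(u, v, LengthSet([value]))
        if not edges:  # single-node network
            tree.add_node(root, network.labels.get(root))
        yield tree


def displays(network: PhyloNetwork, tree: WeightedTree,
             cap: int = DEFAULT_SWITCHING_CAP) -> bool:
    """Membership of ``tree`` in the displayed set, up to isomorphism."""
    if network.taxa() != tree.taxa():
        warnings.warn("taxon sets differ; the tree cannot be displayed")
        return False
    target = tree_canonical_code(tree)
    return any(tree_canonical_code(t) == target
               for t in displayed_trees(network, cap=cap))


def indistinguishable(n1: PhyloNetwork, n2: PhyloNetwork,
                      mode: str = "direct",
                      cap: int = DEFAULT_SWITCHING_CAP) -> bool:
    """Do the two networks display exactly the same set of weighted trees?

    ``direct`` compares the deduplicated displayed-tree sets.  ``canonical``
    compares canonical forms instead — valid only when both networks satisfy
    the no-equally-long-paths property, which is the hypothesis under which
    indistinguishability is equivalent to having the same canonical form.
    """
    if mode == "direct":
        codes1 = {tree_canonical_code(t) for t in displayed_trees(n1, cap=cap)}
        codes2 = {tree_canonical_code(t) for t in displayed_trees(n2, cap=cap)}
        return codes1 == codes2
    if mode == "canonical":
        from .canonical import canonicalize
        from .core import network_canonical_code
        from .nelp import check_nelp
        for name, net in (("first", n1), ("second", n2)):
            ok, _ = check_nelp(net)
            if not ok:
                raise PreconditionError(
                    f"the {name} network violates the no-equally-long-paths "
                    "property; canonical-form comparison requires it "
                    "(canonical forms are unique only under NELP) — use "
                    "mode='direct' instead")
        c1, _ = canonicalize(n1)
        c2, _ = canonicalize(n2)
        return network_canonical_code(c1) == network_canonical_code(c2)
    raise ValueError(f"unknown mode {mode!r}; expected 'direct' or 'canonical'")
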