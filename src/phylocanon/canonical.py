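"""Reduction of a network to its canonical form, and the inverse moves.

The canonical form of a network is a funnel-free network displaying exactly
the same weighted trees.  It is computed by exhaustively applying two local
rewrite rules until neither applies:

* **Funnel suppression (R1).**  A funnel ``v`` (indegree k >= 1, outdegree 1,
  out-edge to ``w``) is removed; each in-edge ``(u_i, v)`` is replaced by
  ``(u_i, w)`` carrying the Minkowski set-sum ``L(u_i, v) + L(v, w)``.
* **Multiedge merging (R2).**  Parallel edges ``u -> w`` are replaced by a
  single edge carrying the union of their length sets.

R1 may transiently create parallel edges, so intermediates live in
``multiedge_mode``; the final output is always simple.  Each step removes at
least one edge, so the reduction terminates, and the result is independent of
the order in which applicable rules are fired (checked as a property, not
assumed: the scheduler is deterministic by default and can be seeded random
for confluence testing).

The inverse moves — ``unzip`` (sliding length from a reticulation's out-edge
onto its in-edges) and ``zip_insert_funnel`` (re-inserting a funnel above a
node) — generate indistinguishable variants of a network without changing
its displayed trees.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction

from .core import (LengthSet, Node, PhyloNetwork, funnel_nodes, require_valid,
                   validate_network)
from .errors import PreconditionError


@dataclass(frozen=True)
class ReductionStep:
    rule: str                      # "R1" or "R2"
    subject: object                # funnel node (R1) or edge endpoints (R2)
    before: tuple[str, ...]        # length-set texts of the edges removed
    after: tuple[str, ...]         # length-set texts of the edges created


class ReductionTrace(list):
    """Ordered record of reduction steps; replayable against the input."""

    def rule_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {"R1": 0, "R2": 0}
        for step in self:
            counts[step.rule] += 1
        return counts

    def replay(self, network: PhyloNetwork) -> PhyloNetwork:
        """Re-apply the recorded steps to ``network`` (same node ids)."""
        current = network.copy()
        current.multiedge_mode = True
        for step in self:
            if step.rule == "R1":
                current = apply_r1(current, step.subject)
            else:
                current = apply_r2(current, step.subject)
        current.multiedge_mode = False
        return current


def apply_r1(network: PhyloNetwork, funnel: Node) -> PhyloNetwork:
    """Suppress one funnel; the result may contain parallel edges."""
    g = network.graph
    if not (g.in_degree(funnel) > 0 and g.out_degree(funnel) == 1):
        raise PreconditionError(f"{funnel!r} is not a funnel")
    out = network.copy()
    out.multiedge_mode = True
    og = out.graph
    (_, w, d_out), = og.out_edges(funnel, data=True)
    out_lengths: LengthSet = d_out["lengths"]
    in_edges = [(u, d["lengths"]) for u, _, d in og.in_edges(funnel, data=True)]
    og.remove_node(funnel)
    for u, in_lengths in in_edges:
        # Minkowski set-sum; duplicates collapse because lengths form a set
        og.add_edge(u, w, lengths=in_lengths + out_lengths)
    return out


def apply_r2(network: PhyloNetwork, endpoints: tuple[Node, Node]) -> PhyloNetwork:
    """Merge all parallel edges between ``endpoints`` into one (union)."""
    u, w = endpoints
    g = network.graph
    if not g.has_edge(u, w) or len(g[u][w]) < 2:
        raise PreconditionError(f"no parallel edges between {u!r} and {w!r}")
    out = network.copy()
    og = out.graph
    union: LengthSet | None = None
    for data in og[u][w].values():
        union = data["lengths"] if union is None else union | data["lengths"]
    while og.has_edge(u, w):
        og.remove_edge(u, w)
    og.add_edge(u, w, lengths=union)
    return out


def canonicalize(network: PhyloNetwork,
                 rng: random.Random | None = None
                 ) -> tuple[PhyloNetwork, ReductionTrace]:
    """Reduce to the unique funnel-free, multiedge-free canonical form.

    The default scheduler is deterministic: merge parallel edges eagerly,
    otherwise suppress the smallest-id funnel.  Passing a seeded ``rng``
    picks uniformly among all applicable rewrites instead, which exists
    solely so the order-independence of the result can be tested.
    """
    require_valid(network)
    current = network.copy()
    current.multiedge_mode = True
    trace = ReductionTrace()
    while True:
        multi = current.parallel_edge_pairs()
        funnels = sorted(funnel_nodes(current), key=str)
        if not multi and not funnels:
            break
        if rng is None:
            action = ("R2", multi[0]) if multi else ("R1", funnels[0])
        else:
            options = [("R2", pair) for pair in multi]
            options += [("R1", node) for node in funnels]
            action = options[rng.randrange(len(options))]
        rule, subject = action
        if rule == "R2":
            u, w = subject
            before = tuple(d["lengths"].text()
                           for d in current.graph[u][w].values())
            current = apply_r2(current, subject)
            after = (current.edge_lengths(u, w).text(),)
        else:
            g = current.graph
            (_, w, d_out), = g.out_edges(subject, data=True)
            before = tuple(d["lengths"].text()
                           for _, _, d in g.in_edges(subject, data=True))
            before += (d_out["lengths"].text(),)
            parents = [u for u, _, _ in g.in_edges(subject, data=True)]
            current = apply_r1(current, subject)
            after = tuple(sorted(
                d["lengths"].text()
                for u, v, d in current.graph.edges(data=True)
                if v == w and u in parents))
        trace.append(ReductionStep(rule, subject, before, after))
    current.multiedge_mode = False
    report = validate_network(current)
    if report:  # cannot happen for valid input; defensive
        raise PreconditionError(f"reduction produced an invalid network: {report}")
    return current, trace


def unzip(network: PhyloNetwork, node: Node, delta: Fraction) -> PhyloNetwork:
    """Slide ``delta`` of length from a reticulation's out-edge to its in-edges.

    ``node`` must have outdegree 1 and single-valued length sets on every
    touched edge.  With ``delta`` equal to the whole out-edge length the
    reticulation merges with its child; the displayed trees are unchanged
    either way.
    """
    delta = Fraction(delta)
    g = network.graph
    if g.out_degree(node) != 1:
        raise PreconditionError(f"{node!r} must have outdegree 1")
    if g.in_degree(node) < 1:
        raise PreconditionError(f"{node!r} must have at least one in-edge")
    (_, w, d_out), = g.out_edges(node, data=True)
    out_length = d_out["lengths"].single()
    in_edges = [(u, d["lengths"].single())
                for u, _, d in g.in_edges(node, data=True)]
    if not (0 < delta <= out_length):
        raise PreconditionError(
            f"delta must satisfy 0 < delta <= {out_length}, got {delta}")

    out = network.copy()
    og = out.graph
    if delta < out_length:
        out.set_edge_lengths(node, w, LengthSet([out_length - delta]))
        for u, lam in in_edges:
            out.set_edge_lengths(u, node, LengthSet([lam + delta]))
    else:  # full unzip: node coincides with its child
        og.remove_node(node)
        for u, lam in in_edges:
            out.add_edge(u, w, LengthSet([lam + delta]))
    return out


def zip_insert_funnel(network: PhyloNetwork, target: Node,
                      parents: list[Node], delta: Fraction) -> PhyloNetwork:
    """Insert a funnel above ``target``, the constructive inverse of R1.

    The in-edges of ``target`` coming from ``parents`` are redirected to a new
    funnel ``v`` with every length value reduced by ``delta``; a new edge
    ``(v, target)`` carries length ``delta``.  Suppressing ``v`` again (R1)
    restores the original network, so the canonical form is unchanged.
    """
    delta = Fraction(delta)
    if delta <= 0:
        raise PreconditionError("delta must be > 0")
    if not parents:
        raise PreconditionError("need at least one in-edge to redirect")
    g = network.graph
    actual = set(network.parents(target))
    for u in parents:
        if u not in actual:
            raise PreconditionError(f"{u!r} is not a parent of {target!r}")
        for value in network.edge_lengths(u, target).values:
            if value <= delta:
                raise PreconditionError(
                    f"delta {delta} must be strictly below every length on "
                    f"edge {u!r}->{target!r} (found {value})")

    out = network.copy()
    v = out.fresh_node("funnel")
    out.add_node(v)
    for u in parents:
        lengths = out.edge_lengths(u, target)
        out.graph.remove_edge(u, target)
        out.add_edge(u, v, LengthSet(x - delta for x in lengths.values))
    out.add_edge(v, target, LengthSet([delta]))
    return out
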