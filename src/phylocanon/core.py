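"""Core data model: weighted rooted phylogenetic networks.

A network is a rooted DAG whose leaves are bijectively labelled with taxa and
whose every edge carries a *finite set* of strictly positive branch lengths
(divergence units, e.g. expected substitutions per site).  Multi-valued length
sets are the compact alternative to parallel edges: an edge with lengths
{1, 2} encodes two evolutionary paths of different lengths between the same
pair of ancestors.  A weighted tree is the special case with no reticulations
and a single length per edge.

All lengths are exact rationals (:class:`fractions.Fraction`) and all
comparisons are exact: no-equally-long-paths checks and funnel-suppression
set-sums are equality-sensitive, so floating point is never used internally.
"""

from __future__ import annotations

import itertools
import re
from fractions import Fraction
from typing import Callable, Hashable, Iterable, Iterator

import networkx as nx

from .errors import CapExceededError, PreconditionError

Node = Hashable

_FRACTION_RE = re.compile(r"^[+-]?\d+(\.\d+)?([eE][+-]?\d+)?$|^[+-]?\d+/\d+$")


def parse_rational(text: str) -> Fraction:
    """Parse decimal ('0.25'), integer ('3') or fraction ('1/3') text exactly."""
    text = text.strip()
    if not _FRACTION_RE.match(text):
        raise ValueError(f"not a rational number: {text!r}")
    return Fraction(text)


def format_rational(value: Fraction) -> str:
    """Render a rational exactly: terminating decimal if possible, else 'p/q'."""
    den = value.denominator
    if den == 1:
        return str(value.numerator)
    d = den
    for p in (2, 5):
        while d % p == 0:
            d //= p
    if d != 1:  # does not terminate in base 10
        return f"{value.numerator}/{value.denominator}"
    # terminates: scale to an integer over a power of ten
    exp = 0
    scaled = value
    while scaled.denominator != 1:
        scaled *= 10
        exp += 1
    digits = str(abs(scaled.numerator)).rjust(exp + 1, "0")
    sign = "-" if value < 0 else ""
    if exp == 0:
        return sign + digits
    return f"{sign}{digits[:-exp]}.{digits[-exp:]}"


class LengthSet:
    """A finite, non-empty set of strictly positive exact branch lengths."""

    __slots__ = ("values",)

    def __init__(self, values: Iterable[Fraction | int | str]):
        vals = frozenset(
            v if isinstance(v, Fraction) else
            (parse_rational(v) if isinstance(v, str) else Fraction(v))
            for v in values
        )
        if not vals:
            raise ValueError("LengthSet must be non-empty")
        if any(v <= 0 for v in vals):
            raise ValueError(f"LengthSet values must be > 0, got {sorted(vals)}")
        self.values: frozenset[Fraction] = vals

    @classmethod
    def of(cls, *values) -> "LengthSet":
        return cls(values)

    def __add__(self, other: "LengthSet") -> "LengthSet":
        """Minkowski set-sum {a + b : a in self, b in other}."""
        return LengthSet(a + b for a in self.values for b in other.values)

    def __or__(self, other: "LengthSet") -> "LengthSet":
        return LengthSet(self.values | other.values)

    def __eq__(self, other) -> bool:
        return isinstance(other, LengthSet) and self.values == other.values

    def __hash__(self) -> int:
        return hash(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self) -> Iterator[Fraction]:
        return iter(sorted(self.values))

    def __contains__(self, value) -> bool:
        return Fraction(value) in self.values

    def single(self) -> Fraction:
        """The unique value; raises if the set is multi-valued."""
        if len(self.values) != 1:
            raise PreconditionError(
                f"expected a single-valued length set, got {self.text()}")
        return next(iter(self.values))

    def text(self) -> str:
        """Normalized text: values ascending, exact; braces iff multi-valued."""
        parts = [format_rational(v) for v in sorted(self.values)]
        if len(parts) == 1:
            return parts[0]
        return "{" + ",".join(parts) + "}"

    def __repr__(self) -> str:
        return f"LengthSet({self.text()})"


class Violation:
    """One violated structural invariant, pointing at the offending element."""

    __slots__ = ("code", "subject", "message")

    def __init__(self, code: str, subject, message: str):
        self.code = code
        self.subject = subject
        self.message = message

    def __repr__(self) -> str:
        return f"Violation({self.code}: {self.message})"

    def __eq__(self, other):
        return (isinstance(other, Violation)
                and (self.code, self.subject) == (other.code, other.subject))

    def __hash__(self):
        return hash((self.code, str(self.subject)))


class PhyloNetwork:
    """A weighted rooted phylogenetic network.

    Thin wrapper around a :class:`networkx.MultiDiGraph`: nodes are opaque
    identifiers, each edge carries a :class:`LengthSet`, and leaves carry taxon
    labels.  Parallel edges are permitted only while ``multiedge_mode`` is on
    (they arise transiently during reduction to canonical form); public,
    validated networks are always simple.
    """

    def __init__(self, multiedge_mode: bool = False):
        self.graph = nx.MultiDiGraph()
        self.labels: dict[Node, str] = {}
        self.multiedge_mode = multiedge_mode

    # -- construction -----------------------------------------------------

    def add_node(self, node: Node, label: str | None = None) -> Node:
        self.graph.add_node(node)
        if label is not None:
            self.labels[node] = label
        return node

    def add_edge(self, u: Node, v: Node, lengths: LengthSet | Iterable) -> None:
        if not isinstance(lengths, LengthSet):
            lengths = LengthSet(lengths)
        if self.graph.has_edge(u, v) and not self.multiedge_mode:
            # Parallel edges with the same endpoints denote the same object as
            # one edge with the union of the lengths; normalize eagerly.
            key = next(iter(self.graph[u][v]))
            self.graph[u][v][key]["lengths"] = self.graph[u][v][key]["lengths"] | lengths
        else:
            self.graph.add_edge(u, v, lengths=lengths)

    def copy(self) -> "PhyloNetwork":
        out = type(self)(self.multiedge_mode)
        out.graph = self.graph.copy()
        out.labels = dict(self.labels)
        return out

    # -- structural queries ------------------------------------------------

    @property
    def nodes(self):
        return self.graph.nodes

    def edges(self) -> list[tuple[Node, Node, LengthSet]]:
        return [(u, v, d["lengths"]) for u, v, d in self.graph.edges(data=True)]

    def edge_lengths(self, u: Node, v: Node) -> LengthSet:
        data = self.graph[u][v]
        if len(data) != 1:
            raise PreconditionError(f"parallel edges between {u!r} and {v!r}")
        return next(iter(data.values()))["lengths"]

    def set_edge_lengths(self, u: Node, v: Node, lengths: LengthSet) -> None:
        data = self.graph[u][v]
        if len(data) != 1:
            raise PreconditionError(f"parallel edges between {u!r} and {v!r}")
        key = next(iter(data))
        self.graph[u][v][key]["lengths"] = lengths

    def parallel_edge_pairs(self) -> list[tuple[Node, Node]]:
        return sorted(
            {(u, v) for u, v in self.graph.edges() if len(self.graph[u][v]) > 1},
            key=lambda p: (str(p[0]), str(p[1])))

    def root(self) -> Node:
        roots = [n for n in self.graph.nodes if self.graph.in_degree(n) == 0]
        if len(roots) != 1:
            raise PreconditionError(f"network has {len(roots)} indegree-0 nodes")
        return roots[0]

    def leaves(self) -> list[Node]:
        return [n for n in self.graph.nodes if self.graph.out_degree(n) == 0]

    def taxa(self) -> frozenset[str]:
        return frozenset(self.labels.values())

    def parents(self, node: Node) -> list[Node]:
        return sorted(self.graph.predecessors(node), key=str)

    def children(self, node: Node) -> list[Node]:
        return sorted(self.graph.successors(node), key=str)

    def fresh_node(self, hint: str = "n") -> Node:
        i = 0
        while f"{hint}{i}" in self.graph.nodes:
            i += 1
        return f"{hint}{i}"

    def leaf_of(self, taxon: str) -> Node:
        for node, label in self.labels.items():
            if label == taxon:
                return node
        raise KeyError(taxon)

    def __repr__(self) -> str:
        return (f"<{type(self).__name__} taxa={sorted(self.taxa())} "
                f"nodes={self.graph.number_of_nodes()} "
                f"edges={self.graph.number_of_edges()}>")


class WeightedTree(PhyloNetwork):
    """A network with no reticulations and exactly one length per edge.

    Displayed trees additionally have no suppressible (indegree-1/outdegree-1)
    nodes; trees *contained in* a network may keep them until suppression.
    A root of outdegree 1 is explicitly permitted — it encodes the stub of an
    omitted outgroup lineage.
    """

    def edge_length(self, u: Node, v: Node) -> Fraction:
        return self.edge_lengths(u, v).single()


# ---------------------------------------------------------------------------
# validation


def validate_network(network: PhyloNetwork,
                     allow_suppressible: bool = True) -> list[Violation]:
    """Report every violated structural invariant; empty report means valid.

    With ``allow_suppressible=False`` (used for displayed trees) indegree-1 /
    outdegree-1 nodes are additionally reported.
    """
    report: list[Violation] = []
    g = network.graph
    if g.number_of_nodes() == 0:
        return [Violation("empty", None, "network has no nodes")]

    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        report.append(Violation("cyclic", cycle,
                                f"directed cycle through {cycle[0][0]!r}"))

    roots = [n for n in g.nodes if g.in_degree(n) == 0]
    if len(roots) != 1:
        report.append(Violation(
            "not rooted", tuple(sorted(map(str, roots))),
            f"expected exactly one indegree-0 node, found {len(roots)}"))

    leaves = {n for n in g.nodes if g.out_degree(n) == 0}
    for node in sorted(g.nodes, key=str):
        labelled = node in network.labels
        if node in leaves and not labelled:
            report.append(Violation("unlabeled leaf", node,
                                    f"outdegree-0 node {node!r} has no taxon"))
        if labelled and node not in leaves:
            report.append(Violation(
                "labeled internal node", node,
                f"node {node!r} has outdegree > 0 but carries taxon "
                f"{network.labels[node]!r}"))

    seen: dict[str, Node] = {}
    for node, taxon in network.labels.items():
        if taxon in seen:
            report.append(Violation("duplicate taxon", taxon,
                                    f"taxon {taxon!r} labels two leaves"))
        seen[taxon] = node

    if not network.multiedge_mode:
        for u, v in network.parallel_edge_pairs():
            report.append(Violation("multiedge", (u, v),
                                    f"parallel edges {u!r}->{v!r}"))

    for u, v, data in g.edges(data=True):
        lengths = data.get("lengths")
        if not isinstance(lengths, LengthSet):
            report.append(Violation("missing lengths", (u, v),
                                    f"edge {u!r}->{v!r} has no length set"))

    if isinstance(network, WeightedTree):
        for node in sorted(g.nodes, key=str):
            if g.in_degree(node) > 1:
                report.append(Violation("reticulation in tree", node,
                                        f"tree node {node!r} has indegree > 1"))
        for u, v, data in g.edges(data=True):
            lengths = data.get("lengths")
            if isinstance(lengths, LengthSet) and len(lengths) != 1:
                report.append(Violation(
                    "multi-valued tree edge", (u, v),
                    f"tree edge {u!r}->{v!r} carries {len(lengths)} lengths"))

    if not allow_suppressible:
        root = roots[0] if len(roots) == 1 else None
        for node in sorted(g.nodes, key=str):
            if node != root and g.in_degree(node) == 1 and g.out_degree(node) == 1:
                report.append(Violation("suppressible node", node,
                                        f"node {node!r} has indegree 1 and "
                                        "outdegree 1"))
    return report


def require_valid(network: PhyloNetwork) -> None:
    report = validate_network(network)
    if report:
        raise PreconditionError(f"invalid network: {report}")


# ---------------------------------------------------------------------------
# structural queries


def reticulation_nodes(network: PhyloNetwork) -> set[Node]:
    """Nodes with indegree > 1 (hybridization / HGT / recombination events)."""
    return {n for n in network.graph.nodes if network.graph.in_degree(n) > 1}


def funnel_nodes(network: PhyloNetwork) -> set[Node]:
    """Nodes with indegree > 0 and outdegree exactly 1.

    The root (indegree 0) and leaves (outdegree 0) are never funnels.  A
    network with no funnels is *canonical* (funnel-free).
    """
    g = network.graph
    return {n for n in g.nodes if g.in_degree(n) > 0 and g.out_degree(n) == 1}


def is_funnel_free(network: PhyloNetwork) -> bool:
    return not funnel_nodes(network)


# ---------------------------------------------------------------------------
# canonical codes
#
# The code of a network is the lexicographically smallest faithful
# serialization over all "admissible" child orderings.  Children are ordered
# by an isomorphism-invariant bottom-up prekey; orderings are only enumerated
# within groups tied under that key.  Reticulation nodes receive indices in
# order of first visit and later occurrences are emitted as references, so the
# string determines the graph up to renaming: equal codes <=> isomorphic.
# Bottom-up signatures alone are *not* a complete invariant for DAGs (distinct
# nodes may share identical descendant structure), hence the explicit
# minimization step.

_ORDERING_CAP = 400_000


def _prekeys(network: PhyloNetwork) -> dict[Node, tuple]:
    """Isomorphism-invariant bottom-up keys ignoring reticulation sharing."""
    keys: dict[Node, tuple] = {}
    for node in nx.topological_sort(network.graph.reverse(copy=False)):
        g = network.graph
        if g.out_degree(node) == 0:
            keys[node] = ("L", network.labels.get(node, ""))
        else:
            items = sorted(
                (d["lengths"].text(), keys[child])
                for _, child, d in g.out_edges(node, data=True))
            keys[node] = ("I", g.in_degree(node), tuple(items))
        # in-degree is part of the key so that sharing is partially visible
    return keys


class CanonicalCode:
    """A text form of a network or tree, equal exactly for isomorphic objects."""

    __slots__ = ("code",)

    def __init__(self, code: str):
        self.code = code

    def __eq__(self, other):
        return isinstance(other, CanonicalCode) and self.code == other.code

    def __hash__(self):
        return hash(self.code)

    def __repr__(self):
        return f"CanonicalCode({self.code!r})"

    def __str__(self):
        return self.code


def network_canonical_code(network: PhyloNetwork) -> CanonicalCode:
    """Deterministic code, invariant under node renaming and child order."""
    if network.parallel_edge_pairs():
        raise PreconditionError(
            "canonical codes are defined for simple networks; merge parallel "
            "edges first (multiedge normalization)")
    root = network.root()
    g = network.graph
    keys = _prekeys(network)
    rets = reticulation_nodes(network)

    # per-node groups of out-edges tied under the invariant ordering key
    orderings: dict[Node, list[list[tuple[str, Node]]]] = {}
    n_orderings = 1
    for node in g.nodes:
        edges = [(d["lengths"].text(), child)
                 for _, child, d in g.out_edges(node, data=True)]
        groups: dict[tuple, list[tuple[str, Node]]] = {}
        for ltext, child in edges:
            groups.setdefault((ltext, keys[child]), []).append((ltext, child))
        cells = [groups[k] for k in sorted(groups)]
        node_orders: list[list[tuple[str, Node]]] = [[]]
        for cell in cells:
            if len(cell) == 1:
                node_orders = [o + cell for o in node_orders]
            else:
                node_orders = [o + list(perm) for o in node_orders
                               for perm in itertools.permutations(cell)]
        orderings[node] = node_orders
        n_orderings *= len(node_orders)
        if n_orderings > _ORDERING_CAP:
            raise CapExceededError(
                f"canonical-code ordering search exceeds {_ORDERING_CAP} "
                "candidates; network too symmetric for this guard")

    best: str | None = None

    def serialize(choice: dict[Node, int]) -> str:
        ret_index: dict[Node, int] = {}
        out: list[str] = []

        def visit(node: Node) -> None:
            if node in rets:
                if node in ret_index:
                    out.append(f"&{ret_index[node]}")
                    return
                ret_index[node] = len(ret_index)
                out.append(f"#{ret_index[node]}=")
            if g.out_degree(node) == 0:
                out.append(network.labels.get(node, ""))
                return
            out.append("(")
            first = True
            for ltext, child in orderings[node][choice[node]]:
                if not first:
                    out.append(",")
                first = False
                visit(child)
                out.append(":" + ltext)
            out.append(")")

        visit(root)
        return "".join(out)

    multi = [n for n in g.nodes if len(orderings[n]) > 1]
    for combo in itertools.product(*(range(len(orderings[n])) for n in multi)):
        choice = {n: 0 for n in g.nodes}
        choice.update(dict(zip(multi, combo)))
        code = serialize(choice)
        if best is None or code < best:
            best = code
    assert best is not None
    return CanonicalCode(best)


def tree_canonical_code(tree: WeightedTree) -> CanonicalCode:
    """Code for weighted trees: sorted child codes plus exact length text."""
    g = tree.graph
    root = tree.root()

    def code_of(node: Node) -> str:
        if g.out_degree(node) == 0:
            return tree.labels.get(node, "")
        parts = sorted(
            code_of(child) + ":" + d["lengths"].text()
            for _, child, d in g.out_edges(node, data=True))
        return "(" + ",".join(parts) + ")"

    return CanonicalCode(code_of(root))


def canonical_code(obj: PhyloNetwork) -> CanonicalCode:
    if isinstance(obj, WeightedTree):
        return tree_canonical_code(obj)
    return network_canonical_code(obj)


# ---------------------------------------------------------------------------
# isomorphism


def are_isomorphic(n1: PhyloNetwork, n2: PhyloNetwork) -> bool:
    """True iff a bijection preserves edges, length sets and leaf labels.

    Implemented as canonical-code equality (sound and complete; cross-checked
    against :func:`brute_force_isomorphic` in the test suite).
    """
    if n1.taxa() != n2.taxa():
        return False
    if (n1.graph.number_of_nodes() != n2.graph.number_of_nodes()
            or n1.graph.number_of_edges() != n2.graph.number_of_edges()):
        return False
    return network_canonical_code(n1) == network_canonical_code(n2)


_BRUTE_FORCE_MAX_NODES = 12


def brute_force_isomorphic(n1: PhyloNetwork, n2: PhyloNetwork) -> bool:
    """Exhaustive search over internal-node bijections; testing oracle only."""
    for net in (n1, n2):
        if net.graph.number_of_nodes() > _BRUTE_FORCE_MAX_NODES:
            raise PreconditionError(
                f"brute-force isomorphism limited to {_BRUTE_FORCE_MAX_NODES} "
                f"nodes, got {net.graph.number_of_nodes()}")
    if n1.taxa() != n2.taxa():
        return False
    if (n1.graph.number_of_nodes() != n2.graph.number_of_nodes()
            or n1.graph.number_of_edges() != n2.graph.number_of_edges()):
        return False

    g1, g2 = n1.graph, n2.graph
    label_to_2 = {lbl: node for node, lbl in n2.labels.items()}
    mapping: dict[Node, Node] = {}
    for node, lbl in n1.labels.items():
        if lbl not in label_to_2:
            return False
        mapping[node] = label_to_2[lbl]

    internal1 = sorted((n for n in g1.nodes if n not in n1.labels), key=str)
    internal2 = [n for n in g2.nodes if n not in n2.labels]

    def degree_sig(g, n):
        return (g.in_degree(n), g.out_degree(n))

    def edge_set(net: PhyloNetwork):
        return {(u, v): d["lengths"]
                for u, v, d in net.graph.edges(data=True)}

    edges1 = edge_set(n1)
    edges2 = edge_set(n2)

    def consistent(m: dict[Node, Node]) -> bool:
        for (u, v), lengths in edges1.items():
            if u in m and v in m:
                other = edges2.get((m[u], m[v]))
                if other is None or other != lengths:
                    return False
        return True

    def backtrack(i: int, used: set[Node]) -> bool:
        if i == len(internal1):
            return consistent(mapping)
        a = internal1[i]
        for b in internal2:
            if b in used or degree_sig(g1, a) != degree_sig(g2, b):
                continue
            mapping[a] = b
            if consistent(mapping) and backtrack(i + 1, used | {b}):
                return True
            del mapping[a]
        return False

    return backtrack(0, set())
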