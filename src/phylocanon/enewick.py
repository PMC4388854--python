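"""Reading and writing networks in an extended-Newick dialect.

The dialect is conservative: plain Newick and plain extended Newick (hybrid
nodes tagged ``#H1``, ``#H2``, ...) remain valid input.  The single extension
is the length *set* syntax ``:{x1,x2,...}`` for edges carrying several
branch lengths.  Numbers are exact decimals when they terminate, otherwise
fractions ``p/q``; they are parsed into exact rationals either way.

Two representations of the same evolutionary scenario are normalized on
input: parallel edges (the same hybrid node listed twice under one parent)
are merged into a single edge whose length set is the union of the parallel
edges' sets.

A length attached to the outermost group (``(a:1,b:1):0.5;``) denotes a root
edge: an explicit root of outdegree 1 is created above the group, which is
how trees and networks with an omitted outgroup lineage are written.
"""

from __future__ import annotations

import re

import networkx as nx

from .core import (LengthSet, Node, PhyloNetwork, WeightedTree, parse_rational,
                   validate_network, _prekeys)
from .errors import (CyclicStructureError, DuplicateLeafError,
                     MalformedSyntaxError, NonPositiveLengthError, ParseError)

_NAME_CHARS = re.compile(r"[^(),:;{}#\s\[\]']")


class ENewickText(str):
    """Text in the extended-Newick dialect described in this module."""


class _Occurrence:
    """One textual occurrence of a node (hybrid nodes may occur repeatedly)."""

    __slots__ = ("children", "name", "tag", "lengths")

    def __init__(self):
        self.children: list[tuple["_Occurrence", LengthSet | None]] = []
        self.name: str = ""
        self.tag: str | None = None
        self.lengths: LengthSet | None = None


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, message: str, token: str | None = None):
        raise MalformedSyntaxError(
            f"{message} at position {self.pos}",
            token if token is not None else self.text[self.pos:self.pos + 12])

    def skip_ws(self) -> None:
        while self.pos < len(self.text):
            char = self.text[self.pos]
            if char.isspace():
                self.pos += 1
            elif char == "[":  # bracketed Newick comment
                end = self.text.find("]", self.pos)
                if end == -1:
                    self.error("unterminated '[' comment")
                self.pos = end + 1
            else:
                break

    def peek(self) -> str:
        self.skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self, char: str) -> None:
        if self.peek() != char:
            self.error(f"expected {char!r}")
        self.pos += 1

    def parse_name(self) -> str:
        self.skip_ws()
        start = self.pos
        while self.pos < len(self.text) and _NAME_CHARS.match(self.text[self.pos]):
            self.pos += 1
        return self.text[start:self.pos]

    def parse_tag(self) -> str | None:
        if self.peek() != "#":
            return None
        self.pos += 1
        tag = self.parse_name()
        if not tag:
            self.error("empty hybrid tag", "#")
        return tag

    def parse_number(self):
        self.skip_ws()
        start = self.pos
        while (self.pos < len(self.text)
               and (self.text[self.pos].isdigit()
                    or self.text[self.pos] in ".+-/eE")):
            self.pos += 1
        token = self.text[start:self.pos]
        if not token:
            self.error("expected a number")
        try:
            value = parse_rational(token)
        except ValueError:
            self.error("malformed number", token)
        if value <= 0:
            raise NonPositiveLengthError(
                "branch lengths must be strictly positive", token)
        return value

    def parse_lengths(self) -> LengthSet | None:
        if self.peek() != ":":
            return None
        self.pos += 1
        if self.peek() == "{":
            self.pos += 1
            values = [self.parse_number()]
            while self.peek() == ",":
                self.pos += 1
                values.append(self.parse_number())
            self.take("}")
            return LengthSet(values)
        return LengthSet([self.parse_number()])

    def parse_item(self) -> _Occurrence:
        occ = _Occurrence()
        if self.peek() == "(":
            self.pos += 1
            occ.children.append(self._child())
            while self.peek() == ",":
                self.pos += 1
                occ.children.append(self._child())
            self.take(")")
        occ.name = self.parse_name()
        occ.tag = self.parse_tag()
        occ.lengths = self.parse_lengths()
        return occ

    def _child(self) -> tuple[_Occurrence, LengthSet | None]:
        child = self.parse_item()
        return child, child.lengths

    def parse(self) -> _Occurrence:
        top = self.parse_item()
        self.take(";")
        self.skip_ws()
        if self.pos != len(self.text):
            self.error("trailing text after ';'")
        if not top.children and not top.name:
            self.error("empty input")
        return top


def _build(top: _Occurrence, cls=PhyloNetwork) -> PhyloNetwork:
    network = cls()
    hybrid_nodes: dict[str, Node] = {}
    hybrid_names: dict[str, str] = {}
    counter = 0

    def node_for(occ: _Occurrence) -> Node:
        nonlocal counter
        if occ.tag is not None:
            if occ.tag not in hybrid_nodes:
                hybrid_nodes[occ.tag] = f"#{occ.tag}"
                network.add_node(hybrid_nodes[occ.tag])
            if occ.name:
                hybrid_names.setdefault(occ.tag, occ.name)
            return hybrid_nodes[occ.tag]
        counter += 1
        node = f"n{counter}"
        network.add_node(node)
        return node

    names: dict[Node, str] = {}

    def walk(occ: _Occurrence) -> Node:
        node = node_for(occ)
        if occ.name and occ.tag is None:
            names[node] = occ.name
        for child_occ, lengths in occ.children:
            child = walk(child_occ)
            if lengths is None:
                raise MalformedSyntaxError(
                    "every edge must carry a branch length",
                    child_occ.name or (child_occ.tag and "#" + child_occ.tag))
            network.add_edge(node, child, lengths)
        return node

    top_node = walk(top)
    if top.lengths is not None:
        root = f"n{len(network.graph.nodes) + 1}_root"
        network.add_node(root)
        network.add_edge(root, top_node, top.lengths)

    if not nx.is_directed_acyclic_graph(network.graph):
        cycle = nx.find_cycle(network.graph)
        raise CyclicStructureError("hybrid references form a directed cycle",
                                   str(cycle[0][0]))

    # attach taxon labels to leaves
    for tag, node in hybrid_nodes.items():
        if network.graph.out_degree(node) == 0:
            name = hybrid_names.get(tag)
            if not name:
                raise MalformedSyntaxError(
                    "hybrid leaf has no taxon label", "#" + tag)
            names[node] = name
    seen: dict[str, Node] = {}
    for node in network.graph.nodes:
        if network.graph.out_degree(node) == 0:
            name = names.get(node)
            if not name:
                raise MalformedSyntaxError("leaf without a taxon label",
                                           str(node))
            if name in seen:
                raise DuplicateLeafError(
                    "the same taxon labels two leaves", name)
            seen[name] = node
            network.labels[node] = name

    network.hybrid_tags = {tag: node for tag, node in hybrid_nodes.items()}
    report = validate_network(network)
    if report:
        raise ParseError(f"parsed graph is not a valid network: {report}")
    return network


def parse_network(text: str) -> PhyloNetwork:
    """Parse extended-Newick text into a validated network.

    Repeated hybrid tags are unified into one reticulation node; parallel
    edges arising from the input are merged into one edge whose length set is
    the union of the parallel edges' sets.
    """
    return _build(_Parser(text).parse(), PhyloNetwork)


def parse_tree(text: str) -> WeightedTree:
    """Parse standard Newick (single branch lengths, no hybrid tags).

    A length on the outermost group encodes a root of outdegree 1.
    """
    top = _Parser(text).parse()

    def forbid_tags(occ: _Occurrence):
        if occ.tag is not None:
            raise MalformedSyntaxError("hybrid tags are not allowed in trees",
                                       "#" + occ.tag)
        for child, _ in occ.children:
            forbid_tags(child)

    forbid_tags(top)
    tree = _build(top, WeightedTree)
    for u, v, lengths in tree.edges():
        if len(lengths) != 1:
            raise MalformedSyntaxError(
                "tree edges carry exactly one length", lengths.text())
    return tree  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# writing


def _write(network: PhyloNetwork) -> str:
    g = network.graph
    if network.parallel_edge_pairs():
        raise ParseError("cannot serialize a network with parallel edges; "
                         "normalize multiedges first")
    root = network.root()
    keys = _prekeys(network)
    rets = {n for n in g.nodes if g.in_degree(n) > 1}
    tag_of: dict[Node, str] = {}
    defined: set[Node] = set()

    def subtree(node: Node) -> str:
        tag = ""
        if node in rets:
            if node in defined:
                return "#" + tag_of[node]
            if node not in tag_of:
                tag_of[node] = f"H{len(tag_of) + 1}"
            defined.add(node)  # first textual occurrence carries the children
            tag = "#" + tag_of[node]
        label = network.labels.get(node, "")
        if g.out_degree(node) == 0:
            return label + tag
        children = sorted(
            ((d["lengths"], child) for _, child, d in g.out_edges(node, data=True)),
            key=lambda item: (item[0].text(), keys[item[1]], str(item[1])))
        parts = [subtree(child) + ":" + lengths.text()
                 for lengths, child in children]
        return "(" + ",".join(parts) + ")" + label + tag

    if g.number_of_nodes() == 1:
        return network.labels[root] + ";"
    if g.out_degree(root) == 1:
        (_, child, data), = g.out_edges(root, data=True)
        return subtree(child) + ":" + data["lengths"].text() + ";"
    return subtree(root) + ";"


def write_network(network: PhyloNetwork) -> ENewickText:
    """Serialize deterministically; ``parse(write(N))`` is isomorphic to N."""
    return ENewickText(_write(network))


def write_tree(tree: WeightedTree) -> ENewickText:
    return ENewickText(_write(tree))
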