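"""Weighted paths, the no-equally-long-paths property, wishbones and cracks.

A *weighted path* is a directed path together with a choice of one length per
edge; two weighted paths over the same underlying path but with different
length choices are distinct.  A network satisfies **NELP** ("no equally long
paths") when no two distinct weighted paths with the same endpoints have the
same total length.  NELP is generic when lengths measure divergence — under
independent continuous draws the probability of an exact tie is zero — but it
systematically fails under a strict molecular clock, where sister lineages
are equally long by construction.

A *wishbone* is the union of two root-leaf weighted paths that have in common
only a prefix; a *crack* is such a union sharing only a prefix and a suffix.
Every root-leaf path is degenerately both.  Networks with the NELP property
are determined up to isomorphism by the wishbones and cracks they contain,
which is what makes these small sub-networks useful as certificates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction

from .core import (CanonicalCode, LengthSet, Node, PhyloNetwork,
                   network_canonical_code, require_valid)
from .errors import CapExceededError

DEFAULT_PATH_CAP = 10**5
DEFAULT_PAIR_CAP = 10**5


@dataclass(frozen=True)
class WeightedPath:
    """A directed path plus one chosen length per edge."""

    nodes: tuple[Node, ...]
    lengths: tuple[Fraction, ...]  # one per edge; empty for a one-node path

    @property
    def edges(self) -> tuple[tuple[Node, Node], ...]:
        return tuple(zip(self.nodes, self.nodes[1:]))

    @property
    def total(self) -> Fraction:
        return sum(self.lengths, Fraction(0))

    @property
    def endpoints(self) -> tuple[Node, Node]:
        return self.nodes[0], self.nodes[-1]

    def weighted_edges(self) -> tuple[tuple[Node, Node, Fraction], ...]:
        return tuple((u, v, lam)
                     for (u, v), lam in zip(self.edges, self.lengths))


def weighted_paths_between(network: PhyloNetwork, u: Node, v: Node,
                           cap: int = DEFAULT_PATH_CAP) -> list[WeightedPath]:
    """All distinct weighted paths from ``u`` to ``v``, deterministic order.

    Distinct length choices over the same underlying path count separately.
    ``u == v`` yields the single trivial (edge-free, length-0) path.
    """
    if u == v:
        return [WeightedPath((u,), ())]
    results: list[WeightedPath] = []

    def extend(node: Node, nodes: list[Node], lengths: list[tuple[Fraction, ...]]):
        if node == v:
            for combo in itertools.product(*lengths):
                if len(results) >= cap:
                    raise CapExceededError(
                        f"more than {cap} weighted paths between "
                        f"{u!r} and {v!r}")
                results.append(WeightedPath(tuple(nodes), combo))
            return
        for child in network.children(node):
            lset = network.edge_lengths(node, child)
            extend(child, nodes + [child], lengths + [tuple(sorted(lset.values))])

    extend(u, [u], [])
    return results


def check_nelp(network: PhyloNetwork,
               cap: int = DEFAULT_PATH_CAP
               ) -> tuple[bool, tuple[WeightedPath, WeightedPath] | None]:
    """Exact-rational NELP verification with a concrete witness on failure."""
    require_valid(network)
    nodes = sorted(network.graph.nodes, key=str)
    for u in nodes:
        for v in nodes:
            if u == v:
                continue
            paths = weighted_paths_between(network, u, v, cap=cap)
            by_total: dict[Fraction, WeightedPath] = {}
            for path in paths:
                other = by_total.get(path.total)
                if other is not None and other != path:
                    return False, (other, path)
                by_total.setdefault(path.total, path)
    return True, None


# ---------------------------------------------------------------------------
# root-leaf paths, wishbones and cracks


def root_leaf_paths(network: PhyloNetwork,
                    cap: int = DEFAULT_PATH_CAP) -> list[WeightedPath]:
    root = network.root()
    paths: list[WeightedPath] = []
    for leaf in sorted(network.leaves(), key=str):
        paths.extend(weighted_paths_between(network, root, leaf, cap=cap))
    return paths


def _common_prefix(p1: WeightedPath, p2: WeightedPath) -> int:
    """Number of *nodes* in the maximal common weighted prefix (>= 1)."""
    n = 1  # both are root-leaf paths, so they share the root
    e1, e2 = p1.weighted_edges(), p2.weighted_edges()
    for a, b in zip(e1, e2):
        if a != b:
            break
        n += 1
    return n


def _common_suffix(p1: WeightedPath, p2: WeightedPath) -> int:
    """Number of nodes in the maximal common weighted suffix (0 if leaves differ)."""
    if p1.nodes[-1] != p2.nodes[-1]:
        return 0
    n = 1
    e1, e2 = p1.weighted_edges(), p2.weighted_edges()
    for a, b in zip(reversed(e1), reversed(e2)):
        if a != b:
            break
        n += 1
    return n


def classify_pair(p1: WeightedPath, p2: WeightedPath) -> set[str]:
    """Classify the union of two root-leaf weighted paths.

    Returns a subset of {"wishbone", "crack"}: the union is a wishbone when
    the paths have in common only a prefix, a crack when they have in common
    only a prefix and a suffix.  An identical pair (a single root-leaf path)
    is both.  Unions sharing anything else (e.g. an interior node reached and
    left by both paths) are neither.
    """
    shared = set(p1.nodes) & set(p2.nodes)
    k_pre = _common_prefix(p1, p2)
    prefix_nodes = set(p1.nodes[:k_pre])
    kinds: set[str] = set()
    if shared == prefix_nodes:
        kinds.add("wishbone")
        if p1.nodes[-1] == p2.nodes[-1]:
            # identical paths: the whole path is both prefix and suffix
            kinds.add("crack")
        return kinds
    k_suf = _common_suffix(p1, p2)
    if k_suf:
        suffix_nodes = set(p1.nodes[len(p1.nodes) - k_suf:])
        if shared == prefix_nodes | suffix_nodes:
            kinds.add("crack")
    return kinds


def _union_subnetwork(network: PhyloNetwork,
                      p1: WeightedPath, p2: WeightedPath) -> PhyloNetwork:
    sub = PhyloNetwork()
    lengths: dict[tuple[Node, Node], set[Fraction]] = {}
    for path in (p1, p2):
        for node in path.nodes:
            sub.add_node(node, network.labels.get(node))
        for u, v, lam in path.weighted_edges():
            lengths.setdefault((u, v), set()).add(lam)
    for (u, v), values in lengths.items():
        sub.add_edge(u, v, LengthSet(values))
    # drop labels of non-leaf nodes (a path may pass through another taxon's
    # ancestor but never through a leaf, so this is defensive only)
    sub.labels = {n: lbl for n, lbl in sub.labels.items()
                  if sub.graph.out_degree(n) == 0}
    return sub


def enumerate_wishbones(network: PhyloNetwork,
                        cap: int = DEFAULT_PAIR_CAP) -> list[PhyloNetwork]:
    """All wishbones of the network, deduplicated up to isomorphism."""
    return _enumerate(network, "wishbone", cap)


def enumerate_cracks(network: PhyloNetwork,
                     cap: int = DEFAULT_PAIR_CAP) -> list[PhyloNetwork]:
    """All cracks of the network, deduplicated up to isomorphism."""
    return _enumerate(network, "crack", cap)


def _enumerate(network: PhyloNetwork, kind: str, cap: int) -> list[PhyloNetwork]:
    require_valid(network)
    paths = root_leaf_paths(network)
    n_pairs = len(paths) * (len(paths) + 1) // 2
    if n_pairs > cap:
        raise CapExceededError(
            f"{n_pairs} root-leaf path pairs exceed the cap of {cap}")
    found: dict[CanonicalCode, PhyloNetwork] = {}
    for i, p1 in enumerate(paths):
        for p2 in paths[i:]:
            if kind in classify_pair(p1, p2):
                sub = _union_subnetwork(network, p1, p2)
                found.setdefault(network_canonical_code(sub), sub)
    return [found[code] for code in sorted(found, key=str)]


def same_wishbones_and_cracks(n1: PhyloNetwork, n2: PhyloNetwork,
                              cap: int = DEFAULT_PAIR_CAP) -> bool:
    """Set equality (up to isomorphism) of the two enumerations.

    For networks with the NELP property this is equivalent to isomorphism;
    without NELP, non-isomorphic networks may share all wishbones and cracks.
    """
    w1 = {network_canonical_code(s) for s in enumerate_wishbones(n1, cap)}
    w2 = {network_canonical_code(s) for s in enumerate_wishbones(n2, cap)}
    if w1 != w2:
        return False
    c1 = {network_canonical_code(s) for s in enumerate_cracks(n1, cap)}
    c2 = {network_canonical_code(s) for s in enumerate_cracks(n2, cap)}
    return c1 == c2
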