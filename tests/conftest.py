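import random

import pytest

import phylocanon as pc


@pytest.fixture
def fix():
    """Loader for the bundled example corpus."""
    return pc.load_fixture


@pytest.fixture
def rng():
    return random.Random(20150407)


def relabel(network: pc.PhyloNetwork, seed: int = 0) -> pc.PhyloNetwork:
    """Copy with randomly permuted internal node identifiers."""
    rand = random.Random(seed)
    nodes = sorted(network.graph.nodes, key=str)
    new_ids = [f"x{i}" for i in range(len(nodes))]
    rand.shuffle(new_ids)
    mapping = dict(zip(nodes, new_ids))
    out = pc.PhyloNetwork(network.multiedge_mode)
    for node in nodes:
        out.add_node(mapping[node], network.labels.get(node))
    for u, v, lengths in network.edges():
        out.add_edge(mapping[u], mapping[v], lengths)
    return out


def tree_code_set(network, cap=10**6):
    return {str(pc.tree_canonical_code(t))
            for t in pc.displayed_trees(network, cap=cap)}


def fig3_n1_with(lam: dict[int, str]) -> pc.PhyloNetwork:
    """The fig3_N1 topology with arbitrary per-edge lengths.

    ``lam[i]`` is the length text of edge i in the fixed numbering used by
    the bundled fixture (edge i has length i by default).
    """
    text = ("((a:{4},(b:{7})#H1:{6})t:{1},((c:{11},(#H1:{8})#H2:{5})u1:{3},"
            "(d:{12},#H2:{9})u2:{10})p:{2})r;")
    for i in range(1, 13):
        text = text.replace("{%d}" % i, lam.get(i, str(i)))
    return pc.parse_network(text)
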