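"""Named example networks and trees bundled with the package.

The corpus collects small, hand-built networks that exercise the structural
features the library is about: nested reticulation funnels and their unique
canonical form (fig3/fig4), a network outside the classical tractable classes
that is nevertheless determined by its displayed trees (fig5), outgroup
omission and outdegree-1 roots (fig7), clock-like funnel-free networks that
violate the no-equally-long-paths property and are mutually indistinguishable
without being isomorphic (fig10), a step-by-step reduction with transient
parallel edges (fig13), and wishbone/crack sub-networks (fig14).

Every fixture is stored as an extended-Newick text file with a bracketed
description comment, parses into a valid object, and round-trips through the
serializer.
"""

from __future__ import annotations

from importlib import resources

from ..core import PhyloNetwork, WeightedTree
from ..enewick import parse_network, parse_tree

_FILES = {
    "fig1_N1": "fig1_N1.enwk",
    "fig1_N2": "fig1_N2.enwk",
    "fig2_N1": "fig2_N1.enwk",
    "fig2_N2": "fig2_N2.enwk",
    "fig2_N3": "fig2_N3.enwk",
    "fig2_T1": "fig2_T1.nwk",
    "fig2_T2": "fig2_T2.nwk",
    "fig3_N1": "fig3_N1.enwk",
    "fig3_N2": "fig3_N2.enwk",
    "fig4_Nprime": "fig4_Nprime.enwk",
    "fig5_N": "fig5_N.enwk",
    "fig5_Nprime": "fig5_Nprime.enwk",
    "fig5_Npp": "fig5_Npp.enwk",
    "fig7_N2prime": "fig7_N2prime.enwk",
    "fig7_T1prime": "fig7_T1prime.nwk",
    "fig7_T2prime": "fig7_T2prime.nwk",
    "fig10_a": "fig10_a.enwk",
    "fig10_b": "fig10_b.enwk",
    "fig10_c": "fig10_c.enwk",
    "fig10_d": "fig10_d.enwk",
    "fig13_start": "fig13_start.enwk",
    "fig13_end": "fig13_end.enwk",
    "fig14_N": "fig14_N.enwk",
    "fig14_P": "fig14_P.enwk",
    "fig14_Q": "fig14_Q.enwk",
    "fig14_R": "fig14_R.enwk",
    "fig14_S": "fig14_S.enwk",
}


def fixture_names() -> list[str]:
    return sorted(_FILES)


def fixture_text(name: str) -> str:
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"known: {', '.join(fixture_names())}")
    return (resources.files(__package__) / _FILES[name]).read_text()


def load_fixture(name: str) -> PhyloNetwork | WeightedTree:
    """Load a named example; ``.nwk`` files parse as trees, ``.enwk`` as networks."""
    text = fixture_text(name)
    if _FILES[name].endswith(".nwk"):
        return parse_tree(text)
    return parse_network(text)
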