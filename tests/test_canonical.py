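"""Reduction rules, canonical forms, and the unzip/zip inverse moves."""

import random
from fractions import Fraction

import pytest

import phylocanon as pc
from conftest import tree_code_set


def _funnel_with(in_sets, out_set):
    """A small network with one funnel whose in/out length sets are given."""
    net = pc.PhyloNetwork()
    net.add_node("r")
    net.add_node("w")
    net.add_node("v")
    net.add_node("a", "a")
    net.add_node("b", "b")
    parents = []
    for i, lengths in enumerate(in_sets):
        u = f"u{i}"
        net.add_node(u)
        net.add_edge("r", u, [i + 10])
        net.add_edge(u, "v", lengths)
        net.add_edge(u, f"leaf{i}", [1])
        net.add_node(f"leaf{i}", f"x{i}")
        parents.append(u)
    net.add_edge("v", "w", out_set)
    net.add_edge("w", "a", [1])
    net.add_edge("w", "b", [2])
    return net


class TestRules:
    def test_r1_set_sum(self):
        net = _funnel_with([[2], [3]], [1])
        out = pc.apply_r1(net, "v")
        assert out.edge_lengths("u0", "w").values == {Fraction(3)}
        assert out.edge_lengths("u1", "w").values == {Fraction(4)}
        assert "v" not in out.graph.nodes
        assert out.graph.number_of_edges() == net.graph.number_of_edges() - 1

    def test_r1_minkowski_collapses_duplicates(self):
        net = _funnel_with([[1, 2]], [1, 2])
        out = pc.apply_r1(net, "v")
        assert out.edge_lengths("u0", "w").values == \
            {Fraction(2), Fraction(3), Fraction(4)}

    def test_r1_never_creates_a_funnel(self, rng):
        for _ in range(20):
            net = pc.random_funnelize(
                pc.canonicalize(pc.random_network(4, 1, rng=rng))[0],
                rng.randint(1, 3), rng=rng)
            before = pc.funnel_nodes(net)
            v = sorted(before, key=str)[0]
            after = pc.funnel_nodes(pc.apply_r1(net, v))
            assert len(after) == len(before) - 1

    def test_r1_creates_parallel_edges_when_parent_already_reaches_child(self, fix):
        # in fig13_start the funnel's parent u already has an edge to the
        # funnel's child w, so suppression transiently produces a multiedge,
        # flagged for R2
        net = fix("fig13_start")
        (v,) = pc.funnel_nodes(net)
        out = pc.apply_r1(net, v)
        assert out.multiedge_mode
        assert out.parallel_edge_pairs()

    def test_r2_union(self):
        net = _funnel_with([[1], [2]], [1])
        net.graph.add_edge("u0", "w", lengths=pc.LengthSet([5]))
        net.multiedge_mode = True
        net.graph.add_edge("u0", "w", lengths=pc.LengthSet([6, 5]))
        out = pc.apply_r2(net, ("u0", "w"))
        assert out.edge_lengths("u0", "w").values == \
            {Fraction(5), Fraction(6)}

    def test_r2_merges_triple_multiedge_in_one_step(self):
        net = pc.PhyloNetwork(multiedge_mode=True)
        net.add_node("r")
        net.add_node("a", "a")
        for lengths in ([1], [2], [2, 3]):
            net.graph.add_edge("r", "a", lengths=pc.LengthSet(lengths))
        out = pc.apply_r2(net, ("r", "a"))
        assert out.edge_lengths("r", "a").values == \
            {Fraction(1), Fraction(2), Fraction(3)}

    def test_rule_preconditions(self):
        net = _funnel_with([[1]], [1])
        with pytest.raises(pc.PreconditionError):
            pc.apply_r1(net, "w")  # not a funnel
        with pytest.raises(pc.PreconditionError):
            pc.apply_r2(net, ("v", "w"))  # no multiedge


class TestCanonicalize:
    def test_fig3_networks_share_the_fig4_canonical_form(self, fix):
        target = fix("fig4_Nprime")
        for name in ("fig3_N1", "fig3_N2"):
            canon, trace = pc.canonicalize(fix(name))
            assert pc.are_isomorphic(canon, target)
            assert trace.rule_counts()["R1"] == 2

    def test_fig13_reduction_with_transient_multiedges(self, fix):
        canon, trace = pc.canonicalize(fix("fig13_start"))
        assert pc.are_isomorphic(canon, fix("fig13_end"))
        assert [s.rule for s in trace] == ["R1", "R2", "R1", "R2"]

    def test_idempotent_on_canonical_input(self, fix):
        for name in ("fig4_Nprime", "fig5_Nprime", "fig10_a"):
            canon, trace = pc.canonicalize(fix(name))
            assert pc.are_isomorphic(canon, fix(name))
            assert list(trace) == []

    def test_output_is_funnel_free_and_simple(self, fix, rng):
        nets = [fix(n) for n in ("fig3_N1", "fig5_N", "fig13_start")]
        nets += [pc.random_network(rng.randint(2, 6), rng.randint(0, 4),
                                   rng=rng) for _ in range(20)]
        for net in nets:
            canon, trace = pc.canonicalize(net)
            assert pc.is_funnel_free(canon)
            assert not canon.parallel_edge_pairs()
            assert len(trace) <= net.graph.number_of_edges()  # termination

    def test_trace_replay_reproduces_output(self, fix):
        for name in ("fig3_N1", "fig13_start"):
            net = fix(name)
            canon, trace = pc.canonicalize(net)
            replayed = trace.replay(net)
            assert pc.are_isomorphic(replayed, canon)

    def test_displayed_trees_preserved(self, fix, rng):
        nets = [fix(n) for n in ("fig3_N1", "fig3_N2", "fig5_N",
                                 "fig13_start", "fig2_N2", "fig7_N2prime")]
        nets += [pc.random_network(rng.randint(2, 6), rng.randint(0, 4),
                                   rng=rng) for _ in range(40)]
        for net in nets:
            canon, _ = pc.canonicalize(net)
            assert tree_code_set(net) == tree_code_set(canon)

    def test_nelp_preserved_by_reduction(self, fix, rng):
        nets = [fix(n) for n in ("fig3_N1", "fig3_N2", "fig5_N")]
        nets += [pc.random_network(rng.randint(2, 5), rng.randint(0, 3),
                                   rng=rng) for _ in range(20)]
        for net in nets:
            if pc.check_nelp(net)[0]:
                canon, _ = pc.canonicalize(net)
                assert pc.check_nelp(canon)[0]

    def test_confluence_of_rule_order(self, fix, rng):
        nets = [fix("fig13_start"), fix("fig3_N1")]
        nets += [pc.random_funnelize(
            pc.canonicalize(pc.random_network(4, 2, rng=rng))[0], 2, rng=rng)
            for _ in range(10)]
        for i, net in enumerate(nets):
            reference, _ = pc.canonicalize(net)
            for seed in range(3):
                randomized, _ = pc.canonicalize(net, rng=random.Random(seed))
                assert pc.are_isomorphic(randomized, reference), (i, seed)

    def test_unique_canonical_form_for_funnelized_variants(self, fix, rng):
        for _ in range(30):
            base, _ = pc.canonicalize(
                pc.random_network(rng.randint(3, 6), rng.randint(0, 2),
                                  rng=rng))
            variant = pc.random_funnelize(base, rng.randint(1, 3), rng=rng)
            back, _ = pc.canonicalize(variant)
            assert pc.are_isomorphic(back, base)


class TestUnzip:
    def test_delta_bounds(self, fix):
        net = fix("fig3_N1")
        (m,) = net.parents(net.leaf_of("b"))
        with pytest.raises(pc.PreconditionError):
            pc.unzip(net, m, Fraction(0))
        with pytest.raises(pc.PreconditionError):
            pc.unzip(net, m, Fraction(8))  # out-edge has length 7

    def test_full_unzip_merges_with_child(self, fix):
        net = fix("fig3_N1")
        (m,) = net.parents(net.leaf_of("b"))
        out = pc.unzip(net, m, Fraction(7))
        assert m not in out.graph.nodes
        assert out.graph.in_degree(out.leaf_of("b")) == 2

    def test_fully_unzipping_both_reticulations_gives_fig4(self, fix):
        net = fix("fig3_N1")
        (m,) = net.parents(net.leaf_of("b"))
        step1 = pc.unzip(net, m, Fraction(7))
        (s,) = [v for v in pc.reticulation_nodes(step1)
                if step1.graph.out_degree(v) == 1]
        (child,) = step1.children(s)
        step2 = pc.unzip(step1, s, step1.edge_lengths(s, child).single())
        assert pc.are_isomorphic(step2, fix("fig4_Nprime"))

    def test_refuses_multivalued_length_sets(self, fix):
        net = fix("fig14_N")  # reticulation below a {1,2} edge
        (h,) = pc.reticulation_nodes(net)
        with pytest.raises(pc.PreconditionError):
            pc.unzip(net, h, Fraction(1, 2))

    def test_displayed_trees_invariant(self, rng):
        checked = 0
        for _ in range(100):
            net = pc.random_network(rng.randint(2, 5), rng.randint(1, 2),
                                    rng=rng)
            sites = [v for v in pc.reticulation_nodes(net)
                     if net.graph.out_degree(v) == 1]
            if not sites:
                continue
            v = sites[rng.randrange(len(sites))]
            (child,) = net.children(v)
            out_len = net.edge_lengths(v, child).single()
            delta = out_len * Fraction(rng.randint(1, 100), 100)
            assert tree_code_set(pc.unzip(net, v, delta)) == \
                tree_code_set(net)
            checked += 1
        assert checked >= 50


class TestZipInsertFunnel:
    def test_single_in_edge_creates_plain_funnel(self, fix):
        net = fix("fig4_Nprime")
        leaf = net.leaf_of("a")
        out = pc.zip_insert_funnel(net, leaf, net.parents(leaf), Fraction(1))
        (v,) = pc.funnel_nodes(out)
        assert out.graph.in_degree(v) == 1
        assert out.graph.out_degree(v) == 1

    def test_delta_must_be_below_every_length(self, fix):
        net = fix("fig4_Nprime")
        leaf = net.leaf_of("a")  # in-edge length 4
        with pytest.raises(pc.PreconditionError):
            pc.zip_insert_funnel(net, leaf, net.parents(leaf), Fraction(4))

    def test_zip_then_canonicalize_is_identity(self, fix, rng):
        for _ in range(50):
            base, _ = pc.canonicalize(
                pc.random_network(rng.randint(3, 6), rng.randint(0, 2),
                                  rng=rng))
            candidates = sorted(
                (n for n in base.graph.nodes if base.graph.in_degree(n) >= 1),
                key=str)
            target = candidates[rng.randrange(len(candidates))]
            parents = base.parents(target)
            subset = [parents[rng.randrange(len(parents))]]
            min_val = min(min(base.edge_lengths(u, target).values)
                          for u in subset)
            delta = min_val * Fraction(1, 2)
            zipped = pc.zip_insert_funnel(base, target, subset, delta)
            back, _ = pc.canonicalize(zipped)
            assert pc.are_isomorphic(back, base)

    def test_repeated_zipping_rebuilds_fig3_from_fig4(self, fix):
        n4 = fix("fig4_Nprime")
        b = n4.leaf_of("b")
        z1 = pc.zip_insert_funnel(n4, b, n4.parents(b), Fraction(7))
        (v,) = pc.funnel_nodes(z1)
        deep = [u for u in z1.parents(v)
                if z1.edge_lengths(u, v).single() in (Fraction(13),
                                                      Fraction(17))]
        z2 = pc.zip_insert_funnel(z1, v, deep, Fraction(8))
        assert pc.are_isomorphic(z2, fix("fig3_N1"))
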