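"""Signed circular gene orders, breakpoint distances, rearrangement events."""
from itertools import combinations

import numpy as np
import pytest

from mitokit.gene_order import (GeneOrder, breakpoint_distance, describe_events,
                                distance_matrix, extract_order,
                                load_reference_order, nj_tree, parse_order,
                                read_orders, restrict_to_common, write_orders)
from mitokit.synthetic import scramble_order


def oracle_breakpoints(a: GeneOrder, b: GeneOrder) -> int:
    """Independent adjacency oracle: canonical signed neighbour pairs
    (a pair and its reverse-complement pair are the same adjacency)."""
    def pairs(order):
        out = set()
        n = len(order.genes)
        for i in range(n):
            x, y = order.genes[i], order.genes[(i + 1) % n]
            fwd = (x, y)
            rev = ((y[0], -y[1]), (x[0], -x[1]))
            out.add(min(fwd, rev))
        return out
    return len(pairs(a) - pairs(b))


def random_order(rng, n):
    genes = [f"g{i}" for i in rng.permutation(n)]
    return GeneOrder(tuple((g, int(rng.choice([1, -1]))) for g in genes))


class TestGeneOrderBasics:
    def test_duplicate_symbols_rejected(self):
        with pytest.raises(ValueError):
            GeneOrder((("a", 1), ("a", -1)))

    def test_parse_and_roundtrip(self, tmp_path):
        o = parse_order("x: +cox1 -trnF +nad5")
        assert o.genes == (("cox1", 1), ("trnF", -1), ("nad5", 1))
        write_orders({"x": o}, tmp_path / "orders.txt")
        again = read_orders(tmp_path / "orders.txt")
        assert again["x"].genes == o.genes

    def test_extract_order_from_table(self, whitefly_table):
        order = extract_order(whitefly_table)
        assert len(order) == 36  # CR excluded
        assert order.genes[:3] == (("cox1", 1), ("trnL1", 1), ("cox2", 1))
        assert "trnS1" not in order.alphabet
        assert "CR" not in order.alphabet

    def test_single_gene_order(self):
        ann_order = GeneOrder((("cox1", 1),))
        assert len(ann_order) == 1


class TestRestrictToCommon:
    def test_whitefly_vs_ancestral_removes_trnS1(self, whitefly_table):
        q = extract_order(whitefly_table)
        ref = load_reference_order()
        rq, rr, removed = restrict_to_common(q, ref)
        assert removed["b"] == ["trnS1"]
        assert removed["a"] == []
        assert rq.alphabet == rr.alphabet

    def test_identical_alphabets_remove_nothing(self):
        a = parse_order("a: +1 +2")
        b = parse_order("b: -2 +1")
        _, _, removed = restrict_to_common(a, b)
        assert removed == {"a": [], "b": []}

    def test_disjoint_alphabets_error(self):
        with pytest.raises(ValueError):
            restrict_to_common(parse_order("a: +1"), parse_order("b: +2"))


class TestBreakpointDistance:
    def test_identity(self):
        a = parse_order("a: +1 +2 +3 +4 +5")
        assert breakpoint_distance(a, a) == 0

    def test_single_inversion_example(self):
        a = parse_order("a: +1 +2 +3 +4 +5")
        b = parse_order("b: +1 -3 -2 +4 +5")
        assert breakpoint_distance(a, b) == 2

    def test_whole_molecule_reversal_is_distance_zero(self):
        a = parse_order("a: +1 -2 +3 +4 -5")
        rev = GeneOrder(tuple((g, -s) for g, s in reversed(a.genes)))
        assert breakpoint_distance(a, rev) == 0

    def test_rotation_invariance(self):
        a = parse_order("a: +1 -2 +3 +4 -5")
        rot = GeneOrder(a.genes[2:] + a.genes[:2])
        assert breakpoint_distance(a, rot) == 0

    def test_alphabet_mismatch_rejected(self):
        with pytest.raises(ValueError):
            breakpoint_distance(parse_order("a: +1 +2"), parse_order("b: +1 +3"))

    def test_metric_properties_and_oracle_on_random_orders(self):
        rng = np.random.default_rng(0)
        orders = [random_order(rng, int(rng.integers(4, 11))) for _ in range(12)]
        # restrict to triples over equal-sized alphabets for the triangle check
        for _ in range(60):
            n = int(rng.integers(4, 11))
            a, b, c = (random_order(rng, n) for _ in range(3))
            dab = breakpoint_distance(a, b)
            dba = breakpoint_distance(b, a)
            assert dab == dba == oracle_breakpoints(a, b)
            assert breakpoint_distance(a, a) == 0
            assert dab <= breakpoint_distance(a, c) + breakpoint_distance(c, b)

    def test_inversions_bound_distance(self):
        rng = np.random.default_rng(1)
        base = random_order(rng, 10)
        for k in (1, 2, 3, 5):
            scrambled, log = scramble_order(base, n_inversions=k, seed=int(rng.integers(1 << 30)))
            assert len(log) == k
            assert breakpoint_distance(base, scrambled) <= 2 * k


class TestDescribeEvents:
    def test_identical_orders_single_in_place_block(self):
        a = parse_order("a: +1 +2 +3 +4")
        rep = describe_events(a, a)
        assert rep.n_breakpoints == 0
        assert len(rep.blocks) == 1
        assert rep.blocks[0].status == "in-place"

    def test_one_gene_inversion(self):
        ref = parse_order("ref: +1 +2 +3 +4 +5")
        q = parse_order("q: +1 -2 +3 +4 +5")
        rep = describe_events(q, ref)
        assert rep.n_breakpoints == 2
        statuses = {b.genes: b.status for b in rep.blocks}
        assert statuses[("2",)] == "inverted"

    def test_whitefly_cluster_inverted_and_translocated(self, whitefly_table):
        q = extract_order(whitefly_table)
        ref = load_reference_order()
        rep = describe_events(q, ref)
        assert rep.missing_in_query == ["trnS1"]
        hit = [b for b in rep.blocks
               if {"nad3", "trnG", "cox3"} <= set(b.genes)]
        assert len(hit) == 1
        assert hit[0].status == "inverted+translocated"

    def test_block_boundaries_match_breakpoints_under_inversions(self):
        # with one or two inversions every run boundary is a signed
        # breakpoint and vice versa (three nested inversions can produce
        # an unflipped order reversal, which merges across a breakpoint)
        rng = np.random.default_rng(4)
        base = random_order(rng, 12)
        for k in (1, 2, 1, 2):
            q, _ = scramble_order(base, n_inversions=k, seed=int(rng.integers(1 << 30)))
            rep = describe_events(q, base)
            # circular decomposition: one block per breakpoint
            expected = rep.n_breakpoints if rep.n_breakpoints else 1
            assert len(rep.blocks) == expected

    def test_breakpoints_plus_shared_equals_adjacencies(self, whitefly_table):
        q = extract_order(whitefly_table)
        ref = load_reference_order()
        rep = describe_events(q, ref)
        assert rep.n_breakpoints + rep.n_shared_adjacencies == 36


class TestDistanceMatrixAndTree:
    def test_matrix_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(2)
        orders = {f"s{i}": random_order(rng, 8) for i in range(5)}
        dm = distance_matrix(orders)
        assert (dm.values == dm.values.T).all()
        assert (np.diag(dm.values) == 0).all()

    def test_three_identical_orders_star_tree(self):
        o = parse_order("o: +1 +2 +3 +4 +5 +6")
        dm = distance_matrix({"a": o, "b": o, "c": o})
        newick = nj_tree(dm)
        import re
        lengths = [float(x) for x in re.findall(r":([0-9.eE+-]+)", newick)]
        assert all(abs(x) < 1e-12 for x in lengths)

    def test_nj_pairs_the_less_scrambled_taxon_with_reference(self):
        rng = np.random.default_rng(3)
        base = random_order(rng, 12)
        near, _ = scramble_order(base, n_inversions=1, seed=10)
        far, _ = scramble_order(base, n_inversions=5, seed=11)
        dm = distance_matrix({"ref": base, "near": near, "far": far, "out": random_order(rng, 12)})
        assert dm.loc["ref", "near"] <= dm.loc["ref", "far"]
        newick = nj_tree(dm)
        import dendropy
        tree = dendropy.Tree.get(data=newick, schema="newick")
        ref_leaf = tree.find_node_with_taxon_label("ref")
        siblings = {lf.taxon.label
                    for lf in ref_leaf.parent_node.leaf_iter()}
        assert "near" in siblings

    def test_tree_needs_three_taxa(self):
        o = parse_order("o: +1 +2 +3")
        dm = distance_matrix({"a": o, "b": o})
        with pytest.raises(ValueError):
            nj_tree(dm)


class TestScrambleOrder:
    def test_zero_events_is_identity(self):
        o = parse_order("o: +1 +2 +3 +4")
        new, log = scramble_order(o, 0, 0, seed=1)
        assert new.genes == o.genes
        assert log == []

    def test_events_are_logged(self):
        o = parse_order("o: +1 +2 +3 +4 +5 +6")
        new, log = scramble_order(o, n_inversions=2, n_translocations=1, seed=9)
        assert [e["event"] for e in log] == ["inversion", "inversion", "translocation"]
        assert sorted(new.alphabet) == sorted(o.alphabet)
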