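"""Signed circular gene orders: extraction, comparison, breakpoint distance."""

import itertools

import numpy as np
import pytest

from mitocomp.geneorder import (
    GeneOrder,
    breakpoint_distance,
    canonicalize,
    compare_orders,
    extract_gene_order,
    order_distance_matrix,
    parse_order_string,
)
from mitocomp.fixtures import load_fixture
from mitocomp.simulate import apply_rearrangement, random_signed_order


def brute_force_breakpoints(ref: GeneOrder, target: GeneOrder) -> int:
    """Independent adjacency enumerator: count ref adjacencies (circular,
    signed, orientation-insensitive) absent from the target."""
    def adjacencies(o):
        elems = list(o.elements)
        out = set()
        for i in range(len(elems)):
            a, b = elems[i], elems[(i + 1) % len(elems)]
            flip = lambda e: (e[0], "-" if e[1] == "+" else "+")
            out.add(frozenset({(a, b), (flip(b), flip(a))}))
        return out

    return len(adjacencies(ref) - adjacencies(target))


class TestExtraction:
    def test_macrodactylus_trnp_trnt_adjacency(self, macro_ann):
        order = extract_gene_order(macro_ann)
        syms = order.symbols()
        i = syms.index("nad4l")
        assert syms[i:i + 4] == ["nad4l", "trnP", "trnT", "nad6"]
        strands = dict(order.elements)
        assert strands["nad4l"] == "-" and strands["trnP"] == "-"
        assert strands["trnT"] == "+" and strands["nad6"] == "+"

    def test_extracted_order_matches_pattern_fixture(self, macro_ann, tenui_ann):
        pattern = load_fixture("palaemon_pattern")
        for ann in (macro_ann, tenui_ann):
            assert extract_gene_order(ann).elements == pattern.elements

    def test_rotation_invariance(self, macro_ann):
        rotated = macro_ann.rotated(6000)
        assert extract_gene_order(rotated).elements == \
            extract_gene_order(macro_ann).elements

    def test_single_gene_annotation(self):
        from mitocomp.annotation import GeneFeature, MitoAnnotation

        ann = MitoAnnotation(
            [GeneFeature("cox1", "PCG", "+", 1, 99)], genome_length=100)
        assert extract_gene_order(ann).elements == (("cox1", "+"),)

    def test_minus_anchor_reflects_whole_order(self):
        # reading the circle from the other strand: reversed and flipped
        o = canonicalize([("cox1", "-"), ("a", "+"), ("b", "-")], anchor="cox1")
        assert o.elements == (("cox1", "+"), ("b", "+"), ("a", "-"))

    def test_missing_anchor_rejected(self):
        with pytest.raises(ValueError):
            parse_order_string("a,b,c")


class TestCompareOrders:
    def test_palaemon_single_trnt_trnp_transposition(self, ancestral):
        rep = compare_orders(ancestral, load_fixture("palaemon_pattern"))
        assert len(rep.events) == 1
        ev = rep.events[0]
        assert ev.kind == "transposition"
        assert set(ev.block_symbols) <= {"trnT", "trnP"}
        assert not rep.lost and not rep.gained

    def test_identical_orders_empty_report(self, ancestral):
        rep = compare_orders(ancestral, ancestral)
        assert rep.identical
        assert rep.breakpoint_distance == 0

    def test_australis_losses_and_events(self, ancestral):
        rep = compare_orders(ancestral, load_fixture("australis_pattern"))
        assert rep.lost == {"trnL2"}
        blocks = [set(e.block_symbols) for e in rep.events]
        assert any(b <= {"trnL1", "16S"} for b in blocks)
        assert any(b <= {"trnW", "trnC", "trnY"} for b in blocks)

    def test_picta_block_relocation_detected(self, ancestral):
        rep = compare_orders(ancestral, load_fixture("picta_pattern"))
        assert len(rep.events) == 1
        assert rep.events[0].kind in ("block_move", "transposition")

    def test_mismatched_anchors_rejected(self, ancestral):
        other = canonicalize([("trnA", "+"), ("cox1", "+")], anchor="trnA")
        with pytest.raises(ValueError):
            compare_orders(ancestral, other)

    def test_self_comparison_empty_on_random_orders(self, rng):
        for _ in range(300):
            o = random_signed_order(10, rng)
            rep = compare_orders(o, o, include_cr=True)
            assert rep.identical and rep.breakpoint_distance == 0

    def test_every_symbol_accounted_for(self, ancestral):
        """Partition invariant: each target symbol is in a conserved block
        or a moved block; each reference-only symbol is in `lost`."""
        target = load_fixture("australis_pattern")
        rep = compare_orders(ancestral, target)
        in_conserved = {s for blk in rep.conserved_blocks for s, _ in blk}
        in_events = {s for e in rep.events for s in e.block_symbols}
        assert not (in_conserved & in_events)
        covered = in_conserved | in_events | rep.lost | rep.gained
        assert covered >= set(s for s, _ in target.elements if s != "CR")


class TestBreakpointDistance:
    def test_adjacent_swap_in_five_gene_circle(self):
        ref = parse_order_string("cox1,a,b,c,d")
        swapped = parse_order_string("cox1,b,a,c,d")
        assert breakpoint_distance(ref, swapped) == 3
        assert brute_force_breakpoints(ref, swapped) == 3

    def test_symmetry_and_identity(self, rng):
        for _ in range(100):
            a = random_signed_order(12, rng)
            b = random_signed_order(12, rng)
            d_ab = breakpoint_distance(a, b)
            assert d_ab == breakpoint_distance(b, a)
            assert d_ab == brute_force_breakpoints(a, b)
            assert (d_ab == 0) == (a.elements == b.elements)

    def test_fixture_distance_matches_enumerator(self, ancestral):
        pal = load_fixture("palaemon_pattern")
        d = breakpoint_distance(ancestral, pal, include_cr=False)
        assert d == brute_force_breakpoints(ancestral.without_cr(), pal.without_cr())
        assert d == 3  # a single-gene transposition breaks 3 adjacencies

    def test_differing_gene_sets_need_restrict(self, ancestral):
        aus = load_fixture("australis_pattern")
        with pytest.raises(ValueError):
            breakpoint_distance(ancestral, aus)
        assert breakpoint_distance(ancestral, aus, restrict=True) > 0


class TestDistanceMatrix:
    def test_fixture_matrix_symmetric_zero_diagonal(self):
        names = ["ancestral_pancrustacean", "palaemon_pattern",
                 "brevicarpalis_pattern", "picta_pattern", "australis_pattern"]
        orders = [load_fixture(n) for n in names]
        labels, mat = order_distance_matrix(orders)
        n = len(names)
        for i in range(n):
            assert mat[i][i] == 0
            for j in range(n):
                assert mat[i][j] == mat[j][i]
        assert mat[0][1] == 3  # ancestral vs palaemon

    def test_identical_orders_off_diagonal_zero(self, ancestral):
        a = GeneOrder(ancestral.elements, name="a")
        b = GeneOrder(ancestral.elements, name="b")
        _, mat = order_distance_matrix([a, b])
        assert mat[0][1] == 0

    def test_duplicate_names_rejected(self, ancestral):
        with pytest.raises(ValueError):
            order_distance_matrix([ancestral, ancestral])
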