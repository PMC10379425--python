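"""Synthetic mitogenome generator and gene-order mutants."""

import numpy as np
import pytest

from mitocomp.annotation import gap_between, summarize
from mitocomp.codons import coding_sequence, detect_start_stop
from mitocomp.composition import base_composition
from mitocomp.geneorder import extract_gene_order
from mitocomp.io import read_annotation_tsv, write_annotation_tsv
from mitocomp.simulate import (
    SyntheticSpec,
    apply_rearrangement,
    base_probs,
    generate_mitogenome,
    random_event,
    random_signed_order,
)


class TestBaseProbs:
    def test_uniform(self):
        assert base_probs(0.5, 0.0, 0.0) == (0.25, 0.25, 0.25, 0.25)

    def test_closed_form_example(self):
        pA, pC, pG, pT = base_probs(0.68, 0.05)
        assert pA == pytest.approx(0.357)
        assert pT == pytest.approx(0.323)

    def test_algebraic_round_trip(self, rng):
        for _ in range(100):
            at = rng.uniform(0.2, 0.9)
            sa = rng.uniform(-0.5, 0.5)
            sg = rng.uniform(-0.5, 0.5)
            pA, pC, pG, pT = base_probs(at, sa, sg)
            assert pA + pC + pG + pT == pytest.approx(1.0)
            assert pA + pT == pytest.approx(at)
            assert (pA - pT) / (pA + pT) == pytest.approx(sa)
            assert (pG - pC) / (pG + pC) == pytest.approx(sg)

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ValueError):
            base_probs(1.5)
        with pytest.raises(ValueError):
            base_probs(0.5, 1.5, 0.0)


class TestGenerateMitogenome:
    def test_template_round_trip(self):
        spec = SyntheticSpec(seed=1)
        g = generate_mitogenome(spec)
        assert len(g.annotation) == 38  # 37 genes + CR
        assert extract_gene_order(g.annotation).elements == \
            spec.order_template.elements

    def test_documented_atp8_atp6_overlap(self):
        g = generate_mitogenome(SyntheticSpec(seed=2))
        ann = g.annotation
        assert gap_between(ann.get("atp8"), ann.get("atp6"), len(g)) == -7

    def test_custom_overlap_spec(self):
        spec = SyntheticSpec(seed=2, overlap_spec=[("atp8", "atp6", 7),
                                                   ("nad4", "nad4l", 7)])
        g = generate_mitogenome(spec)
        ann = g.annotation
        assert gap_between(ann.get("nad4"), ann.get("nad4l"), len(g)) == -7

    def test_non_adjacent_overlap_pair_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(seed=0, overlap_spec=[("cox1", "cox3", 5)])

    def test_byte_identical_under_fixed_seed(self):
        a = generate_mitogenome(SyntheticSpec(seed=42))
        b = generate_mitogenome(SyntheticSpec(seed=42))
        assert a.sequence == b.sequence
        assert [(f.symbol, f.start, f.end) for f in a.annotation.features] == \
               [(f.symbol, f.start, f.end) for f in b.annotation.features]
        c = generate_mitogenome(SyntheticSpec(seed=43))
        assert c.sequence != a.sequence

    def test_pcg_start_stop_codons_valid(self):
        spec = SyntheticSpec(seed=5, incomplete_stop_genes=frozenset({"cox1", "cytb"}))
        g = generate_mitogenome(spec)
        for f in g.annotation.of_type("PCG"):
            start, stop = detect_start_stop(coding_sequence(g, f))
            assert start in ("ATG", "ATT", "ATA", "ATC")
            if f.symbol in ("cox1", "cytb"):
                assert stop in ("T(AA)", "TA(A)")
            else:
                assert stop in ("TAA", "TAG")

    def test_annotation_tsv_round_trip(self, tmp_path):
        g = generate_mitogenome(SyntheticSpec(seed=6))
        p = tmp_path / "sim.tsv"
        write_annotation_tsv(g.annotation, p)
        back = read_annotation_tsv(p)
        assert [(f.symbol, f.strand, f.start, f.end) for f in back.features] == \
               [(f.symbol, f.strand, f.start, f.end) for f in g.annotation.features]
        assert back.genome_length == g.annotation.genome_length

    def test_cr_is_at_enriched(self):
        g = generate_mitogenome(SyntheticSpec(seed=8, cr_length=2000,
                                              cr_at_enrichment=1.3))
        from mitocomp.composition import span_sequence

        cr = g.annotation.get("CR")
        cr_at = base_composition(span_sequence(g.sequence, cr)).pct_AT / 100
        assert cr_at > 0.75  # target 0.68 * 1.3 = 0.884, well above background


class TestApplyRearrangement:
    def test_trnt_transposition_reproduces_palaemon_adjacency(self, ancestral):
        syms = ancestral.symbols()
        # move trnT to just after trnP: positions in the post-removal list
        remaining = [s for s in syms if s != "trnT"]
        pos = remaining.index("trnP") + 1
        mutated = apply_rearrangement(ancestral, ("transposition", ["trnT"], pos))
        out = mutated.symbols()
        i = out.index("nad4l")
        assert out[i:i + 4] == ["nad4l", "trnP", "trnT", "nad6"]

    def test_single_gene_inversion_flips_strand_in_place(self, ancestral):
        mutated = apply_rearrangement(ancestral, ("inversion", ["trnG"], 0))
        assert mutated.symbols() == ancestral.symbols()
        strands = dict(mutated.elements)
        assert strands["trnG"] == "-"  # was +
        ref_strands = dict(ancestral.elements)
        changed = {s for s in strands if strands[s] != ref_strands[s]}
        assert changed == {"trnG"}

    def test_multi_gene_inversion_reverses_block(self):
        o = random_signed_order(8, np.random.default_rng(0))
        block = [o.elements[2][0], o.elements[3][0]]
        mutated = apply_rearrangement(o, ("inversion", block, 0))
        assert mutated.elements[2][0] == block[1]
        assert mutated.elements[3][0] == block[0]
        assert mutated.elements[2][1] != dict(o.elements)[block[1]]

    def test_loss_removes_genes(self, ancestral):
        mutated = apply_rearrangement(ancestral, ("loss", ["trnL2"], 0))
        assert "trnL2" not in mutated.symbols()
        assert len(mutated) == len(ancestral) - 1

    def test_non_contiguous_block_rejected(self, ancestral):
        with pytest.raises(ValueError):
            apply_rearrangement(ancestral, ("transposition", ["cox2", "atp8"], 0))

    def test_moving_anchor_rejected(self, ancestral):
        with pytest.raises(ValueError):
            apply_rearrangement(ancestral, ("transposition", ["cox1"], 5))

    def test_apply_then_compare_recovers_random_events(self, rng):
        from mitocomp.geneorder import compare_orders

        for _ in range(50):
            o = random_signed_order(10, rng)
            kind, block, pos = random_event(o, rng)
            mutated = apply_rearrangement(o, (kind, block, pos))
            rep = compare_orders(o, mutated, include_cr=True)
            assert rep.events, (kind, block, pos)
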