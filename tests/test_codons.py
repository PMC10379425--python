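"""Codon extraction, start/stop detection, and RSCU under table 5."""

import pytest
from hypothesis import given, settings, strategies as st

from mitocomp.annotation import GeneFeature
from mitocomp.codons import (
    ALL_CODONS,
    INVERTEBRATE_MITO,
    CodonProfile,
    coding_sequence,
    count_codons,
    detect_start_stop,
    preferred_codons,
    rscu,
)
from mitocomp.io import Mitogenome, reverse_complement


def pcg(symbol, start, end, strand="+"):
    return GeneFeature(symbol=symbol, ftype="PCG", strand=strand,
                       start=start, end=end)


class TestGeneticCode:
    def test_table5_particulars(self):
        code = INVERTEBRATE_MITO
        fwd = code.forward_table
        # the invertebrate mitochondrial reassignments
        assert fwd["AGA"] == "S" and fwd["AGG"] == "S"
        assert fwd["ATA"] == "M"
        assert fwd["TGA"] == "W"
        assert set(code.stop_codons) == {"TAA", "TAG"}

    def test_families_partition_sense_codons(self):
        fams = INVERTEBRATE_MITO.families()
        all_members = [c for cs in fams.values() for c in cs]
        assert len(all_members) == 62  # 64 - 2 stops
        assert len(set(all_members)) == 62
        assert set(fams["Leu1"]) == {"CTT", "CTC", "CTA", "CTG"}
        assert set(fams["Leu2"]) == {"TTA", "TTG"}
        assert set(fams["Ser1"]) == {"AGT", "AGC", "AGA", "AGG"}
        assert set(fams["Ser2"]) == {"TCT", "TCC", "TCA", "TCG"}


class TestCodingSequence:
    def test_plus_strand(self):
        g = Mitogenome(sequence="ATGTAAGGGGGG")
        assert coding_sequence(g, pcg("cox1", 1, 6)) == "ATGTAA"

    def test_minus_strand_is_reverse_complement(self):
        g = Mitogenome(sequence="ATGTAAGGGGGG")
        assert coding_sequence(g, pcg("nad5", 1, 6, "-")) == \
            reverse_complement("ATGTAA")

    def test_wrap_around_gene(self):
        # string-slicing oracle: tail + head
        seq = "AAACCCGGGTTT"
        g = Mitogenome(sequence=seq)
        f = pcg("nad2", 10, 3)
        assert coding_sequence(g, f) == seq[9:] + seq[:3]

    def test_non_pcg_rejected(self):
        g = Mitogenome(sequence="ATGTAA")
        f = GeneFeature(symbol="trnA", ftype="tRNA", strand="+", start=1, end=6)
        with pytest.raises(ValueError):
            coding_sequence(g, f)


class TestDetectStartStop:
    def test_complete_stop(self):
        assert detect_start_stop("ATG" + "GGC" * 5 + "TAA") == ("ATG", "TAA")

    def test_incomplete_single_t(self):
        # cox1-style: 1535 bp ending in T -> polyadenylation completes TAA
        cds = "ATG" + "GGC" * 510 + "CT"
        assert len(cds) == 1535
        assert detect_start_stop(cds) == ("ATG", "T(AA)")

    def test_incomplete_ta(self):
        cds = "ATT" + "GGC" * 4 + "TA"
        assert detect_start_stop(cds) == ("ATT", "TA(A)")

    def test_verbatim_convention_reports_final_triplet(self):
        # the published macrodactylus cox1 row reports the non-canonical CTA
        cds = "ATG" + "GGC" * 509 + "CTA" + "GT"
        assert len(cds) == 1535
        assert detect_start_stop(cds, polyadenylation_aware=False) == ("ATG", "CTA")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detect_start_stop("ATGTA")

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=6, max_size=120).filter(
        lambda s: len(s) % 3 == 0))
    def test_multiple_of_three_never_incomplete(self, cds):
        _, stop = detect_start_stop(cds)
        assert "(" not in stop


class TestCountCodons:
    def test_simple_tally(self):
        profile = count_codons(["ATGATGTAA"])
        assert profile.codon_counts["ATG"] == 2
        assert "TAA" not in profile.codon_counts  # stops excluded by default

    def test_stop_inclusion_flag(self):
        profile = count_codons(["ATGATGTAA"], include_stops=True)
        assert profile.codon_counts["TAA"] == 1

    def test_terminal_incomplete_codon_dropped(self):
        profile = count_codons(["ATGATGT"])  # trailing T is not a triplet
        assert profile.total == 2

    def test_concatenation_invariance(self):
        a, b = ["ATGGCCTAA"], ["ATTAAAGGG"]
        merged = count_codons(a + b).codon_counts
        separate = count_codons(a).codon_counts
        for codon, n in count_codons(b).codon_counts.items():
            separate[codon] = separate.get(codon, 0) + n
        assert merged == separate

    def test_matches_sliding_triplet_oracle(self, synthetic_genome):
        """Counts over the 13 synthetic PCGs equal a brute-force tally."""
        g = synthetic_genome
        cds_list = [coding_sequence(g, f) for f in g.annotation.of_type("PCG")]
        profile = count_codons(cds_list)
        oracle: dict[str, int] = {}
        for cds in cds_list:
            for i in range(0, len(cds) - len(cds) % 3, 3):
                codon = cds[i:i + 3]
                if codon not in ("TAA", "TAG"):
                    oracle[codon] = oracle.get(codon, 0) + 1
        assert profile.codon_counts == oracle

    def test_aa_counts_sum_to_total(self, synthetic_genome):
        g = synthetic_genome
        profile = count_codons(
            [coding_sequence(g, f) for f in g.annotation.of_type("PCG")])
        assert sum(profile.aa_counts.values()) == profile.total


class TestRscu:
    def test_two_fold_family_extremes(self):
        # counts (4, 0) in a 2-fold family -> RSCU (2.0, 0.0)
        values = rscu({"TTA": 4, "TTG": 0})
        assert values["TTA"] == 2.0
        assert values["TTG"] == 0.0

    def test_uniform_four_fold_family(self):
        values = rscu({c: 5 for c in ("GTT", "GTC", "GTA", "GTG")})
        for c in ("GTT", "GTC", "GTA", "GTG"):
            assert values[c] == 1.0

    def test_unobserved_family_is_zero_and_flagged(self):
        profile = CodonProfile(codon_counts={"TTA": 3})
        assert all(profile.rscu[c] == 0.0 for c in ("TGT", "TGC"))
        assert "C" in profile.unobserved_families

    def test_matches_per_family_recomputation(self, rng):
        """RSCU on random profiles equals a brute-force recomputation."""
        fams = INVERTEBRATE_MITO.families()
        for _ in range(20):
            counts = {c: int(rng.integers(0, 50)) for c in ALL_CODONS}
            values = rscu(counts)
            for label, members in fams.items():
                total = sum(counts[c] for c in members)
                for c in members:
                    expected = counts[c] * len(members) / total if total else 0.0
                    assert values[c] == pytest.approx(expected)

    @settings(max_examples=100, deadline=None)
    @given(st.dictionaries(st.sampled_from(ALL_CODONS),
                           st.integers(min_value=0, max_value=1000)))
    def test_family_sums_equal_family_size(self, counts):
        values = rscu(counts)
        for label, members in INVERTEBRATE_MITO.families().items():
            total = sum(counts.get(c, 0) for c in members)
            fam_sum = sum(values[c] for c in members)
            if total:
                assert fam_sum == pytest.approx(len(members))
            else:
                assert fam_sum == 0.0


class TestPreferredCodons:
    def test_uniform_profile_all_preferred(self):
        values = rscu({c: 1 for c in ALL_CODONS})
        assert preferred_codons(values) == set(
            c for fam in INVERTEBRATE_MITO.families().values() for c in fam)

    def test_skewed_family_only_top(self):
        values = rscu({"TTA": 4, "TTG": 0})
        preferred = {c for c in preferred_codons(values) if c in ("TTA", "TTG")}
        assert preferred == {"TTA"}

    def test_stops_never_preferred(self):
        values = dict.fromkeys(ALL_CODONS, 1.5)
        assert "TAA" not in preferred_codons(values)
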