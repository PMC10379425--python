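"""Published reference values for the two Palaemon mitogenomes.

These are the values printed in the original report of GenBank records
OQ512152 (*Palaemon macrodactylus*) and OP650931 (*P. tenuidactylus*),
kept in one place so that "published truth" never leaks into the
computation it is compared against.  Each entry notes what the number
summarizes.

Two printed totals for *P. tenuidactylus* are internally inconsistent
with the record's own annotation table and are therefore flagged as
known discrepancies rather than used as correctness oracles:

* printed tRNA total 1,411 bp vs the column sum 1,436 bp;
* printed PCG total 11,127 bp vs the column sum 11,134 bp (the 7-bp
  difference equals the nad4/nad4l overlap, suggesting overlap
  de-duplication in one total but not the other).

The *P. macrodactylus* totals reconcile exactly and are used as oracles.
"""

from __future__ import annotations

MACRODACTYLUS = {
    "accession": "OQ512152",
    "genome_length": 15744,          # complete-molecule size, bp
    "pcg_total": 11101,              # sum of the 13 PCG lengths, bp
    "trna_total": 1442,              # sum of the 22 tRNA lengths, bp
    "rrnL_length": 1337,             # 16S rRNA, bp
    "rrnS_length": 803,              # 12S rRNA, bp
    "cr_length": 180,                # control region, bp
    "longest_pcg": ("nad5", 1713),
    "shortest_pcg": ("atp8", 159),
    "largest_gap": ("CR", "trnI", 439),        # largest intergenic spacer
    "second_gap": ("12S", "CR", 331),
    "largest_overlap": ("trnL1", "16S", 40),
    "n_overlaps_printed": 11,
    "n_gaps_printed": 16,
    "heavy_strand_genes": 23,        # genes annotated on the plus (heavy) strand
    # whole-genome composition
    "pct_A": 35.77, "pct_T": 32.29, "pct_G": 11.78, "pct_C": 20.17,
    "pct_AT": 68.06, "at_skew": 0.051, "gc_skew": -0.262,
    # per-class composition (published convention unstated; see docs)
    "pcg_pct_AT": 65.96, "pcg_at_skew": -0.156,
    "trna_pct_AT": 66.99, "trna_at_skew": 0.022, "trna_gc_skew": 0.138,
    "rrna_pct_AT": 73.04, "rrna_at_skew": -0.059, "rrna_gc_skew": 0.285,
    "n_preferred_codons": 34,        # codons with RSCU >= 1 over the 13 PCGs
}

TENUIDACTYLUS = {
    "accession": "OP650931",
    "genome_length": 15735,
    "pcg_total": 11127,              # printed; column sum is 11134 (EXPECTED-DIFF)
    "pcg_total_column_sum": 11134,
    "trna_total": 1411,              # printed; column sum is 1436 (EXPECTED-DIFF)
    "trna_total_column_sum": 1436,
    "rrnL_length": 1308,
    "rrnS_length": 801,
    "cr_length": 200,
    "longest_pcg": ("nad5", 1713),
    "shortest_pcg": ("atp8", 159),
    "largest_gap": ("CR", "trnI", 506),
    "second_gap": ("12S", "CR", 242),
    "largest_overlap": ("trnL1", "16S", 40),
    "n_overlaps_printed": 11,
    "n_gaps_printed": 17,
    "heavy_strand_genes": 23,
    "pct_A": 36.85, "pct_T": 36.68, "pct_G": 9.94, "pct_C": 16.53,
    "pct_AT": 73.53, "at_skew": 0.002, "gc_skew": -0.248,
    "pcg_pct_AT": 71.89, "pcg_at_skew": -0.173,
    "trna_pct_AT": 73.78, "trna_at_skew": 0.025, "trna_gc_skew": 0.145,
    "rrna_pct_AT": 75.74, "rrna_at_skew": -0.015, "rrna_gc_skew": 0.398,
    "n_preferred_codons": 33,
}

REFERENCE = {"macrodactylus": MACRODACTYLUS, "tenuidactylus": TENUIDACTYLUS}

#: Printed totals known to disagree with the record's own column sums.
KNOWN_DISCREPANCIES = {
    ("tenuidactylus", "trna_total"): (1411, 1436),
    ("tenuidactylus", "pcg_total"): (11127, 11134),
}
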