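#!/usr/bin/env python
"""Sequence-level composition and codon usage from downloaded records.

The packaged fixtures carry the annotation tables but not the nucleotide
sequences, so whole-genome composition, strand skews and RSCU require the
deposited GenBank records.  Download them first, e.g.:

    efetch -db nuccore -id OQ512152 -format gb > OQ512152.gb
    efetch -db nuccore -id OP650931 -format gb > OP650931.gb

then run:

    python analysis/05_accession_composition.py OQ512152.gb [OP650931.gb ...]

Published values for comparison: OQ512152 whole-genome A+T 68.06%,
AT-skew 0.051, GC-skew -0.262, 34 preferred codons (RSCU >= 1) over the
13 PCGs; OP650931 A+T 73.53%, AT-skew 0.002, GC-skew -0.248, 33 preferred
codons.
"""

import sys
from pathlib import Path

from mitocomp.codons import coding_sequence, count_codons
from mitocomp.composition import base_composition, class_composition
from mitocomp.io import read_genbank

if len(sys.argv) < 2:
    sys.exit("usage: 05_accession_composition.py RECORD.gb [RECORD.gb ...]\n"
             "(requires downloaded GenBank records; see the module docstring)")

for path in map(Path, sys.argv[1:]):
    g = read_genbank(path)
    st = base_composition(g.sequence)
    print(f"{path.name}: {len(g)} bp; A {st.pct_A:.2f}%, T {st.pct_T:.2f}%, "
          f"G {st.pct_G:.2f}%, C {st.pct_C:.2f}%; A+T {st.pct_AT:.2f}%")
    print(f"  AT-skew {st.at_skew:.3f}, GC-skew {st.gc_skew:.3f}")
    for ftype in ("PCG", "tRNA", "rRNA"):
        cs = class_composition(g, ftype, "coding_strand")
        print(f"  {ftype}: A+T {cs.pct_AT:.2f}%, AT-skew {cs.at_skew:.3f}, "
              f"GC-skew {cs.gc_skew:.3f}")
    profile = count_codons(
        [coding_sequence(g, f) for f in g.annotation.of_type("PCG")])
    print(f"  preferred codons (RSCU >= 1): {len(profile.preferred)}")
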