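#!/usr/bin/env python
"""Ground-truth validation of the pipeline on synthetic mitogenomes.

Generates genomes with known composition targets, documented overlaps and
incomplete stops, and checks that every statistic the pipeline reports
recovers the simulated truth; writes the recovery table under results/.
"""

from pathlib import Path

import numpy as np

from mitocomp.annotation import gap_between
from mitocomp.codons import coding_sequence, detect_start_stop
from mitocomp.composition import base_composition
from mitocomp.geneorder import extract_gene_order
from mitocomp.simulate import SyntheticSpec, generate_mitogenome

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

target_at = 0.70
rows = ["seed\tgenome_bp\tat_pct\tat_abs_error\torder_round_trip\tatp8_atp6_gap"]
errors = []
for seed in range(20):
    spec = SyntheticSpec(seed=seed, target_at=target_at, cr_at_enrichment=1.0,
                         incomplete_stop_genes=frozenset({"cox1", "cytb"}))
    g = generate_mitogenome(spec)
    st = base_composition(g.sequence)
    err = abs(st.pct_AT / 100 - target_at)
    errors.append(err)
    order_ok = extract_gene_order(g.annotation).elements == spec.order_template.elements
    gap = gap_between(g.annotation.get("atp8"), g.annotation.get("atp6"), len(g))
    rows.append(f"{seed}\t{len(g)}\t{st.pct_AT:.2f}\t{err:.4f}\t{int(order_ok)}\t{gap}")

(OUT / "synthetic_recovery.tsv").write_text("\n".join(rows) + "\n")
n = 15000
se = np.sqrt(target_at * (1 - target_at) / n)
print(f"AT recovery over 20 seeds: mean |error| = {np.mean(errors):.4f} "
      f"(per-genome 3 SE at ~{n} bp = {3 * se:.4f})")

g = generate_mitogenome(SyntheticSpec(seed=0, incomplete_stop_genes=frozenset({"cox1"})))
stops = {f.symbol: detect_start_stop(coding_sequence(g, f))[1]
         for f in g.annotation.of_type("PCG")}
print(f"incomplete stop enforced on cox1: {stops['cox1']!r}; "
      f"all other stops complete: "
      f"{all(v in ('TAA', 'TAG') for k, v in stops.items() if k != 'cox1')}")
print(f"wrote {OUT / 'synthetic_recovery.tsv'}")
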