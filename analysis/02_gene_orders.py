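#!/usr/bin/env python
"""Gene-arrangement comparison of the Palaemonidae patterns.

Compares the five packaged arrangement patterns (and the orders extracted
directly from the two Palaemon annotations) against the ancestral
pancrustacean arrangement, classifies the rearrangement events, and writes
the event table plus a breakpoint-distance matrix in PHYLIP format.
"""

from pathlib import Path

from mitocomp.fixtures import ORDER_FIXTURES, load_fixture
from mitocomp.geneorder import compare_orders, extract_gene_order, order_distance_matrix
from mitocomp.io import write_phylip_matrix

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

ancestral = load_fixture("ancestral_pancrustacean")
rows = ["pattern\tlost\tevents\tbreakpoint_distance"]

for name in ORDER_FIXTURES[1:]:
    rep = compare_orders(ancestral, load_fixture(name))
    events = "; ".join(f"{e.kind}({','.join(e.block_symbols)})" for e in rep.events) or "-"
    lost = ",".join(sorted(rep.lost)) or "-"
    rows.append(f"{name}\t{lost}\t{events}\t{rep.breakpoint_distance}")
    print(f"{name}: events = {events}; lost = {lost}; "
          f"breakpoints = {rep.breakpoint_distance}")

for species in ("macrodactylus", "tenuidactylus"):
    order = extract_gene_order(load_fixture(species))
    rep = compare_orders(ancestral, order)
    events = "; ".join(f"{e.kind}({','.join(e.block_symbols)})" for e in rep.events)
    print(f"{species} (from annotation): {events}; "
          f"breakpoints = {rep.breakpoint_distance}")

(OUT / "gene_order_events.tsv").write_text("\n".join(rows) + "\n")

orders = [load_fixture(n) for n in ORDER_FIXTURES]
names, mat = order_distance_matrix(orders)
write_phylip_matrix(list(ORDER_FIXTURES), mat, OUT / "breakpoint_matrix.phy")
print(f"\nwrote {OUT / 'gene_order_events.tsv'} and {OUT / 'breakpoint_matrix.phy'}")
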