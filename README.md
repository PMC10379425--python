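# mitocomp

Comparative statistics for circular mitochondrial genomes, built around
the two newly sequenced *Palaemon* shrimp mitogenomes *P. macrodactylus*
(GenBank OQ512152, 15,744 bp) and *P. tenuidactylus* (OP650931,
15,735 bp). The package reproduces the full comparative analysis of
these records from their annotation tables — coordinate-derived
annotation statistics, nucleotide composition and strand skews, codon
usage under the invertebrate mitochondrial code, and signed gene-order
rearrangement detection against the ancestral pancrustacean arrangement
— and ships a synthetic-mitogenome generator so every stage is testable
with known ground truth and no downloads.

It is written for molecular systematists and mitogenomicists who want
these routine but error-prone computations (circular coordinate
arithmetic, incomplete stop codons, RSCU family bookkeeping, signed
circular order comparison) done once, tested, and scriptable.

## The statistics

**Annotation statistics.** Features are 1-based inclusive intervals on a
circle of length *N*; a feature spanning the origin (end < start) has
length *N* − start + 1 + end. The signed intergenic distance from a
feature to its circular successor is `next.start − prev.end − 1`
(negative = overlap). Class totals are plain sums of feature lengths —
overlapping bases count once per feature.

**Strand skews.** AT-skew = (A − T)/(A + T), GC-skew = (G − C)/(G + C),
over unambiguous bases. Reverse complementation negates both skews
exactly. Per-class composition concatenates the class's spans either as
deposited (`genome_plus`) or gene-sense (`coding_strand`, default).

**RSCU.** For codon *c* in a synonymous family of size *k* with counts
*n₁…n_k*: RSCU(*c*) = *n_c*·*k* / Σᵢ*nᵢ*, under translation table 5
(AGA/AGG = Ser, ATA = Met, TGA = Trp), with Leu and Ser split into the
conventional CUN/UUR and UCN/AGN families. RSCU ≥ 1 marks a preferred
codon. Incomplete stops (a terminal T or TA completed to UAA by
polyadenylation) are detected under a polyadenylation-aware convention
("T(AA)"/"TA(A)") or reported verbatim as the final in-frame triplet.

**Gene orders.** An arrangement is a signed circular permutation
anchored at cox1(+). Two arrangements are compared by set-differencing
gene complements (lost/gained), extracting a conserved backbone by
longest common subsequence over signed elements, and classifying
off-backbone blocks as transpositions, inversions, inverse
transpositions or block moves. The breakpoint distance counts signed
circular adjacencies of one order absent from the other.

## Worked example

```python
>>> from mitocomp import load_fixture, summarize, compare_orders
>>> s = summarize(load_fixture("macrodactylus"))
>>> s.class_totals["PCG"], s.class_totals["tRNA"]
(11101, 1442)
>>> s.longest_pcg, s.shortest_pcg
(('nad5', 1713), ('atp8', 159))
>>> s.largest_gap          # largest intergenic spacer: CR -> trnI, 439 bp
('CR', 'trnI', 439)
>>> s.largest_overlap      # trnL1 overlaps 16S by 40 bp
('trnL1', '16S', 40)
>>> rep = compare_orders(load_fixture("ancestral_pancrustacean"),
...                      load_fixture("palaemon_pattern"))
>>> [(e.kind, e.block_symbols) for e in rep.events]
[('transposition', ('trnT',))]
>>> rep.breakpoint_distance
3
```

The PCG total of 11,101 bp is the summed length of the 13 protein-coding
genes; nad5 (1,713 bp) and atp8 (159 bp) are the longest and shortest.
The single trnT transposition (equivalently: a trnT/trnP swap) is the
rearrangement that separates the *Palaemon* arrangement from the
ancestral pancrustacean gene order, breaking 3 of its 37 adjacencies.

The same analyses are scripted under `analysis/` (numbered drivers
writing tables to `results/`) and exposed as a CLI:

```
mitocomp stats macrodactylus
mitocomp order compare --ref ancestral_pancrustacean --target palaemon_pattern
mitocomp simulate --seed 42 --at 0.70 --out-prefix sim
mitocomp fixtures verify
mitocomp report --outdir report
```

Sequence-level statistics (whole-genome composition, skews, RSCU) need
the deposited nucleotide records, which are not packaged; download them
and run `analysis/05_accession_composition.py` or `mitocomp rscu`.

## Layout

- `src/mitocomp/` — the library (annotation model, io, composition,
  codons, geneorder, simulate, fixtures/reference, report, cli)
- `src/mitocomp/data/` — transcribed annotation tables, arrangement
  patterns, species metadata (checksummed at load)
- `analysis/` — numbered narrative drivers over the library
- `tests/` — pytest suite (unit, property-based, acceptance)
- `docs/methods.md` — models, conventions, design decisions, limitations
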