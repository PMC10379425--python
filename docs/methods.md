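# Methods

This note records the models, conventions and design decisions behind
`mitocomp`, and what its tests do and do not establish.

## Scope and data

The package reproduces the comparative analysis of two caridean shrimp
mitogenomes, *Palaemon macrodactylus* (GenBank OQ512152, 15,744 bp) and
*P. tenuidactylus* (OP650931, 15,735 bp), from their published
annotation tables, which are transcribed verbatim into
`src/mitocomp/data/*.tsv` and checksummed at load time. Each genome
carries the 37 canonical metazoan mitochondrial genes (13 PCGs, 22
tRNAs, 2 rRNAs) plus the control region (CR), 23 genes on the heavy
(plus) strand and 14 on the light strand, with the CR between 12S and
trnI. The nucleotide sequences themselves are not packaged; statistics
that need them (composition, skews, RSCU) run when the user supplies the
deposited records, and are otherwise exercised on synthetic genomes.

Out of scope by design: read trimming/assembly, de-novo annotation
(MITOS-style), tRNA secondary-structure folding, phylogenetic inference,
and reconstruction of mechanistic rearrangement scenarios
(duplication–random-loss and related models).

## Coordinate model

Coordinates are 1-based inclusive, the convention of GenBank feature
tables; converters to 0-based half-open exist only at I/O boundaries
(the Biopython GenBank reader). On a circle of length *N* a feature with
end < start wraps the origin and has length *N* − start + 1 + end. The
signed gap between circular neighbours is `next.start − prev.end − 1`,
wrapped for the last→first pair; negative values are overlaps. Features
wholly contained in another's span (trnL1 starts inside the 16S interval
here) need no special casing — all statistics are pure coordinate
arithmetic.

Class totals are sums of feature lengths without unioning overlapped
bases. This choice is validated by the data: the *P. macrodactylus* PCG
total of 11,101 bp is reproduced exactly only under plain summation.

### Overlap/gap counting conventions

The published counts ("11 gene overlaps, 16 and 17 gene gaps") do not
state whether the CR→trnI adjacency is counted. Recomputing from the
tables gives 11 overlaps/16 gaps for *P. macrodactylus* and 12/17 for
*P. tenuidactylus* under the annotation-table convention (adjacencies
whose upstream feature is not the CR, i.e. the rows where the printed
intergenic column has a number), and 11/17 resp. 12/18 over all circular
adjacencies. Since no convention reproduces the printed 11 for
*P. tenuidactylus* (its table contains 12 negative intergenic cells:
nad4/nad4l and trnM/nad2 overlap there but not in *P. macrodactylus*),
`summarize` reports both conventions and neither printed count is used
as a correctness oracle.

### Known printed discrepancies

Two printed totals for *P. tenuidactylus* disagree with the sum of that
record's own table column: tRNA total 1,411 vs column sum 1,436 bp, and
PCG total 11,127 vs column sum 11,134 bp (the 7-bp difference equals the
nad4/nad4l overlap, suggesting de-duplication in one total only). The
package computes the column sums and flags the printed values as
EXPECTED-DIFF in `verify_fixtures` and the report. The *P. macrodactylus*
totals reconcile exactly and serve as oracles. Likewise, the deposited
abstract describes a trnK-trnD reversal, but the record's own table
shows trnK before trnD — identical to the ancestral arrangement — and
the results text instead reports the trnT/trnP transposition; the
fixtures encode the table.

## Composition and skews

AT-skew = (A − T)/(A + T), GC-skew = (G − C)/(G + C). Ambiguous bases
are excluded from counts and denominators and reported separately; a
zero denominator yields an undefined (None) skew, not an exception.
Percentages are formatted to 2 decimals in reports and kept at full
precision internally.

Per-class statistics concatenate feature spans in genome order,
overlapping spans contributing once per feature. The published per-class
skews do not state their strand convention; both are implemented, with
`coding_strand` (reverse-complementing light-strand genes) the default —
the published combined-PCG AT-skew of −0.156 is only plausible on coding
strands, since the heavy-strand reading of 4 of the 13 PCGs would flip
their contributions.

## Codon usage

Translation table 5 (invertebrate mitochondrial) is fixed by the
organisms but configurable. Synonymous families split Leu into CUN/UUR
(Leu1/Leu2) and Ser into UCN/AGN (Ser2/Ser1), giving 22 families over 62
sense codons. RSCU(c) = count(c)·k/Σfamily; unobserved families get 0.0
for every member with an explicit flag (never NaN), so family sums equal
the family size exactly for every observed family. Stop codons (UAA/UAG
only under table 5) are excluded from amino-acid frequencies and RSCU by
default, and terminal incomplete codons are never tallied; both are
flags, since the published analysis (via MEGA-X) does not state its
handling.

Incomplete stop detection is convention-dependent — the two records
annotate same-length cox1 genes differently ("CTA" verbatim vs "T(AA)").
Default is polyadenylation-aware: a frame remainder of "TA" reports
"TA(A)", a remainder ending in T reports "T(AA)"; the verbatim
convention always reports the final complete in-frame triplet (which is
how the non-canonical CTA/ACT/ATT stops arise). A CDS whose length is a
multiple of 3 never reports an incomplete stop.

## Gene orders

An arrangement is one traversal of the circle as signed (symbol, strand)
pairs, canonically rotated to cox1 and reflected if cox1 is on the minus
strand; comparisons between orders with different anchors are rejected
rather than silently re-anchored. The CR is kept in the fixtures (the
published figure draws it) but excluded from comparisons by default,
CR calls being the least reliable part of deposited annotations.

Comparison pipeline: (1) gene-set differences → lost/gained; (2) longest
common subsequence over signed elements of the shared genes (the common
anchor resolves the cyclic alignment; the backtrack prefers consuming
the reference first, which is deterministic) → conserved backbone;
(3) off-backbone target genes grouped into maximal blocks contiguous in
both orders; (4) classification: same strand at a new position =
transposition (single gene) or block move (multi-gene block relocated
intact, the field's usual distinction); flipped strand between the same
flanking genes = inversion; flipped strand elsewhere = inverse
transposition. No minimal-event scenario is inferred.

Relocating a block over a shorter stretch is intrinsically ambiguous
(moving A past B equals moving B past A), so the LCS reports the smaller
moved set; the round-trip tests therefore check the reported event
against the brute-force enumeration of *all* single events that
reproduce the mutated order, with transposition and block move treated
as one relocation family. This equivalence-set check is exhaustive for
all single transpositions and inversions of blocks ≤ 3 genes on 10-gene
circles.

Breakpoint distance counts signed circular adjacencies of one order
absent from the other, orientation-insensitively (a→b ≡ −b→−a). It is
symmetric, zero iff the signed circular orders are rotation-equal, and
restricted to the shared gene set when complements differ — in which
case triangle-inequality violations are possible and documented rather
than hidden.

### Transcribed arrangement patterns

The ancestral pancrustacean order is the standard ground pattern
(cox1, trnL2, cox2, trnK, trnD, atp8, atp6, cox3, trnG, nad3, trnA,
trnR, trnN, trnS1, trnE, −trnF, −nad5, −trnH, −nad4, −nad4l, trnT,
−trnP, nad6, cytb, trnS2, −nad1, −trnL1, −16S, −trnV, −12S, CR, trnI,
−trnQ, trnM, nad2, trnW, −trnC, −trnY). The four variant Palaemonidae
patterns are transcribed from the published prose descriptions: the
*Palaemon* pattern (trnT/trnP transposed), *Ancylocaris brevicarpalis*
(16S/trnV transposed), *Hymenocera picta* (the block
nad1–trnL1–16S–trnV–12S–trnI–trnQ relocated from downstream of trnS2 to
downstream of nad4l; the described block excludes the CR, which the
fixture keeps at the vacated position — immaterial under the default
CR-excluded comparison), and *Anchistus australis* (trnL2 absent,
trnL1/16S transposed, trnW transposed with the trnC–trnY block).

## Synthetic generator

`SyntheticSpec` defaults emulate the structure of these genomes: the
ancestral template, 68% AT, AT-skew +0.05, GC-skew −0.26 on coding
strands, tRNAs 61–68 bp, rRNAs 800–1340 bp, PCGs 159–1713 bp (the
observed extremes), intergenic spacers 0–20 bp, the documented 7-bp
atp8/atp6 overlap, and a 180-bp AT-enriched CR (enrichment ×1.15,
configurable; real control regions are AT-rich).

Bases are i.i.d. draws per coding strand from the closed-form
probabilities pA = p(1+s)/2 etc.; start codons are drawn from the
observed {ATG, ATT, ATA, ATC}, stops are TAA/TAG or a trailing T/TA for
genes nominated as incomplete-stop. Start/stop codons are written in a
second pass so that a downstream overlapping gene cannot clobber them
(for the 7-bp atp8/atp6 overlap the enforced regions are disjoint). All
randomness flows from a single seeded generator; output is
byte-identical across runs.

What the generator does *not* emulate: codon structure beyond enforced
start/stops, substitution processes, strand-specific mutational
gradients along the molecule, tRNA cloverleaf foldability, or repeat
structure in the CR. Passing recovery tests therefore validate the
*counting and detection* code, not any claim about real sequence
evolution. Note also that because minus-strand genes are drawn on their
coding strand, plus-strand genome-wide skews are diluted relative to the
targets (the AT *content* is unaffected, which is what the recovery
tests measure).

## Numerical and testing choices

- All headline table statistics are integers and compared exactly; the
  only tolerances are statistical (composition recovery within 3
  standard errors, binomial SE √(p(1−p)/n)) or rounding-propagation
  bounds (skews recomputed from 2-decimal percentages carry ~10⁻³ of
  error).
- Problem sizes: property tests use 10–12-gene circles (exhaustive
  single-event enumeration), 1,000-iteration randomized sweeps for RSCU
  and skew invariants, and 20–50 synthetic genomes of ~10–15 kb for
  recovery — sizes at which the full suite runs in a few seconds while
  the exhaustive checks remain genuinely exhaustive.
- Degenerate inputs: empty sequences/annotations and out-of-range
  coordinates raise typed errors; undefined skews and unobserved RSCU
  families are flagged values, not exceptions; unknown GenBank gene
  names are preserved with a warning, never dropped.
- The fixtures are loaded through a sha256 checksum guard so that
  accidental edits of the transcribed tables fail loudly.

## Known limitations

- Sequence-dependent published values (whole-genome A+T 68.06%, AT-skew
  0.051, GC-skew −0.262, 34/33 preferred codons) can only be recomputed
  once the deposited records are downloaded; the pipeline supports this
  (`analysis/05_accession_composition.py`) but ships no sequences.
- Event classification reports one parsimonious reading of an
  arrangement difference; genuinely ambiguous relocations are reported
  deterministically but not enumerated.
- The gene-order comparison assumes unique gene symbols; duplicated
  genes must be disambiguated upstream.
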