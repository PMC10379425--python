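"""Synthetic circular mitogenomes and gene-order mutants with known truth.

The generator emulates the *structure* of a decapod mitogenome — 37 genes
plus a control region laid out per a template arrangement, configurable
strand layout, AT content and skews, deliberate gene overlaps, incomplete
stop codons — so that every counting, skew and rearrangement routine can
be tested without downloads.  Sequence bases are i.i.d. draws per coding
strand from probabilities solved from the target composition; there is no
codon-structure realism beyond the enforced start/stop codons, which is
sufficient for testing bookkeeping code and is documented as such.

Base probabilities solve the two skew equations in closed form: with AT
fraction ``p`` and skews ``s_AT``, ``s_GC``,

    pA = p(1+s_AT)/2,  pT = p(1-s_AT)/2,
    pG = (1-p)(1+s_GC)/2,  pC = (1-p)(1-s_GC)/2,

so recomputing the skews from the probabilities returns the targets
exactly.  All randomness flows from one ``numpy`` Generator seeded by the
spec, making output byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .annotation import GeneFeature, MitoAnnotation, ftype_for_symbol
from .geneorder import GeneOrder, SignedGene, canonicalize
from .io import Mitogenome, reverse_complement

__all__ = [
    "SyntheticSpec",
    "base_probs",
    "generate_mitogenome",
    "apply_rearrangement",
    "random_signed_order",
    "random_event",
    "default_template",
]

_START_CODONS = ("ATG", "ATT", "ATA", "ATC")
_STOP_CODONS = ("TAA", "TAG")


def default_template() -> GeneOrder:
    from .fixtures import load_fixture

    return load_fixture("ancestral_pancrustacean")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic mitogenome.

    Defaults emulate a typical caridean mitogenome: ~68% AT, mildly
    positive AT-skew and negative GC-skew on the plus strand, tRNAs of
    61-68 bp, the documented atp8/atp6 7-bp overlap, and an AT-enriched
    control region of 180 bp.
    """

    order_template: Optional[GeneOrder] = None
    gene_length_ranges: dict = field(default_factory=lambda: {
        "PCG": (159, 1713),
        "tRNA": (61, 68),
        "rRNA": (800, 1340),
    })
    target_at: float = 0.68
    target_at_skew: float = 0.05
    target_gc_skew: float = -0.26
    intergenic_range: tuple[int, int] = (0, 20)
    overlap_spec: list = field(default_factory=lambda: [("atp8", "atp6", 7)])
    incomplete_stop_genes: frozenset = frozenset()
    cr_length: int = 180
    cr_at_enrichment: float = 1.15  # multiplicative boost of AT in the CR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.order_template is None:
            self.order_template = default_template()
        for p in base_probs(self.target_at, self.target_at_skew, self.target_gc_skew):
            if not (0.0 <= p <= 1.0):
                raise ValueError("infeasible composition targets")
        pairs = [(u, d) for u, d, _ in self.overlap_spec]
        syms = self.order_template.symbols()
        n = len(syms)
        for u, d in pairs:
            if u not in syms or d not in syms:
                raise ValueError(f"overlap pair ({u}, {d}) not in template")
            if (syms.index(d) - syms.index(u)) % n != 1:
                raise ValueError(f"overlap pair ({u}, {d}) not adjacent in template")


def base_probs(target_at: float, target_at_skew: float = 0.0,
               target_gc_skew: float = 0.0) -> tuple[float, float, float, float]:
    """(pA, pC, pG, pT) hitting the AT fraction and both skews exactly."""
    if not 0.0 < target_at < 1.0:
        raise ValueError("target_at must be in (0, 1)")
    p, sa, sg = target_at, target_at_skew, target_gc_skew
    pA = p * (1 + sa) / 2
    pT = p * (1 - sa) / 2
    pG = (1 - p) * (1 + sg) / 2
    pC = (1 - p) * (1 - sg) / 2
    probs = (pA, pC, pG, pT)
    if any(x < 0 or x > 1 for x in probs):
        raise ValueError("infeasible skew targets for this AT fraction")
    return probs


def _draw(rng: np.random.Generator, probs, n: int) -> str:
    return "".join(rng.choice(np.array(list("ACGT")), size=n, p=np.array(probs)))


def _write_coding(seq: list[str], f: GeneFeature, offset: int, bases: str) -> None:
    """Write ``bases`` at coding-relative ``offset`` of a feature into the
    plus-strand sequence list (strand-aware)."""
    if f.strand == "+":
        for j, b in enumerate(bases):
            seq[f.start - 1 + offset + j] = b
    else:
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        for j, b in enumerate(bases):
            # coding position offset+j sits at plus position end-1-(offset+j)
            seq[f.end - 1 - offset - j] = comp[b]


def generate_mitogenome(spec: SyntheticSpec) -> Mitogenome:
    """Simulate one annotated circular mitogenome from a spec.

    Genes are laid out along the template with drawn lengths and
    intergenic spacers (negative for pairs in ``overlap_spec``); PCGs get
    valid start codons and complete or incomplete stops; coordinates in
    the returned annotation are exact.
    """
    rng = np.random.default_rng(spec.seed)
    probs = base_probs(spec.target_at, spec.target_at_skew, spec.target_gc_skew)
    at_cr = min(spec.target_at * spec.cr_at_enrichment, 0.95)
    probs_cr = base_probs(at_cr, spec.target_at_skew, spec.target_gc_skew)

    template = spec.order_template.elements
    overlap_by_pair = {(u, d): o for u, d, o in spec.overlap_spec}

    # ---- draw lengths and gaps
    lengths: list[int] = []
    for sym, _strand in template:
        ftype = ftype_for_symbol(sym) or "CR"
        if ftype == "CR":
            lengths.append(spec.cr_length)
        elif ftype == "PCG":
            lo, hi = spec.gene_length_ranges["PCG"]
            raw = int(rng.integers(lo, hi + 1))
            length = max(6, raw - raw % 3)  # complete codons
            if sym in spec.incomplete_stop_genes:
                length += int(rng.integers(1, 3))  # trailing T or TA
            lengths.append(length)
        else:
            lo, hi = spec.gene_length_ranges[ftype]
            lengths.append(int(rng.integers(lo, hi + 1)))

    gaps: list[int] = []  # gap after element i (to element i+1, circular)
    for i, (sym, _strand) in enumerate(template):
        nxt = template[(i + 1) % len(template)][0]
        if (sym, nxt) in overlap_by_pair:
            gaps.append(-overlap_by_pair[(sym, nxt)])
        else:
            gaps.append(int(rng.integers(spec.intergenic_range[0],
                                         spec.intergenic_range[1] + 1)))

    genome_length = sum(lengths) + sum(gaps)
    if genome_length < max(lengths):
        raise ValueError("infeasible packing: overlaps exceed gene lengths")

    # ---- coordinates
    features: list[GeneFeature] = []
    pos = 1
    for (sym, strand), length, gap in zip(template, lengths, gaps):
        start = pos
        end = start + length - 1
        if end > genome_length:
            raise ValueError("infeasible packing: features exceed genome length")
        ftype = ftype_for_symbol(sym) or "CR"
        features.append(GeneFeature(symbol=sym, ftype=ftype, strand=strand,
                                    start=start, end=end))
        pos = end + gap + 1

    # ---- sequence: filler first, then feature spans (later features win
    # inside deliberate overlaps, which only affects bookkeeping tests)
    seq = list(_draw(rng, probs, genome_length))
    for f, length in zip(features, lengths):
        src = probs_cr if f.ftype == "CR" else probs
        plus = _draw(rng, src, length)
        if f.strand == "-":
            plus = reverse_complement(plus)
        seq[f.start - 1:f.end] = list(plus)

    # second pass: enforce PCG start/stop codons after all spans are
    # written, so a downstream overlapping gene cannot clobber them
    # (deliberate overlaps like atp8/atp6 leave start and stop disjoint)
    for f, length in zip(features, lengths):
        if f.ftype != "PCG":
            continue
        start_codon = _START_CODONS[rng.integers(0, len(_START_CODONS))]
        _write_coding(seq, f, 0, start_codon)
        r = length % 3
        if r == 1:
            _write_coding(seq, f, length - 1, "T")
        elif r == 2:
            _write_coding(seq, f, length - 2, "TA")
        else:
            _write_coding(seq, f, length - 3,
                          _STOP_CODONS[rng.integers(0, len(_STOP_CODONS))])

    annotation = MitoAnnotation(
        features=features,
        genome_length=genome_length,
        organism="synthetic",
        accession=None,
    )
    return Mitogenome(sequence="".join(seq), annotation=annotation)


# ---------------------------------------------------------------------------
# gene-order mutants

def apply_rearrangement(order: GeneOrder, event, seed: Optional[int] = None) -> GeneOrder:
    """Apply one rearrangement event to a signed circular order.

    ``event`` is ``(kind, block_symbols, position)`` with kind in
    {transposition, block_move, inversion, inverse_transposition, loss};
    ``block_symbols`` must be contiguous in the order (in order), and
    ``position`` is the insertion index into the order after block removal
    (ignored for in-place inversions and losses).  The result is
    re-canonicalized at the original anchor.
    """
    kind, block_symbols, position = event
    block_symbols = list(block_symbols)
    elems = list(order.elements)
    syms = [s for s, _ in elems]
    k = len(block_symbols)
    n = len(elems)

    # locate the block as a circular run
    start = None
    doubled = syms + syms
    for i in range(n):
        if doubled[i:i + k] == block_symbols:
            start = i
            break
    if start is None:
        raise ValueError(f"block {block_symbols} is not contiguous in the order")
    idx = [(start + j) % n for j in range(k)]
    block = [elems[i] for i in idx]
    if order.anchor in block_symbols and kind != "loss":
        raise ValueError("refusing to move or invert the anchor gene")

    if kind == "loss":
        remaining = [e for i, e in enumerate(elems) if i not in set(idx)]
        return canonicalize(remaining, anchor=order.anchor, name=order.name)

    if kind == "inversion":
        flipped = [(s, "-" if st == "+" else "+") for s, st in reversed(block)]
        out = elems[:]
        for i, e in zip(idx, flipped):
            out[i] = e
        return canonicalize(out, anchor=order.anchor, name=order.name)

    if kind in ("transposition", "block_move", "inverse_transposition"):
        moved = block if kind != "inverse_transposition" else \
            [(s, "-" if st == "+" else "+") for s, st in reversed(block)]
        remaining = [e for i, e in enumerate(elems) if i not in set(idx)]
        p = position % (len(remaining) + 1)
        out = remaining[:p] + moved + remaining[p:]
        return canonicalize(out, anchor=order.anchor, name=order.name)

    raise ValueError(f"unknown event kind {kind!r}")


def random_signed_order(n_genes: int, rng: np.random.Generator,
                        anchor: str = "g0") -> GeneOrder:
    """Random signed circular order over genes g0..g{n-1}, anchored at g0."""
    rest = [f"g{i}" for i in range(1, n_genes)]
    rng.shuffle(rest)
    elements: list[SignedGene] = [("g0", "+")]
    for s in rest:
        elements.append((s, "+" if rng.random() < 0.5 else "-"))
    return canonicalize(elements, anchor=anchor)


def random_event(order: GeneOrder, rng: np.random.Generator,
                 kinds: Sequence[str] = ("transposition", "inversion"),
                 max_block: int = 3):
    """Draw a random valid single event not touching the anchor."""
    n = len(order.elements)
    while True:
        kind = kinds[rng.integers(0, len(kinds))]
        k = int(rng.integers(1, max_block + 1))
        start = int(rng.integers(1, n))  # never start at the anchor (index 0)
        idx = [(start + j) % n for j in range(k)]
        if 0 in idx:
            continue
        block = [order.elements[i][0] for i in idx]
        if kind == "inversion":
            return (kind, block, 0)
        position = int(rng.integers(0, n - k + 1))
        # require the event to actually change the arrangement
        candidate = apply_rearrangement(order, (kind, block, position))
        if candidate.elements != order.elements:
            return (kind, block, position)
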