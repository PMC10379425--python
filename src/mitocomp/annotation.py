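"""Core data model for annotated circular mitochondrial genomes.

A metazoan mitogenome is a closed circular molecule of roughly 15-17 kb
carrying 37 genes (13 protein-coding genes, 22 tRNAs, 2 rRNAs) plus a
non-coding, AT-rich control region (CR).  Everything in this module is
pure coordinate arithmetic over a feature table: feature lengths, signed
intergenic gaps (negative = overlap), and per-class aggregates.

Coordinates are 1-based inclusive throughout, the convention of GenBank
feature tables and of published annotation tables.  A feature may wrap
the origin of the circle (end < start), in which case its length is
``genome_length - start + 1 + end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

__all__ = [
    "PCG_SYMBOLS",
    "TRNA_SYMBOLS",
    "RRNA_SYMBOLS",
    "GENE_VOCABULARY",
    "GeneFeature",
    "MitoAnnotation",
    "AnnotationSummary",
    "feature_length",
    "gap_between",
    "summarize",
    "genome_length_from_annotation",
]

#: The 13 mitochondrial protein-coding genes.
PCG_SYMBOLS = (
    "cox1", "cox2", "cox3", "atp6", "atp8",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
    "cytb",
)

#: The 22 tRNA genes; leucine and serine each have two isoacceptors,
#: distinguished by codon family (trnL1=CUN, trnL2=UUR; trnS1=AGN, trnS2=UCN).
TRNA_SYMBOLS = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)

#: Large (16S) and small (12S) ribosomal-subunit rRNA genes.
RRNA_SYMBOLS = ("16S", "12S")

#: Full 37-gene vocabulary plus the control region.
GENE_VOCABULARY = frozenset(PCG_SYMBOLS) | frozenset(TRNA_SYMBOLS) | frozenset(RRNA_SYMBOLS) | {"CR"}

_FTYPES = ("PCG", "tRNA", "rRNA", "CR")


class CoordinateError(ValueError):
    """A feature coordinate falls outside [1, genome_length]."""


class EmptyAnnotationError(ValueError):
    """An operation that needs features received none."""


def ftype_for_symbol(symbol: str) -> Optional[str]:
    """Infer the feature class from a canonical gene symbol, or None."""
    if symbol in PCG_SYMBOLS:
        return "PCG"
    if symbol in TRNA_SYMBOLS or symbol.startswith("trn"):
        return "tRNA"
    if symbol in RRNA_SYMBOLS:
        return "rRNA"
    if symbol == "CR":
        return "CR"
    return None


@dataclass(frozen=True)
class GeneFeature:
    """One annotated element of a mitogenome.

    ``start``/``end`` are 1-based inclusive.  ``stop_codon`` may encode an
    incomplete stop completed by polyadenylation, e.g. ``"T(AA)"``.
    """

    symbol: str
    ftype: str
    strand: str
    start: int
    end: int
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ftype not in _FTYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise CoordinateError(
                f"{self.symbol}: coordinates must be >= 1, got ({self.start}, {self.end})"
            )
        inferred = ftype_for_symbol(self.symbol)
        if inferred is not None and inferred != self.ftype:
            raise ValueError(
                f"{self.symbol}: feature type {self.ftype!r} inconsistent with symbol "
                f"(expected {inferred!r})"
            )


@dataclass
class MitoAnnotation:
    """An ordered circular feature table plus the genome length."""

    features: list[GeneFeature]
    genome_length: int
    circular: bool = True
    organism: str = ""
    accession: Optional[str] = None

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.start > self.genome_length or f.end > self.genome_length:
                raise CoordinateError(
                    f"{f.symbol}: ({f.start}, {f.end}) outside genome of "
                    f"{self.genome_length} bp"
                )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def get(self, symbol: str) -> GeneFeature:
        for f in self.features:
            if f.symbol == symbol:
                return f
        raise KeyError(symbol)

    def symbols(self) -> list[str]:
        return [f.symbol for f in self.features]

    def of_type(self, ftype: str) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype == ftype]

    def rotated(self, offset: int) -> "MitoAnnotation":
        """Return the same circular annotation with the origin shifted by
        ``offset`` bp (coordinates rebased modulo genome length).  Used by
        property tests to check rotation invariance of derived statistics."""
        n = self.genome_length

        def shift(pos: int) -> int:
            return (pos - 1 - offset) % n + 1

        feats = [replace(f, start=shift(f.start), end=shift(f.end)) for f in self.features]
        return MitoAnnotation(
            features=feats,
            genome_length=n,
            circular=self.circular,
            organism=self.organism,
            accession=self.accession,
        )


def feature_length(f: GeneFeature, genome_length: int) -> int:
    """Length in bp of a feature on a circle of ``genome_length`` bp.

    ``end >= start`` is the ordinary linear case; ``end < start`` means the
    feature wraps the origin.
    """
    if not (1 <= f.start <= genome_length and 1 <= f.end <= genome_length):
        raise CoordinateError(
            f"{f.symbol}: ({f.start}, {f.end}) outside [1, {genome_length}]"
        )
    if f.end >= f.start:
        return f.end - f.start + 1
    return genome_length - f.start + 1 + f.end


def gap_between(f_up: GeneFeature, f_down: GeneFeature, genome_length: int) -> int:
    """Signed intergenic distance from ``f_up`` to the next feature ``f_down``.

    Positive = intergenic spacer of that many bp, 0 = abutting, negative =
    the two features overlap by ``|gap|`` bp.  The last->first adjacency of
    the circle wraps modulo the genome length.
    """
    if f_up is f_down or (f_up.symbol == f_down.symbol and f_up.start == f_down.start):
        raise ValueError("gap_between requires two distinct adjacent features")
    gap = f_down.start - f_up.end - 1
    if f_down.start < f_up.start:  # circular wrap: f_down is past the origin
        gap += genome_length
    return gap


@dataclass
class AnnotationSummary:
    """Aggregate statistics derived from a :class:`MitoAnnotation`.

    ``n_overlaps``/``n_gaps`` count over *all* circular adjacencies;
    ``n_overlaps_table``/``n_gaps_table`` count only adjacencies whose
    upstream feature is not the control region — the convention of printed
    annotation tables, whose intergenic column leaves the CR row blank.
    Published overlap/gap counts do not state which convention they use, so
    both are reported.
    """

    per_feature: list[tuple[str, int, int]]  # (symbol, length, gap_to_next)
    class_totals: dict[str, int]
    strand_counts: dict[str, int]
    longest_pcg: tuple[str, int]
    shortest_pcg: tuple[str, int]
    largest_gap: tuple[str, str, int]      # upstream, downstream, bp
    largest_overlap: tuple[str, str, int]  # upstream, downstream, bp (positive)
    n_overlaps: int
    n_gaps: int
    n_overlaps_table: int
    n_gaps_table: int
    genome_length: int

    def length_of(self, symbol: str) -> int:
        for sym, length, _ in self.per_feature:
            if sym == symbol:
                return length
        raise KeyError(symbol)


def summarize(a: MitoAnnotation) -> AnnotationSummary:
    """Compute all aggregate statistics for one annotation.

    Class totals are plain sums of feature lengths: bases shared by two
    overlapping features count once per feature, not unioned.  Adjacency
    gaps run over consecutive features in start order including the
    circular last->first pair.
    """
    if not a.features:
        raise EmptyAnnotationError("cannot summarize an empty annotation")

    n = len(a.features)
    per_feature: list[tuple[str, int, int]] = []
    class_totals: dict[str, int] = {}
    strand_counts: dict[str, int] = {}
    largest_gap = ("", "", -(10**9))
    largest_overlap = ("", "", 0)
    n_overlaps = n_gaps = 0
    n_overlaps_table = n_gaps_table = 0

    for i, f in enumerate(a.features):
        length = feature_length(f, a.genome_length)
        class_totals[f.ftype] = class_totals.get(f.ftype, 0) + length
        strand_counts[f.strand] = strand_counts.get(f.strand, 0) + 1
        if n > 1:
            nxt = a.features[(i + 1) % n]
            gap = gap_between(f, nxt, a.genome_length)
        else:
            gap = a.genome_length - length  # lone feature: rest of the circle
        per_feature.append((f.symbol, length, gap))
        if n > 1:
            if gap > 0:
                n_gaps += 1
                if f.ftype != "CR":
                    n_gaps_table += 1
                if gap > largest_gap[2]:
                    largest_gap = (f.symbol, nxt.symbol, gap)
            elif gap < 0:
                n_overlaps += 1
                if f.ftype != "CR":
                    n_overlaps_table += 1
                if -gap > largest_overlap[2]:
                    largest_overlap = (f.symbol, nxt.symbol, -gap)

    pcgs = [(f.symbol, row[1]) for f, row in zip(a.features, per_feature) if f.ftype == "PCG"]
    longest_pcg = max(pcgs, key=lambda t: t[1]) if pcgs else ("", 0)
    shortest_pcg = min(pcgs, key=lambda t: t[1]) if pcgs else ("", 0)
    if largest_gap[2] == -(10**9):
        largest_gap = ("", "", 0)

    return AnnotationSummary(
        per_feature=per_feature,
        class_totals=class_totals,
        strand_counts=strand_counts,
        longest_pcg=longest_pcg,
        shortest_pcg=shortest_pcg,
        largest_gap=largest_gap,
        largest_overlap=largest_overlap,
        n_overlaps=n_overlaps,
        n_gaps=n_gaps,
        n_overlaps_table=n_overlaps_table,
        n_gaps_table=n_gaps_table,
        genome_length=a.genome_length,
    )


def genome_length_from_annotation(a: MitoAnnotation) -> tuple[int, bool]:
    """Maximum end coordinate and whether it equals the declared length.

    Returns ``(max_end, consistent)``; a mismatch usually means the
    annotation stops short of the control region's downstream flank.
    """
    if not a.features:
        raise EmptyAnnotationError("empty annotation has no coordinates")
    max_end = max(f.end for f in a.features)
    return max_end, max_end == a.genome_length
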