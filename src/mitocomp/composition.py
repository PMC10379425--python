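"""Base composition and strand-skew statistics.

Strand asymmetry is summarized by the usual skew statistics,

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

computed over unambiguous bases.  Ambiguity codes (N etc.) are excluded
from counts and denominators and reported separately.  Reverse
complementation exchanges A<->T and G<->C, so it negates both skews
exactly — the basic sanity property of any implementation.

Per-class statistics (all PCGs, all tRNAs, ...) concatenate the feature
spans in genome order.  Two strand conventions are offered: ``genome_plus``
reads every span off the plus strand as deposited, ``coding_strand``
(the default) reverse-complements minus-strand features first, i.e. reads
each gene in its sense orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .annotation import MitoAnnotation, GeneFeature, feature_length
from .io import Mitogenome, reverse_complement

__all__ = [
    "CompositionStats",
    "base_composition",
    "skews",
    "span_sequence",
    "class_composition",
    "merge_stats",
]


@dataclass(frozen=True)
class CompositionStats:
    n_A: int
    n_C: int
    n_G: int
    n_T: int
    n_ambiguous: int = 0

    @property
    def length(self) -> int:
        """Unambiguous bases counted."""
        return self.n_A + self.n_C + self.n_G + self.n_T

    @property
    def pct_A(self) -> float:
        return 100.0 * self.n_A / self.length

    @property
    def pct_C(self) -> float:
        return 100.0 * self.n_C / self.length

    @property
    def pct_G(self) -> float:
        return 100.0 * self.n_G / self.length

    @property
    def pct_T(self) -> float:
        return 100.0 * self.n_T / self.length

    @property
    def pct_AT(self) -> float:
        return 100.0 * (self.n_A + self.n_T) / self.length

    @property
    def pct_GC(self) -> float:
        return 100.0 * (self.n_G + self.n_C) / self.length

    @property
    def at_skew(self) -> Optional[float]:
        """(A-T)/(A+T); None when A+T == 0 (undefined, not an error)."""
        denom = self.n_A + self.n_T
        return (self.n_A - self.n_T) / denom if denom else None

    @property
    def gc_skew(self) -> Optional[float]:
        """(G-C)/(G+C); None when G+C == 0."""
        denom = self.n_G + self.n_C
        return (self.n_G - self.n_C) / denom if denom else None


def base_composition(seq: str) -> CompositionStats:
    """Count bases of a nucleotide string (case-insensitive)."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    bad = set(s) - set("ACGTNRYSWKMBDHV")
    if bad:
        raise ValueError(f"non-IUPAC characters: {sorted(bad)}")
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    return CompositionStats(
        n_A=a, n_C=c, n_G=g, n_T=t, n_ambiguous=len(s) - a - c - g - t
    )


def skews(stats: CompositionStats) -> tuple[Optional[float], Optional[float]]:
    """(AT-skew, GC-skew); a zero-denominator skew is None."""
    return stats.at_skew, stats.gc_skew


def merge_stats(parts: list[CompositionStats]) -> CompositionStats:
    """Length-weighted merge: counts are additive over a partition."""
    return CompositionStats(
        n_A=sum(p.n_A for p in parts),
        n_C=sum(p.n_C for p in parts),
        n_G=sum(p.n_G for p in parts),
        n_T=sum(p.n_T for p in parts),
        n_ambiguous=sum(p.n_ambiguous for p in parts),
    )


def span_sequence(sequence: str, f: GeneFeature) -> str:
    """Plus-strand bases covered by a feature; origin-wrapping supported."""
    n = len(sequence)
    if f.end >= f.start:
        return sequence[f.start - 1:f.end]
    return sequence[f.start - 1:] + sequence[:f.end]


def class_composition(g: Mitogenome, ftype: str,
                      strand_mode: str = "coding_strand") -> CompositionStats:
    """Composition of the concatenated spans of one feature class.

    Overlapping spans contribute once per feature (no unioning), matching
    the convention of per-class totals in annotation tables.
    """
    if g.annotation is None:
        raise ValueError("class_composition requires an annotated genome")
    if strand_mode not in ("genome_plus", "coding_strand"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    feats = [f for f in g.annotation.features if f.ftype == ftype] \
        if ftype != "genome" else list(g.annotation.features)
    if ftype == "genome":
        return base_composition(g.sequence)
    if not feats:
        raise ValueError(f"no features of class {ftype!r} in annotation")
    chunks = []
    for f in feats:
        span = span_sequence(g.sequence, f)
        if strand_mode == "coding_strand" and f.strand == "-":
            span = reverse_complement(span)
        chunks.append(span)
    return base_composition("".join(chunks))
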