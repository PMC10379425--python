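"""Codon usage under the invertebrate mitochondrial genetic code.

Translation table 5 is fixed by the organisms' class (AGA/AGG encode Ser,
AUA is Met, UGA is Trp; UAA/UAG are the only stops) but the code id is
configurable for reuse.  Leucine and serine are kept as two synonymous
families each, split by codon family — Leu1 = CUN, Leu2 = UUR, Ser1 = AGN,
Ser2 = UCN — as is conventional in mitogenome codon-usage plots.

Relative synonymous codon usage of codon c in a family of size k with
counts n_1..n_k is

    RSCU(c) = n_c * k / (n_1 + ... + n_k),

so uniform usage gives 1 for every member and the family's RSCU values
always sum to k; RSCU >= 1 marks a preferred codon.

Stop codons are excluded from amino-acid frequencies and RSCU by default
(configurable), and incomplete terminal codons are never counted.
Mitochondrial PCGs frequently end on a bare T or TA completed to UAA by
polyadenylation of the transcript; stop detection therefore has two
conventions, polyadenylation-aware (reporting "T(AA)"/"TA(A)") and
verbatim (reporting the final in-frame triplet).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio.Data import CodonTable

from .annotation import GeneFeature
from .composition import span_sequence
from .io import Mitogenome, reverse_complement

__all__ = [
    "CodonAssignment",
    "CodonProfile",
    "coding_sequence",
    "detect_start_stop",
    "count_codons",
    "rscu",
    "preferred_codons",
    "INVERTEBRATE_MITO",
]

_BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


@dataclass(frozen=True)
class CodonAssignment:
    """A genetic code plus the conventions used on top of it."""

    table_id: int = 5
    start_codons: tuple[str, ...] = ("ATG", "ATT", "ATA", "ATC")

    @property
    def forward_table(self) -> dict[str, str]:
        table = CodonTable.unambiguous_dna_by_id[self.table_id]
        return dict(table.forward_table)

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(CodonTable.unambiguous_dna_by_id[self.table_id].stop_codons)

    def amino_acid(self, codon: str) -> Optional[str]:
        """One-letter amino acid, or None for a stop codon."""
        return self.forward_table.get(codon)

    def families(self) -> dict[str, tuple[str, ...]]:
        """Synonymous families keyed by label, with Leu/Ser split in two.

        Labels are amino-acid names with Leu1/Leu2/Ser1/Ser2 distinguished;
        every sense codon appears in exactly one family.
        """
        fwd = self.forward_table
        fams: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            aa = fwd.get(codon)
            if aa is None:
                continue
            label = aa
            if aa == "L":
                label = "Leu1" if codon.startswith("CT") else "Leu2"
            elif aa == "S":
                label = "Ser1" if codon.startswith("AG") else "Ser2"
            fams.setdefault(label, []).append(codon)
        return {k: tuple(v) for k, v in fams.items()}

    def family_of(self, codon: str) -> Optional[str]:
        for label, members in self.families().items():
            if codon in members:
                return label
        return None


INVERTEBRATE_MITO = CodonAssignment(table_id=5)


def coding_sequence(g: Mitogenome, f: GeneFeature) -> str:
    """Sense-strand CDS of a protein-coding feature (wrap-aware)."""
    if f.ftype != "PCG":
        raise ValueError(f"{f.symbol} is not a protein-coding gene")
    span = span_sequence(g.sequence, f)
    return reverse_complement(span) if f.strand == "-" else span


def detect_start_stop(cds: str, *, polyadenylation_aware: bool = True
                      ) -> tuple[str, str]:
    """Identify the start codon and the (possibly incomplete) stop.

    Under the polyadenylation-aware convention (default) a trailing frame
    remainder of "T" or "TA" is reported as "T(AA)"/"TA(A)" — the bases the
    poly(A) tail completes to UAA.  A remainder of two bases ending in T is
    also reported as "T(AA)", matching how such genes are annotated in
    deposited records.  Otherwise, and always under the verbatim
    convention, the final complete in-frame triplet is reported as-is
    (published tables contain non-canonical verbatim stops such as CTA and
    ACT).
    """
    cds = cds.upper()
    if len(cds) < 6:
        raise ValueError(f"CDS too short to carry start and stop ({len(cds)} bp)")
    start = cds[:3]
    r = len(cds) % 3
    last_triplet = cds[3 * ((len(cds) - r) // 3 - 1): 3 * ((len(cds) - r) // 3)]
    if polyadenylation_aware and r:
        tail = cds[-r:]
        if tail == "TA":
            return start, "TA(A)"
        if tail.endswith("T"):
            return start, "T(AA)"
    return start, last_triplet


@dataclass
class CodonProfile:
    """Codon counts plus derived amino-acid frequencies and RSCU."""

    codon_counts: dict[str, int]
    assignment: CodonAssignment = field(default_factory=lambda: INVERTEBRATE_MITO)
    include_stops: bool = False

    @property
    def total(self) -> int:
        return sum(self.codon_counts.values())

    @property
    def aa_counts(self) -> dict[str, int]:
        """Counts per amino-acid label (Leu1/Leu2, Ser1/Ser2 distinct);
        stop codons excluded unless ``include_stops``."""
        out: dict[str, int] = {}
        fams = self.assignment.families()
        for label, members in fams.items():
            out[label] = sum(self.codon_counts.get(c, 0) for c in members)
        if self.include_stops:
            out["*"] = sum(self.codon_counts.get(c, 0)
                           for c in self.assignment.stop_codons)
        return out

    @property
    def rscu(self) -> dict[str, float]:
        return rscu(self.codon_counts, self.assignment)

    @property
    def unobserved_families(self) -> set[str]:
        fams = self.assignment.families()
        return {label for label, members in fams.items()
                if sum(self.codon_counts.get(c, 0) for c in members) == 0}

    @property
    def preferred(self) -> set[str]:
        return preferred_codons(self.rscu, self.assignment)


def count_codons(cds_list: Iterable[str],
                 assignment: CodonAssignment = INVERTEBRATE_MITO,
                 include_stops: bool = False) -> CodonProfile:
    """Tally complete triplets over a list of CDSs.

    Terminal incomplete codons (frame remainder) are dropped; stop codons
    are excluded from the tally unless ``include_stops``.
    """
    counts: dict[str, int] = {}
    stops = set(assignment.stop_codons)
    for cds in cds_list:
        s = cds.upper()
        if len(s) < 6:
            raise ValueError(f"CDS too short ({len(s)} bp)")
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i:i + 3]
            if set(codon) - set("ACGT"):
                continue  # ambiguous triplets are not countable
            if codon in stops and not include_stops:
                continue
            counts[codon] = counts.get(codon, 0) + 1
    return CodonProfile(codon_counts=counts, assignment=assignment,
                        include_stops=include_stops)


def rscu(codon_counts: dict[str, int],
         assignment: CodonAssignment = INVERTEBRATE_MITO) -> dict[str, float]:
    """RSCU per sense codon; all-zero families get 0.0 for every member
    (flagged via :attr:`CodonProfile.unobserved_families`, never NaN)."""
    out: dict[str, float] = {}
    for label, members in assignment.families().items():
        k = len(members)
        fam_total = sum(codon_counts.get(c, 0) for c in members)
        for c in members:
            out[c] = (codon_counts.get(c, 0) * k / fam_total) if fam_total else 0.0
    return out


def preferred_codons(rscu_map: dict[str, float],
                     assignment: CodonAssignment = INVERTEBRATE_MITO) -> set[str]:
    """Sense codons with RSCU >= 1 (the boundary value counts)."""
    stops = set(assignment.stop_codons)
    return {c for c, v in rscu_map.items() if v >= 1.0 and c not in stops}
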