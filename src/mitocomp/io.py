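"""Readers and writers for the formats the pipeline touches.

FASTA and GenBank flat files are handled through Biopython's ``SeqIO``;
annotation tables travel as TSV mirroring the columns of published
mitogenome annotation tables (symbol, strand, start, end, size,
intergenic, start/stop codon, anticodon, "." for absent values).
Gene orders use a one-line-per-genome text format of comma-separated
signed symbols (``cox1,trnL2,...,-trnF``).

Gene symbols from GenBank records are normalized to the canonical
37-gene vocabulary (``cox1``..., ``trnA``..., ``16S``/``12S``, ``CR``);
depositor naming is wildly inconsistent, so the mapping is explicit and
unknown symbols are kept verbatim with a warning rather than dropped.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq

from .annotation import (
    GeneFeature,
    MitoAnnotation,
    AnnotationSummary,
    feature_length,
    gap_between,
    ftype_for_symbol,
)
from .geneorder import GeneOrder, parse_order_string, format_order_string

__all__ = [
    "Mitogenome",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "write_summary_tsv",
    "read_gene_orders",
    "write_gene_orders",
    "write_phylip_matrix",
    "normalize_symbol",
]

_VALID_BASES = set("ACGTNRYSWKMBDHV")


@dataclass
class Mitogenome:
    """Plus-strand nucleotide sequence plus its annotation."""

    sequence: str
    annotation: Optional[MitoAnnotation] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
        if self.annotation is not None and len(self.sequence) != self.annotation.genome_length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != annotated genome length "
                f"{self.annotation.genome_length}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: Union[str, Path]) -> dict[str, str]:
    """Read a (multi-record) FASTA file into {id: uppercased sequence}."""
    path = Path(path)
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences: dict[str, str], path: Union[str, Path],
                width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# gene-symbol normalization

# canonical mapping; keys are lowercase with punctuation stripped
_AA_BY_LETTER = {
    "a": "A", "c": "C", "d": "D", "e": "E", "f": "F", "g": "G", "h": "H",
    "i": "I", "k": "K", "l": "L", "m": "M", "n": "N", "p": "P", "q": "Q",
    "r": "R", "s": "S", "t": "T", "v": "V", "w": "W", "y": "Y",
}

_THREE_LETTER_AA = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "gln": "Q",
    "glu": "E", "gly": "G", "his": "H", "ile": "I", "leu": "L", "lys": "K",
    "met": "M", "phe": "F", "pro": "P", "ser": "S", "thr": "T", "trp": "W",
    "tyr": "Y", "val": "V",
}

_SYMBOL_TABLE = {
    "cox1": "cox1", "coi": "cox1", "co1": "cox1", "coxi": "cox1",
    "cox2": "cox2", "coii": "cox2", "co2": "cox2", "coxii": "cox2",
    "cox3": "cox3", "coiii": "cox3", "co3": "cox3", "coxiii": "cox3",
    "atp6": "atp6", "atpase6": "atp6", "atp8": "atp8", "atpase8": "atp8",
    "nd1": "nad1", "nad1": "nad1", "nd2": "nad2", "nad2": "nad2",
    "nd3": "nad3", "nad3": "nad3", "nd4": "nad4", "nad4": "nad4",
    "nd4l": "nad4l", "nad4l": "nad4l", "nd5": "nad5", "nad5": "nad5",
    "nd6": "nad6", "nad6": "nad6",
    "cytb": "cytb", "cob": "cytb", "cb": "cytb",
    "rrnl": "16S", "16s": "16S", "lrrna": "16S", "rrn16": "16S",
    "16srrna": "16S", "16sribosomalrna": "16S",
    "rrns": "12S", "12s": "12S", "srrna": "12S", "rrn12": "12S",
    "12srrna": "12S", "12sribosomalrna": "12S",
    "dloop": "CR", "controlregion": "CR", "cr": "CR",
    "atrich": "CR", "atrichregion": "CR", "putativecontrolregion": "CR",
}


def normalize_symbol(raw: str) -> Optional[str]:
    """Map a depositor gene name onto the canonical vocabulary, or None."""
    key = re.sub(r"[\s\-_().'/]", "", raw).lower()
    if key in _SYMBOL_TABLE:
        return _SYMBOL_TABLE[key]
    # tRNA spellings: trnL2, trnL(UUR), tRNA-Leu, trnl-uur, trnS1 ...
    m = re.match(r"^trna?([a-z])(\d?)(uur|cun|ucn|agn|uuy|ucu|uga|tag|taa|gct|tga)?$", key)
    if m:
        letter, num, codon = m.groups()
        aa = _AA_BY_LETTER.get(letter)
        if aa:
            return _trna_symbol(aa, num, codon)
    m = re.match(r"^trna?([a-z]{3})(\d?)(uur|cun|ucn|agn)?$", key)
    if m:
        three, num, codon = m.groups()
        aa = _THREE_LETTER_AA.get(three)
        if aa:
            return _trna_symbol(aa, num, codon)
    return None


def _trna_symbol(aa: str, num: str, codon: Optional[str]) -> str:
    if aa in ("L", "S"):
        if num in ("1", "2"):
            return f"trn{aa}{num}"
        if codon in ("cun", "tag"):
            return "trnL1"
        if codon in ("uur", "taa"):
            return "trnL2"
        if codon in ("agn", "gct", "ucu"):
            return "trnS1"
        if codon in ("ucn", "uga", "tga"):
            return "trnS2"
        # undisambiguated leucine/serine: default to the L1/S1 family,
        # flagged by the caller via the unknown-symbol path if needed
        return f"trn{aa}1"
    return f"trn{aa}"


# ---------------------------------------------------------------------------
# GenBank

_GB_FTYPE = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
             "D-loop": "CR", "D_loop": "CR"}


def read_genbank(path: Union[str, Path]) -> Mitogenome:
    """Read a GenBank flat file into a :class:`Mitogenome`.

    CDS/tRNA/rRNA/D-loop features are mapped onto :class:`GeneFeature`;
    ``complement(...)`` locations become strand "-"; D-loop or
    control-region misc_features become the CR.  Unknown gene names are
    preserved (and warned about), never silently dropped.
    """
    path = Path(path)
    record = next(SeqIO.parse(str(path), "genbank"))
    sequence = str(record.seq).upper()
    n = len(sequence)

    features: list[GeneFeature] = []
    seen: set[tuple[str, int]] = set()
    for feat in record.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "D-loop", "D_loop", "misc_feature"):
            continue
        quals = feat.qualifiers
        raw = (quals.get("gene") or quals.get("product") or quals.get("note") or [""])[0]
        if feat.type in ("D-loop", "D_loop") or "control region" in raw.lower():
            symbol: Optional[str] = "CR"
        else:
            symbol = normalize_symbol(raw)
            if feat.type == "misc_feature" and symbol is None:
                continue
        if symbol is None:
            warnings.warn(f"unrecognized gene name {raw!r} in {path.name}; kept verbatim")
            symbol = raw
        start = int(feat.location.start) + 1  # 0-based half-open -> 1-based inclusive
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        ftype = _GB_FTYPE.get(feat.type) or ftype_for_symbol(symbol) or "CR"
        if ftype == "CR" and symbol != "CR":
            ftype = ftype_for_symbol(symbol) or "tRNA"
        key = (symbol, start)
        if key in seen:
            continue
        seen.add(key)
        codon_start = quals.get("codon_start", ["1"])[0]
        features.append(GeneFeature(
            symbol=symbol,
            ftype=ftype if ftype in ("PCG", "tRNA", "rRNA", "CR") else "CR",
            strand=strand,
            start=start,
            end=end,
        ))

    annotation = MitoAnnotation(
        features=features,
        genome_length=n,
        circular="circular" in (record.annotations.get("topology", "") or ""),
        organism=record.annotations.get("organism", ""),
        accession=record.id,
    )
    return Mitogenome(sequence=sequence, annotation=annotation)


# ---------------------------------------------------------------------------
# annotation TSV

_TSV_COLUMNS = ["symbol", "strand", "start", "end", "size", "intergenic",
                "start_codon", "stop_codon", "anticodon"]


def read_annotation_tsv(path: Union[str, Path],
                        genome_length: Optional[int] = None) -> MitoAnnotation:
    """Read an annotation TSV (the published-table column layout).

    Header comment lines may carry ``genome_length=``, ``organism=`` and
    ``accession=`` tokens; an explicit ``genome_length`` argument wins.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[dict[str, str]] = []
    header: Optional[list[str]] = None
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            for m in re.finditer(r"(genome_length|organism|accession)=([^\t#]+?)(?=\s{2,}|\s+\w+=|$)", line.lstrip("# ")):
                meta[m.group(1)] = m.group(2).strip()
            continue
        cells = line.rstrip("\n").split("\t")
        if header is None:
            header = cells
            continue
        rows.append(dict(zip(header, cells)))
    if header is None or not rows:
        raise ValueError(f"no annotation rows in {path}")

    features = []
    for row in rows:
        symbol = row["symbol"]
        start, end = int(row["start"]), int(row["end"])
        ftype = ftype_for_symbol(symbol)
        if ftype is None:
            ftype = "CR"
        features.append(GeneFeature(
            symbol=symbol,
            ftype=ftype,
            strand=row["strand"],
            start=start,
            end=end,
            anticodon=_cell(row.get("anticodon")),
            start_codon=_cell(row.get("start_codon")),
            stop_codon=_cell(row.get("stop_codon")),
        ))

    if genome_length is None:
        if "genome_length" in meta:
            genome_length = int(meta["genome_length"])
        else:
            genome_length = max(f.end for f in features)
    return MitoAnnotation(
        features=features,
        genome_length=genome_length,
        organism=meta.get("organism", ""),
        accession=meta.get("accession"),
    )


def _cell(value: Optional[str]) -> Optional[str]:
    if value is None or value in (".", ""):
        return None
    return value


def write_annotation_tsv(a: MitoAnnotation, path: Union[str, Path]) -> None:
    """Write an annotation as TSV; re-reading reproduces the annotation."""
    path = Path(path)
    n = len(a.features)
    lines = [
        f"# genome_length={a.genome_length}  organism={a.organism}  "
        f"accession={a.accession or '.'}",
        "\t".join(_TSV_COLUMNS),
    ]
    for i, f in enumerate(a.features):
        if n > 1:
            gap = gap_between(f, a.features[(i + 1) % n], a.genome_length)
            gap_s = str(gap)
        else:
            gap_s = "."
        lines.append("\t".join([
            f.symbol, f.strand, str(f.start), str(f.end),
            str(feature_length(f, a.genome_length)), gap_s,
            f.start_codon or ".", f.stop_codon or ".", f.anticodon or ".",
        ]))
    path.write_text("\n".join(lines) + "\n")


def write_summary_tsv(summary: AnnotationSummary, path: Union[str, Path]) -> None:
    """Write per-feature lengths/gaps plus aggregate rows, deterministically."""
    path = Path(path)
    lines = ["symbol\tlength\tgap_to_next"]
    for sym, length, gap in summary.per_feature:
        lines.append(f"{sym}\t{length}\t{gap}")
    lines.append("")
    lines.append("statistic\tvalue")
    lines.append(f"genome_length\t{summary.genome_length}")
    for ftype in sorted(summary.class_totals):
        lines.append(f"total_{ftype}\t{summary.class_totals[ftype]}")
    for strand in sorted(summary.strand_counts):
        lines.append(f"strand_{strand}\t{summary.strand_counts[strand]}")
    lines.append(f"longest_pcg\t{summary.longest_pcg[0]}:{summary.longest_pcg[1]}")
    lines.append(f"shortest_pcg\t{summary.shortest_pcg[0]}:{summary.shortest_pcg[1]}")
    lines.append(
        f"largest_gap\t{summary.largest_gap[0]}>{summary.largest_gap[1]}:{summary.largest_gap[2]}"
    )
    lines.append(
        f"largest_overlap\t{summary.largest_overlap[0]}>{summary.largest_overlap[1]}:"
        f"{summary.largest_overlap[2]}"
    )
    lines.append(f"n_overlaps\t{summary.n_overlaps}")
    lines.append(f"n_gaps\t{summary.n_gaps}")
    lines.append(f"n_overlaps_table\t{summary.n_overlaps_table}")
    lines.append(f"n_gaps_table\t{summary.n_gaps_table}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# gene orders & distance matrices

def read_gene_orders(path: Union[str, Path], anchor: str = "cox1") -> dict[str, GeneOrder]:
    path = Path(path)
    orders: dict[str, GeneOrder] = {}
    for i, line in enumerate(path.read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            name, text = line.split("\t", 1)
        else:
            name, text = f"order{i}", line
        orders[name] = parse_order_string(text, name=name, anchor=anchor)
    if not orders:
        raise ValueError(f"no gene orders in {path}")
    return orders


def write_gene_orders(orders: dict[str, GeneOrder], path: Union[str, Path]) -> None:
    path = Path(path)
    lines = [f"{name}\t{format_order_string(o)}" for name, o in orders.items()]
    path.write_text("\n".join(lines) + "\n")


def write_phylip_matrix(names: list[str], matrix, path: Union[str, Path]) -> None:
    """Write a PHYLIP square distance matrix (name width 10+)."""
    path = Path(path)
    width = max(10, max(len(n) for n in names) + 2)
    lines = [f"{len(names)}"]
    for name, row in zip(names, matrix):
        lines.append(name.ljust(width) + "  ".join(f"{v:g}" for v in row))
    path.write_text("\n".join(lines) + "\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement via Biopython (IUPAC-aware)."""
    return str(Seq(seq).reverse_complement())
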