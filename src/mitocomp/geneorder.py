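"""Signed circular gene orders and rearrangement detection.

A mitochondrial gene arrangement is modelled as a signed circular
permutation: one full traversal of the circle as a list of
``(symbol, strand)`` pairs, canonically anchored at ``cox1`` on the plus
strand.  Two arrangements are compared by

1. set-differencing the gene complements (``lost`` / ``gained``),
2. finding a conserved backbone as the longest common subsequence of
   signed elements over the shared genes (both orders are anchored at the
   same gene, which resolves the cyclic alignment),
3. grouping off-backbone genes of the target into maximal blocks that are
   contiguous in both orders, and
4. classifying each block by strand and placement: same strand at a new
   position is a transposition (single gene) or block move (multi-gene
   block relocated intact); flipped strand in the same slot is an
   inversion; flipped strand at a new position is an inverse transposition.

The breakpoint distance — the number of signed adjacencies of one order,
including the circular closing adjacency, missing from the other — is the
standard summary statistic for arrangement divergence.  No attempt is made
to reconstruct a minimal event scenario (tandem-duplication-random-loss
style histories are out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .annotation import MitoAnnotation

__all__ = [
    "SignedGene",
    "GeneOrder",
    "RearrangementEvent",
    "RearrangementReport",
    "extract_gene_order",
    "compare_orders",
    "breakpoint_distance",
    "order_distance_matrix",
    "parse_order_string",
    "format_order_string",
]

SignedGene = tuple[str, str]  # (symbol, "+" | "-")


def _flip(e: SignedGene) -> SignedGene:
    return (e[0], "-" if e[1] == "+" else "+")


@dataclass(frozen=True)
class GeneOrder:
    """One traversal of a circular genome as signed elements from an anchor."""

    elements: tuple[SignedGene, ...]
    anchor: str = "cox1"
    includes_cr: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        syms = [s for s, _ in self.elements]
        dupes = {s for s in syms if syms.count(s) > 1}
        if dupes:
            raise ValueError(f"duplicate symbols in gene order: {sorted(dupes)}")
        if self.elements:
            a_sym, a_strand = self.elements[0]
            if a_sym != self.anchor:
                raise ValueError(
                    f"order must start at its anchor {self.anchor!r}, got {a_sym!r}"
                )
            if a_strand != "+":
                raise ValueError("anchor must be on the plus strand after canonicalization")

    def __len__(self) -> int:
        return len(self.elements)

    def symbols(self) -> list[str]:
        return [s for s, _ in self.elements]

    def without_cr(self) -> "GeneOrder":
        if not self.includes_cr:
            return self
        return GeneOrder(
            elements=tuple(e for e in self.elements if e[0] != "CR"),
            anchor=self.anchor,
            includes_cr=False,
            name=self.name,
        )

    def restricted_to(self, symbols: set[str]) -> "GeneOrder":
        return GeneOrder(
            elements=tuple(e for e in self.elements if e[0] in symbols),
            anchor=self.anchor,
            includes_cr=self.includes_cr and "CR" in symbols,
            name=self.name,
        )


def canonicalize(elements: Sequence[SignedGene], anchor: str = "cox1",
                 name: str = "", includes_cr: Optional[bool] = None) -> GeneOrder:
    """Rotate (and if needed reflect) a signed circular list so ``anchor``
    comes first on the plus strand."""
    syms = [s for s, _ in elements]
    if anchor not in syms:
        raise ValueError(f"anchor {anchor!r} not present in order")
    i = syms.index(anchor)
    rot = list(elements[i:]) + list(elements[:i])
    if rot[0][1] == "-":
        # reading the circle from the opposite strand: reverse and flip,
        # keeping the anchor first
        rot = [_flip(rot[0])] + [_flip(e) for e in rot[:0:-1]]
    if includes_cr is None:
        includes_cr = "CR" in syms
    return GeneOrder(tuple(rot), anchor=anchor, includes_cr=includes_cr, name=name)


def extract_gene_order(a: MitoAnnotation, anchor: str = "cox1",
                       include_cr: bool = True) -> GeneOrder:
    """Read the signed gene order off an annotation, anchored at ``anchor``."""
    elements: list[SignedGene] = [
        (f.symbol, f.strand) for f in a.features if include_cr or f.symbol != "CR"
    ]
    return canonicalize(elements, anchor=anchor, name=a.organism or (a.accession or ""),
                        includes_cr=include_cr and any(s == "CR" for s, _ in elements))


# ---------------------------------------------------------------------------
# order comparison

@dataclass(frozen=True)
class RearrangementEvent:
    kind: str                      # transposition | inversion | inverse_transposition | block_move
    block: tuple[SignedGene, ...]  # moved/flipped block, in target order

    @property
    def block_symbols(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.block)


@dataclass
class RearrangementReport:
    reference: str
    target: str
    lost: set[str]
    gained: set[str]
    events: list[RearrangementEvent]
    conserved_blocks: list[tuple[SignedGene, ...]]
    breakpoint_distance: int

    @property
    def identical(self) -> bool:
        return not (self.lost or self.gained or self.events)


def _lcs_backbone(ref: Sequence[SignedGene], tgt: Sequence[SignedGene]) -> list[SignedGene]:
    """Longest common subsequence of signed elements.

    Both inputs start at the shared anchor, so the cyclic alignment is
    already resolved.  Tie-break favours keeping earlier target elements
    (standard LCS backtrack preferring matches), which is deterministic.
    """
    n, m = len(ref), len(tgt)
    # dp[i][j] = LCS length of ref[i:], tgt[j:]
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        row, nxt = dp[i], dp[i + 1]
        for j in range(m - 1, -1, -1):
            if ref[i] == tgt[j]:
                row[j] = nxt[j + 1] + 1
            else:
                row[j] = max(nxt[j], row[j + 1])
    out: list[SignedGene] = []
    i = j = 0
    while i < n and j < m:
        if ref[i] == tgt[j]:
            out.append(ref[i])
            i += 1
            j += 1
        elif dp[i + 1][j] >= dp[i][j + 1]:
            i += 1
        else:
            j += 1
    return out


def _contiguous_in(order: Sequence[SignedGene], block_syms: Sequence[str]) -> bool:
    """Is ``block_syms`` a contiguous run (circularly, either direction) of ``order``?"""
    syms = [s for s, _ in order]
    n = len(syms)
    k = len(block_syms)
    if k > n:
        return False
    doubled = syms + syms
    fwd = list(block_syms)
    rev = fwd[::-1]
    for i in range(n):
        if doubled[i:i + k] == fwd or doubled[i:i + k] == rev:
            return True
    return False


def compare_orders(ref: GeneOrder, target: GeneOrder,
                   include_cr: bool = False) -> RearrangementReport:
    """Classify the differences between two signed circular gene orders.

    The control region is excluded by default: annotation of the CR is the
    least reliable part of deposited mitogenomes, and published arrangement
    comparisons are made over the 37 genes.
    """
    if ref.anchor != target.anchor:
        raise ValueError(f"orders anchored differently: {ref.anchor!r} vs {target.anchor!r}")
    if not include_cr:
        ref = ref.without_cr()
        target = target.without_cr()

    ref_syms = set(ref.symbols())
    tgt_syms = set(target.symbols())
    lost = ref_syms - tgt_syms
    gained = tgt_syms - ref_syms
    shared = ref_syms & tgt_syms
    if not shared:
        raise ValueError("orders share no genes")

    r = ref.restricted_to(shared).elements
    t = target.restricted_to(shared).elements

    backbone = _lcs_backbone(r, t)
    backbone_set = set(backbone)

    # group off-backbone target elements into maximal runs contiguous in target
    events: list[RearrangementEvent] = []
    runs: list[list[SignedGene]] = []
    current: list[SignedGene] = []
    for e in t:
        if e in backbone_set:
            if current:
                runs.append(current)
                current = []
        else:
            current.append(e)
    if current:
        runs.append(current)

    ref_index = {s: i for i, (s, _) in enumerate(r)}
    ref_strand = {s: st for s, st in r}
    tgt_index = {s: i for i, (s, _) in enumerate(t)}

    for run in runs:
        # split the run into blocks that are also contiguous in the reference
        blocks: list[list[SignedGene]] = []
        cur = [run[0]]
        for prev, e in zip(run, run[1:]):
            i_prev, i_e = ref_index[prev[0]], ref_index[e[0]]
            if abs(i_e - i_prev) == 1 or abs(i_e - i_prev) == len(r) - 1:
                cur.append(e)
            else:
                blocks.append(cur)
                cur = [e]
        blocks.append(cur)

        for block in blocks:
            flipped = all(st != ref_strand[sym] for sym, st in block)
            same_strand = all(st == ref_strand[sym] for sym, st in block)
            # "same slot": the block's ref-order neighbours still flank it in target
            in_place = _same_neighbourhood(block, r, t)
            if flipped and in_place:
                kind = "inversion"
            elif flipped:
                kind = "inverse_transposition"
            elif same_strand and len(block) == 1:
                kind = "transposition"
            elif same_strand:
                kind = "block_move"
            else:
                kind = "inverse_transposition"  # mixed strands: complex relocation
            events.append(RearrangementEvent(kind=kind, block=tuple(block)))

    conserved: list[tuple[SignedGene, ...]] = []
    cur_block: list[SignedGene] = []
    prev_i = prev_j = None
    for e in backbone:
        i, j = ref_index[e[0]], tgt_index[e[0]]
        if cur_block and (i != prev_i + 1 or j != prev_j + 1):
            conserved.append(tuple(cur_block))
            cur_block = []
        cur_block.append(e)
        prev_i, prev_j = i, j
    if cur_block:
        conserved.append(tuple(cur_block))

    bp = breakpoint_distance(ref, target, restrict=True, include_cr=True)

    return RearrangementReport(
        reference=ref.name,
        target=target.name,
        lost=lost,
        gained=gained,
        events=events,
        conserved_blocks=conserved,
        breakpoint_distance=bp,
    )


def _same_neighbourhood(block: list[SignedGene], r: Sequence[SignedGene],
                        t: Sequence[SignedGene]) -> bool:
    """True when the block occupies the same circular slot in both orders,
    i.e. the elements flanking its symbols are identical genes (an in-place
    inversion keeps its neighbours)."""
    syms = {s for s, _ in block}

    def flanks(order: Sequence[SignedGene]) -> Optional[tuple[str, str]]:
        n = len(order)
        idx = sorted(i for i, (s, _) in enumerate(order) if s in syms)
        if len(idx) != len(syms) or len(idx) == n:
            return None
        # a circular arc has exactly one non-unit gap among the cyclic
        # differences of its sorted member indices
        diffs = [b - a for a, b in zip(idx, idx[1:])] + [idx[0] + n - idx[-1]]
        gaps = [k for k, d in enumerate(diffs) if d != 1]
        if len(gaps) != 1:
            return None
        end_i = idx[gaps[0]]
        start_i = idx[(gaps[0] + 1) % len(idx)]
        return order[(start_i - 1) % n][0], order[(end_i + 1) % n][0]

    fr, ft = flanks(r), flanks(t)
    return fr is not None and ft is not None and fr == ft


# ---------------------------------------------------------------------------
# breakpoint distance

def _adjacencies(order: GeneOrder) -> set[frozenset]:
    """Signed circular adjacencies, orientation-insensitive: the adjacency
    a->b equals -b->-a read from the other strand."""
    elems = order.elements
    n = len(elems)
    adj = set()
    for i in range(n):
        a, b = elems[i], elems[(i + 1) % n]
        adj.add(frozenset({(a, b), (_flip(b), _flip(a))}))
    return adj


def breakpoint_distance(ref: GeneOrder, target: GeneOrder, *,
                        restrict: bool = False, include_cr: bool = True) -> int:
    """Number of signed adjacencies of ``ref`` absent from ``target``.

    With ``restrict=True`` both orders are first restricted to their shared
    genes (required when the gene complements differ).  Zero iff the two
    circular signed orders are identical up to rotation.  Note the statistic
    is not guaranteed to satisfy the triangle inequality once restricted to
    differing gene sets.
    """
    if not include_cr:
        ref, target = ref.without_cr(), target.without_cr()
    shared = set(ref.symbols()) & set(target.symbols())
    if not shared:
        raise ValueError("orders share no genes")
    if set(ref.symbols()) != set(target.symbols()):
        if not restrict:
            raise ValueError("gene sets differ; pass restrict=True to compare the intersection")
        ref = ref.restricted_to(shared)
        target = target.restricted_to(shared)
    return len(_adjacencies(ref) - _adjacencies(target))


def order_distance_matrix(orders: Sequence[GeneOrder], *,
                          include_cr: bool = False):
    """Symmetric breakpoint-distance matrix over named orders.

    Returns ``(names, matrix)`` where matrix is a list of lists of ints.
    """
    import itertools

    names = [o.name or f"order{i}" for i, o in enumerate(orders)]
    if len(names) != len(set(names)):
        raise ValueError("duplicate order names")
    if len(orders) < 2:
        raise ValueError("need at least two orders")
    n = len(orders)
    mat = [[0] * n for _ in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        d = breakpoint_distance(orders[i], orders[j], restrict=True,
                                include_cr=include_cr)
        mat[i][j] = mat[j][i] = d
    return names, mat


# ---------------------------------------------------------------------------
# text format

def parse_order_string(text: str, name: str = "", anchor: str = "cox1") -> GeneOrder:
    """Parse ``"cox1, trnL2, -trnF, ..."`` into a canonical GeneOrder."""
    elements: list[SignedGene] = []
    for tok in text.replace(" ", "").split(","):
        if not tok:
            continue
        if tok.startswith("-"):
            elements.append((tok[1:], "-"))
        else:
            elements.append((tok.lstrip("+"), "+"))
    return canonicalize(elements, anchor=anchor, name=name)


def format_order_string(order: GeneOrder) -> str:
    return ",".join(("-" if st == "-" else "") + s for s, st in order.elements)
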