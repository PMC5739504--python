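"""Cloverleaf structure model for mitochondrial tRNA genes.

Each of the 22 human mt-tRNAs folds into the canonical cloverleaf: an
acceptor stem, a D arm (stem + loop), an anticodon arm carrying the
anticodon triplet, a variable region, and a TpsiC arm, closed by the 3'
half of the acceptor stem and a discriminator base.  This module turns a
flat annotation table (one row per cloverleaf element, mtDNA coordinates)
plus the reference sequence into :class:`TRNAGene` objects, resolves
arbitrary mtDNA positions to tRNA-internal loci (:func:`locate`), and
builds the *generic* cross-tRNA coordinate system (:func:`align_generic`)
in which structurally analogous positions of different tRNAs share a slot.

The generic alignment is anchored on the four stems and on the anticodon
triplet itself.  Loop and variable-region positions, which the anchors do
not constrain, are aligned from each loop end toward the middle (5' ties
first), so loops of different length share their end-proximal slots and
longer loops own extra central slots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "ELEMENT_ORDER",
    "STEM_PARTNER",
    "STEM_KINDS",
    "LOOP_KINDS",
    "AnnotationError",
    "AlignmentError",
    "NotATRNAPositionError",
    "CloverleafElement",
    "TRNAGene",
    "TRNALocus",
    "GenericSlot",
    "parse_annotation",
    "locate",
    "align_generic",
    "slot_map_table",
    "load_reference",
]

# Canonical 5'->3' order of cloverleaf elements on the tRNA sense strand.
ELEMENT_ORDER = (
    "acceptor_stem_5p",
    "d_stem_5p",
    "d_loop",
    "d_stem_3p",
    "anticodon_stem_5p",
    "anticodon_loop",
    "anticodon_stem_3p",
    "variable_loop",
    "t_stem_5p",
    "t_loop",
    "t_stem_3p",
    "acceptor_stem_3p",
    "discriminator",
)

STEM_PARTNER = {
    "acceptor_stem_5p": "acceptor_stem_3p",
    "acceptor_stem_3p": "acceptor_stem_5p",
    "d_stem_5p": "d_stem_3p",
    "d_stem_3p": "d_stem_5p",
    "anticodon_stem_5p": "anticodon_stem_3p",
    "anticodon_stem_3p": "anticodon_stem_5p",
    "t_stem_5p": "t_stem_3p",
    "t_stem_3p": "t_stem_5p",
}
STEM_KINDS = frozenset(STEM_PARTNER)
LOOP_KINDS = frozenset({"d_loop", "anticodon_loop", "variable_loop", "t_loop"})

# Stems every gene must carry for the cross-tRNA alignment.
REQUIRED_STEMS = (
    "acceptor_stem_5p",
    "d_stem_5p",
    "anticodon_stem_5p",
    "t_stem_5p",
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class AnnotationError(ValueError):
    """Malformed cloverleaf annotation (bad tiling, unequal stem halves...)."""


class AlignmentError(ValueError):
    """A gene cannot participate in the generic alignment."""


class NotATRNAPositionError(KeyError):
    """The queried mtDNA coordinate is not inside any annotated tRNA."""


@dataclass(frozen=True)
class CloverleafElement:
    """One element of the cloverleaf: a stem half, a loop, or the discriminator."""

    kind: str
    length: int

    @property
    def pair_partner(self) -> str | None:
        return STEM_PARTNER.get(self.kind)

    @property
    def is_stem(self) -> bool:
        return self.kind in STEM_KINDS


@dataclass
class TRNAGene:
    """A mitochondrial tRNA gene with strand, coordinates and cloverleaf annotation.

    ``start``/``end`` are 1-based inclusive mtDNA coordinates; ``sequence``
    is the tRNA-sense sequence 5'->3' (reverse complement of the reference
    slice for light-strand genes).  tRNA-internal indices (``index_5p``)
    are 0-based along that sense sequence.
    """

    name: str
    strand: str  # "+" (heavy) or "-" (light)
    start: int
    end: int
    elements: list[CloverleafElement]
    sequence: str
    _offsets: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.name}: strand must be '+' or '-'")
        total = sum(e.length for e in self.elements)
        if total != self.end - self.start + 1:
            raise AnnotationError(
                f"{self.name}: elements sum to {total} nt but gene spans "
                f"{self.end - self.start + 1} nt"
            )
        if len(self.sequence) != total:
            raise AnnotationError(f"{self.name}: sequence length mismatch")
        kinds = [e.kind for e in self.elements]
        if len(set(kinds)) != len(kinds):
            raise AnnotationError(f"{self.name}: duplicated element kind")
        order = [ELEMENT_ORDER.index(k) for k in kinds]
        if order != sorted(order):
            raise AnnotationError(f"{self.name}: elements out of 5'->3' order")
        for e in self.elements:
            partner = e.pair_partner
            if partner is not None:
                other = self.element(partner)
                if other is None:
                    raise AnnotationError(
                        f"{self.name}: stem half {e.kind} lacks partner {partner}"
                    )
                if other.length != e.length:
                    raise AnnotationError(
                        f"{self.name}: stem halves {e.kind}/{partner} have "
                        f"unequal lengths {e.length}/{other.length}"
                    )
        ac = self.element("anticodon_loop")
        if ac is not None and ac.length < 3:
            raise AnnotationError(f"{self.name}: anticodon loop shorter than 3 nt")
        off = 0
        for e in self.elements:
            self._offsets[e.kind] = off
            off += e.length

    # -- basic geometry -------------------------------------------------

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def element(self, kind: str) -> CloverleafElement | None:
        for e in self.elements:
            if e.kind == kind:
                return e
        return None

    def element_offset(self, kind: str) -> int:
        return self._offsets[kind]

    def mtdna_position(self, index_5p: int) -> int:
        """Project a tRNA-internal index back to the 1-based mtDNA coordinate."""
        if not 0 <= index_5p < self.length:
            raise IndexError(index_5p)
        if self.strand == "+":
            return self.start + index_5p
        return self.end - index_5p

    def index_of(self, mtdna_position: int) -> int:
        if not self.start <= mtdna_position <= self.end:
            raise NotATRNAPositionError(mtdna_position)
        if self.strand == "+":
            return mtdna_position - self.start
        return self.end - mtdna_position

    @property
    def anticodon_offset(self) -> int | None:
        """tRNA index of the first anticodon base (triplet centred in the loop)."""
        ac = self.element("anticodon_loop")
        if ac is None:
            return None
        return self._offsets["anticodon_loop"] + (ac.length - 3) // 2

    def locus(self, index_5p: int) -> "TRNALocus":
        if not 0 <= index_5p < self.length:
            raise NotATRNAPositionError(index_5p)
        for e in self.elements:
            off = self._offsets[e.kind]
            if off <= index_5p < off + e.length:
                within = index_5p - off
                paired = e.is_stem
                partner_index: int | None = None
                if paired:
                    partner_kind = e.pair_partner
                    assert partner_kind is not None
                    partner_off = self._offsets[partner_kind]
                    partner_index = partner_off + (e.length - 1 - within)
                is_ac = False
                ac_off = self.anticodon_offset
                if ac_off is not None and ac_off <= index_5p < ac_off + 3:
                    is_ac = True
                return TRNALocus(
                    gene=self,
                    index_5p=index_5p,
                    element=e,
                    within_element_index=within,
                    paired=paired,
                    partner_index_5p=partner_index,
                    is_anticodon=is_ac,
                    mtdna_position=self.mtdna_position(index_5p),
                )
        raise AssertionError("unreachable: elements tile the gene")


@dataclass
class TRNALocus:
    """A single position within one tRNA, with pairing and element context."""

    gene: TRNAGene
    index_5p: int
    element: CloverleafElement
    within_element_index: int
    paired: bool
    partner_index_5p: int | None
    is_anticodon: bool
    mtdna_position: int

    @property
    def partner(self) -> "TRNALocus | None":
        if self.partner_index_5p is None:
            return None
        return self.gene.locus(self.partner_index_5p)

    @property
    def stem_pair_index(self) -> int | None:
        """Index of this base pair along the stem, 0 at the stem's outer end.

        Both halves of a pair share the same pair index, so the quadratic
        end-of-stem weighting is symmetric across the two strands.
        """
        if not self.paired:
            return None
        if self.element.kind.endswith("_5p"):
            return self.within_element_index
        return self.element.length - 1 - self.within_element_index


@dataclass(frozen=True)
class GenericSlot:
    """One position of the generic (cross-tRNA) cloverleaf coordinate system.

    ``within_element_index`` is signed for loops: non-negative indices count
    from the 5' end of the element, negative indices from the 3' end (-1 is
    the 3'-most position), which is what makes end-anchored alignment of
    loops of different lengths well defined.
    """

    element_kind: str
    within_element_index: int
    anchor_class: str  # "stem" | "anticodon" | "loop"

    @property
    def slot_id(self) -> str:
        return f"{self.element_kind}:{self.within_element_index:+d}"


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def load_reference(source) -> str:
    """Read a single-record FASTA (path or handle) into an uppercase string."""
    records = list(SeqIO.parse(source, "fasta"))
    if len(records) != 1:
        raise AnnotationError(f"expected exactly one reference record, got {len(records)}")
    return str(records[0].seq).upper()


def parse_annotation(annotation, reference) -> list[TRNAGene]:
    """Build :class:`TRNAGene` objects from an element table and a reference.

    Parameters
    ----------
    annotation
        Path to a tab-separated table with columns ``gene``, ``strand``
        (+/-), ``start``, ``end`` (1-based inclusive mtDNA coordinates of
        the element), ``element`` — one row per cloverleaf element, rows of
        a gene in 5'->3' tRNA order — or an equivalent DataFrame.
    reference
        Reference sequence as a plain string, or a FASTA path/handle.

    Light-strand genes come back with their tRNA-sense sequence (reverse
    complement of the reference slice); heavy-strand genes with the forward
    slice.
    """
    if isinstance(annotation, pd.DataFrame):
        table = annotation.copy()
    else:
        table = pd.read_csv(annotation, sep="\t", dtype={"gene": str})
    required = {"gene", "strand", "start", "end", "element"}
    if not required.issubset(table.columns):
        raise AnnotationError(f"annotation must have columns {sorted(required)}")
    if not (isinstance(reference, str) and set(reference.upper()) <= set("ACGTN")):
        reference = load_reference(reference)
    reference = reference.upper()
    ref_len = len(reference)

    genes: list[TRNAGene] = []
    for name, rows in table.groupby("gene", sort=False):
        strands = set(rows["strand"])
        if len(strands) != 1 or not strands.issubset({"+", "-"}):
            raise AnnotationError(f"{name}: inconsistent or invalid strand")
        strand = strands.pop()
        starts = rows["start"].astype(int).to_list()
        ends = rows["end"].astype(int).to_list()
        kinds = rows["element"].to_list()
        for k in kinds:
            if k not in ELEMENT_ORDER:
                raise AnnotationError(f"{name}: unknown element kind {k!r}")
        for s, e in zip(starts, ends):
            if not (1 <= s <= e <= ref_len):
                raise AnnotationError(f"{name}: element [{s},{e}] outside reference")
        # Elements must tile the gene contiguously in tRNA 5'->3' order.
        for i in range(1, len(starts)):
            if strand == "+":
                if starts[i] != ends[i - 1] + 1:
                    raise AnnotationError(f"{name}: elements do not tile contiguously")
            else:
                if ends[i] != starts[i - 1] - 1:
                    raise AnnotationError(f"{name}: elements do not tile contiguously")
        gstart, gend = min(starts), max(ends)
        if sum(e - s + 1 for s, e in zip(starts, ends)) != gend - gstart + 1:
            raise AnnotationError(f"{name}: elements do not tile the gene exactly")
        elements = [
            CloverleafElement(kind=k, length=e - s + 1)
            for k, s, e in zip(kinds, starts, ends)
        ]
        ref_slice = reference[gstart - 1 : gend]
        sense = ref_slice if strand == "+" else str(Seq(ref_slice).reverse_complement())
        genes.append(
            TRNAGene(
                name=str(name),
                strand=strand,
                start=gstart,
                end=gend,
                elements=elements,
                sequence=sense,
            )
        )
    _check_no_overlap(genes)
    return genes


def _check_no_overlap(genes: Iterable[TRNAGene]) -> None:
    spans = sorted((g.start, g.end, g.name) for g in genes)
    for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise AnnotationError(f"genes {n1} and {n2} overlap on the mtDNA")


# ---------------------------------------------------------------------------
# Locating mtDNA positions
# ---------------------------------------------------------------------------

def locate(genes: Iterable[TRNAGene], mtdna_position: int) -> TRNALocus:
    """Resolve a 1-based mtDNA coordinate to a tRNA-internal locus.

    Raises :class:`NotATRNAPositionError` if the coordinate is not inside
    any annotated tRNA.
    """
    for gene in genes:
        if gene.start <= mtdna_position <= gene.end:
            return gene.locus(gene.index_of(mtdna_position))
    raise NotATRNAPositionError(
        f"position {mtdna_position} is not inside any annotated tRNA"
    )


# ---------------------------------------------------------------------------
# Generic cross-tRNA alignment
# ---------------------------------------------------------------------------

def _loop_slot_indices(n: int) -> list[int]:
    """End-anchored signed slot indices for a loop of length ``n``.

    Positions are claimed alternately from the two loop ends moving inward,
    5' first: position i gets slot i while i < ceil(n/2), and slot i - n
    (negative, counted from the 3' end) otherwise.  Loops of different
    lengths therefore share all their end-proximal slots and a longer loop
    alone owns the extra central ones.
    """
    head = (n + 1) // 2
    return [i if i < head else i - n for i in range(n)]


def align_generic(
    genes: Iterable[TRNAGene],
) -> dict[tuple[str, int], GenericSlot]:
    """Map every (gene name, tRNA index) to its :class:`GenericSlot`.

    Stems align by (stem kind, within-stem index); the anticodon triplet
    aligns position-by-position in its own anchored slots; loop flanks and
    free loops align end-toward-middle.  The map is total over all tRNA
    positions of all genes.
    """
    genes = list(genes)
    for g in genes:
        for stem in REQUIRED_STEMS:
            if g.element(stem) is None:
                raise AlignmentError(f"{g.name}: missing {stem} annotation")
    slot_map: dict[tuple[str, int], GenericSlot] = {}
    for g in genes:
        ac_off = g.anticodon_offset
        for e in g.elements:
            off = g.element_offset(e.kind)
            if e.is_stem:
                for i in range(e.length):
                    slot_map[(g.name, off + i)] = GenericSlot(e.kind, i, "stem")
            elif e.kind == "anticodon_loop":
                assert ac_off is not None
                a = ac_off - off  # 5' flank length
                for i in range(e.length):
                    idx = off + i
                    if a <= i < a + 3:
                        slot = GenericSlot("anticodon", i - a, "anticodon")
                    elif i < a:
                        slot = GenericSlot(e.kind, i, "loop")
                    else:
                        slot = GenericSlot(e.kind, i - e.length, "loop")
                    slot_map[(g.name, idx)] = slot
            elif e.kind == "discriminator":
                slot_map[(g.name, off)] = GenericSlot(e.kind, 0, "loop")
            else:
                for i, s in enumerate(_loop_slot_indices(e.length)):
                    slot_map[(g.name, off + i)] = GenericSlot(e.kind, s, "loop")
    return slot_map


def slot_map_table(genes: Iterable[TRNAGene], slot_map=None) -> pd.DataFrame:
    """Tabular export of the generic alignment, one row per tRNA position."""
    genes = list(genes)
    if slot_map is None:
        slot_map = align_generic(genes)
    rows = []
    for g in genes:
        for i in range(g.length):
            slot = slot_map[(g.name, i)]
            rows.append(
                {
                    "gene": g.name,
                    "mtdna_position": g.mtdna_position(i),
                    "trna_index": i,
                    "element": g.locus(i).element.kind,
                    "within_element_index": g.locus(i).within_element_index,
                    "generic_slot": slot.slot_id,
                }
            )
    return pd.DataFrame(rows).sort_values("mtdna_position", ignore_index=True)
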