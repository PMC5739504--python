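"""Readers and writers for the variant-evidence tables.

Three tables feed the scoring system: per-variant population evidence
(GenBank-style observation counts plus curated pathogenicity reports with
heteroplasmy and confirmation flags), a per-position cross-species
conservation panel (base counts over a fixed species set, emulating a
Mamit-tRNA Euarchontoglires alignment), and an optional haplogroup
association table used only for display suppression.  All files are plain
tab-separated text; variants are given in reference-strand (rCRS-style)
coordinates with ``del`` as the single-base deletion token.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .structure import TRNAGene

__all__ = [
    "BASES",
    "DELETION",
    "ValidationError",
    "Variant",
    "PathReport",
    "VariantEvidence",
    "ConservationColumn",
    "read_evidence",
    "write_evidence",
    "read_conservation",
    "write_conservation",
    "read_haplogroups",
    "novel_evidence",
]

BASES = ("A", "C", "G", "T")
DELETION = "del"

EVIDENCE_COLUMNS = [
    "position",
    "ref",
    "alt",
    "genbank_count",
    "total_sequences",
    "n_reports_het_confirmed",
    "n_reports_het_unconfirmed",
    "n_reports_hom_confirmed",
    "n_reports_hom_unconfirmed",
]

CONSERVATION_COLUMNS = [
    "gene",
    "trna_index",
    "count_A",
    "count_C",
    "count_G",
    "count_T",
    "n_species",
]


class ValidationError(ValueError):
    """An input table violates its schema or an internal consistency rule."""


@dataclass(frozen=True, order=True)
class Variant:
    """A single-base substitution or deletion in reference-strand coordinates."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in BASES:
            raise ValidationError(f"invalid ref base {self.ref!r}")
        if self.alt not in BASES + (DELETION,):
            raise ValidationError(f"invalid alt allele {self.alt!r}")
        if self.alt == self.ref:
            raise ValidationError(f"alt equals ref at position {self.position}")

    @property
    def is_deletion(self) -> bool:
        return self.alt == DELETION

    def __str__(self) -> str:  # m.5628T>C style
        if self.is_deletion:
            return f"m.{self.position}{self.ref}del"
        return f"m.{self.position}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class PathReport:
    """One curated pathogenicity report.

    ``confirmed`` means single-fiber or cybrid confirmation; the curation
    itself happens upstream and arrives here as a boolean.
    """

    heteroplasmic: bool
    confirmed: bool


@dataclass
class VariantEvidence:
    """Population counts and pathogenicity reports for one variant."""

    variant: Variant
    genbank_count: int = 0
    total_sequences: int = 0
    reports: tuple[PathReport, ...] = ()
    haplogroup_frequencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genbank_count < 0:
            raise ValidationError(f"{self.variant}: negative genbank_count")
        if self.total_sequences and self.genbank_count > self.total_sequences:
            raise ValidationError(
                f"{self.variant}: genbank_count exceeds total_sequences"
            )
        for frac in self.haplogroup_frequencies.values():
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"{self.variant}: haplogroup fraction not in [0,1]")


def novel_evidence(variant: Variant) -> VariantEvidence:
    """Canonical evidence object for a variant never seen before (count 0, no reports)."""
    return VariantEvidence(variant=variant)


@dataclass
class ConservationColumn:
    """Cross-species base counts at one tRNA position (gaps allowed)."""

    gene: str
    index_5p: int
    base_counts: dict[str, int]
    n_species: int
    is_gap_fill: bool = False

    def __post_init__(self) -> None:
        if self.n_species <= 0:
            raise ValidationError(f"{self.gene}:{self.index_5p}: n_species must be > 0")
        if any(c < 0 for c in self.base_counts.values()):
            raise ValidationError(f"{self.gene}:{self.index_5p}: negative count")
        if sum(self.base_counts.values()) > self.n_species:
            raise ValidationError(
                f"{self.gene}:{self.index_5p}: base counts exceed panel size"
            )


# ---------------------------------------------------------------------------
# Evidence table
# ---------------------------------------------------------------------------

def _reports_from_counts(het_conf, het_unconf, hom_conf, hom_unconf) -> tuple[PathReport, ...]:
    reports: list[PathReport] = []
    reports += [PathReport(True, True)] * int(het_conf)
    reports += [PathReport(True, False)] * int(het_unconf)
    reports += [PathReport(False, True)] * int(hom_conf)
    reports += [PathReport(False, False)] * int(hom_unconf)
    return tuple(reports)


def read_evidence(path, reference: str | None = None) -> dict[Variant, VariantEvidence]:
    """Read the variant-evidence TSV into a map ``Variant -> VariantEvidence``.

    If ``reference`` (plain sequence string) is given, each row's ref base is
    checked against it.  Duplicate variant rows and ref mismatches raise
    :class:`ValidationError`.  Variants absent from the table are meant to be
    handled downstream via :func:`novel_evidence`, never as an error.
    """
    table = pd.read_csv(path, sep="\t")
    missing = set(EVIDENCE_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"evidence table missing columns {sorted(missing)}")
    out: dict[Variant, VariantEvidence] = {}
    for row in table.itertuples(index=False):
        variant = Variant(int(row.position), str(row.ref), str(row.alt))
        if variant in out:
            raise ValidationError(f"duplicate evidence row for {variant}")
        if reference is not None and reference[variant.position - 1] != variant.ref:
            raise ValidationError(
                f"{variant}: ref {variant.ref} does not match reference "
                f"{reference[variant.position - 1]} at position {variant.position}"
            )
        out[variant] = VariantEvidence(
            variant=variant,
            genbank_count=int(row.genbank_count),
            total_sequences=int(row.total_sequences),
            reports=_reports_from_counts(
                row.n_reports_het_confirmed,
                row.n_reports_het_unconfirmed,
                row.n_reports_hom_confirmed,
                row.n_reports_hom_unconfirmed,
            ),
        )
    return out


def write_evidence(evidence: Mapping[Variant, VariantEvidence], path) -> None:
    rows = []
    for variant in sorted(evidence):
        ev = evidence[variant]
        reports = list(ev.reports)
        rows.append(
            {
                "position": variant.position,
                "ref": variant.ref,
                "alt": variant.alt,
                "genbank_count": ev.genbank_count,
                "total_sequences": ev.total_sequences,
                "n_reports_het_confirmed": sum(
                    1 for r in reports if r.heteroplasmic and r.confirmed
                ),
                "n_reports_het_unconfirmed": sum(
                    1 for r in reports if r.heteroplasmic and not r.confirmed
                ),
                "n_reports_hom_confirmed": sum(
                    1 for r in reports if not r.heteroplasmic and r.confirmed
                ),
                "n_reports_hom_unconfirmed": sum(
                    1 for r in reports if not r.heteroplasmic and not r.confirmed
                ),
            }
        )
    pd.DataFrame(rows, columns=EVIDENCE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Conservation table
# ---------------------------------------------------------------------------

def read_conservation(
    path, genes: Iterable[TRNAGene] | None = None
) -> dict[tuple[str, int], ConservationColumn]:
    """Read the conservation TSV into a map ``(gene, trna_index) -> column``.

    When ``genes`` is supplied, every annotated tRNA position is guaranteed
    a column: positions missing from the file are filled with an all-gap
    column (zero counts) flagged ``is_gap_fill`` rather than erroring.
    """
    table = pd.read_csv(path, sep="\t")
    missing = set(CONSERVATION_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"conservation table missing columns {sorted(missing)}")
    out: dict[tuple[str, int], ConservationColumn] = {}
    for row in table.itertuples(index=False):
        key = (str(row.gene), int(row.trna_index))
        if key in out:
            raise ValidationError(f"duplicate conservation row for {key}")
        out[key] = ConservationColumn(
            gene=key[0],
            index_5p=key[1],
            base_counts={
                "A": int(row.count_A),
                "C": int(row.count_C),
                "G": int(row.count_G),
                "T": int(row.count_T),
            },
            n_species=int(row.n_species),
        )
    if genes is not None:
        panel = max((c.n_species for c in out.values()), default=1)
        for g in genes:
            for i in range(g.length):
                if (g.name, i) not in out:
                    out[(g.name, i)] = ConservationColumn(
                        gene=g.name,
                        index_5p=i,
                        base_counts={b: 0 for b in BASES},
                        n_species=panel,
                        is_gap_fill=True,
                    )
    return out


def write_conservation(
    columns: Mapping[tuple[str, int], ConservationColumn], path
) -> None:
    rows = []
    for key in sorted(columns):
        col = columns[key]
        rows.append(
            {
                "gene": col.gene,
                "trna_index": col.index_5p,
                "count_A": col.base_counts.get("A", 0),
                "count_C": col.base_counts.get("C", 0),
                "count_G": col.base_counts.get("G", 0),
                "count_T": col.base_counts.get("T", 0),
                "n_species": col.n_species,
            }
        )
    pd.DataFrame(rows, columns=CONSERVATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Haplogroup table
# ---------------------------------------------------------------------------

def read_haplogroups(path) -> dict[Variant, dict[str, float]]:
    """Read the optional haplogroup TSV: columns position, ref, alt, haplogroup, fraction."""
    table = pd.read_csv(path, sep="\t")
    required = {"position", "ref", "alt", "haplogroup", "fraction"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"haplogroup table missing columns {sorted(missing)}")
    out: dict[Variant, dict[str, float]] = {}
    for row in table.itertuples(index=False):
        variant = Variant(int(row.position), str(row.ref), str(row.alt))
        frac = float(row.fraction)
        if not 0.0 <= frac <= 1.0:
            raise ValidationError(f"{variant}: haplogroup fraction {frac} not in [0,1]")
        out.setdefault(variant, {})[str(row.haplogroup)] = frac
    return out


def attach_haplogroups(
    evidence: Mapping[Variant, VariantEvidence],
    haplogroups: Mapping[Variant, Mapping[str, float]],
) -> None:
    """Fold haplogroup fractions into matching evidence entries in place."""
    for variant, fracs in haplogroups.items():
        if variant in evidence:
            evidence[variant].haplogroup_frequencies.update(fracs)
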