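"""The pathogenicity score: variant history & conservation, position, structure.

The total score of a candidate variant is an additive combination of three
sub-scores, each scaled by its own weight:

``total = var_hx_cons_scal * vhc + Pos_scal * position + SS_scal * structure``

*Variant history and conservation (vhc)* combines three ingredients
through a decision tree: a population-frequency percentile score for
observed benign variants (``pop``), a report-stratum score for variants
with pathogenicity reports (``path``, heteroplasmic/confirmed reports
weighing most), and a logarithmic cross-species conservation score
(``cons``) that treats absence of the alternate base from the species
panel as evidence of constraint.  Variants never observed in the
population receive a flat novelty base score instead of a history term.

*Position score* transfers evidence between structurally analogous
positions: it averages per-position vhc summaries over all tRNA positions
sharing a generic-alignment slot.

*Secondary-structure score* penalizes stem variants for the steric class
of the base pair they create, weighted by a quadratic along the stem that
is maximal at the stem ends and floors at the center.  Substitutions that
improve pairing (e.g. a G.U wobble restored to G:C) score negative.

All tunable constants below are deliberately grouped in one block so the
whole scheme can be re-tuned in one place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import percentileofscore

from .evidence import (
    BASES,
    DELETION,
    ConservationColumn,
    PathReport,
    Variant,
    VariantEvidence,
    novel_evidence,
)
from .structure import GenericSlot, TRNAGene, TRNALocus, align_generic

__all__ = [
    "ScalingFactors",
    "ScoreBreakdown",
    "ConfigurationError",
    "DegenerateStemError",
    "pop_score",
    "path_score",
    "cons_score",
    "variant_history_and_conservation",
    "position_score",
    "secondary_structure_score",
    "total_score",
    "score_all",
    "ScoringModel",
    "benign_count_distribution",
    "pair_steric_class",
    "quadratic_weight",
    "read_factors",
    "write_factors",
]

# ---------------------------------------------------------------------------
# Tunable scoring constants (single block by design)
# ---------------------------------------------------------------------------

#: Report stratum weights keyed by (heteroplasmic, confirmed); a confirmed
#: heteroplasmic report is the strongest evidence of pathogenicity.
PATH_STRATUM_WEIGHTS: dict[tuple[bool, bool], float] = {
    (True, True): 1.0,
    (False, True): 0.8,
    (True, False): 0.6,
    (False, False): 0.4,
}

#: Steric classes of a stem base pair, ordered by disruption.
STERIC_WATSON_CRICK = 0
STERIC_WOBBLE = 1
STERIC_PYR_PYR = 2
STERIC_OTHER_MISMATCH = 3
STERIC_PUR_PUR = 4
STERIC_DELETION = 4  # a deletion breaks the pairing register entirely

#: Quadratic end-of-stem weight floors at this value at the stem center.
QUADRATIC_FLOOR = 0.25

_WATSON_CRICK_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "T"), ("T", "G")}
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Deterministic allele ordering used by score_all rows: substitutions
#: alphabetically, then the deletion.
def _alt_order(ref: str) -> list[str]:
    return [b for b in BASES if b != ref] + [DELETION]


class ConfigurationError(ValueError):
    """A scoring input (distribution, panel) is unusable."""


class DegenerateStemError(ValueError):
    """A stem of length 1 has no defined end-of-stem geometry."""


# ---------------------------------------------------------------------------
# Scaling factors
# ---------------------------------------------------------------------------

FACTOR_NAMES = (
    "var_hx_scal",
    "cons_scal",
    "var_hx_cons_scal",
    "SS_scal",
    "Pos_scal",
    "base_scal",
)


@dataclass(frozen=True)
class ScalingFactors:
    """The six named weights of the scoring system.

    ``var_hx_scal`` and ``cons_scal`` set the relative weight of variant
    history versus interspecies conservation inside the vhc sub-score;
    ``var_hx_cons_scal``, ``Pos_scal`` and ``SS_scal`` weigh the three
    sub-scores in the total; ``base_scal`` is the flat novelty score given
    to variants with no population history.
    """

    var_hx_scal: float
    cons_scal: float
    var_hx_cons_scal: float
    SS_scal: float
    Pos_scal: float
    base_scal: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ConfigurationError(f"{f.name} must be finite, got {v}")
        for name in ("var_hx_cons_scal", "SS_scal", "Pos_scal"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    @classmethod
    def unit(cls) -> "ScalingFactors":
        return cls(1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "ScalingFactors":
        return cls(**dict(zip(FACTOR_NAMES, map(float, values))))

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FACTOR_NAMES], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in FACTOR_NAMES}


def read_factors(path) -> ScalingFactors:
    """Read a two-column (name, value) factors TSV."""
    table = pd.read_csv(path, sep="\t")
    mapping = dict(zip(table.iloc[:, 0], table.iloc[:, 1]))
    missing = set(FACTOR_NAMES) - set(mapping)
    if missing:
        raise ConfigurationError(f"factors file missing {sorted(missing)}")
    return ScalingFactors(**{n: float(mapping[n]) for n in FACTOR_NAMES})


def write_factors(factors: ScalingFactors, path) -> None:
    pd.DataFrame(
        {"factor": FACTOR_NAMES, "value": [getattr(factors, n) for n in FACTOR_NAMES]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sub-scores
# ---------------------------------------------------------------------------

def benign_count_distribution(
    evidence: Mapping[Variant, VariantEvidence]
) -> np.ndarray:
    """Sorted GenBank counts of observed, report-free variants.

    This is the reference distribution against which an observed variant's
    population frequency is percentile-ranked; variants with pathogenicity
    reports are excluded because their counts do not describe the benign
    background.
    """
    counts = sorted(
        ev.genbank_count
        for ev in evidence.values()
        if ev.genbank_count >= 1 and not ev.reports
    )
    return np.asarray(counts, dtype=float)


def pop_score(evidence: VariantEvidence | int, benign_distribution) -> float:
    """Population-frequency score in [0, 1]; commoner variants score lower.

    The variant's GenBank count is percentile-ranked (fraction of the
    benign count distribution strictly below it) and the score is
    ``1 - percentile/100``, so a count above the whole distribution scores
    0 and a count below every entry scores 1.  Monotone non-increasing in
    the count.  Only defined for observed variants (count >= 1).
    """
    count = evidence if isinstance(evidence, (int, np.integer)) else evidence.genbank_count
    dist = np.asarray(benign_distribution, dtype=float)
    if dist.size == 0:
        raise ConfigurationError("empty benign frequency distribution")
    if count < 1:
        raise ConfigurationError("pop_score undefined for unobserved variants")
    pct = percentileofscore(dist, count, kind="strict")
    return 1.0 - pct / 100.0


def path_score(reports: Iterable[PathReport]) -> float:
    """Pathogenicity-report score: max stratum weight, 0 with no reports."""
    weights = [
        PATH_STRATUM_WEIGHTS[(r.heteroplasmic, r.confirmed)] for r in reports
    ]
    return max(weights, default=0.0)


def cons_score(column: ConservationColumn, alt: str) -> float:
    """Conservation score 1 - log(1+k)/log(1+N) for alt seen in k of N species.

    ``alt`` is the tRNA-sense alternate base; deletions and unseen bases
    have k = 0 and score 1 (absence from the panel read as constraint),
    while an alternate carried by the whole panel scores 0.  Strictly
    decreasing in k.
    """
    if column.n_species <= 0:
        raise ConfigurationError("conservation panel size must be positive")
    k = 0 if alt == DELETION else column.base_counts.get(alt, 0)
    return 1.0 - math.log1p(k) / math.log1p(column.n_species)


@dataclass(frozen=True)
class VhcParts:
    """vhc decision-tree output plus the sub-scores that fed it."""

    pop: float  # NaN when the population branch was not taken
    path: float
    cons: float
    value: float
    branch: int  # 1 reported, 2 observed benign, 3 novel


def _vhc_parts(
    evidence: VariantEvidence,
    column: ConservationColumn,
    factors: ScalingFactors,
    benign_distribution,
    alt: str,
) -> VhcParts:
    cons = cons_score(column, alt)
    if evidence.reports:
        p = path_score(evidence.reports)
        return VhcParts(
            pop=float("nan"),
            path=p,
            cons=cons,
            value=factors.var_hx_scal * p + factors.cons_scal * cons,
            branch=1,
        )
    if evidence.genbank_count >= 1:
        pop = pop_score(evidence, benign_distribution)
        # Common benign variants are rewarded: the history term is minus
        # the frequency deficit (1 - pop), most negative at the mode.
        return VhcParts(
            pop=pop,
            path=0.0,
            cons=cons,
            value=factors.var_hx_scal * (-(1.0 - pop)) + factors.cons_scal * cons,
            branch=2,
        )
    return VhcParts(
        pop=float("nan"),
        path=0.0,
        cons=cons,
        value=factors.base_scal + factors.cons_scal * cons,
        branch=3,
    )


def variant_history_and_conservation(
    evidence: VariantEvidence,
    column: ConservationColumn,
    factors: ScalingFactors,
    benign_distribution,
    alt: str | None = None,
) -> float:
    """Decision-tree combination of pop/path/cons into the vhc score.

    Branch 1 (any pathogenicity report): ``var_hx_scal*path + cons_scal*cons``.
    Branch 2 (observed, report-free): ``-var_hx_scal*(1-pop) + cons_scal*cons``.
    Branch 3 (novel): ``base_scal + cons_scal*cons``.

    ``alt`` is the tRNA-sense alternate allele; defaults to the variant's
    own alt (correct for heavy-strand genes).
    """
    if alt is None:
        alt = evidence.variant.alt
    return _vhc_parts(evidence, column, factors, benign_distribution, alt).value


# ---------------------------------------------------------------------------
# Position score
# ---------------------------------------------------------------------------

def position_score(
    slot: GenericSlot,
    per_position_summary: Mapping[tuple[str, int], float],
    slot_map: Mapping[tuple[str, int], GenericSlot],
) -> float:
    """Mean per-position vhc summary over all tRNA positions mapped to ``slot``.

    Each position's summary is itself the mean vhc over its four candidate
    alleles (three substitutions and the deletion), computed upstream.
    """
    values = [
        per_position_summary[key]
        for key, s in slot_map.items()
        if (s.element_kind, s.within_element_index)
        == (slot.element_kind, slot.within_element_index)
    ]
    if not values:
        raise ConfigurationError(f"no tRNA position maps to slot {slot.slot_id}")
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Secondary-structure score
# ---------------------------------------------------------------------------

def pair_steric_class(five_base: str, three_base: str) -> int:
    """Steric class of a base pair (either base may be the deletion token)."""
    if five_base == DELETION or three_base == DELETION:
        return STERIC_DELETION
    pair = (five_base, three_base)
    if pair in _WATSON_CRICK_PAIRS:
        return STERIC_WATSON_CRICK
    if pair in _WOBBLE_PAIRS:
        return STERIC_WOBBLE
    if five_base in _PYRIMIDINES and three_base in _PYRIMIDINES:
        return STERIC_PYR_PYR
    if five_base in _PURINES and three_base in _PURINES:
        return STERIC_PUR_PUR
    return STERIC_OTHER_MISMATCH


def quadratic_weight(pair_index: int, stem_length: int) -> float:
    """End-of-stem weight: 1 at both stem ends, QUADRATIC_FLOOR at the center."""
    if stem_length < 2:
        raise DegenerateStemError("stems of length < 2 have no end/center geometry")
    half = (stem_length - 1) / 2.0
    return QUADRATIC_FLOOR + (1.0 - QUADRATIC_FLOOR) * ((pair_index - half) ** 2) / half**2


def secondary_structure_score(
    locus: TRNALocus, alt: str, sense_sequence: str | None = None
) -> float:
    """Steric impact of a variant on its stem, 0 for unpaired positions.

    ``alt`` is the tRNA-sense alternate allele.  The score is the change in
    steric class from the wild-type pair to the mutant pair, weighted by
    the quadratic end-of-stem profile; improving a pair (wobble to
    Watson-Crick) therefore scores negative.
    """
    if not locus.paired:
        return 0.0
    seq = sense_sequence if sense_sequence is not None else locus.gene.sequence
    stem_length = locus.element.length
    pair_index = locus.stem_pair_index
    assert pair_index is not None
    w = quadratic_weight(pair_index, stem_length)
    self_base = seq[locus.index_5p]
    partner_base = seq[locus.partner_index_5p]
    if locus.element.kind.endswith("_5p"):
        old = (self_base, partner_base)
        new = (alt, partner_base)
    else:
        old = (partner_base, self_base)
        new = (partner_base, alt)
    steric = pair_steric_class(*new) - pair_steric_class(*old)
    return w * steric


# ---------------------------------------------------------------------------
# Total score
# ---------------------------------------------------------------------------

@dataclass
class ScoreBreakdown:
    """All sub-parts of one variant's pathogenicity score."""

    position: int
    ref: str
    alt: str
    gene: str
    element: str
    generic_slot: str
    pop_score: float
    path_score: float
    cons_score: float
    branch: int
    var_hx_cons_score: float
    position_score: float
    secondary_structure_score: float
    total_score: float


def _sense_alt(gene: TRNAGene, alt: str) -> str:
    """Reference-strand alt allele expressed on the tRNA sense strand."""
    if alt == DELETION or gene.strand == "+":
        return alt
    return _COMPLEMENT[alt]


def total_score(
    variant: Variant,
    locus: TRNALocus,
    evidence: VariantEvidence,
    column: ConservationColumn,
    factors: ScalingFactors,
    benign_distribution,
    position_scores: Mapping[tuple[str, int], float],
    slot_map: Mapping[tuple[str, int], GenericSlot] | None = None,
) -> ScoreBreakdown:
    """Score one variant: scaled sum of vhc, position and structure sub-scores.

    ``position_scores`` maps (gene name, tRNA index) to the slot-averaged
    position score of that position.  This is the scalar reference path;
    :class:`ScoringModel` computes identical numbers vectorized.
    """
    gene = locus.gene
    alt_sense = _sense_alt(gene, variant.alt)
    parts = _vhc_parts(evidence, column, factors, benign_distribution, alt_sense)
    pos = float(position_scores[(gene.name, locus.index_5p)])
    ss = secondary_structure_score(locus, alt_sense)
    total = (
        factors.var_hx_cons_scal * parts.value
        + factors.Pos_scal * pos
        + factors.SS_scal * ss
    )
    slot_id = ""
    if slot_map is not None:
        slot_id = slot_map[(gene.name, locus.index_5p)].slot_id
    return ScoreBreakdown(
        position=variant.position,
        ref=variant.ref,
        alt=variant.alt,
        gene=gene.name,
        element=locus.element.kind,
        generic_slot=slot_id,
        pop_score=parts.pop,
        path_score=parts.path,
        cons_score=parts.cons,
        branch=parts.branch,
        var_hx_cons_score=parts.value,
        position_score=pos,
        secondary_structure_score=ss,
        total_score=total,
    )


# ---------------------------------------------------------------------------
# Vectorized scoring engine
# ---------------------------------------------------------------------------

class ScoringModel:
    """Precomputed scoring engine over every possible variant of a gene set.

    The vhc score is linear in (var_hx_scal, cons_scal, base_scal) once the
    decision-tree branch of each allele is fixed, and the position score is
    a fixed linear average of vhc values.  The model therefore precomputes
    per-allele coefficient arrays once and can re-evaluate the full score
    table for arbitrary scaling factors with a handful of array operations,
    which is what makes take-one-out optimization tractable.
    """

    def __init__(
        self,
        genes: Sequence[TRNAGene],
        evidence: Mapping[Variant, VariantEvidence],
        conservation: Mapping[tuple[str, int], ConservationColumn],
        benign_distribution=None,
    ) -> None:
        self.genes = list(genes)
        self.evidence = evidence
        self.conservation = conservation
        self.slot_map = align_generic(self.genes)
        if benign_distribution is None:
            benign_distribution = benign_count_distribution(evidence)
        self.benign_distribution = np.asarray(benign_distribution, dtype=float)

        # Enumerate positions sorted by mtDNA coordinate, then 4 alleles each.
        positions: list[tuple[TRNAGene, int]] = []
        for g in self.genes:
            for i in range(g.length):
                positions.append((g, i))
        positions.sort(key=lambda gi: gi[0].mtdna_position(gi[1]))
        self.positions = positions
        self._pos_index = {
            (g.name, i): p for p, (g, i) in enumerate(positions)
        }

        slot_ids = sorted({s.slot_id for s in self.slot_map.values()})
        self._slot_index = {sid: j for j, sid in enumerate(slot_ids)}
        self.n_slots = len(slot_ids)
        self._position_slot = np.array(
            [self._slot_index[self.slot_map[(g.name, i)].slot_id] for g, i in positions],
            dtype=int,
        )

        rows_static = []
        A, B, C = [], [], []
        pop, path, cons, branch, ss = [], [], [], [], []
        allele_pos_index = []
        self._allele_index: dict[Variant, int] = {}
        for p, (g, i) in enumerate(positions):
            locus = g.locus(i)
            mt = locus.mtdna_position
            ref_strand_base = (
                g.sequence[i] if g.strand == "+" else _COMPLEMENT[g.sequence[i]]
            )
            for alt in _alt_order(ref_strand_base):
                variant = Variant(mt, ref_strand_base, alt)
                alt_sense = _sense_alt(g, alt)
                ev = evidence.get(variant) or novel_evidence(variant)
                column = conservation[(g.name, i)]
                parts = _vhc_parts(
                    ev, column, ScalingFactors.unit(), self.benign_distribution, alt_sense
                )
                # Store branch-wise linear coefficients, not the unit value.
                if parts.branch == 1:
                    A.append(parts.path)
                    B.append(0.0)
                elif parts.branch == 2:
                    A.append(-(1.0 - parts.pop))
                    B.append(0.0)
                else:
                    A.append(0.0)
                    B.append(1.0)
                C.append(parts.cons)
                pop.append(parts.pop)
                path.append(parts.path)
                cons.append(parts.cons)
                branch.append(parts.branch)
                ss.append(secondary_structure_score(locus, alt_sense))
                allele_pos_index.append(p)
                self._allele_index[variant] = len(A) - 1
                rows_static.append(
                    {
                        "position": mt,
                        "ref": ref_strand_base,
                        "alt": alt,
                        "gene": g.name,
                        "element": locus.element.kind,
                        "generic_slot": self.slot_map[(g.name, i)].slot_id,
                    }
                )
        self._static = pd.DataFrame(rows_static)
        self.A = np.array(A)
        self.B = np.array(B)
        self.C = np.array(C)
        self.pop = np.array(pop)
        self.path = np.array(path)
        self.cons = np.array(cons)
        self.branch = np.array(branch, dtype=int)
        self.ss = np.array(ss)
        self._allele_pos = np.array(allele_pos_index, dtype=int)
        self.n_positions = len(positions)
        self.n_alleles = len(A)

        # Per-position means of the vhc coefficients (over the 4 alleles),
        # then per-slot means of those: the position-score coefficients.
        self._Ap, self._Bp, self._Cp = (
            self._slot_average(self._position_mean(x)) for x in (self.A, self.B, self.C)
        )

    # -- linear algebra helpers -----------------------------------------

    def _position_mean(self, allele_values: np.ndarray) -> np.ndarray:
        sums = np.bincount(
            self._allele_pos, weights=allele_values, minlength=self.n_positions
        )
        counts = np.bincount(self._allele_pos, minlength=self.n_positions)
        return sums / counts

    def _slot_average(self, position_values: np.ndarray) -> np.ndarray:
        """Slot-mean of per-position values, broadcast back to positions."""
        sums = np.bincount(
            self._position_slot, weights=position_values, minlength=self.n_slots
        )
        counts = np.bincount(self._position_slot, minlength=self.n_slots)
        return (sums / counts)[self._position_slot]

    # -- evaluation ------------------------------------------------------

    def vhc_values(self, factors: ScalingFactors) -> np.ndarray:
        return (
            factors.var_hx_scal * self.A
            + factors.cons_scal * self.C
            + factors.base_scal * self.B
        )

    def position_scores(self, factors: ScalingFactors) -> np.ndarray:
        """Per-position position score (slot-averaged vhc summaries)."""
        return (
            factors.var_hx_scal * self._Ap
            + factors.cons_scal * self._Cp
            + factors.base_scal * self._Bp
        )

    def position_score_map(self, factors: ScalingFactors) -> dict[tuple[str, int], float]:
        values = self.position_scores(factors)
        return {
            (g.name, i): float(values[p])
            for p, (g, i) in enumerate(self.positions)
        }

    def totals(self, factors: ScalingFactors) -> np.ndarray:
        vhc = self.vhc_values(factors)
        pos = self.position_scores(factors)[self._allele_pos]
        return (
            factors.var_hx_cons_scal * vhc
            + factors.Pos_scal * pos
            + factors.SS_scal * self.ss
        )

    def score_table(self, factors: ScalingFactors) -> pd.DataFrame:
        table = self._static.copy()
        table["pop_score"] = self.pop
        table["path_score"] = self.path
        table["cons_score"] = self.cons
        table["branch"] = self.branch
        table["var_hx_cons_score"] = self.vhc_values(factors)
        table["position_score"] = self.position_scores(factors)[self._allele_pos]
        table["secondary_structure_score"] = self.ss
        table["total_score"] = self.totals(factors)
        return table

    def score_of(self, variant: Variant, factors: ScalingFactors) -> ScoreBreakdown:
        """Breakdown for one variant (must be a possible change at a tRNA position)."""
        try:
            idx = self._allele_index[variant]
        except KeyError:
            raise KeyError(f"{variant} is not a possible tRNA variant here") from None
        row = self.score_table(factors).iloc[idx]
        return ScoreBreakdown(**{f.name: row[f.name] for f in fields(ScoreBreakdown)})


def score_all(
    genes: Sequence[TRNAGene],
    evidence: Mapping[Variant, VariantEvidence],
    conservation: Mapping[tuple[str, int], ConservationColumn],
    factors: ScalingFactors,
    benign_distribution=None,
) -> pd.DataFrame:
    """Score every possible substitution and single-base deletion.

    Returns exactly four rows per annotated tRNA position, ordered by
    mtDNA position then alternate allele (substitutions alphabetically,
    deletion last); deterministic for fixed inputs.
    """
    model = ScoringModel(genes, evidence, conservation, benign_distribution)
    return model.score_table(factors)
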