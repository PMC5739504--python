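"""Take-one-out evaluation, threshold sweep, and score interpretation.

The scoring system is validated by re-scoring reference pathogenic and
benign variants *naively*: each variant's own database evidence (reports
and population counts) is deleted before it is scored, so it is treated
exactly like a newly observed variant, and the position score of its
alignment slot is recomputed without its contribution.  Sweeping a score
threshold over the resulting labeled scores yields sensitivity and
specificity curves whose crossover is the system's single operating point.

For end users a score is interpreted against the distribution of all
possible variants: a percentile clamped to 1-99 and a four-category call
(likely/possibly pathogenic, possibly/likely benign) by quartile, with
display suppression for known-pathogenic and frequent-polymorphism
variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, percentileofscore

from .evidence import Variant, VariantEvidence, novel_evidence
from .scoring import (
    ScalingFactors,
    ScoreBreakdown,
    ScoringModel,
    benign_count_distribution,
)
from .structure import TRNAGene

__all__ = [
    "EvaluationError",
    "LabeledVariant",
    "SweepResult",
    "LOOEvaluator",
    "loo_score",
    "sweep",
    "percentile_interpret",
    "display_status",
    "read_labels",
    "write_labels",
    "evaluation_report",
    "CATEGORIES",
]

PATHOGENIC = "pathogenic"
BENIGN = "benign"

CATEGORIES = (
    "likely benign",
    "possibly benign",
    "possibly pathogenic",
    "likely pathogenic",
)


class EvaluationError(ValueError):
    """The evaluation inputs are unusable (single class, empty table...)."""


@dataclass(frozen=True)
class LabeledVariant:
    variant: Variant
    label: str  # "pathogenic" | "benign"

    def __post_init__(self) -> None:
        if self.label not in (PATHOGENIC, BENIGN):
            raise EvaluationError(f"unknown label {self.label!r}")


def read_labels(path) -> list[LabeledVariant]:
    table = pd.read_csv(path, sep="\t")
    required = {"position", "ref", "alt", "label"}
    missing = required - set(table.columns)
    if missing:
        raise EvaluationError(f"labels table missing columns {sorted(missing)}")
    return [
        LabeledVariant(Variant(int(r.position), str(r.ref), str(r.alt)), str(r.label))
        for r in table.itertuples(index=False)
    ]


def write_labels(labeled: Iterable[LabeledVariant], path) -> None:
    rows = [
        {
            "position": lv.variant.position,
            "ref": lv.variant.ref,
            "alt": lv.variant.alt,
            "label": lv.label,
        }
        for lv in labeled
    ]
    pd.DataFrame(rows, columns=["position", "ref", "alt", "label"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Take-one-out scoring
# ---------------------------------------------------------------------------

class LOOEvaluator:
    """Fast take-one-out scorer for a fixed labeled variant set.

    Deleting one variant's evidence changes (a) its own vhc branch (it
    becomes novel), (b) the benign count distribution (its count leaves,
    shifting the population percentile of every observed report-free
    allele) and (c) through both, the position score of its alignment
    slot.  Only the target's own slot feeds its total, so per target we
    precompute corrected linear vhc coefficients for the slot's alleles
    once; the LOO score for arbitrary scaling factors is then a handful of
    vector operations, matching the delete-and-rescore oracle exactly.
    """

    def __init__(
        self,
        genes: Sequence[TRNAGene],
        evidence: Mapping[Variant, VariantEvidence],
        conservation,
        labeled: Sequence[LabeledVariant],
    ) -> None:
        if not labeled:
            raise EvaluationError("empty labeled set")
        self.model = ScoringModel(genes, evidence, conservation)
        self.labeled = list(labeled)
        self.labels = np.array([lv.label == PATHOGENIC for lv in labeled])
        m = self.model
        for lv in labeled:
            if lv.variant not in evidence:
                raise EvaluationError(f"{lv.variant} absent from the evidence map")
            if lv.variant not in m._allele_index:
                raise EvaluationError(f"{lv.variant} is not a scored tRNA variant")

        n = len(labeled)
        # Target's own vhc coefficients after deletion: always branch 3.
        self.own_A = np.zeros(n)
        self.own_B = np.ones(n)
        self.own_C = np.empty(n)
        # Slot position-score coefficients after deletion.
        self.slot_A = np.empty(n)
        self.slot_B = np.empty(n)
        self.slot_C = np.empty(n)
        self.ss = np.empty(n)

        for t, lv in enumerate(labeled):
            idx = m._allele_index[lv.variant]
            self.own_C[t] = m.C[idx]
            self.ss[t] = m.ss[idx]
            self.slot_A[t], self.slot_B[t], self.slot_C[t] = self._slot_coeffs(lv.variant)

    def _loo_distribution(self, target: Variant) -> np.ndarray:
        ev = self.model.evidence[target]
        dist = self.model.benign_distribution
        if ev.genbank_count >= 1 and not ev.reports:
            pos = np.searchsorted(dist, float(ev.genbank_count))
            dist = np.delete(dist, pos)
        return dist

    def _slot_coeffs(self, target: Variant) -> tuple[float, float, float]:
        """Position-score coefficients of the target's slot with the target removed."""
        from .scoring import _vhc_parts, _sense_alt  # internal coefficient recompute

        m = self.model
        target_idx = m._allele_index[target]
        slot = m._position_slot[m._allele_pos[target_idx]]
        positions = np.flatnonzero(m._position_slot == slot)
        dist = self._loo_distribution(target)
        dist_changed = dist.shape != m.benign_distribution.shape
        unit = ScalingFactors.unit()

        pos_means = []
        for p in positions:
            # alleles are enumerated 4 per position, in position order
            allele_idx = range(4 * p, 4 * p + 4)
            coeffs = []
            for idx in allele_idx:
                if idx == target_idx:
                    coeffs.append((0.0, 1.0, m.C[idx]))  # novel
                elif m.branch[idx] == 2 and dist_changed:
                    g, i = m.positions[p]
                    row = m._static.iloc[idx]
                    variant = Variant(int(row.position), str(row.ref), str(row.alt))
                    ev = m.evidence[variant]
                    parts = _vhc_parts(
                        ev,
                        m.conservation[(g.name, i)],
                        unit,
                        dist,
                        _sense_alt(g, variant.alt),
                    )
                    coeffs.append((-(1.0 - parts.pop), 0.0, parts.cons))
                else:
                    coeffs.append((m.A[idx], m.B[idx], m.C[idx]))
            pos_means.append(np.mean(coeffs, axis=0))
        slot_mean = np.mean(pos_means, axis=0)
        return float(slot_mean[0]), float(slot_mean[1]), float(slot_mean[2])

    def scores(self, factors: ScalingFactors) -> np.ndarray:
        """LOO total scores of all labeled variants under ``factors``."""
        vhc = (
            factors.var_hx_scal * self.own_A
            + factors.cons_scal * self.own_C
            + factors.base_scal * self.own_B
        )
        pos = (
            factors.var_hx_scal * self.slot_A
            + factors.cons_scal * self.slot_C
            + factors.base_scal * self.slot_B
        )
        return (
            factors.var_hx_cons_scal * vhc
            + factors.Pos_scal * pos
            + factors.SS_scal * self.ss
        )

    def breakdown(self, index: int, factors: ScalingFactors) -> ScoreBreakdown:
        """Full LOO breakdown for labeled variant ``index``."""
        lv = self.labeled[index]
        m = self.model
        idx = m._allele_index[lv.variant]
        row = m._static.iloc[idx]
        vhc = (
            factors.var_hx_scal * self.own_A[index]
            + factors.cons_scal * self.own_C[index]
            + factors.base_scal * self.own_B[index]
        )
        pos = (
            factors.var_hx_scal * self.slot_A[index]
            + factors.cons_scal * self.slot_C[index]
            + factors.base_scal * self.slot_B[index]
        )
        return ScoreBreakdown(
            position=int(row.position),
            ref=str(row.ref),
            alt=str(row.alt),
            gene=str(row.gene),
            element=str(row.element),
            generic_slot=str(row.generic_slot),
            pop_score=float("nan"),
            path_score=0.0,
            cons_score=float(self.own_C[index]),
            branch=3,
            var_hx_cons_score=float(vhc),
            position_score=float(pos),
            secondary_structure_score=float(self.ss[index]),
            total_score=float(self.scores(factors)[index]),
        )


def loo_score(
    target: LabeledVariant,
    genes: Sequence[TRNAGene],
    evidence: Mapping[Variant, VariantEvidence],
    conservation,
    factors: ScalingFactors,
) -> ScoreBreakdown:
    """Score ``target`` with its own evidence deleted (treated as novel).

    Equivalent to deleting the variant from the evidence map and re-running
    the full scoring, including recomputation of the benign count
    distribution and of its slot's position score.
    """
    if target.variant not in evidence:
        raise EvaluationError(f"{target.variant} absent from the evidence map")
    evaluator = LOOEvaluator(genes, evidence, conservation, [target])
    return evaluator.breakdown(0, factors)


# ---------------------------------------------------------------------------
# Sensitivity/specificity sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    crossover_threshold: float
    crossover_value: float
    degenerate: bool = False

    def at_crossover(self) -> tuple[float, float]:
        i = int(np.argmin(np.abs(self.sensitivity - self.specificity)))
        return float(self.sensitivity[i]), float(self.specificity[i])


def sweep(scores, labels=None) -> SweepResult:
    """Sensitivity/specificity over thresholds; call pathogenic when score >= t.

    ``scores`` is either a mapping ``LabeledVariant -> score`` or an array
    paired with a boolean/str ``labels`` array (True/"pathogenic" for the
    pathogenic class).  Thresholds are the sorted unique scores plus the
    midpoints between adjacent ones; the crossover is the threshold
    minimizing |sensitivity - specificity|, ties resolved toward the lower
    threshold (higher sensitivity).
    """
    if labels is None:
        items = list(scores.items())
        values = np.array([v for _, v in items], dtype=float)
        is_path = np.array([lv.label == PATHOGENIC for lv, _ in items])
    else:
        values = np.asarray(scores, dtype=float)
        labels = np.asarray(labels)
        is_path = (
            labels if labels.dtype == bool else np.array([l == PATHOGENIC for l in labels])
        )
    if is_path.all() or (~is_path).all():
        raise EvaluationError("sweep requires both pathogenic and benign labels")

    uniq = np.unique(values)
    thresholds = np.sort(np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2.0]))
    path_sorted = np.sort(values[is_path])
    ben_sorted = np.sort(values[~is_path])
    # sensitivity: fraction of pathogenic scores >= t (non-increasing in t)
    sens = 1.0 - np.searchsorted(path_sorted, thresholds, side="left") / path_sorted.size
    # specificity: fraction of benign scores < t (non-decreasing in t)
    spec = np.searchsorted(ben_sorted, thresholds, side="left") / ben_sorted.size
    i = int(np.argmin(np.abs(sens - spec)))
    return SweepResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        crossover_threshold=float(thresholds[i]),
        crossover_value=float((sens[i] + spec[i]) / 2.0),
        degenerate=bool(uniq.size == 1),
    )


# ---------------------------------------------------------------------------
# Interpretation
# ---------------------------------------------------------------------------

def percentile_interpret(all_scores, query_score: float) -> tuple[int, str]:
    """Percentile (1-99) of a score among all possible variants, plus category.

    The percentile is the mean rank of the query within the full score
    table, rounded and clamped to [1, 99]; the category is assigned by
    quartile with inclusive upper boundaries (<=25 likely benign, <=50
    possibly benign, <=75 possibly pathogenic, else likely pathogenic).
    """
    if isinstance(all_scores, pd.DataFrame):
        all_scores = all_scores["total_score"]
    values = np.asarray(all_scores, dtype=float)
    if values.size == 0:
        raise EvaluationError("empty score table")
    pct = int(round(percentileofscore(values, query_score, kind="mean")))
    pct = min(99, max(1, pct))
    if pct <= 25:
        category = CATEGORIES[0]
    elif pct <= 50:
        category = CATEGORIES[1]
    elif pct <= 75:
        category = CATEGORIES[2]
    else:
        category = CATEGORIES[3]
    return pct, category


KNOWN_PATHOGENIC = "known_pathogenic"
FREQUENT_POLYMORPHISM = "frequent_polymorphism"
SCORED = "scored"

#: Display-suppression frequency rules (strict inequalities).
GENBANK_FREQUENCY_CUTOFF = 0.01
HAPLOGROUP_FREQUENCY_CUTOFF = 0.10


def display_status(
    variant: Variant,
    evidence: VariantEvidence | None,
    known_pathogenic: Iterable[Variant] = (),
) -> str:
    """Display class: known_pathogenic > frequent_polymorphism > scored.

    A variant confirmed pathogenic is always reported as such regardless
    of frequency; otherwise variants above 1% of all sequences or above
    10% in any single haplogroup division (both strict) are reported as
    frequent polymorphisms; everything else shows its score.  Suppressed
    variants still carry a full breakdown internally.
    """
    if variant in set(known_pathogenic):
        return KNOWN_PATHOGENIC
    if evidence is not None:
        if (
            evidence.total_sequences > 0
            and evidence.genbank_count / evidence.total_sequences
            > GENBANK_FREQUENCY_CUTOFF
        ):
            return FREQUENT_POLYMORPHISM
        if any(
            frac > HAPLOGROUP_FREQUENCY_CUTOFF
            for frac in evidence.haplogroup_frequencies.values()
        ):
            return FREQUENT_POLYMORPHISM
    return SCORED


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def evaluation_report(
    evaluator: LOOEvaluator, factors: ScalingFactors
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-variant LOO table, sweep curve, and summary statistics.

    The summary carries sensitivity/specificity at the crossover, the
    crossover threshold, and a Mann-Whitney U test of pathogenic vs benign
    LOO scores.
    """
    loo = evaluator.scores(factors)
    full = evaluator.model.totals(factors)
    full_by_variant = {
        v: full[i] for v, i in evaluator.model._allele_index.items()
    }
    result = sweep(loo, evaluator.labels)
    rows = []
    for t, lv in enumerate(evaluator.labeled):
        rows.append(
            {
                "variant": str(lv.variant),
                "label": lv.label,
                "full_score": float(full_by_variant[lv.variant]),
                "loo_score": float(loo[t]),
                "call_at_crossover": (
                    PATHOGENIC if loo[t] >= result.crossover_threshold else BENIGN
                ),
            }
        )
    per_variant = pd.DataFrame(rows)
    curve = pd.DataFrame(
        {
            "threshold": result.thresholds,
            "sensitivity": result.sensitivity,
            "specificity": result.specificity,
        }
    )
    sens, spec = result.at_crossover()
    path_scores = loo[evaluator.labels]
    ben_scores = loo[~evaluator.labels]
    if result.degenerate:
        mw_p = float("nan")
    else:
        mw_p = float(mannwhitneyu(path_scores, ben_scores, alternative="greater").pvalue)
    summary = {
        "n_pathogenic": int(evaluator.labels.sum()),
        "n_benign": int((~evaluator.labels).sum()),
        "sensitivity": sens,
        "specificity": spec,
        "crossover_threshold": result.crossover_threshold,
        "crossover_value": result.crossover_value,
        "degenerate": result.degenerate,
        "mannwhitney_p_greater": mw_p,
    }
    return per_variant, curve, summary
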