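"""Take-one-out scoring, the threshold sweep, and score interpretation."""

import numpy as np
import pytest

from trnapath.evaluation import (
    BENIGN,
    PATHOGENIC,
    EvaluationError,
    LabeledVariant,
    LOOEvaluator,
    display_status,
    evaluation_report,
    loo_score,
    percentile_interpret,
    sweep,
)
from trnapath.evidence import PathReport, Variant, VariantEvidence
from trnapath.scoring import ScalingFactors, ScoringModel

FACTORS = ScalingFactors(1.4, 0.9, 1.2, 1.8, 0.6, 1.1)


class TestLooScore:
    def test_matches_delete_and_rescore_oracle(self, small_fixture):
        fx = small_fixture
        rng = np.random.default_rng(2)
        targets = [fx.labeled[i] for i in rng.choice(len(fx.labeled), 8, replace=False)]
        # ensure both classes get exercised
        targets += [
            next(lv for lv in fx.labeled if lv.label == PATHOGENIC),
            next(lv for lv in fx.labeled if lv.label == BENIGN),
        ]
        for lv in targets:
            fast = loo_score(lv, fx.genes, fx.evidence, fx.conservation, FACTORS)
            reduced = {k: v for k, v in fx.evidence.items() if k != lv.variant}
            oracle = ScoringModel(fx.genes, reduced, fx.conservation).score_of(
                lv.variant, FACTORS
            )
            assert fast.total_score == pytest.approx(oracle.total_score, abs=1e-12)
            assert fast.position_score == pytest.approx(oracle.position_score, abs=1e-12)
            assert fast.branch == 3

    def test_variant_without_evidence_is_a_no_op(self, small_fixture):
        fx = small_fixture
        # find a scored allele with no evidence entry and register empty evidence
        model = ScoringModel(fx.genes, fx.evidence, fx.conservation)
        table = model.score_table(FACTORS)
        row = next(
            r for r in table.itertuples(index=False)
            if Variant(int(r.position), str(r.ref), str(r.alt)) not in fx.evidence
        )
        variant = Variant(int(row.position), str(row.ref), str(row.alt))
        evidence = dict(fx.evidence)
        evidence[variant] = VariantEvidence(variant)  # present but empty
        lv = LabeledVariant(variant, BENIGN)
        loo = loo_score(lv, fx.genes, evidence, fx.conservation, FACTORS)
        full = ScoringModel(fx.genes, evidence, fx.conservation).score_of(
            variant, FACTORS
        )
        assert loo.total_score == pytest.approx(full.total_score, abs=1e-12)

    def test_reported_variant_flips_to_novel_branch(self, small_fixture):
        fx = small_fixture
        lv = next(
            l for l in fx.labeled
            if l.label == PATHOGENIC and fx.evidence[l.variant].reports
        )
        full = ScoringModel(fx.genes, fx.evidence, fx.conservation).score_of(
            lv.variant, FACTORS
        )
        loo = loo_score(lv, fx.genes, fx.evidence, fx.conservation, FACTORS)
        assert full.branch == 1
        assert loo.branch == 3

    def test_absent_target_is_an_evaluation_error(self, small_fixture):
        fx = small_fixture
        model = ScoringModel(fx.genes, fx.evidence, fx.conservation)
        table = model.score_table(FACTORS)
        row = next(
            r for r in table.itertuples(index=False)
            if Variant(int(r.position), str(r.ref), str(r.alt)) not in fx.evidence
        )
        lv = LabeledVariant(Variant(int(row.position), str(row.ref), str(row.alt)), BENIGN)
        with pytest.raises(EvaluationError):
            loo_score(lv, fx.genes, fx.evidence, fx.conservation, FACTORS)


class TestSweep:
    def _labeled(self, n, label):
        return [
            LabeledVariant(Variant(1000 + i + (0 if label == PATHOGENIC else 5000), "A", "C"), label)
            for i in range(n)
        ]

    def test_perfect_separation_reaches_unity(self):
        scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array([False, False, False, True, True, True])
        result = sweep(scores, labels)
        sens, spec = result.at_crossover()
        assert sens == spec == 1.0
        assert 3.0 < result.crossover_threshold <= 10.0

    def test_monotonic_in_threshold(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=400)
        labels = rng.random(400) < 0.3
        result = sweep(scores, labels)
        assert np.all(np.diff(result.sensitivity) <= 1e-12)
        assert np.all(np.diff(result.specificity) >= -1e-12)

    def test_random_labels_cross_near_half(self):
        rng = np.random.default_rng(42)
        scores = rng.normal(size=2000)
        labels = rng.permutation([True] * 600 + [False] * 1400)
        result = sweep(scores, labels)
        assert result.crossover_value == pytest.approx(0.5, abs=0.05)

    def test_identical_scores_flagged_degenerate(self):
        result = sweep(np.ones(10), np.array([True] * 4 + [False] * 6))
        assert result.degenerate
        sens, spec = result.at_crossover()
        assert (sens, spec) in ((1.0, 0.0), (0.0, 1.0))

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            sweep(np.arange(5.0), np.ones(5, dtype=bool))


class TestPercentileInterpretation:
    TABLE = np.arange(101, dtype=float)  # 0..100, unique scores

    def test_extremes_clamped(self):
        assert percentile_interpret(self.TABLE, 100.0) == (99, "likely pathogenic")
        assert percentile_interpret(self.TABLE, 0.0) == (1, "likely benign")

    def test_median_is_possibly_benign(self):
        assert percentile_interpret(self.TABLE, 50.0) == (50, "possibly benign")

    def test_quartile_categories(self):
        assert percentile_interpret(self.TABLE, 20.0)[1] == "likely benign"
        assert percentile_interpret(self.TABLE, 60.0)[1] == "possibly pathogenic"
        assert percentile_interpret(self.TABLE, 90.0)[1] == "likely pathogenic"

    def test_bounds_always_1_to_99(self):
        rng = np.random.default_rng(1)
        for q in rng.normal(50, 80, size=200):
            pct, _ = percentile_interpret(self.TABLE, float(q))
            assert 1 <= pct <= 99

    def test_empty_table_rejected(self):
        with pytest.raises(EvaluationError):
            percentile_interpret(np.array([]), 1.0)


class TestDisplayStatus:
    V = Variant(583, "G", "A")

    def test_known_pathogenic_takes_precedence(self):
        ev = VariantEvidence(self.V, genbank_count=500, total_sequences=10000)
        assert display_status(self.V, ev, {self.V}) == "known_pathogenic"

    def test_frequency_rule_is_strict(self):
        common = VariantEvidence(self.V, genbank_count=110, total_sequences=10000)
        assert display_status(self.V, common) == "frequent_polymorphism"
        boundary = VariantEvidence(self.V, genbank_count=100, total_sequences=10000)
        assert display_status(self.V, boundary) == "scored"  # exactly 1%

    def test_haplogroup_rule_is_strict(self):
        at_boundary = VariantEvidence(
            self.V, haplogroup_frequencies={"H": 0.10}
        )
        assert display_status(self.V, at_boundary) == "scored"
        above = VariantEvidence(self.V, haplogroup_frequencies={"H": 0.101})
        assert display_status(self.V, above) == "frequent_polymorphism"

    def test_novel_variant_is_scored(self):
        assert display_status(self.V, None) == "scored"


class TestEvaluationReport:
    def test_summary_and_tables(self, small_fixture):
        fx = small_fixture
        evaluator = LOOEvaluator(fx.genes, fx.evidence, fx.conservation, fx.labeled)
        per_variant, curve, summary = evaluation_report(evaluator, FACTORS)
        assert len(per_variant) == len(fx.labeled)
        assert summary["n_pathogenic"] == 8
        assert summary["n_benign"] == 40
        assert 0.0 <= summary["sensitivity"] <= 1.0
        assert 0.0 <= summary["specificity"] <= 1.0
        assert set(per_variant["call_at_crossover"]) <= {PATHOGENIC, BENIGN}
        assert list(curve.columns) == ["threshold", "sensitivity", "specificity"]
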