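"""Sub-score formulas, the vhc decision tree, structure penalties, score_all."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trnapath.evidence import ConservationColumn, PathReport, Variant, VariantEvidence, novel_evidence
from trnapath.scoring import (
    ConfigurationError,
    DegenerateStemError,
    ScalingFactors,
    benign_count_distribution,
    cons_score,
    pair_steric_class,
    path_score,
    pop_score,
    position_score,
    quadratic_weight,
    score_all,
    secondary_structure_score,
    total_score,
    variant_history_and_conservation,
)
from trnapath.structure import align_generic


def _column(counts, n=30, gene="g", idx=0):
    return ConservationColumn(gene, idx, counts, n)


FULL = _column({"A": 30, "C": 0, "G": 0, "T": 0})


class TestPopScore:
    def test_count_below_all_entries_scores_one(self):
        assert pop_score(1, [2, 5, 9]) == 1.0

    def test_count_above_all_entries_scores_zero(self):
        assert pop_score(10, [2, 5, 9]) == 0.0

    def test_strict_rank_on_enumerated_distribution(self):
        # one of four entries lies strictly below 2 -> percentile 25
        assert pop_score(2, [1, 2, 3, 4]) == pytest.approx(0.75)

    def test_empty_distribution_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            pop_score(3, [])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(1, 500), min_size=1, max_size=40),
        c1=st.integers(1, 500),
        c2=st.integers(1, 500),
    )
    def test_monotone_non_increasing_in_count(self, counts, c1, c2):
        lo, hi = sorted((c1, c2))
        assert pop_score(lo, counts) >= pop_score(hi, counts)


class TestPathScore:
    def test_no_reports_scores_zero(self):
        assert path_score([]) == 0.0

    def test_confirmed_heteroplasmic_is_maximal(self):
        assert path_score([PathReport(True, True)]) == 1.0

    def test_max_over_strata(self):
        reports = [PathReport(False, False), PathReport(True, False)]
        assert path_score(reports) == 0.6

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.tuples(st.booleans(), st.booleans()), max_size=6),
        st.tuples(st.booleans(), st.booleans()),
    )
    def test_adding_a_report_never_lowers_the_score(self, flags, extra):
        reports = [PathReport(*f) for f in flags]
        assert path_score(reports + [PathReport(*extra)]) >= path_score(reports)


class TestConsScore:
    def test_unseen_alternate_scores_one(self):
        assert cons_score(FULL, "C") == 1.0
        assert cons_score(FULL, "del") == 1.0  # deletions are never panel bases

    def test_universal_alternate_scores_zero(self):
        assert cons_score(FULL, "A") == 0.0

    def test_logarithmic_form(self):
        col = _column({"A": 25, "C": 5, "G": 0, "T": 0}, n=30)
        assert cons_score(col, "C") == pytest.approx(1 - math.log(6) / math.log(31))

    def test_strictly_decreasing_in_species_count(self):
        scores = [
            cons_score(_column({"A": 30 - k, "C": k, "G": 0, "T": 0}), "C")
            for k in range(31)
        ]
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestDecisionTree:
    factors = ScalingFactors(var_hx_scal=2.0, cons_scal=3.0, var_hx_cons_scal=1.0,
                             SS_scal=1.0, Pos_scal=1.0, base_scal=5.0)

    def test_novel_variant_takes_base_plus_conservation(self):
        v = Variant(10, "A", "C")
        vhc = variant_history_and_conservation(
            novel_evidence(v), FULL, self.factors, [1, 2, 3]
        )
        assert vhc == pytest.approx(5.0 + 3.0 * 1.0)

    def test_reported_variant_takes_path_branch(self):
        v = Variant(10, "A", "C")
        ev = VariantEvidence(v, genbank_count=4, reports=(PathReport(True, True),))
        vhc = variant_history_and_conservation(ev, FULL, self.factors, [1, 2, 3])
        # reports take precedence over the population branch
        assert vhc == pytest.approx(2.0 * 1.0 + 3.0 * 1.0)

    def test_observed_benign_variant_is_rewarded(self):
        v = Variant(10, "A", "C")
        ev = VariantEvidence(v, genbank_count=9)
        pop = pop_score(9, [1, 2, 3, 4])  # above the whole distribution -> 0
        col = _column({"A": 0, "C": 30, "G": 0, "T": 0})  # alt universal, cons 0
        vhc = variant_history_and_conservation(ev, col, self.factors, [1, 2, 3, 4])
        assert pop == 0.0
        assert vhc == pytest.approx(2.0 * (-(1.0 - 0.0)) + 0.0)
        assert vhc < 0

    def test_benign_distribution_excludes_reported_variants(self):
        v1, v2, v3 = Variant(1, "A", "C"), Variant(2, "C", "G"), Variant(3, "G", "T")
        evidence = {
            v1: VariantEvidence(v1, genbank_count=5),
            v2: VariantEvidence(v2, genbank_count=9, reports=(PathReport(True, True),)),
            v3: VariantEvidence(v3, genbank_count=0),
        }
        assert benign_count_distribution(evidence).tolist() == [5.0]


class TestQuadraticWeight:
    @pytest.mark.parametrize("L", range(2, 11))
    def test_symmetric_and_end_maximal(self, L):
        weights = [quadratic_weight(i, L) for i in range(L)]
        assert weights == pytest.approx(list(reversed(weights)))
        assert weights[0] == pytest.approx(1.0)
        if L >= 3:
            assert all(weights[0] > w for w in weights[1:-1])

    def test_center_floors_at_quarter(self):
        assert quadratic_weight(3, 7) == pytest.approx(0.25)

    def test_degenerate_stem_rejected(self):
        with pytest.raises(DegenerateStemError):
            quadratic_weight(0, 1)


class TestStericClasses:
    ALLELES = ["A", "C", "G", "T", "del"]

    def test_reference_classes(self):
        assert pair_steric_class("G", "C") == 0
        assert pair_steric_class("G", "T") == 1  # wobble
        assert pair_steric_class("C", "T") == 2  # pyrimidine-pyrimidine
        assert pair_steric_class("A", "C") == 3  # other mismatch
        assert pair_steric_class("A", "G") == 4  # purine-purine
        assert pair_steric_class("del", "C") == 4

    def test_steric_change_is_antisymmetric(self):
        for p in self.ALLELES:
            for q in self.ALLELES:
                forward = pair_steric_class("G", p) - pair_steric_class("G", q)
                backward = pair_steric_class("G", q) - pair_steric_class("G", p)
                assert forward == -backward


class TestSecondaryStructure:
    def test_unpaired_locus_scores_zero(self, small_fixture):
        g = small_fixture.genes[0]
        loop_index = g.element_offset("d_loop")
        locus = g.locus(loop_index)
        assert not locus.paired
        assert secondary_structure_score(locus, "A") == 0.0

    def test_wobble_to_watson_crick_scores_negative(self, small_fixture):
        found = False
        for g in small_fixture.genes:
            for i in range(g.length):
                locus = g.locus(i)
                if not locus.paired or not locus.element.kind.endswith("_5p"):
                    continue
                pair = (g.sequence[i], g.sequence[locus.partner_index_5p])
                if pair == ("G", "T"):
                    # repairing the partner T -> C restores G:C
                    partner = locus.partner
                    assert secondary_structure_score(partner, "C") < 0
                    found = True
        assert found, "fixture should contain seeded G.T wobbles"

    def test_end_vs_center_ratio_in_7bp_stem(self):
        # identical mismatch at pair index 0 vs 3 of a 7 bp stem: weights 1 vs 0.25
        assert quadratic_weight(0, 7) / quadratic_weight(3, 7) == pytest.approx(4.0)


class TestPositionScore:
    def test_constant_summaries_average_to_constant(self, small_fixture):
        genes = small_fixture.genes
        slot_map = align_generic(genes)
        summaries = {key: 2.0 for key in slot_map}
        slot = next(iter(slot_map.values()))
        assert position_score(slot, summaries, slot_map) == pytest.approx(2.0)

    def test_matches_brute_force_mean(self, small_fixture):
        genes = small_fixture.genes
        slot_map = align_generic(genes)
        rng = np.random.default_rng(5)
        summaries = {key: float(rng.normal()) for key in slot_map}
        for slot in set(slot_map.values()):
            members = [k for k, s in slot_map.items() if s == slot]
            brute = float(np.mean([summaries[k] for k in members]))
            assert position_score(slot, summaries, slot_map) == pytest.approx(
                brute, abs=1e-12
            )


class TestTotalScore:
    def test_summation_identity_with_random_factors(self, small_model):
        rng = np.random.default_rng(3)
        factors = ScalingFactors(
            var_hx_scal=float(rng.uniform(-2, 5)),
            cons_scal=float(rng.uniform(0, 5)),
            var_hx_cons_scal=float(rng.uniform(0.1, 5)),
            SS_scal=float(rng.uniform(0.1, 5)),
            Pos_scal=float(rng.uniform(0.1, 5)),
            base_scal=float(rng.uniform(0, 5)),
        )
        table = small_model.score_table(factors)
        expected = (
            factors.var_hx_cons_scal * table["var_hx_cons_score"]
            + factors.Pos_scal * table["position_score"]
            + factors.SS_scal * table["secondary_structure_score"]
        )
        assert np.abs(table["total_score"] - expected).max() == 0.0

    def test_scalar_path_matches_vectorized_model(self, small_fixture, small_model):
        """The per-variant reference implementation agrees with the engine."""
        from trnapath.structure import locate

        fx = small_fixture
        factors = ScalingFactors(1.3, 0.8, 1.1, 2.0, 0.5, 0.9)
        table = small_model.score_table(factors)
        position_scores = small_model.position_score_map(factors)
        rng = np.random.default_rng(7)
        rows = table.iloc[rng.choice(len(table), 25, replace=False)]
        for r in rows.itertuples(index=False):
            variant = Variant(int(r.position), str(r.ref), str(r.alt))
            locus = locate(fx.genes, variant.position)
            ev = fx.evidence.get(variant) or novel_evidence(variant)
            column = fx.conservation[(locus.gene.name, locus.index_5p)]
            breakdown = total_score(
                variant, locus, ev, column, factors,
                small_model.benign_distribution, position_scores,
                small_model.slot_map,
            )
            assert breakdown.total_score == pytest.approx(r.total_score, abs=1e-12)
            assert breakdown.var_hx_cons_score == pytest.approx(
                r.var_hx_cons_score, abs=1e-12
            )
            assert breakdown.branch == r.branch


class TestScoreAll:
    def test_four_rows_per_position_in_order(self, small_fixture):
        fx = small_fixture
        table = score_all(fx.genes, fx.evidence, fx.conservation, ScalingFactors.unit())
        total_nt = sum(g.length for g in fx.genes)
        assert len(table) == 4 * total_nt
        assert table["position"].is_monotonic_increasing
        per_pos = table.groupby("position", sort=False)["alt"].apply(list)
        for ref, alts in zip(table["ref"][::4], per_pos):
            assert alts == sorted(b for b in "ACGT" if b != ref) + ["del"]

    def test_rerun_is_byte_identical(self, small_fixture):
        fx = small_fixture
        t1 = score_all(fx.genes, fx.evidence, fx.conservation, ScalingFactors.unit())
        t2 = score_all(fx.genes, fx.evidence, fx.conservation, ScalingFactors.unit())
        assert t1.to_csv(sep="\t", index=False) == t2.to_csv(sep="\t", index=False)
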