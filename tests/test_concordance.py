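"""Unit tests for the trial-vs-meta-analysis concordance pipeline."""

import math

import pytest

from metaconcord.concordance import (
    AgreementClass,
    EffectDirection,
    MeasureClass,
    ReviewOutcome,
    agreement_table,
    build_concordance,
    ci_relationship,
    classify_significance,
    conditional_rates,
    discrepancy_report,
    estimate_rank_correlation,
    most_precise_trial,
    stratify_by_weight,
)
from metaconcord.core import (
    Direction,
    Measure,
    PooledResult,
    PoolingModel,
    Scale,
    TrialEffect,
    normal_quantile,
)

from _oracle import brute_spearman

Z = normal_quantile(0.95)


def trial_from_effect(tid, y, se, measure=Measure.RR, n=None):
    to_nat = math.exp if measure.is_ratio else float
    return TrialEffect(
        trial_id=tid, measure=measure,
        point=to_nat(y), ci_lower=to_nat(y - Z * se), ci_upper=to_nat(y + Z * se),
        n=n,
    )


def review_from_effects(pairs, review_id="R1", model="fixed", measure=Measure.RR,
                        ns=None):
    ns = ns or [None] * len(pairs)
    trials = tuple(
        trial_from_effect(f"t{i}", y, se, measure, n)
        for i, ((y, se), n) in enumerate(zip(pairs, ns))
    )
    return ReviewOutcome(
        review_id=review_id, outcome_name="primary", trials=trials, model=model
    )


class TestMostPreciseTrial:
    def test_smallest_se_wins(self):
        review = review_from_effects([(0.0, 1.0), (0.0, 0.5), (0.0, 2.0)])
        idx, share = most_precise_trial(review)
        assert idx == 1
        assert share == pytest.approx(4.0 / 5.25, abs=1e-12)

    def test_single_trial(self):
        review = review_from_effects([(0.1, 0.5)])
        assert most_precise_trial(review) == (0, 1.0)

    def test_tie_broken_by_sample_size_then_order(self):
        review = review_from_effects(
            [(0.0, 0.5), (0.2, 0.5)], ns=[100, 200]
        )
        idx, _ = most_precise_trial(review)
        assert idx == 1
        review2 = review_from_effects([(0.0, 0.5), (0.2, 0.5)])
        assert most_precise_trial(review2)[0] == 0


class TestClassifySignificance:
    @pytest.mark.parametrize(
        "p, expected", [(0.04, True), (0.05, False), (1.0, False), (0.0, True)]
    )
    def test_strict_threshold(self, p, expected):
        assert classify_significance(p) is expected

    def test_rejects_bad_p(self):
        with pytest.raises(ValueError):
            classify_significance(1.5)


class TestBuildConcordance:
    def test_conflicting_trials_give_trial_sig_only(self):
        # top trial clearly significant; opposing trial cancels the pool
        review = review_from_effects([(0.30, 0.12), (-0.28, 0.13)])
        rec = build_concordance(review)
        assert rec.trial_sig and not rec.meta_sig
        assert rec.agreement_class is AgreementClass.TRIAL_SIG_ONLY
        assert rec.i2 > 50.0

    def test_single_significant_trial(self):
        rec = build_concordance(review_from_effects([(-0.5, 0.1)]))
        assert rec.agreement_class is AgreementClass.SINGLE_TRIAL_SIG
        assert rec.weight_share == 1.0
        assert rec.trial_p == rec.meta_p

    def test_duplicated_trial_meta_p_not_larger(self):
        review = review_from_effects([(-0.3, 0.2), (-0.3, 0.2)])
        rec = build_concordance(review)
        assert rec.meta_y == pytest.approx(rec.trial_y, abs=1e-12)
        assert rec.meta_p <= rec.trial_p

    def test_directions_follow_declared_benefit(self):
        rec = build_concordance(review_from_effects([(-0.5, 0.1)]))
        assert rec.trial_direction is EffectDirection.FAVORS
        harm = review_from_effects([(0.5, 0.1)])
        assert build_concordance(harm).trial_direction is EffectDirection.AGAINST

    def test_review_id_attached_to_errors(self):
        bad = review_from_effects([(0.0, 0.0), (0.1, 0.5)], review_id="RBAD")
        with pytest.raises(Exception, match="RBAD"):
            build_concordance(bad)


class TestAgreementTable:
    def test_empty_input_zero_table(self):
        table = agreement_table([])
        assert table.total == 0
        assert (table.n11, table.n10, table.n01, table.n00) == (0, 0, 0, 0)

    def test_all_both_sig(self):
        recs = [
            build_concordance(review_from_effects(
                [(-0.5, 0.1), (-0.5, 0.12)], review_id=f"R{i}"))
            for i in range(3)
        ]
        table = agreement_table(recs)
        assert table.n11 == 3 and table.n10 == table.n01 == table.n00 == 0

    def test_total_matches_record_count(self, reference_records):
        table = agreement_table(reference_records)
        assert table.total == len(reference_records)


class TestConditionalRates:
    def test_zero_denominators_yield_none(self):
        from metaconcord.concordance import AgreementTable

        table = AgreementTable(
            n11=2, n10=1, n01=0, n00=0, n11_single=0, n00_single=0, alpha=0.05
        )
        rates = conditional_rates(table)
        assert rates.p_meta_sig_given_trial_nonsig is None
        assert rates.p_meta_sig_given_trial_sig == pytest.approx(2 / 3)

    def test_empty_table(self):
        rates = conditional_rates(agreement_table([]))
        assert rates.overall_agreement is None


class TestRankCorrelation:
    def _records(self, pairs, measure=Measure.RR):
        # choose the companion trial so the pooled estimate equals m exactly
        se_a, se_b = 0.1, 0.4
        w_a, w_b = se_a**-2, se_b**-2
        records = []
        for i, (t, m) in enumerate(pairs):
            y_b = (m * (w_a + w_b) - w_a * t) / w_b
            records.append(
                build_concordance(
                    review_from_effects(
                        [(t, se_a), (y_b, se_b)],
                        review_id=f"R{i}", measure=measure,
                    )
                )
            )
        return records

    def test_monotone_pairs(self):
        recs = self._records([(-0.4, -0.38), (-0.2, -0.19), (0.1, 0.12), (0.3, 0.31)])
        assert estimate_rank_correlation(recs, MeasureClass.RATIO) == pytest.approx(1.0)

    def test_reversed_order(self):
        recs = self._records([(-0.4, 0.4), (-0.2, 0.2), (0.1, -0.1), (0.3, -0.3)])
        assert estimate_rank_correlation(recs, MeasureClass.RATIO) == pytest.approx(-1.0)

    def test_one_swap_matches_brute_force(self):
        pairs = [(-0.4, -0.38), (-0.2, 0.05), (0.0, -0.18), (0.2, 0.22), (0.4, 0.45)]
        recs = self._records(pairs)
        got = estimate_rank_correlation(recs, MeasureClass.RATIO)
        expected = brute_spearman(
            [r.trial_y for r in recs], [r.meta_y for r in recs]
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_requires_three_records(self):
        with pytest.raises(ValueError):
            estimate_rank_correlation(self._records([(0.1, 0.1)]), MeasureClass.RATIO)

    def test_standardized_class_never_mixes_raw_scales(self):
        ratio = self._records([(-0.4, -0.4), (-0.2, -0.2)], Measure.RR)
        diff = self._records([(5.0, 5.0), (7.0, 7.0)], Measure.MD)
        rho = estimate_rank_correlation(
            ratio + diff, MeasureClass.POOLED_STANDARDIZED
        )
        assert -1.0 <= rho <= 1.0


class TestCiRelationship:
    def _pooled(self, estimate, lo, hi, scale=Scale.LOG):
        return PooledResult(
            estimate=estimate, y_pooled=math.log(estimate), se_pooled=0.1,
            ci_lower=lo, ci_upper=hi, p=0.5, model=PoolingModel.FIXED,
            weights=(1.0,), k=1, scale=scale,
        )

    def test_identical_intervals(self):
        trial = TrialEffect("t", Measure.RR, 1.0, 0.5, 2.0)
        rel = ci_relationship(trial, self._pooled(1.0, 0.5, 2.0))
        assert rel.contains_pooled_estimate and rel.intervals_overlap

    def test_disjoint_intervals(self):
        trial = TrialEffect("t", Measure.RR, 0.3, 0.2, 0.4)
        rel = ci_relationship(trial, self._pooled(2.0, 1.5, 3.0))
        assert not rel.contains_pooled_estimate and not rel.intervals_overlap

    def test_containment_with_overlap(self):
        trial = TrialEffect("t", Measure.RR, 1.0, 0.5, 2.0)
        rel = ci_relationship(trial, self._pooled(1.9, 1.8, 3.0))
        assert rel.contains_pooled_estimate and rel.intervals_overlap

    def test_scale_mismatch_rejected(self):
        trial = TrialEffect("t", Measure.MD, 0.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            ci_relationship(trial, self._pooled(1.0, 0.5, 2.0))


class TestDiscrepancyReport:
    def test_row_count_equals_n10(self, reference_records):
        table = agreement_table(reference_records)
        report = discrepancy_report(reference_records)
        assert len(report) == table.n10
        assert (report["i2"] > 0).all()
        assert list(report["review_id"]) == sorted(report["review_id"])

    def test_no_discordance_empty(self):
        recs = [build_concordance(review_from_effects([(-0.5, 0.1), (-0.5, 0.12)]))]
        assert discrepancy_report(recs).empty


class TestStratifyByWeight:
    def test_single_trial_corpus_one_stratum(self):
        recs = [
            build_concordance(review_from_effects([(-0.5, 0.1)], review_id=f"R{i}"))
            for i in range(4)
        ]
        strata = stratify_by_weight(recs)
        assert strata["high"].count == 4
        assert strata["low"].count == 0
        assert strata["low"].agreement_rate is None

    def test_threshold_zero_recovers_overall_agreement(self, reference_records):
        strata = stratify_by_weight(reference_records, threshold=0.0)
        assert strata["low"].count == 0
        table = agreement_table(reference_records)
        overall = conditional_rates(table).overall_agreement
        assert strata["high"].agreement_rate == pytest.approx(overall)

    def test_point_sets_cover_all_records(self, reference_records):
        strata = stratify_by_weight(reference_records)
        total_points = sum(len(s.estimate_points) for s in strata.values())
        assert total_points == len(reference_records)
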