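"""Truth matching, precision-recall curves, AUPRC and concordance partitions."""

import itertools

import numpy as np
import pytest

from vcfuse.evaluation import (
    EvalCurve,
    auprc,
    concordance_partition,
    mae_precision,
    match_to_reference,
    pr_curve,
    quality_hard_filter,
    rank_callset,
)
from vcfuse.io_merge import SNP, VariantKey, load_bed, merge_callsets

from conftest import make_callset, make_record


def k(pos, ref="A", alt="C"):
    return VariantKey("chr1", pos, ref, alt)


def brute_force_auprc(labels, denominator):
    """Independent integrator: walk the ranked labels, collect the
    (recall, precision) point at each true call by direct counting, and
    accumulate trapezoid slices from the recall-0 anchor."""
    points = []
    tp = 0
    for i, lab in enumerate(labels, start=1):
        tp += lab
        if lab == 1:
            points.append((tp / denominator, tp / i))
    if not points:
        return 0.0
    area = 0.0
    prev_r, prev_p = 0.0, points[0][1]
    for r, p in points:
        area += (r - prev_r) * (p + prev_p) / 2.0
        prev_r, prev_p = r, p
    return area


class TestMatchToReference:
    def test_set_arithmetic(self):
        labels, kept, denom = match_to_reference(
            [k(1), k(2)], {k(1), k(3)}
        )
        assert labels.tolist() == [1, 0]
        assert denom == 2

    def test_subset_call_set_is_all_tp(self):
        labels, _, denom = match_to_reference([k(1), k(3)], {k(1), k(2), k(3)})
        assert labels.tolist() == [1, 1]
        curve = pr_curve(labels, denom)
        assert np.all(curve.precision == 1.0)

    def test_confident_region_restriction(self, tmp_path):
        bed = tmp_path / "conf.bed"
        bed.write_text("chr1\t0\t100\n")  # covers pos 1..100 only
        labels, kept, denom = match_to_reference(
            [k(50), k(150)], {k(50), k(150), k(70)}, confident_regions=load_bed(bed)
        )
        assert kept.tolist() == [True, False]
        assert labels.tolist() == [1]
        assert denom == 2  # truth at 150 excluded from the denominator

    def test_empty_truth_in_region_fatal(self, tmp_path):
        bed = tmp_path / "conf.bed"
        bed.write_text("chr1\t0\t10\n")
        with pytest.raises(ValueError, match="no truth variants"):
            match_to_reference([k(5)], {k(500)}, confident_regions=load_bed(bed))

    def test_class_restricted_denominator(self):
        truth = {k(1), k(2, "AT", "A"), k(3)}
        _, _, denom = match_to_reference([k(1)], truth, variant_class=SNP)
        assert denom == 2

    def test_strict_genotype_mode(self):
        call_gt = {k(1): (0, 1)}
        truth_gt = {k(1): (1, 1)}
        labels, _, _ = match_to_reference(
            [k(1)], {k(1)}, call_genotypes=call_gt, truth_genotypes=truth_gt
        )
        assert labels.tolist() == [0]


class TestPrCurve:
    def test_worked_example(self):
        curve = pr_curve([1, 1, 0], 2)
        assert np.allclose(curve.precision, [1, 1, 2 / 3])
        assert np.allclose(curve.recall, [0.5, 1, 1])

    def test_all_false(self):
        curve = pr_curve([0, 0, 0], 5)
        assert np.all(curve.precision == 0)

    def test_interleaved(self):
        curve = pr_curve([1, 0, 1], 2)
        assert np.allclose(curve.precision, [1, 0.5, 2 / 3])
        assert np.allclose(curve.recall, [0.5, 0.5, 1])

    def test_recall_non_decreasing(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 100)
        curve = pr_curve(labels, max(int(labels.sum()), 1))
        assert np.all(np.diff(curve.recall) >= 0)


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc(pr_curve([1, 1, 0, 0], 2)) == pytest.approx(1.0)

    def test_worst_two_of_four(self):
        assert auprc(pr_curve([0, 0, 1, 1], 2)) == pytest.approx(0.375)

    def test_matches_brute_force_on_all_orderings_up_to_8(self):
        for n in range(1, 9):
            for labels in itertools.product([0, 1], repeat=n):
                denom = max(sum(labels), 1)
                got = auprc(pr_curve(list(labels), denom))
                expect = brute_force_auprc(list(labels), denom)
                assert got == pytest.approx(expect, abs=1e-12), labels

    def test_random_scores_give_prevalence(self):
        rng = np.random.default_rng(42)
        n = 4000
        labels = np.array([1] * (n // 2) + [0] * (n // 2))
        vals = []
        for _ in range(10):
            rng.shuffle(labels)
            vals.append(auprc(pr_curve(labels, n // 2)))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.03)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            labels = rng.integers(0, 2, 30)
            denom = max(int(labels.sum()), 1)
            v = auprc(pr_curve(labels, denom))
            assert 0.0 <= v <= 1.0

    def test_tie_block_permutation_stability(self):
        # permuting a tied block changes AUPRC by at most the block's own
        # contribution (width of the recall it spans)
        head, block, denom = [1, 1], [1, 0, 0, 1], 4
        areas = {
            auprc(pr_curve(head + list(p), denom))
            for p in itertools.permutations(block)
        }
        width = 2 / denom  # recall spanned by the block's true calls
        assert max(areas) - min(areas) <= width + 1e-12


class TestMae:
    def test_identical(self):
        assert mae_precision([0.5, 0.5], [0.5, 0.5]) == 0.0

    def test_constant_offset(self):
        assert mae_precision([1, 1], [0.5, 0.5]) == pytest.approx(0.5)

    def test_mixed(self):
        assert mae_precision([0.9, 0.8], [1.0, 0.6]) == pytest.approx(0.15)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            mae_precision([0.5], [0.5, 0.6])


class TestConcordancePartition:
    def make_table(self):
        callers = {
            "A": [1, 2, 3, 4, 5, 6, 7, 8, 100, 101],
            "B": [1, 2, 3, 4, 5, 6, 7, 8],
            "C": [1, 2, 3, 4, 5, 6, 7, 8],
            "D": [1, 2, 3, 4, 5, 6, 7, 8],
        }
        return merge_callsets(
            [make_callset(c, [make_record(k(p)) for p in ps])
             for c, ps in callers.items()]
        )

    def test_fractions(self):
        parts = concordance_partition(self.make_table())
        assert np.allclose(parts["all"], [0.2, 0, 0, 0.8])

    def test_sum_to_one(self):
        parts = concordance_partition(self.make_table())
        assert parts["all"].sum() == pytest.approx(1.0)

    def test_truth_split(self):
        truth = {k(p) for p in range(1, 9)}
        parts = concordance_partition(self.make_table(), truth)
        assert parts["true"].sum() == pytest.approx(1.0)
        assert parts["false"].sum() == pytest.approx(1.0)
        assert np.allclose(parts["true"], [0, 0, 0, 1.0])
        assert np.allclose(parts["false"], [1.0, 0, 0, 0])


class TestQualityHardFilter:
    def make_callset(self):
        return make_callset(
            "A",
            [make_record(k(1), qual=10), make_record(k(2), qual=30),
             make_record(k(3), qual=100)],
        )

    def test_threshold_30(self):
        assert len(quality_hard_filter(self.make_callset(), 30)) == 2

    def test_threshold_100(self):
        assert len(quality_hard_filter(self.make_callset(), 100)) == 1

    def test_threshold_0_is_identity(self):
        assert len(quality_hard_filter(self.make_callset(), 0)) == 3

    def test_missing_qual_dropped_with_warning(self):
        cs = make_callset("A", [make_record(k(1), qual=None)])
        with pytest.warns(UserWarning, match="missing QUAL"):
            assert len(quality_hard_filter(cs, 0)) == 0


def test_rank_callset_order():
    cs = make_callset(
        "A",
        [make_record(k(1), qual=10, depth=5),
         make_record(k(2), qual=50, depth=5),
         make_record(k(3), qual=50, depth=9)],
    )
    order = rank_callset(cs)
    assert [key.pos for key in order] == [3, 2, 1]
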