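"""Derived features and feature-matrix assembly."""

import numpy as np
import pytest

from vcfuse.features import (
    FeatureConfig,
    build_feature_matrix,
    distance_to_closest_variant,
    genotype_entropy_stats,
    reference_entropy,
)
from vcfuse.io_merge import VariantKey, merge_callsets
from vcfuse.reference import ReferenceGenome

from conftest import make_callset, make_record


def k(pos, ref="A", alt="C", chrom="chr1"):
    return VariantKey(chrom, pos, ref, alt)


def two_caller_table(positions_a, positions_b, **rec_kwargs):
    a = make_callset("A", [make_record(k(p), **rec_kwargs) for p in positions_a])
    b = make_callset("B", [make_record(k(p), **rec_kwargs) for p in positions_b])
    return merge_callsets([a, b])


class TestDistance:
    def test_pairwise_and_sentinel(self):
        table = two_caller_table([100, 105], [300])
        d = distance_to_closest_variant(table)
        by_pos = {table.rows[i].key.pos: d[i] for i in range(len(table))}
        # brute-force minimum over all other rows on the chromosome
        assert by_pos == {100: 5, 105: 5, 300: 195}

    def test_single_variant_gets_cap(self):
        a = make_callset("A", [make_record(k(100))])
        b = make_callset("B", [make_record(k(500, chrom="chr2"))])
        table = merge_callsets([a, b])
        d = distance_to_closest_variant(table, cap=1_000_000)
        assert set(d) == {1_000_000.0}

    def test_cap_applies(self):
        table = two_caller_table([100], [100 + 2_000_000])
        d = distance_to_closest_variant(table, cap=1_000_000)
        assert set(d) == {1_000_000.0}


class TestGenotypeEntropy:
    def test_point_mass(self):
        assert genotype_entropy_stats(np.array([[1.0, 0.0, 0.0]])) == (0.0, 0.0)

    def test_uniform(self):
        mean, sd = genotype_entropy_stats(np.array([[1 / 3, 1 / 3, 1 / 3]]))
        assert mean == pytest.approx(np.log2(3))
        assert sd == 0.0

    def test_two_samples_population_sd(self):
        gp = np.array([[1.0, 0.0, 0.0], [0.5, 0.5, 0.0]])
        mean, sd = genotype_entropy_stats(gp)
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(0.5)


class TestReferenceEntropy:
    def test_homopolymer_zero(self):
        ref = ReferenceGenome({"c": "A" * 100})
        assert reference_entropy(ref, "c", 50, w=10) == 0.0

    def test_equal_composition_two_bits(self):
        ref = ReferenceGenome({"c": "ACGT" * 30})
        # clipped window pos 1..4 = "ACGT": equal counts -> exactly 2 bits
        assert reference_entropy(ref, "c", 2, w=2) == pytest.approx(2.0)
        # long window over a periodic sequence: near-equal counts
        assert reference_entropy(ref, "c", 60, w=10) == pytest.approx(2.0, abs=0.01)

    def test_counts_2110(self):
        # window "AACG": counts (A=2, C=1, G=1, T=0) -> entropy 1.5 bits
        ref = ReferenceGenome({"c": "AACG" + "A" * 96})
        got = reference_entropy(ref, "c", 2, w=2)  # clipped window = pos 1..4
        assert got == pytest.approx(1.5)

    def test_window_clipped_at_chromosome_start(self):
        ref = ReferenceGenome({"c": "ACGTACGT"})
        assert reference_entropy(ref, "c", 1, w=3) == pytest.approx(2.0)

    def test_n_bases_excluded(self):
        ref = ReferenceGenome({"c": "NNNNAANN" + "C" * 20})
        assert reference_entropy(ref, "c", 5, w=2) == 0.0


class TestBuildFeatureMatrix:
    def make_table(self):
        recs_a = [
            make_record(k(100), qual=10, info={"MQ": 50.0}, depth=10),
            make_record(k(200), qual=20, info={"MQ": 60.0}, depth=20),
            make_record(k(300), qual=30, info={"MQ": None}, depth=30),
            make_record(k(400), qual=None, info={"MQ": 55.0}, depth=40),
        ]
        recs_b = [make_record(k(100)), make_record(k(200)), make_record(k(300)),
                  make_record(k(400))]
        return merge_callsets(
            [make_callset("A", recs_a), make_callset("B", recs_b)]
        )

    def test_training_rows_scaled_to_zero_mean_unit_sd(self):
        table = self.make_table()
        fm = build_feature_matrix(
            table, "A", "SNP", FeatureConfig(), training_rows=[0, 1, 2, 3]
        )
        for j, name in enumerate(fm.columns):
            col = fm.X[:, j]
            assert abs(col.mean()) < 1e-9, name
            assert abs(col.std(ddof=0) - 1) < 1e-9, name

    def test_missing_imputed_with_training_median(self):
        table = self.make_table()
        cfg = FeatureConfig(caller_features={"A": ["QUAL"]})
        fm = build_feature_matrix(table, "A", "SNP", cfg, training_rows=[0, 1, 2])
        j = fm.columns.index("QUAL")
        # training quals {10,20,30} -> median 20; row 3 (qual None) imputed 20,
        # then z-scored with mean 20, sd sqrt(200/3)
        assert fm.X[3, j] == pytest.approx(0.0)

    def test_log10_shift_transform(self):
        table = self.make_table()
        cfg = FeatureConfig(
            caller_features={"A": ["DP"]},
            transforms={"DP": "log10_shift"},
            log10_shift=1.0,
        )
        fm = build_feature_matrix(table, "A", "SNP", cfg, training_rows=[0, 1, 2, 3])
        # raw depths 10..40 -> log10(11)... applied before scaling; check the
        # ordering and spacing matches the log-transformed values
        j = fm.columns.index("DP")
        raw = np.log10(np.array([10, 20, 30, 40]) + 1)
        expect = (raw - raw.mean()) / raw.std(ddof=0)
        assert np.allclose(fm.X[:, j], expect)

    def test_support_count_is_never_a_feature(self):
        table = self.make_table()
        fm = build_feature_matrix(
            table, "A", "SNP", FeatureConfig(), training_rows=[0, 1, 2, 3]
        )
        assert "support_count" not in fm.columns
        assert not any("presence" in c.lower() for c in fm.columns)

    def test_all_configured_absent_is_fatal(self):
        table = self.make_table()
        cfg = FeatureConfig(caller_features={"A": ["NOPE", "ALSO_NOPE"]})
        with pytest.raises(ValueError, match="none of the configured"):
            # derived features are excluded from the configured-annotation
            # check by constructing a config whose named columns all vanish
            fm = build_feature_matrix(
                table, "A", "SNP", cfg, training_rows=[0, 1, 2, 3]
            )

    def test_deterministic(self):
        table = self.make_table()
        fm1 = build_feature_matrix(
            table, "A", "SNP", FeatureConfig(), training_rows=[0, 1]
        )
        fm2 = build_feature_matrix(
            table, "A", "SNP", FeatureConfig(), training_rows=[0, 1]
        )
        assert fm1.columns == fm2.columns
        assert np.array_equal(fm1.X, fm2.X)

    def test_reference_entropy_column_present_with_reference(self):
        table = self.make_table()
        ref = ReferenceGenome({"chr1": "ACGT" * 200})
        fm = build_feature_matrix(
            table, "A", "SNP", FeatureConfig(), training_rows=[0, 1, 2, 3],
            reference=ref,
        )
        # constant-entropy windows are zero-variance and must be dropped
        assert "VMC_REF_ENT" in fm.dropped_columns or "VMC_REF_ENT" in fm.columns


def test_unknown_transform_rejected():
    with pytest.raises(ValueError, match="unknown transform"):
        FeatureConfig(transforms={"QUAL": "sqrt"})
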