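"""The synthetic truth/call-set generator."""

import numpy as np
import pytest

from vcfuse.io_merge import INDEL, SNP, merge_callsets, normalize_callset
from vcfuse.synthetic import (
    CallerProfile,
    TruthModel,
    default_profiles,
    generate_reference,
    simulate_bundle,
    simulate_callsets,
    simulate_truth,
)


class TestGenerateReference:
    def test_deterministic(self):
        r1 = generate_reference(2000, seed=3)
        r2 = generate_reference(2000, seed=3)
        assert r1.fetch("chr1", 1, 2000) == r2.fetch("chr1", 1, 2000)

    def test_base_frequencies_near_uniform(self):
        seq = generate_reference(40_000, seed=1).fetch("chr1", 1, 40_000)
        n = len(seq)
        sigma = np.sqrt(n * 0.25 * 0.75)
        for b in "ACGT":
            assert abs(seq.count(b) - 0.25 * n) < 3 * sigma

    def test_repeat_tract_present(self):
        ref = generate_reference(2000, seed=2, repeat_tracts=[("CAG", 12)])
        assert "CAG" * 12 in ref.fetch("chr1", 1, 2000)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            generate_reference(10, seed=0)


class TestSimulateTruth:
    def test_deterministic_per_seed(self):
        m = TruthModel(reference_length=30_000, n_sites=100, n_samples=3, seed=5)
        t1, t2 = simulate_truth(m), simulate_truth(m)
        assert [v.key for v in t1.variants] == [v.key for v in t2.variants]
        assert all(
            np.array_equal(a.genotypes, b.genotypes)
            for a, b in zip(t1.variants, t2.variants)
        )

    def test_class_counts_match_fraction(self):
        m = TruthModel(reference_length=60_000, n_sites=200, snp_fraction=0.8,
                       n_samples=2, seed=1)
        truth = simulate_truth(m)
        n_snp = sum(v.variant_class == SNP for v in truth.variants)
        assert n_snp == 160

    def test_sites_non_overlapping(self):
        m = TruthModel(reference_length=60_000, n_sites=300, n_samples=2, seed=2)
        truth = simulate_truth(m)
        positions = sorted(v.key.pos for v in truth.variants)
        assert min(np.diff(positions)) >= m.min_site_gap

    def test_hardy_weinberg_het_fraction(self):
        # frequency pinned at 0.5, many samples: het fraction ~ 2pq = 0.5
        m = TruthModel(
            reference_length=30_000, n_sites=60, n_samples=1000,
            freq_low=0.4999, freq_high=0.5001, seed=3,
        )
        truth = simulate_truth(m)
        gts = np.vstack([v.genotypes for v in truth.variants])
        het = float((gts == 1).mean())
        sigma = np.sqrt(0.5 * 0.5 / gts.size)
        assert abs(het - 0.5) < 4 * sigma

    def test_monomorphic_sites_absent_from_polymorphic_truth(self):
        m = TruthModel(
            reference_length=30_000, n_sites=200, n_samples=1,
            freq_low=0.05, freq_high=0.2, seed=4,
        )
        truth = simulate_truth(m)
        mono = [v for v in truth.variants if not v.genotypes.any()]
        assert mono  # at low frequency with one sample some must be empty
        assert all(v.key not in truth.truth_keys() for v in mono)


class TestSimulateCallsets:
    def make_truth(self, n_samples=3, seed=9):
        m = TruthModel(reference_length=80_000, n_sites=300, snp_fraction=0.8,
                       n_samples=n_samples, seed=seed)
        return simulate_truth(m)

    def test_label_map_exhaustive(self):
        truth = self.make_truth()
        callsets, labels = simulate_callsets(truth, default_profiles(4), 9)
        for cs in callsets:
            assert set(cs.records) == set(labels[cs.caller_id])

    def test_rho_one_gives_full_concordance(self):
        truth = self.make_truth()
        profiles = default_profiles(4)
        for p in profiles:
            p.rho = 1.0
            p.false_rate = {SNP: 0.0, INDEL: 0.0}
        callsets, labels = simulate_callsets(truth, profiles, 11)
        table = merge_callsets(callsets)
        assert set(table.support_counts()) == {4}

    def test_false_calls_are_private_singletons(self):
        truth = self.make_truth()
        callsets, labels = simulate_callsets(truth, default_profiles(4), 9)
        table = merge_callsets(callsets)
        false_keys = {
            key for lm in labels.values() for key, lab in lm.items() if not lab
        }
        for row in table.rows:
            if row.key in false_keys:
                assert row.support_count == 1

    def test_rho_zero_independence_closed_form(self):
        # P(support = N | detected at least once) = s^N / (1 - (1-s)^N)
        m = TruthModel(reference_length=300_000, n_sites=2500, snp_fraction=1.0,
                       n_samples=2, seed=13, freq_low=0.3, freq_high=0.9)
        truth = simulate_truth(m)
        s, n_callers = 0.7, 3
        profiles = default_profiles(n_callers)
        for p in profiles:
            p.rho = 0.0
            p.sensitivity = {SNP: s, INDEL: s}
            p.false_rate = {SNP: 0.0, INDEL: 0.0}
        callsets, _ = simulate_callsets(truth, profiles, 21)
        table = merge_callsets(callsets)
        support = table.support_counts()
        frac_full = float((support == n_callers).mean())
        expect = s ** n_callers / (1 - (1 - s) ** n_callers)
        n = len(support)
        assert abs(frac_full - expect) < 4 * np.sqrt(expect * (1 - expect) / n)

    def test_seed_determinism(self):
        truth = self.make_truth()
        cs1, l1 = simulate_callsets(truth, default_profiles(3), 5)
        cs2, l2 = simulate_callsets(truth, default_profiles(3), 5)
        for a, b in zip(cs1, cs2):
            assert set(a.records) == set(b.records)
            for key in a.records:
                assert a.records[key].qual == b.records[key].qual

    def test_annotations_separate_true_from_false(self):
        truth = self.make_truth()
        callsets, labels = simulate_callsets(truth, default_profiles(4), 9)
        cs = callsets[0]
        lm = labels[cs.caller_id]
        mq_true = [r.info["MQ"] for k, r in cs.records.items() if lm[k]]
        mq_false = [r.info["MQ"] for k, r in cs.records.items() if not lm[k]]
        assert np.mean(mq_true) > np.mean(mq_false)

    def test_fewer_than_two_profiles_rejected(self):
        truth = self.make_truth()
        with pytest.raises(ValueError, match="at least 2"):
            simulate_callsets(truth, default_profiles(4)[:1], 9)

    def test_normalized_callsets_keep_labels_resolvable(self):
        # left-aligning the emulated calls must not collide distinct sites
        truth = self.make_truth()
        callsets, labels = simulate_callsets(truth, default_profiles(4), 9)
        for cs in callsets:
            norm = normalize_callset(cs, truth.reference)
            assert len(norm) == len(cs)


class TestBundle:
    def test_bundle_roundtrip(self, tmp_path):
        from vcfuse.io_merge import read_callset
        from vcfuse.reference import ReferenceGenome

        model = TruthModel(reference_length=30_000, n_sites=80, n_samples=2,
                           seed=6)
        manifest = simulate_bundle(tmp_path, model, default_profiles(2))
        ref = ReferenceGenome.from_fasta(manifest["paths"]["reference"])
        for cid, path in manifest["paths"]["callers"].items():
            cs = read_callset(path, cid, reference=ref)
            assert len(cs) > 0
        truth_cs = read_callset(manifest["paths"]["truth"], "truth")
        assert len(truth_cs) > 0
        assert (tmp_path / "manifest.yaml").exists()
        assert (tmp_path / "labels.tsv").exists()

    def test_bundle_deterministic(self, tmp_path):
        model = TruthModel(reference_length=30_000, n_sites=80, n_samples=2,
                           seed=6)
        m1 = simulate_bundle(tmp_path / "a", model, default_profiles(2))
        m2 = simulate_bundle(tmp_path / "b", model, default_profiles(2))
        t1 = (tmp_path / "a" / "callerA.vcf").read_text()
        t2 = (tmp_path / "b" / "callerA.vcf").read_text()
        assert t1 == t2
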