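import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vcfuse.io_merge import CallerCallSet, CallerRecord, VariantKey
from vcfuse.reference import ReferenceGenome

settings.register_profile(
    "fixed",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


def make_record(key, qual=30.0, info=None, gp=None, depth=10.0, n_samples=1):
    if gp is None:
        gp = np.tile([1.0, 0.0, 0.0], (n_samples, 1))
    return CallerRecord(
        key=key, qual=qual, info=dict(info or {}), genotype_probs=np.asarray(gp),
        depth=depth,
    )


def make_callset(caller_id, records, samples=("S0",)):
    cs = CallerCallSet(caller_id=caller_id, samples=list(samples))
    for rec in records:
        cs.add(rec)
    return cs


def splice(seq: str, pos: int, ref: str, alt: str) -> str:
    """Alternate haplotype from substituting alt for ref at 1-based pos."""
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def minimal_representation(seq: str, pos: int, ref: str, alt: str):
    """Independent oracle: exhaustively enumerate every (pos, ref, alt)
    producing the identical alternate haplotype; return the shortest
    (parsimonious) alleles, then the smallest pos — the canonical
    left-aligned form."""
    target = splice(seq, pos, ref, alt)
    delta = len(alt) - len(ref)
    best = None
    for p in range(1, len(seq) + 1):
        for lr in range(1, len(seq) - p + 2):
            la = lr + delta
            if la < 1 or p - 1 + lr > len(seq):
                continue
            r = seq[p - 1 : p - 1 + lr]
            a = target[p - 1 : len(target) - (len(seq) - (p - 1 + lr))]
            if len(a) != la or r == a:
                continue
            if splice(seq, p, r, a) == target:
                cand = (lr, p, r, a)
                if best is None or cand < best:
                    best = cand
    assert best is not None
    return VariantKey("chrom", best[1], best[2], best[3])


@pytest.fixture
def toy_reference():
    #            1234567890123456789012345678
    seq = "GGTCACACAGTTACGTACGTAAAATTTTCCGG" * 4
    return ReferenceGenome({"chr1": seq, "chr2": "ACGT" * 300})


@pytest.fixture(scope="session")
def small_sim():
    """Small synthetic benchmark shared by labeling/pipeline tests."""
    from vcfuse.synthetic import (
        TruthModel,
        default_profiles,
        simulate_callsets,
        simulate_truth,
    )

    model = TruthModel(
        reference_length=60_000, n_sites=400, snp_fraction=0.8, n_samples=4,
        seed=7,
    )
    truth = simulate_truth(model)
    callsets, labels = simulate_callsets(truth, default_profiles(4), 7)
    return truth, callsets, labels
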