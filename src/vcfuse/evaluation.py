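"""Benchmarking scored call sets against a truth set.

Matching is exact on the normalized (chrom, pos, ref, alt) key, restricted
to confident regions when supplied.  Precision-recall curves are computed
at every threshold index of the ranked call list; AUPRC uses trapezoid
integration over the recall levels where a true call enters, anchored at
recall 0 with the first such point's precision.  Genotype agreement is not
required for a true-positive (site/allele discovery is what is scored); a
strict-genotype mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from vcfuse.io_merge import (
    CallerCallSet,
    MergedVariantTable,
    VariantKey,
    classify_variant,
    in_regions,
)


@dataclass
class EvalCurve:
    labels: np.ndarray       # 1 = true positive, 0 = false positive, in rank order
    precision: np.ndarray    # at each threshold index
    recall: np.ndarray
    denominator: int         # truth variants in-region (recall denominator)

    @property
    def auprc(self) -> float:
        return auprc(self)


def match_to_reference(
    keys,
    truth_keys,
    confident_regions=None,
    variant_class: str | None = None,
    call_genotypes: dict | None = None,
    truth_genotypes: dict | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Label each call TP/FP against a truth key set.

    ``keys`` is an ordered sequence of (normalized) :class:`VariantKey`;
    ``truth_keys`` an iterable of truth keys.  Calls and truth variants
    outside the confident regions are dropped (calls via the returned
    keep-mask, truth from the recall denominator).  ``variant_class``
    restricts the truth denominator to SNP or INDEL.  With both genotype
    maps given, a TP additionally requires identical genotype tuples.

    Returns ``(labels, kept_mask, denominator)`` where ``labels`` aligns
    with the kept calls.
    """
    truth = set(truth_keys)
    if variant_class is not None:
        truth = {k for k in truth if classify_variant(k) == variant_class}
    truth_in_region = {
        k for k in truth if in_regions(confident_regions, k.chrom, k.pos)
    }
    if truth and not truth_in_region:
        raise ValueError("no truth variants fall inside the confident regions")

    kept = np.array(
        [in_regions(confident_regions, k.chrom, k.pos) for k in keys], dtype=bool
    )
    labels = []
    for k, keep in zip(keys, kept):
        if not keep:
            continue
        tp = k in truth_in_region
        if tp and call_genotypes is not None and truth_genotypes is not None:
            tp = tuple(call_genotypes.get(k, ())) == tuple(truth_genotypes.get(k, ()))
        labels.append(1 if tp else 0)
    return np.array(labels, dtype=int), kept, len(truth_in_region)


def pr_curve(labels, denominator: int) -> EvalCurve:
    """Precision and recall at every threshold index of an ordered label
    vector (1 = true call)."""
    y = np.asarray(labels, dtype=int)
    if denominator <= 0:
        raise ValueError("recall denominator must be positive")
    idx = np.arange(1, y.size + 1, dtype=float)
    tp = np.cumsum(y)
    return EvalCurve(
        labels=y,
        precision=tp / idx if y.size else np.array([]),
        recall=tp / denominator if y.size else np.array([]),
        denominator=denominator,
    )


def auprc(curve: EvalCurve) -> float:
    """Trapezoid area under precision over recall.

    Curve points are taken at the indices where recall increases (a true
    call enters), so duplicate-recall points contribute zero width; an
    anchor at recall 0 carries the first such point's precision.
    """
    tp_idx = np.flatnonzero(curve.labels == 1)
    if tp_idx.size == 0:
        return 0.0
    recalls = curve.recall[tp_idx]
    precisions = curve.precision[tp_idx]
    recalls = np.concatenate([[0.0], recalls])
    precisions = np.concatenate([[precisions[0]], precisions])
    return float(np.trapezoid(precisions, recalls))


def mae_precision(estimated, true) -> float:
    """Mean absolute error between estimated and true precision vectors
    along the same ordering."""
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(true, dtype=float)
    if est.shape != tru.shape:
        raise ValueError(
            f"length mismatch: estimated {est.shape} vs true {tru.shape}"
        )
    return float(np.mean(np.abs(est - tru)))


def concordance_partition(
    table: MergedVariantTable,
    truth_keys=None,
    variant_class: str | None = None,
) -> dict[str, np.ndarray]:
    """Fraction of variants called by exactly k callers, k = 1..N.

    With ``truth_keys`` the partition is additionally computed over true
    and over false calls separately.  Each returned vector sums to 1 over
    its own population (empty populations return zeros).
    """
    rows = table.rows
    if variant_class is not None:
        rows = [r for r in rows if r.variant_class == variant_class]
    n = table.n_callers

    def fractions(selected) -> np.ndarray:
        counts = np.zeros(n)
        for r in selected:
            counts[r.support_count - 1] += 1
        total = counts.sum()
        return counts / total if total > 0 else counts

    out = {"all": fractions(rows)}
    if truth_keys is not None:
        truth = set(truth_keys)
        out["true"] = fractions([r for r in rows if r.key in truth])
        out["false"] = fractions([r for r in rows if r.key not in truth])
    return out


def quality_hard_filter(
    callset: CallerCallSet, qual_threshold: float
) -> CallerCallSet:
    """Keep records with QUAL >= threshold; missing QUAL drops the record."""
    import warnings

    out = CallerCallSet(caller_id=callset.caller_id, samples=list(callset.samples))
    for key, rec in callset.records.items():
        if rec.qual is None:
            warnings.warn(f"{callset.caller_id}: missing QUAL at {key}, dropped")
            continue
        if rec.qual >= qual_threshold:
            out.records[key] = rec
    return out


def rank_callset(
    callset: CallerCallSet, score_field: str | None = None
) -> list[VariantKey]:
    """A call set's ranking: score desc, depth desc, coordinate asc.

    The score is QUAL by default; ``score_field`` names an INFO annotation
    to rank by instead (e.g. a fused-probability field on a scored VCF).
    """
    def sort_key(item):
        key, rec = item
        if score_field is not None:
            q = rec.info.get(score_field)
        else:
            q = rec.qual
        q = q if q is not None else -np.inf
        d = rec.depth if rec.depth is not None else -np.inf
        return (-q, -d, key.chrom, key.pos, key.ref, key.alt)

    return [k for k, _ in sorted(callset.records.items(), key=sort_key)]
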