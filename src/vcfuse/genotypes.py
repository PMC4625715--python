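"""Combined genotypes and the annotated output VCF.

Per sample, genotype-probability vectors from the callers that called a
variant are averaged and renormalized (a product-of-likelihoods combiner
is available behind a flag); the maximum-probability genotype becomes GT,
with ties resolved toward the lower genotype index.  The output VCF
carries every merged variant with the fused probability (VMC_PROB), the
running expected precision at its rank (VMC_EPREC), the support count
(VMC_SUP) and the calling callers (VMC_CALLERS); with a target precision
the FILTER column distinguishes PASS from LowPrecision.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np

from vcfuse.io_merge import MergedVariantTable
from vcfuse.precision import PrecisionCurve
from vcfuse.reference import ReferenceGenome


def combine_genotypes(
    caller_vectors: Sequence[np.ndarray], product: bool = False
) -> tuple[np.ndarray, int]:
    """Combine one sample's genotype-probability vectors across callers.

    Default: arithmetic mean then renormalize.  ``product=True`` multiplies
    the vectors (treating them as independent likelihoods) instead.
    Returns (combined 3-vector, argmax genotype index; ties -> lower index).
    """
    if not caller_vectors:
        raise ValueError("at least one caller must supply a genotype vector")
    vecs = np.asarray(list(caller_vectors), dtype=float)
    if product:
        combined = np.prod(vecs, axis=0)
        s = combined.sum()
        combined = combined / s if s > 0 else np.array([1.0, 0.0, 0.0])
    else:
        combined = vecs.mean(axis=0)
        combined = combined / combined.sum()
    gt = int(np.argmax(combined))  # argmax takes the first (lowest) maximum
    return combined, gt


def combine_genotype_block(
    table: MergedVariantTable, row_index: int, product: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """All-sample combined genotype probabilities for one merged variant."""
    row = table.rows[row_index]
    n_samples = len(table.samples)
    probs = np.zeros((n_samples, 3))
    gts = np.zeros(n_samples, dtype=int)
    for s in range(n_samples):
        vecs = [rec.genotype_probs[s] for rec in row.per_caller.values()]
        probs[s], gts[s] = combine_genotypes(vecs, product=product)
    return probs, gts


_GT_STRINGS = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def write_output_vcf(
    table: MergedVariantTable,
    p_svm: Sequence[float],
    curve: PrecisionCurve,
    sink: str | os.PathLike,
    reference: ReferenceGenome | None = None,
    target_precision: float | None = None,
    cutoff_index: int | None = None,
    product_genotypes: bool = False,
    provenance: dict | None = None,
) -> None:
    """Write the fused call set as a VCF 4.2 file.

    ``curve`` must have been computed from ``p_svm`` via
    :func:`vcfuse.precision.rank_variants` /
    :func:`vcfuse.precision.expected_precision_curve` so each variant's
    rank (and hence VMC_EPREC) is well defined.  With ``target_precision``
    and ``cutoff_index`` given, variants ranked within the cutoff are
    FILTER=PASS and the rest LowPrecision; otherwise FILTER is '.'.
    """
    import pysam

    p = np.asarray(p_svm, dtype=float)
    if len(p) != len(table.rows):
        raise ValueError("one fused probability per merged variant required")
    rank_of = np.empty(len(p), dtype=int)
    rank_of[curve.order] = np.arange(len(p))

    header = pysam.VariantHeader()
    header.add_line("##source=vcfuse")
    for key, value in (provenance or {}).items():
        header.add_line(f"##vcfuse_{key}={value}")
    chroms: dict[str, int] = {}
    for row in table.rows:
        end = row.key.pos + len(row.key.ref)
        chroms[row.key.chrom] = max(chroms.get(row.key.chrom, 0), end)
    for chrom, min_len in chroms.items():
        length = reference.length(chrom) if reference is not None else min_len
        header.contigs.add(chrom, length=length)
    header.add_line(
        '##INFO=<ID=VMC_PROB,Number=1,Type=Float,Description='
        '"Fused SVM probability that the variant is real">'
    )
    header.add_line(
        '##INFO=<ID=VMC_EPREC,Number=1,Type=Float,Description='
        '"Expected precision of the call set truncated at this variant\'s rank">'
    )
    header.add_line(
        '##INFO=<ID=VMC_SUP,Number=1,Type=Integer,Description='
        '"Number of callers that called this variant">'
    )
    header.add_line(
        '##INFO=<ID=VMC_CALLERS,Number=.,Type=String,Description='
        '"Comma-joined ids of the calling callers">'
    )
    header.add_line(
        '##FILTER=<ID=LowPrecision,Description='
        '"Ranked below the requested expected-precision cutoff">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=GP,Number=G,Type=Float,Description='
        '"Combined genotype probabilities (hom-ref, het, hom-alt)">'
    )
    for s in table.samples:
        header.add_sample(s)

    vcf = pysam.VariantFile(str(sink), "w", header=header)
    for i, row in enumerate(table.rows):
        rec = vcf.new_record(
            contig=row.key.chrom,
            start=row.key.pos - 1,
            alleles=(row.key.ref, row.key.alt),
        )
        rank = int(rank_of[i])
        rec.info["VMC_PROB"] = round(float(p[i]), 6)
        rec.info["VMC_EPREC"] = round(float(curve.e_prec[rank]), 6)
        rec.info["VMC_SUP"] = row.support_count
        # written comma-joined in the VCF body
        rec.info["VMC_CALLERS"] = tuple(
            c for c in table.caller_ids if c in row.per_caller
        )
        if target_precision is not None and cutoff_index is not None:
            rec.filter.add("PASS" if rank < cutoff_index else "LowPrecision")
        if table.samples:
            probs, gts = combine_genotype_block(table, i, product=product_genotypes)
            for s_idx, s in enumerate(table.samples):
                rec.samples[s]["GT"] = _GT_STRINGS[int(gts[s_idx])]
                rec.samples[s]["GP"] = tuple(
                    round(float(v), 4) for v in probs[s_idx]
                )
        vcf.write(rec)
    vcf.close()
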