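# vcfuse

Ensemble fusion of germline variant call sets with per-caller support
vector machines and quantitative, precision-based filtering.

## The problem

Variant callers run on the same samples disagree — and the disagreement
carries signal. A variant called by every caller is almost always real; a
variant private to one caller is strongly enriched for artefacts. Each
caller also emits annotations (quality, depth, mapping quality, bias
statistics) whose distributions differ between real variants and
artefacts, but choosing hard-filter thresholds on them is guesswork, and
recalibration approaches need genome-scale data and gold-standard
resources. `vcfuse` is for analyses of gene panels up to exomes — and for
organisms without curated truth sets — where neither works: it learns the
filtering from the call sets themselves.

## Method

Given N unfiltered call sets over the same samples, `vcfuse`:

1. splits records into biallelic units, left-aligns the alleles and
   merges everything into one table keyed by (chrom, pos, ref, alt);
2. labels variants called by ≥ t callers (t starting at N, decremented
   until every caller contributes) as positives and singly-called
   variants as negatives, separately for SNPs and indels — falling back
   to a one-class SVM when a caller has no singletons;
3. trains one RBF-kernel SVM per caller on that caller's annotations plus
   derived features (distance to the nearest variant, genotype-entropy
   statistics, local reference entropy), selecting (C, γ) by a two-level
   grid search under stratified 5-fold cross-validation and calibrating
   probabilities by Platt scaling;
4. fuses the per-caller probabilities with a fixed denominator,

       P_SVM(i) = (1/N) Σ_{j=1..N} Pr(y_ij = 1 | x_ij),

   a non-calling caller contributing 0;
5. ranks variants by P_SVM (ties: mean depth, then coordinate) and
   reports the running expected precision E_PREC(i) = (1/i) Σ_{j≤i}
   P_SVM(j) and expected FDR 1 − E_PREC, so a target precision translates
   directly into a cutoff with estimated TP/FP counts.

A synthetic-data module emulates truth sets and per-caller call sets with
controllable sensitivity, false-call rate, cross-caller concordance and
annotation separation, so the whole pipeline is testable offline. See
`docs/methods.md` for the full model description and design choices.

## Worked example

`examples/01_simulate_and_fuse.py` simulates four callers over a 60 kb
reference (400 candidate sites, 4 samples) and fuses them:

```
truth: 331 polymorphic variants; call sets: [349, 347, 350, 349]
SNP: threshold t=4, 257 positives, mode=two_class
INDEL: threshold t=4, 61 positives, mode=two_class
  callerA/SNP: C=2^-1.4 gamma=2^-7.2 CV accuracy 1.000
  ...
rank  variant                 support  P_SVM   E_PREC
   1  chr1:53936:T>A             4  0.9980  0.9980
   2  chr1:8141:A>T              4  0.9979  0.9979
```

P_SVM is the fused probability that the call is a real variant; E_PREC at
rank i is the expected precision of the call set truncated there, so
keeping the top i variants is expected to include E_PREC(i)·i true calls.
`examples/02_precision_filtering.py` turns target precisions into
cutoffs, and `examples/03_benchmark_against_truth.py` scores the fused
ranking against the simulated truth (AUPRC per class, calibration MAE,
concordance partition).

The same pipeline runs from the shell:

```
vcfuse simulate --out-dir bundle --seed 11
vcfuse fuse --vcf hc=bundle/callerA.vcf --vcf fb=bundle/callerB.vcf \
    --vcf st=bundle/callerC.vcf --vcf ug=bundle/callerD.vcf \
    --reference bundle/reference.fa --target-precision 0.95 \
    --out fused.vcf --curve-out curve.tsv
vcfuse evaluate --vcf fused=fused.vcf --truth bundle/truth.vcf \
    --reference bundle/reference.fa --out-prefix report
```

The output VCF annotates every merged variant with `VMC_PROB` (fused
probability), `VMC_EPREC` (expected precision at its rank), `VMC_SUP`
(support count) and `VMC_CALLERS`, plus combined GT/GP per sample; with
`--target-precision` the FILTER column separates PASS from LowPrecision.

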