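# Methods

## The problem

Different germline variant callers run on the same alignments disagree
substantially, and the disagreement is informative: a variant called by
every caller is almost always real, while variants private to a single
caller are strongly enriched for artefacts. At the same time each caller
emits a rich set of per-variant annotations (quality, depth, mapping
quality, bias statistics) whose joint distribution differs between real
variants and artefacts. `vcfuse` fuses both kinds of information: it
treats cross-caller concordance as a source of weak training labels and
the annotation vectors as features, learns one classifier per caller, and
combines the calibrated outputs into a single per-variant probability.

## Model and procedure

**Merge.** Each caller's unfiltered VCF is split into biallelic records;
multiallelic rows are split with `Number=A/R` INFO fields sliced by allele
index; MNP/complex records (equal-length multi-base alleles) and symbolic
alleles are dropped. Alleles are canonicalized by left alignment: shared
suffix bases are trimmed, the variant is shifted left through repeat
context when an allele would empty, and any shared prefix beyond the VCF
padding base is removed. Matching across callers is exact equality of the
normalized `(chrom, pos, ref, alt)` key. Within one caller duplicate keys
collapse to the higher QUAL.

**Weak labels.** For each variant class (SNPs and indels separately) a
threshold `t` starts at the number of callers `N` and is decremented until
the set of variants with support `>= t` is non-empty *and* every caller
called at least one of them; those variants are the positives. Negatives
for caller *j* are the variants *j* called that at most `singleton_max`
(default 1) callers found. If any caller has no negatives, all callers
fall back to a one-class SVM trained on positives only. The label
construction itself only requires the non-empty/all-contribute conditions;
the pipeline separately refuses to fit an SVM when a caller has fewer than
`min_positives` (default 10) positive examples, because a meaningful fit
below that is not possible.

**Features.** Per caller and class: QUAL, DP and every numeric INFO field
present in at least 50 % of that caller's records (or an explicit
per-caller list from the YAML config), plus three derived features —
distance to the closest variant in the merged table (capped at 1 Mb; the
cap doubles as the sentinel for a variant alone on its chromosome), mean
and population-SD across samples of the Shannon entropy of each sample's
genotype-probability distribution, and the Shannon entropy of reference
mononucleotide frequencies in a ±10 bp window. Entropies are in bits; any
fixed base is equivalent up to a scale factor that the z-scoring absorbs.
Genotype distributions come from PL, falling back to GL, then GP, then a
point mass on the called genotype. Columns may be transformed
(`identity`, `log10_shift`, `rank`), are median-imputed and z-scored with
statistics fitted on the training rows only; zero-variance columns are
dropped and recorded.

**Per-caller SVMs.** RBF-kernel support vector machines. (C, γ) are
selected by stratified 5-fold cross-validated accuracy on a two-level
grid: a coarse level with C = 2⁻⁵ … 2¹⁷ in steps of 2² (12 values) and
γ = 2⁻¹⁷ … 2³ in steps of 2² (11 values; 132 pairs), then a fine level in
steps of 2^0.2 spanning ±2² in exponent around the coarse optimum, clipped
to the coarse bounds. Ties in CV accuracy resolve to the smaller C, then
the smaller γ. The winning pair is refit on the whole training set with
Platt sigmoid calibration fitted through internal cross-validation
(`CalibratedClassifierCV(..., ensemble=False)`), so the final model sees
every training row. For speed the model *selection* runs on a stratified,
seed-deterministic subsample of at most 600 training rows; selection on a
subsample plus a full-data refit preserves the protocol while keeping the
grid search quadratic cost bounded. The subsample cap, grids, folds, seed
and the fine-grid half-width are all configurable.

In one-class mode a `OneClassSVM` (ν = 0.1, configurable) is trained on
positives only; γ is chosen from the coarse γ grid by maximizing the
fraction of held-out positives scored above 0.5 under 5-fold CV. One-class
decision values carry no probability semantics, so they are squashed to
[0, 1] by a logistic whose slope anchors the *median training decision
value* at 0.9 — a training inlier should look confidently real, the
decision boundary itself maps to 0.5, and far outliers go to 0. The anchor
is a design choice with no counterpart in a published recipe and is
exposed as a parameter.

**Fusion.** The fused score of variant *i* is

    P_SVM(i) = (1/N) Σ_{j=1..N} Pr(y_ij = 1 | x_ij),

with the sum over *all* N callers: a caller that did not call the variant
contributes 0. This fixed denominator penalizes low-support calls
consistently with the negative-label heuristic; averaging over calling
callers only is available behind `mean_over_calling`.

**Ranking and expected precision.** Variants are ordered by decreasing
P_SVM, then decreasing mean read depth (over calling callers), then
genomic coordinate as a deterministic final tie-break. Along the ordering

    E_PREC(i) = (1/i) Σ_{j<=i} P_SVM(j),      E_FDR(i) = 1 − E_PREC(i),

with TP(i) = Σ_{j<=i} P_SVM(j) and FP(i) = i − TP(i). A target precision
maps to the largest index where E_PREC still meets it; the output VCF
marks variants above that cutoff PASS. E_PREC is a running mean of a
non-increasing sequence and therefore non-increasing itself.

**Probability adjustment.** A monotone calibration map [0, 1] → [0, 1]
can be applied to the fused probabilities before ranking (identity by
default; monotonicity is verified on a probe grid, so ranks are
preserved). A least-squares utility fits an `a·exp(b·x) + c` map from a
labeled calibration run (expected vs realized precision along the same
ordering); no fitted constants ship with the package because they are
specific to a sequencing context.

**Combined genotypes.** Per sample, the genotype-probability vectors of
the calling callers are averaged and renormalized (product-of-likelihoods
behind a flag); the argmax genotype becomes GT, ties resolving to the
lower genotype index. Non-calling callers contribute nothing here — they
emit no genotype vector — in deliberate contrast to the fixed-N fusion
denominator.

**Evaluation.** A call is a true positive iff its normalized key occurs
in the (normalized) truth set; genotype agreement is not required by
default (site/allele discovery is what is scored) but a strict-genotype
mode exists. With a confident-region BED both the calls and the recall
denominator are restricted to the regions. Precision/recall are computed
at every threshold index; AUPRC integrates precision over recall by the
trapezoid rule using the points where recall increases (duplicate-recall
points contribute zero width) with an anchor at recall 0 carrying the
first such point's precision — the common convention, stated here because
conventions differ. Single-caller rankings use QUAL descending, then
depth, then coordinate. Hard quality filters (e.g. QUAL ≥ 30 or ≥ 100)
are provided for constructing comparison call sets.

## The synthetic benchmark

The generator emulates call sets at the variant/annotation level; it does
not simulate reads, alignment or the callers themselves, because the
package consumes VCFs. A uniform-random reference (optionally with
planted repeat tracts for normalization stress tests) carries
non-overlapping candidate sites, SNPs and indels in a configurable ratio;
each site has an allele frequency drawn Uniform(0.05, 0.5) and per-sample
genotypes drawn from Hardy-Weinberg, so rare sites can be monomorphic in
the sampled cohort (they stay in the truth model but leave the evaluable
truth set). Each true variant carries a latent quality u ~ U(0, 1);
caller *j* detects it iff ρ·u + (1−ρ)·ε_j exceeds 1 − sensitivity, which
couples detection across callers (ρ = 1: identical call sets; ρ = 0:
independent). False calls are caller-private, placed at random non-truth
sites at a per-class rate relative to the truth count. Annotations are
Gaussian with true/false means separated by d′ = 2; QUAL increases with u
for true calls and is low-but-overlapping for false calls, so each
caller's own QUAL ranking is informative but imperfect.

Default profile (4 callers): SNP sensitivity 0.95 and false-call rate
0.05, ρ = 0.8, genotype-error rate 0.02. Indels use sensitivity 0.85 and
false rate 0.15, chosen once to mirror the published observation that
indel concordance is far lower and indel false-call rates roughly an
order of magnitude higher than for SNPs. The default truth model has
2,200 candidate sites (2,000 SNP, 200 indel), 10 samples and a 300 kb
reference; this is the benchmark the acceptance script runs.

What passing on this generator does and does not show: it demonstrates
that the labeling heuristic, the per-caller SVMs, the fusion rule and the
expected-precision estimate behave correctly when the generator's
assumptions hold (Gaussian annotations, site-independent errors,
caller-private false calls, no linkage between sites, no systematic
region effects). Real call sets violate several of these — false calls
can recur across callers at alignment-difficult loci, annotations are
heavy-tailed and correlated, and error rates vary along the genome — so
benchmark numbers here do not predict performance on real data; they
validate the machinery.

## Numerical choices and degenerate inputs

- CV accuracy ties break to smaller C, then smaller γ; the fine grid is
  scanned in ascending order so the first optimum wins deterministically.
- The CV fold count drops (to no fewer than 2) with a warning when the
  smallest class cannot fill 5 folds.
- Genotype-probability vectors must sum to 1 within 1e-6 at construction.
- Left alignment stops shifting at position 1; a REF/FASTA mismatch is
  fatal rather than silently producing a wrong canonical key.
- An empty reference-entropy window (fully clipped or all-N) scores 0.
- Missing QUAL sorts last in single-caller rankings and drops the record
  in hard filtering, with a warning.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` chains and seeded scikit-learn splitters;
  a fixed seed gives bit-identical (C, γ) selections, probabilities and
  output files.

## Known limitations

- The quadratic SVM training cost makes whole-genome-scale input
  impractical without subsampling; the intended scale is gene panels to
  exomes.
- Weak labels are noisy by construction (some singletons are real); the
  method relies on the SVM tolerating label noise, and no iterative label
  refinement is implemented.
- Structural variants, symbolic alleles, breakends, phasing and
  multi-allelic re-joining on output are out of scope.
- Sample columns must match by name across callers; no reconciliation is
  attempted.
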