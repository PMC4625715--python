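"""Synthetic truth sets and emulated multi-caller call sets.

Emulation happens at the variant/annotation level, not the read level: the
package consumes VCFs, so what must be realistic is the structure of the
call sets, not the reads.  A diploid truth set is drawn over a random
reference (genotypes per site via Hardy-Weinberg from a site allele
frequency); each caller then detects true variants with a per-class
sensitivity, coupled across callers through a shared latent quality
u ~ U(0,1) mixed with caller-private noise (mixing weight rho: rho -> 1
makes callers agree, rho -> 0 makes them independent), and adds
caller-private false calls at random non-truth sites.  Annotations are
drawn from Gaussians whose parameters differ between true and false
calls; QUAL is correlated with u.  Every emitted record carries a known
truth label, so the labeling heuristic, the SVMs and the evaluation layer
can all be tested end to end without external data.
"""

from __future__ import annotations

import bisect
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from vcfuse.io_merge import (
    INDEL,
    SNP,
    CallerCallSet,
    CallerRecord,
    VariantKey,
    classify_variant,
)
from vcfuse.reference import ReferenceGenome

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Reference


def generate_reference(
    length: int,
    seed: int,
    chrom: str = "chr1",
    repeat_tracts: Sequence[tuple[str, int]] | None = None,
) -> ReferenceGenome:
    """Uniform random A/C/G/T sequence, deterministic per seed.

    ``repeat_tracts`` are (motif, copies) pairs spliced in at random
    positions — repeat context for exercising indel left-alignment.
    """
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    rng = np.random.default_rng(seed)
    seq = rng.choice(list(_BASES), size=length)
    if repeat_tracts:
        for motif, copies in repeat_tracts:
            tract = list(motif.upper() * copies)
            start = int(rng.integers(0, length - len(tract)))
            seq[start : start + len(tract)] = tract
    return ReferenceGenome({chrom: "".join(seq)})


# ---------------------------------------------------------------------------
# Truth model


@dataclass
class TruthModel:
    """Ground-truth generator settings.

    Allele frequencies are Uniform(freq_low, freq_high); indel lengths are
    geometric (p = indel_len_p) capped at indel_max_len, insertions and
    deletions equally likely.  Sites are placed non-overlapping with a
    safety gap.
    """

    reference_length: int = 300_000
    n_sites: int = 2200
    snp_fraction: float = 2000 / 2200
    n_samples: int = 10
    freq_low: float = 0.05
    freq_high: float = 0.5
    indel_max_len: int = 8
    indel_len_p: float = 0.5
    min_site_gap: int = 20
    chrom: str = "chr1"
    seed: int = 42

    def __post_init__(self):
        if not (0 <= self.freq_low < self.freq_high <= 1):
            raise ValueError("need 0 <= freq_low < freq_high <= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class TruthVariant:
    key: VariantKey
    variant_class: str
    frequency: float
    genotypes: np.ndarray  # per-sample alt-allele counts in {0, 1, 2}


@dataclass
class SimTruth:
    model: TruthModel
    reference: ReferenceGenome
    samples: list[str]
    variants: list[TruthVariant]  # every candidate site, monomorphic included

    def polymorphic(self) -> list[TruthVariant]:
        """Sites carried by at least one sample — the evaluable truth set."""
        return [v for v in self.variants if v.genotypes.any()]

    def truth_keys(self) -> set[VariantKey]:
        return {v.key for v in self.polymorphic()}


def _place_sites(rng, length, n_sites, gap, margin) -> list[int]:
    taken: list[int] = []
    max_tries = 50 * n_sites
    tries = 0
    while len(taken) < n_sites:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_sites} non-overlapping sites on a "
                f"{length} bp reference after {max_tries} tries"
            )
        pos = int(rng.integers(margin, length - margin))
        i = bisect.bisect_left(taken, pos)
        if i > 0 and pos - taken[i - 1] < gap:
            continue
        if i < len(taken) and taken[i] - pos < gap:
            continue
        taken.insert(i, pos)
    return taken


def simulate_truth(
    model: TruthModel, reference: ReferenceGenome | None = None
) -> SimTruth:
    """Draw the diploid truth set; deterministic per model seed."""
    rng = np.random.default_rng([model.seed, 17])
    if reference is None:
        reference = generate_reference(model.reference_length, model.seed,
                                       chrom=model.chrom)
    length = reference.length(model.chrom)
    margin = model.indel_max_len + model.min_site_gap
    positions = _place_sites(
        rng, length, model.n_sites, model.min_site_gap, margin
    )

    n_snps = int(round(model.n_sites * model.snp_fraction))
    classes = np.array([SNP] * n_snps + [INDEL] * (model.n_sites - n_snps))
    rng.shuffle(classes)

    samples = [f"S{i:02d}" for i in range(model.n_samples)]
    variants: list[TruthVariant] = []
    for pos, vclass in zip(positions, classes):
        ref_base = reference.base(model.chrom, pos)
        if vclass == SNP:
            alt = str(rng.choice([b for b in _BASES if b != ref_base]))
            key = VariantKey(model.chrom, pos, ref_base, alt)
        else:
            d = min(int(rng.geometric(model.indel_len_p)), model.indel_max_len)
            if rng.random() < 0.5:  # deletion
                ref = reference.fetch(model.chrom, pos, pos + d)
                key = VariantKey(model.chrom, pos, ref, ref_base)
            else:  # insertion
                ins = "".join(rng.choice(list(_BASES), size=d))
                key = VariantKey(model.chrom, pos, ref_base, ref_base + ins)
        freq = float(rng.uniform(model.freq_low, model.freq_high))
        genotypes = rng.binomial(2, freq, size=model.n_samples)
        variants.append(
            TruthVariant(
                key=key,
                variant_class=classify_variant(key),
                frequency=freq,
                genotypes=genotypes,
            )
        )
    return SimTruth(
        model=model, reference=reference, samples=samples, variants=variants
    )


# ---------------------------------------------------------------------------
# Caller profiles


def _default_annotations() -> dict[str, tuple[float, float, float, float]]:
    # name -> (mu_true, sd_true, mu_false, sd_false); separation d' = 2
    return {
        "MQ": (60.0, 5.0, 50.0, 5.0),
        "QD": (15.0, 3.0, 9.0, 3.0),
        "BQ": (30.0, 4.0, 22.0, 4.0),
    }


@dataclass
class CallerProfile:
    """Error and annotation model of one emulated caller."""

    caller_id: str
    sensitivity: dict[str, float] = field(
        default_factory=lambda: {SNP: 0.95, INDEL: 0.85}
    )
    false_rate: dict[str, float] = field(
        default_factory=lambda: {SNP: 0.05, INDEL: 0.15}
    )
    annotations: dict[str, tuple[float, float, float, float]] = field(
        default_factory=_default_annotations
    )
    rho: float = 0.8              # cross-caller concordance coupling
    genotype_error: float = 0.02
    seed_offset: int = 0

    def __post_init__(self):
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must lie in [0, 1]")
        for d in (self.sensitivity, self.false_rate):
            for v in d.values():
                if not 0 <= v <= 1:
                    raise ValueError("rates must lie in [0, 1]")


def default_profiles(n_callers: int = 4) -> list[CallerProfile]:
    if n_callers < 2:
        raise ValueError("at least 2 caller profiles are required")
    return [
        CallerProfile(caller_id=f"caller{chr(ord('A') + i)}", seed_offset=i)
        for i in range(n_callers)
    ]


# ---------------------------------------------------------------------------
# Call-set emulation


def _true_gp(genotype: int, u: float, rng) -> np.ndarray:
    conc = 0.80 + 0.18 * u
    gp = np.full(3, (1 - conc) / 2)
    gp[genotype] = conc
    return gp / gp.sum()


def _false_gp(carrier: bool) -> np.ndarray:
    return np.array([0.30, 0.60, 0.10]) if carrier else np.array([0.95, 0.04, 0.01])


def simulate_callsets(
    truth: SimTruth,
    profiles: Sequence[CallerProfile],
    master_seed: int,
    coverage: float = 30.0,
) -> tuple[list[CallerCallSet], dict[str, dict[VariantKey, bool]]]:
    """Emulate one call set per profile, with an exhaustive label map.

    True variant i carries a latent quality u_i ~ U(0,1); caller j detects
    it iff rho*u_i + (1-rho)*eps_ij > 1 - sensitivity.  False calls are
    caller-private: drawn at distinct random non-truth sites per caller at
    false_rate x (number of polymorphic truth variants of the class).
    Returns the call sets and {caller_id: {key: is_true}}.
    """
    if len(profiles) < 2:
        raise ValueError("at least 2 caller profiles are required")
    chrom = truth.model.chrom
    reference = truth.reference
    length = reference.length(chrom)
    poly = truth.polymorphic()
    rng_u = np.random.default_rng([master_seed, 101])
    u = rng_u.uniform(size=len(poly))

    used_positions = {v.key.pos for v in truth.variants}
    margin = truth.model.indel_max_len + 2
    rng_sites = np.random.default_rng([master_seed, 103])

    callsets: list[CallerCallSet] = []
    labels: dict[str, dict[VariantKey, bool]] = {}
    n_true = {
        SNP: sum(1 for v in poly if v.variant_class == SNP),
        INDEL: sum(1 for v in poly if v.variant_class == INDEL),
    }

    for profile in profiles:
        rng = np.random.default_rng([master_seed, 211, profile.seed_offset])
        cs = CallerCallSet(caller_id=profile.caller_id, samples=list(truth.samples))
        label_map: dict[VariantKey, bool] = {}

        # detections of true variants
        for i, var in enumerate(poly):
            eps = rng.uniform()
            signal = profile.rho * u[i] + (1 - profile.rho) * eps
            if signal <= 1 - profile.sensitivity[var.variant_class]:
                continue
            genotypes = var.genotypes.copy()
            for s in range(len(genotypes)):
                if rng.uniform() < profile.genotype_error:
                    choices = [g for g in (0, 1, 2) if g != genotypes[s]]
                    genotypes[s] = int(rng.choice(choices))
            gp = np.vstack([_true_gp(int(g), u[i], rng) for g in genotypes])
            qual = max(float(20 + 60 * u[i] + rng.normal(0, 5)), 0.01)
            dp = float(rng.poisson(coverage))
            info = {
                name: float(rng.normal(mu_t, sd_t))
                for name, (mu_t, sd_t, _, _) in profile.annotations.items()
            }
            info["DP"] = dp
            rec = CallerRecord(
                key=var.key, qual=qual, info=info, genotype_probs=gp, depth=dp
            )
            cs.add(rec)
            label_map[var.key] = True

        # caller-private false calls
        for vclass in (SNP, INDEL):
            n_false = int(round(profile.false_rate[vclass] * n_true[vclass]))
            placed = 0
            tries = 0
            while placed < n_false:
                tries += 1
                if tries > 200 * max(n_false, 1):
                    raise RuntimeError("could not place false-call sites")
                pos = int(rng_sites.integers(margin, length - margin))
                if any(abs(pos - q) < margin for q in
                       range(pos - margin, pos + margin) if q in used_positions):
                    continue
                used_positions.add(pos)
                ref_base = reference.base(chrom, pos)
                if vclass == SNP:
                    alt = str(rng.choice([b for b in _BASES if b != ref_base]))
                    key = VariantKey(chrom, pos, ref_base, alt)
                else:
                    d = min(int(rng.geometric(0.5)), truth.model.indel_max_len)
                    if rng.random() < 0.5:
                        ref = reference.fetch(chrom, pos, pos + d)
                        key = VariantKey(chrom, pos, ref, ref_base)
                    else:
                        ins = "".join(rng.choice(list(_BASES), size=d))
                        key = VariantKey(chrom, pos, ref_base, ref_base + ins)
                carrier = int(rng.integers(0, len(truth.samples)))
                gp = np.vstack(
                    [_false_gp(s == carrier) for s in range(len(truth.samples))]
                )
                w = rng.uniform()
                qual = max(float(30 * w + rng.normal(0, 5)), 0.01)
                dp = float(rng.poisson(coverage))
                info = {
                    name: float(rng.normal(mu_f, sd_f))
                    for name, (_, _, mu_f, sd_f) in profile.annotations.items()
                }
                info["DP"] = dp
                rec = CallerRecord(
                    key=key, qual=qual, info=info, genotype_probs=gp, depth=dp
                )
                cs.add(rec)
                label_map[key] = False
                placed += 1

        callsets.append(cs)
        labels[profile.caller_id] = label_map
    return callsets, labels


# ---------------------------------------------------------------------------
# VCF / bundle writers


def write_truth_vcf(truth: SimTruth, path: str | os.PathLike) -> None:
    """Polymorphic truth variants with per-sample GT, as plain VCF 4.2."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={truth.model.chrom},"
                 f"length={truth.reference.length(truth.model.chrom)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(truth.samples) + "\n")
        for v in sorted(truth.polymorphic(), key=lambda v: v.key.pos):
            gts = "\t".join(gt_str[int(g)] for g in v.genotypes)
            fh.write(
                f"{v.key.chrom}\t{v.key.pos}\t.\t{v.key.ref}\t{v.key.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def write_callset_vcf(
    callset: CallerCallSet,
    path: str | os.PathLike,
    reference: ReferenceGenome,
) -> None:
    """One emulated caller's output as plain VCF 4.2 with INFO + GT/PL/DP."""
    info_names = sorted(
        {n for rec in callset.records.values() for n in rec.info if n != "DP"}
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={callset.caller_id}\n")
        for chrom in reference.contigs():
            fh.write(f"##contig=<ID={chrom},length={reference.length(chrom)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        for name in info_names:
            fh.write(
                f'##INFO=<ID={name},Number=1,Type=Float,Description='
                f'"Simulated annotation {name}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PL,Number=G,Type=Integer,Description='
                 '"Phred-scaled genotype likelihoods">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(callset.samples) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
        for key in sorted(callset.records, key=lambda k: (k.chrom, k.pos, k.ref, k.alt)):
            rec = callset.records[key]
            parts = []
            if rec.depth is not None:
                parts.append(f"DP={int(rec.depth)}")
            for name in info_names:
                v = rec.info.get(name)
                if v is not None:
                    parts.append(f"{name}={v:.4f}")
            info_str = ";".join(parts) if parts else "."
            cols = []
            for s in range(len(callset.samples)):
                gp = np.clip(rec.genotype_probs[s], 1e-10, 1.0)
                pl = -10 * np.log10(gp)
                pl = np.round(pl - pl.min()).astype(int)
                gt = gt_str[int(np.argmax(gp))]
                cols.append(f"{gt}:{pl[0]},{pl[1]},{pl[2]}")
            qual = f"{rec.qual:.2f}" if rec.qual is not None else "."
            fh.write(
                f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t{qual}\t.\t"
                f"{info_str}\tGT:PL\t" + "\t".join(cols) + "\n"
            )


def simulate_bundle(
    outdir: str | os.PathLike,
    model: TruthModel | None = None,
    profiles: Sequence[CallerProfile] | None = None,
    seed: int | None = None,
    coverage: float = 30.0,
) -> dict:
    """Write a complete fixture bundle: reference FASTA, truth VCF, one VCF
    per emulated caller, a label TSV and a manifest with every parameter.

    Returns a manifest dict that includes the output paths.
    """
    import yaml

    model = model or TruthModel()
    if seed is not None:
        model.seed = seed
    profiles = list(profiles) if profiles is not None else default_profiles()
    os.makedirs(outdir, exist_ok=True)

    truth = simulate_truth(model)
    callsets, labels = simulate_callsets(truth, profiles, model.seed, coverage)

    ref_path = os.path.join(outdir, "reference.fa")
    truth.reference.to_fasta(ref_path)
    truth_path = os.path.join(outdir, "truth.vcf")
    write_truth_vcf(truth, truth_path)

    caller_paths = {}
    for cs in callsets:
        p = os.path.join(outdir, f"{cs.caller_id}.vcf")
        write_callset_vcf(cs, p, truth.reference)
        caller_paths[cs.caller_id] = p

    labels_path = os.path.join(outdir, "labels.tsv")
    with open(labels_path, "w") as fh:
        fh.write("caller\tchrom\tpos\tref\talt\tis_true\n")
        for caller_id, lm in labels.items():
            for key in sorted(lm, key=lambda k: (k.chrom, k.pos, k.ref, k.alt)):
                fh.write(
                    f"{caller_id}\t{key.chrom}\t{key.pos}\t{key.ref}\t"
                    f"{key.alt}\t{int(lm[key])}\n"
                )

    manifest = {
        "seed": model.seed,
        "coverage": coverage,
        "model": {k: getattr(model, k) for k in (
            "reference_length", "n_sites", "snp_fraction", "n_samples",
            "freq_low", "freq_high", "indel_max_len", "indel_len_p",
            "min_site_gap", "chrom", "seed",
        )},
        "profiles": [
            {
                "caller_id": p.caller_id,
                "sensitivity": p.sensitivity,
                "false_rate": p.false_rate,
                "rho": p.rho,
                "genotype_error": p.genotype_error,
                "seed_offset": p.seed_offset,
                "annotations": {k: list(v) for k, v in p.annotations.items()},
            }
            for p in profiles
        ],
        "paths": {
            "reference": ref_path,
            "truth": truth_path,
            "labels": labels_path,
            "callers": caller_paths,
        },
    }
    with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
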