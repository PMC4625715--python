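"""Reading, normalizing and merging per-caller VCF call sets.

Each caller contributes an unfiltered, possibly multi-sample VCF.  Records
are split into biallelic units, allele representations are canonicalized by
left alignment against the reference, and the call sets are merged into a
single table keyed by (chrom, pos, ref, alt) with per-caller provenance,
annotations and genotype-probability blocks.
"""

from __future__ import annotations

import logging
import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from vcfuse.reference import ReferenceGenome

log = logging.getLogger(__name__)

_BASES = frozenset("ACGTN")

SNP = "SNP"
INDEL = "INDEL"


@dataclass(frozen=True, order=True)
class VariantKey:
    """A biallelic variant: chromosome, 1-based position, REF and ALT."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        bad = (set(self.ref) | set(self.alt)) - _BASES
        if bad:
            raise ValueError(f"non-ACGTN characters {bad} in {self}")


@dataclass
class CallerRecord:
    """One biallelic call from one caller."""

    key: VariantKey
    qual: float | None
    info: dict[str, float | None]
    # shape (n_samples, 3): P(hom-ref), P(het), P(hom-alt) per sample
    genotype_probs: np.ndarray
    depth: float | None

    def __post_init__(self):
        gp = np.asarray(self.genotype_probs, dtype=float)
        if gp.ndim != 2 or gp.shape[1] != 3:
            raise ValueError("genotype_probs must have shape (n_samples, 3)")
        sums = gp.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("genotype probability vectors must sum to 1")
        self.genotype_probs = gp


@dataclass
class CallerCallSet:
    """All biallelic calls of a single caller, keyed by variant."""

    caller_id: str
    samples: list[str]
    records: dict[VariantKey, CallerRecord] = field(default_factory=dict)

    def add(self, record: CallerRecord) -> None:
        """Insert, collapsing duplicate keys by keeping the higher QUAL."""
        old = self.records.get(record.key)
        if old is not None:
            q_old = -math.inf if old.qual is None else old.qual
            q_new = -math.inf if record.qual is None else record.qual
            if q_new <= q_old:
                return
        self.records[record.key] = record

    def keys(self):
        return self.records.keys()

    def __len__(self):
        return len(self.records)


@dataclass
class MergedRow:
    key: VariantKey
    variant_class: str  # SNP or INDEL
    per_caller: dict[str, CallerRecord]

    @property
    def support_count(self) -> int:
        return len(self.per_caller)

    @property
    def mean_depth(self) -> float:
        depths = [r.depth for r in self.per_caller.values() if r.depth is not None]
        return float(np.mean(depths)) if depths else 0.0


@dataclass
class MergedVariantTable:
    """Unified variant table across callers, sorted by genomic coordinate."""

    caller_ids: list[str]
    samples: list[str]
    rows: list[MergedRow]

    @property
    def n_callers(self) -> int:
        return len(self.caller_ids)

    def __len__(self):
        return len(self.rows)

    def support_counts(self) -> np.ndarray:
        return np.array([r.support_count for r in self.rows], dtype=int)

    def mean_depths(self) -> np.ndarray:
        return np.array([r.mean_depth for r in self.rows], dtype=float)

    def class_indices(self, variant_class: str) -> np.ndarray:
        return np.array(
            [i for i, r in enumerate(self.rows) if r.variant_class == variant_class],
            dtype=int,
        )

    def caller_indices(self, caller_id: str) -> np.ndarray:
        return np.array(
            [i for i, r in enumerate(self.rows) if caller_id in r.per_caller],
            dtype=int,
        )

    def to_dataframe(self):
        """Tab-friendly debug view (key, class, support, presence, depth)."""
        import pandas as pd

        recs = []
        for r in self.rows:
            d = {
                "chrom": r.key.chrom,
                "pos": r.key.pos,
                "ref": r.key.ref,
                "alt": r.key.alt,
                "variant_class": r.variant_class,
                "support_count": r.support_count,
                "mean_depth": r.mean_depth,
            }
            for c in self.caller_ids:
                d[f"called_{c}"] = c in r.per_caller
            recs.append(d)
        return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Normalization


def left_align(key: VariantKey, reference: ReferenceGenome) -> VariantKey:
    """Canonical parsimonious, left-aligned representation of a variant.

    Shared suffix bases are trimmed while both alleles are longer than one
    base; when an allele would empty, both alleles are extended one
    reference base to the left (shifting the variant through repeat
    context); finally any shared prefix beyond the single VCF padding base
    is trimmed.  Idempotent.  Shifting stops at position 1.
    """
    chrom, pos, ref, alt = key.chrom, key.pos, key.ref, key.alt
    obs = reference.fetch(chrom, pos, pos + len(ref) - 1)
    if obs != ref:
        raise ValueError(
            f"REF mismatch at {chrom}:{pos}: VCF has {ref!r}, reference has {obs!r}"
        )

    while True:
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if len(ref) > 1 and len(alt) > 1:
                ref, alt = ref[:-1], alt[:-1]
            else:
                # one allele is a single base: shift left through the repeat
                if pos == 1:
                    break
                b = reference.base(chrom, pos - 1)
                ref, alt = b + ref[:-1], b + alt[:-1]
                pos -= 1
            continue
        break

    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    return VariantKey(chrom, pos, ref, alt)


def classify_variant(key: VariantKey) -> str:
    """SNP iff both alleles are single bases; INDEL iff lengths differ."""
    lr, la = len(key.ref), len(key.alt)
    if lr == 1 and la == 1:
        return SNP
    assert lr != la, f"MNP/complex record reached classify_variant: {key}"
    return INDEL


def normalize_callset(
    callset: CallerCallSet, reference: ReferenceGenome
) -> CallerCallSet:
    """Left-align every record; duplicate keys collapse by higher QUAL."""
    out = CallerCallSet(caller_id=callset.caller_id, samples=list(callset.samples))
    for rec in callset.records.values():
        k = left_align(rec.key, reference)
        out.add(
            CallerRecord(
                key=k,
                qual=rec.qual,
                info=dict(rec.info),
                genotype_probs=rec.genotype_probs,
                depth=rec.depth,
            )
        )
    return out


# ---------------------------------------------------------------------------
# BED regions


def load_bed(path: str | os.PathLike):
    """Read a BED file into per-chromosome interval trees (0-based half-open)."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end > start:
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def in_regions(regions, chrom: str, pos: int) -> bool:
    """1-based position membership in half-open BED intervals."""
    if regions is None:
        return True
    tree = regions.get(chrom)
    return bool(tree is not None and tree.overlaps_point(pos - 1))


# ---------------------------------------------------------------------------
# VCF reading


def _phred_probs(pl: Sequence[float]) -> np.ndarray | None:
    vals = np.array([v for v in pl], dtype=float)
    if np.any(~np.isfinite(vals)):
        return None
    w = np.power(10.0, -vals / 10.0)
    s = w.sum()
    if s <= 0:
        return None
    return w / s


def _gl_probs(gl: Sequence[float]) -> np.ndarray | None:
    vals = np.array([v for v in gl], dtype=float)
    if np.any(~np.isfinite(vals)):
        return None
    w = np.power(10.0, vals - vals.max())
    return w / w.sum()


def _genotype_triplet_indices(alt_index: int) -> tuple[int, int, int]:
    """Indices of (0/0, 0/k, k/k) in VCF's diploid genotype ordering."""
    k = alt_index + 1
    return (0, k * (k + 1) // 2, k * (k + 1) // 2 + k)


def _sample_genotype_probs(sample, alt_index: int, n_alts: int) -> np.ndarray:
    """Genotype probabilities for one sample, one alt allele.

    Preference order PL > GL > GP; otherwise a point mass on the called
    genotype (hom-ref if the call is missing).
    """
    i00, i0k, ikk = _genotype_triplet_indices(alt_index)
    n_geno = (n_alts + 1) * (n_alts + 2) // 2

    for field_name, conv in (("PL", _phred_probs), ("GL", _gl_probs), ("GP", None)):
        try:
            vals = sample.get(field_name)
        except (KeyError, ValueError):  # field not declared in the header
            vals = None
        if vals is None:
            continue
        vals = [v for v in vals]
        if len(vals) < n_geno or any(v is None for v in vals):
            continue
        if conv is None:
            triple = np.array([vals[i00], vals[i0k], vals[ikk]], dtype=float)
            s = triple.sum()
            if s <= 0:
                continue
            return triple / s
        full = conv(vals)
        if full is None:
            continue
        triple = full[[i00, i0k, ikk]]
        s = triple.sum()
        if s <= 0:
            continue
        return triple / s

    gt = sample.get("GT")
    alt_allele = alt_index + 1
    if gt is None or all(a is None for a in gt):
        n_alt_copies = 0
    else:
        n_alt_copies = sum(1 for a in gt if a == alt_allele)
    out = np.zeros(3)
    out[min(n_alt_copies, 2)] = 1.0
    return out


def _numeric(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, bool):
        return float(value)
    if isinstance(value, (int, float)):
        v = float(value)
        return v if math.isfinite(v) else None
    try:
        v = float(value)
        return v if math.isfinite(v) else None
    except (TypeError, ValueError):
        return None


def _slice_info(info_items, header_info, alt_index: int) -> dict[str, float | None]:
    """Numeric INFO values for one alt allele; Number=A/R sliced by index."""
    out: dict[str, float | None] = {}
    for name, value in info_items:
        meta = header_info.get(name)
        number = getattr(meta, "number", None)
        if getattr(meta, "type", None) == "Flag":
            out[name] = 1.0
            continue
        if isinstance(value, tuple):
            if number == "A":
                value = value[alt_index] if alt_index < len(value) else None
            elif number == "R":
                value = value[alt_index + 1] if alt_index + 1 < len(value) else None
            else:
                value = value[0] if len(value) == 1 else None
        if isinstance(value, str):
            continue  # non-numeric annotation
        out[name] = _numeric(value)  # None records a missing value
    return out


def read_callset(
    vcf_source: str | os.PathLike,
    caller_id: str,
    regions=None,
    reference: ReferenceGenome | None = None,
) -> CallerCallSet:
    """Read one caller's VCF into a :class:`CallerCallSet`.

    Multiallelic records are split into biallelic rows; symbolic alleles and
    MNP/complex records (equal-length multi-base alleles) are skipped with a
    warning.  ``regions`` (from :func:`load_bed`) restricts to target
    intervals.  If ``reference`` is given every key is left-aligned.
    """
    import pysam

    if isinstance(regions, (str, os.PathLike)):
        regions = load_bed(regions)

    vcf = pysam.VariantFile(str(vcf_source))
    samples = list(vcf.header.samples)
    out = CallerCallSet(caller_id=caller_id, samples=samples)

    for rec in vcf:
        if rec.alts is None:
            continue
        if not in_regions(regions, rec.chrom, rec.pos):
            continue
        n_alts = len(rec.alts)
        info_items = list(rec.info.items())
        for alt_index, alt in enumerate(rec.alts):
            if alt is None:
                continue
            if alt in ("*", ".") or alt.startswith("<") or "[" in alt or "]" in alt:
                warnings.warn(
                    f"{caller_id}: skipping symbolic ALT {alt!r} at "
                    f"{rec.chrom}:{rec.pos}"
                )
                continue
            ref = rec.ref.upper()
            alt = alt.upper()
            if (set(ref) | set(alt)) - _BASES or ref == alt:
                warnings.warn(
                    f"{caller_id}: skipping unparseable alleles {ref}>{alt} at "
                    f"{rec.chrom}:{rec.pos}"
                )
                continue
            if len(ref) == len(alt) and len(ref) > 1:
                warnings.warn(
                    f"{caller_id}: dropping MNP/complex record {ref}>{alt} at "
                    f"{rec.chrom}:{rec.pos}"
                )
                continue

            gp = np.vstack(
                [
                    _sample_genotype_probs(rec.samples[s], alt_index, n_alts)
                    for s in samples
                ]
            ) if samples else np.zeros((0, 3))

            try:
                depth = _numeric(rec.info.get("DP"))
            except (KeyError, ValueError):  # DP absent from the header
                depth = None
            if depth is None and samples:
                dps = [
                    _numeric(rec.samples[s].get("DP"))
                    for s in samples
                ]
                dps = [d for d in dps if d is not None]
                depth = float(np.mean(dps)) if dps else None

            key = VariantKey(rec.chrom, rec.pos, ref, alt)
            if reference is not None:
                key = left_align(key, reference)
            out.add(
                CallerRecord(
                    key=key,
                    qual=_numeric(rec.qual),
                    info=_slice_info(info_items, vcf.header.info, alt_index),
                    genotype_probs=gp,
                    depth=depth,
                )
            )
    vcf.close()
    return out


# ---------------------------------------------------------------------------
# Merge


def merge_callsets(callsets: Sequence[CallerCallSet]) -> MergedVariantTable:
    """Union the (normalized) call sets into one table with provenance.

    Requires at least two call sets sharing the same sample names.
    """
    if len(callsets) < 2:
        raise ValueError(
            f"at least 2 caller call sets are required for fusion, got {len(callsets)}"
        )
    ids = [cs.caller_id for cs in callsets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate caller ids: {ids}")
    samples = callsets[0].samples
    for cs in callsets[1:]:
        if cs.samples != samples:
            raise ValueError(
                f"sample columns differ between callers "
                f"({callsets[0].caller_id}: {samples} vs {cs.caller_id}: {cs.samples})"
            )

    by_key: dict[VariantKey, dict[str, CallerRecord]] = {}
    for cs in callsets:
        for key, rec in cs.records.items():
            by_key.setdefault(key, {})[cs.caller_id] = rec

    rows = [
        MergedRow(key=key, variant_class=classify_variant(key), per_caller=pc)
        for key, pc in by_key.items()
    ]
    rows.sort(key=lambda r: (r.key.chrom, r.key.pos, r.key.ref, r.key.alt))
    return MergedVariantTable(caller_ids=ids, samples=list(samples), rows=rows)
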