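"""Per-caller feature matrices.

Each caller's SVM sees the annotations that caller emitted (QUAL, DP, MQ
and any sufficiently present numeric INFO field) plus three features
derived here: distance to the closest variant in the merged table, the
mean and SD of the per-sample genotype-distribution entropy, and the
Shannon entropy of the reference sequence around the variant.  Columns are
median-imputed and z-scored with statistics fitted on the training rows
only, so the scaler never sees rows it will later be asked to score as if
unseen.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from vcfuse.io_merge import MergedVariantTable
from vcfuse.reference import ReferenceGenome

log = logging.getLogger(__name__)

DERIVED_FEATURES = (
    "VMC_DIST",      # bases to the closest other variant
    "VMC_GT_ENT_MEAN",
    "VMC_GT_ENT_SD",
    "VMC_REF_ENT",
)

_TRANSFORMS = ("identity", "log10_shift", "rank")


@dataclass
class FeatureConfig:
    """Which annotations feed each caller's SVM and how they are prepared.

    ``caller_features`` maps caller id to an explicit annotation list; a
    missing entry means automatic selection (QUAL, DP plus every numeric
    INFO field present in at least ``min_presence`` of that caller's
    records).  ``transforms`` maps feature name to one of ``identity``,
    ``log10_shift`` or ``rank``.  ``entropy_window`` is the half-width w of
    the reference-entropy window; ``distance_cap`` bounds the
    closest-variant distance.
    """

    caller_features: dict[str, list[str]] = field(default_factory=dict)
    transforms: dict[str, str] = field(default_factory=dict)
    log10_shift: float = 1.0
    entropy_window: int = 10
    distance_cap: int = 1_000_000
    min_presence: float = 0.5

    def __post_init__(self):
        if self.entropy_window < 1:
            raise ValueError("entropy_window must be >= 1")
        for name, t in self.transforms.items():
            if t not in _TRANSFORMS:
                raise ValueError(
                    f"unknown transform {t!r} for {name!r}; "
                    f"supported: {_TRANSFORMS}"
                )

    @classmethod
    def from_yaml(cls, path) -> "FeatureConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class FeatureMatrix:
    caller_id: str
    variant_class: str
    row_indices: np.ndarray          # indices into MergedVariantTable.rows
    columns: list[str]
    X: np.ndarray                    # scaled values, no missing entries
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    impute_median: np.ndarray
    dropped_columns: list[str]

    def positions_of(self, table_rows: np.ndarray) -> np.ndarray:
        """Positions inside this matrix of the given table row indices."""
        lookup = {int(r): i for i, r in enumerate(self.row_indices)}
        return np.array([lookup[int(r)] for r in table_rows], dtype=int)


# ---------------------------------------------------------------------------
# Derived features


def distance_to_closest_variant(
    table: MergedVariantTable, cap: int = 1_000_000
) -> np.ndarray:
    """Per-row distance (bp) to the nearest other variant on the same
    chromosome, capped at ``cap``; ``cap`` when the variant is alone."""
    dist = np.full(len(table.rows), float(cap))
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, r in enumerate(table.rows):
        by_chrom.setdefault(r.key.chrom, []).append((r.key.pos, i))
    for entries in by_chrom.values():
        entries.sort()
        pos = np.array([p for p, _ in entries], dtype=float)
        idx = np.array([i for _, i in entries], dtype=int)
        if len(pos) < 2:
            continue
        gaps = np.diff(pos)
        left = np.concatenate([[np.inf], gaps])
        right = np.concatenate([gaps, [np.inf]])
        dist[idx] = np.minimum(np.minimum(left, right), float(cap))
    return dist


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def genotype_entropy_stats(genotype_probs: np.ndarray) -> tuple[float, float]:
    """Mean and population SD across samples of the Shannon entropy (bits)
    of each sample's genotype distribution."""
    gp = np.asarray(genotype_probs, dtype=float)
    if gp.size == 0:
        return 0.0, 0.0
    ents = np.array([_entropy_bits(row) for row in gp])
    return float(ents.mean()), float(ents.std(ddof=0))


def reference_entropy(
    reference: ReferenceGenome, chrom: str, pos: int, w: int = 10
) -> float:
    """Shannon entropy (bits) of mononucleotide frequencies in the window
    [pos-w, pos+w], clipped to the chromosome; N bases excluded."""
    window = reference.fetch(chrom, pos - w, pos + w)
    counts = np.array([window.count(b) for b in "ACGT"], dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    return _entropy_bits(counts / total)


# ---------------------------------------------------------------------------
# Matrix assembly


def _auto_features(table, caller_id, row_idx, min_presence: float) -> list[str]:
    counts: dict[str, int] = {}
    n = len(row_idx)
    for i in row_idx:
        rec = table.rows[int(i)].per_caller[caller_id]
        for name, value in rec.info.items():
            if value is not None:
                counts[name] = counts.get(name, 0) + 1
    selected = sorted(n_ for n_, c in counts.items() if c >= min_presence * n)
    return ["QUAL", "DP"] + selected


def _raw_column(table, caller_id, row_idx, name) -> np.ndarray:
    vals = np.full(len(row_idx), np.nan)
    for j, i in enumerate(row_idx):
        rec = table.rows[int(i)].per_caller[caller_id]
        if name == "QUAL":
            v = rec.qual
        elif name == "DP":
            v = rec.depth if rec.depth is not None else rec.info.get("DP")
        else:
            v = rec.info.get(name)
        if v is not None:
            vals[j] = v
    return vals


def build_feature_matrix(
    table: MergedVariantTable,
    caller_id: str,
    variant_class: str,
    config: FeatureConfig,
    training_rows: Sequence[int],
    reference: ReferenceGenome | None = None,
    distances: np.ndarray | None = None,
) -> FeatureMatrix:
    """Feature matrix for one caller and one variant class.

    Rows are the merged-table rows of ``variant_class`` called by
    ``caller_id``; ``training_rows`` (table row indices, a subset of those
    rows) fit the imputation medians and z-score parameters applied
    everywhere.  ``distances`` may carry a precomputed
    :func:`distance_to_closest_variant` vector for the whole table.
    """
    class_idx = set(table.class_indices(variant_class).tolist())
    row_idx = np.array(
        [int(i) for i in table.caller_indices(caller_id) if int(i) in class_idx],
        dtype=int,
    )
    if row_idx.size == 0:
        raise ValueError(f"{caller_id} called no {variant_class} variants")
    train_set = set(int(i) for i in training_rows)
    if not train_set <= set(row_idx.tolist()):
        raise ValueError("training_rows must be rows called by this caller")
    train_mask = np.array([int(i) in train_set for i in row_idx])
    if not train_mask.any():
        raise ValueError("empty training row set")

    names = config.caller_features.get(
        caller_id, _auto_features(table, caller_id, row_idx, config.min_presence)
    )

    columns: list[str] = []
    raw_cols: list[np.ndarray] = []
    dropped: list[str] = []
    for name in names:
        col = _raw_column(table, caller_id, row_idx, name)
        if np.all(np.isnan(col)):
            log.warning("%s/%s: annotation %s absent everywhere, dropped",
                        caller_id, variant_class, name)
            dropped.append(name)
            continue
        columns.append(name)
        raw_cols.append(col)
    if not raw_cols:
        raise ValueError(
            f"{caller_id}/{variant_class}: none of the configured annotations "
            f"{names} are present in any record"
        )

    if distances is None:
        distances = distance_to_closest_variant(table, cap=config.distance_cap)
    else:
        distances = np.minimum(np.asarray(distances, dtype=float),
                               float(config.distance_cap))
    ent_mean = np.empty(len(row_idx))
    ent_sd = np.empty(len(row_idx))
    for j, i in enumerate(row_idx):
        rec = table.rows[int(i)].per_caller[caller_id]
        ent_mean[j], ent_sd[j] = genotype_entropy_stats(rec.genotype_probs)
    derived = {
        "VMC_DIST": distances[row_idx],
        "VMC_GT_ENT_MEAN": ent_mean,
        "VMC_GT_ENT_SD": ent_sd,
    }
    if reference is not None:
        derived["VMC_REF_ENT"] = np.array(
            [
                reference_entropy(
                    reference,
                    table.rows[int(i)].key.chrom,
                    table.rows[int(i)].key.pos,
                    config.entropy_window,
                )
                for i in row_idx
            ]
        )
    for name, col in derived.items():
        columns.append(name)
        raw_cols.append(np.asarray(col, dtype=float))

    X = np.column_stack(raw_cols)

    # transforms, then training-median imputation, then z-scoring
    for j, name in enumerate(columns):
        t = config.transforms.get(name, "identity")
        if t == "log10_shift":
            X[:, j] = np.log10(np.maximum(X[:, j] + config.log10_shift, 1e-300))
        elif t == "rank":
            col = X[:, j]
            finite = np.isfinite(col)
            ranks = np.full_like(col, np.nan)
            ranks[finite] = rankdata(col[finite])
            X[:, j] = ranks

    medians = np.array(
        [
            np.nanmedian(X[train_mask, j]) if np.any(np.isfinite(X[train_mask, j]))
            else 0.0
            for j in range(X.shape[1])
        ]
    )
    for j in range(X.shape[1]):
        col = X[:, j]
        col[~np.isfinite(col)] = medians[j]

    mean = X[train_mask].mean(axis=0)
    sd = X[train_mask].std(axis=0, ddof=0)

    keep = sd > 0
    if not np.all(keep):
        for j in np.flatnonzero(~keep):
            log.warning("%s/%s: zero-variance column %s dropped",
                        caller_id, variant_class, columns[j])
        dropped.extend([columns[j] for j in np.flatnonzero(~keep)])
    X = (X[:, keep] - mean[keep]) / sd[keep]
    kept_cols = [c for c, k in zip(columns, keep) if k]

    return FeatureMatrix(
        caller_id=caller_id,
        variant_class=variant_class,
        row_indices=row_idx,
        columns=kept_cols,
        X=X,
        scale_mean=mean[keep],
        scale_sd=sd[keep],
        impute_median=medians[keep],
        dropped_columns=dropped,
    )
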