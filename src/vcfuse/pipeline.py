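"""End-to-end fusion: merge -> features -> labels -> SVMs -> ranking.

`run_fusion` is the library entry point that the CLI wraps.  It takes the
(already read) per-caller call sets, normalizes and merges them, builds
the weak training labels per variant class, trains one SVM per caller and
class, fuses the calibrated probabilities and returns the ranked result
with its expected-precision curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from vcfuse.features import (
    FeatureConfig,
    build_feature_matrix,
    distance_to_closest_variant,
)
from vcfuse.io_merge import (
    INDEL,
    SNP,
    CallerCallSet,
    MergedVariantTable,
    merge_callsets,
    normalize_callset,
)
from vcfuse.labeling import ONE_CLASS, TrainingSets, build_training_sets
from vcfuse.precision import PrecisionCurve, expected_precision_curve, rank_variants
from vcfuse.reference import ReferenceGenome
from vcfuse.svm_fusion import (
    GridConfig,
    TrainedCallerModel,
    fuse_probabilities,
    grid_search_train,
    train_one_class,
)

log = logging.getLogger(__name__)


@dataclass
class FusionResult:
    table: MergedVariantTable
    p_svm: np.ndarray                                   # per table row
    per_caller_probs: dict[str, np.ndarray]             # NaN where not called
    training: dict[str, TrainingSets]                   # per variant class
    models: dict[tuple[str, str], TrainedCallerModel]   # (caller, class)
    order: np.ndarray
    curve: PrecisionCurve

    def ordered_keys(self):
        return [self.table.rows[int(i)].key for i in self.order]


def run_fusion(
    callsets: Sequence[CallerCallSet],
    reference: ReferenceGenome | None = None,
    feature_config: FeatureConfig | None = None,
    grid: GridConfig | None = None,
    t_init: int | None = None,
    singleton_max: int = 1,
    min_positives: int = 10,
    mean_over_calling: bool = False,
    normalize: bool = True,
    seed: int | None = None,
) -> FusionResult:
    """Fuse two or more caller call sets into ranked, scored variants.

    ``min_positives`` is the floor below which an SVM is not fit (fatal).
    ``seed`` overrides the grid's seed for every stochastic step.  With
    ``normalize`` (requires ``reference``) the call sets are left-aligned
    before merging.
    """
    feature_config = feature_config or FeatureConfig()
    grid = grid or GridConfig()
    if seed is not None:
        grid.seed = seed

    if normalize and reference is not None:
        callsets = [normalize_callset(cs, reference) for cs in callsets]
    table = merge_callsets(callsets)
    n = table.n_callers
    distances = distance_to_closest_variant(table, cap=feature_config.distance_cap)

    per_caller = {
        c: np.full(len(table.rows), np.nan) for c in table.caller_ids
    }
    training: dict[str, TrainingSets] = {}
    models: dict[tuple[str, str], TrainedCallerModel] = {}

    for vclass in (SNP, INDEL):
        class_rows = table.class_indices(vclass)
        if class_rows.size == 0:
            log.info("no %s variants; class skipped", vclass)
            continue
        ts = build_training_sets(
            table, vclass, t_init=t_init, singleton_max=singleton_max
        )
        training[vclass] = ts
        pos_set = set(ts.positives.tolist())

        for caller in table.caller_ids:
            called = set(int(i) for i in table.caller_indices(caller))
            pos_j = np.array(sorted(pos_set & called), dtype=int)
            if pos_j.size < min_positives:
                raise ValueError(
                    f"{caller}/{vclass}: only {pos_j.size} positive training "
                    f"variants (< floor {min_positives}); cannot fit an SVM"
                )
            if ts.mode == ONE_CLASS:
                train_rows = pos_j
            else:
                neg_j = ts.negatives[caller]
                train_rows = np.concatenate([pos_j, neg_j])
            fm = build_feature_matrix(
                table,
                caller,
                vclass,
                feature_config,
                training_rows=train_rows,
                reference=reference,
                distances=distances,
            )
            if ts.mode == ONE_CLASS:
                model = train_one_class(
                    fm.X[fm.positions_of(pos_j)],
                    grid,
                    caller_id=caller,
                    variant_class=vclass,
                    columns=fm.columns,
                    min_positives=min_positives,
                )
            else:
                X_train = fm.X[fm.positions_of(train_rows)]
                y = np.concatenate(
                    [np.ones(pos_j.size, dtype=int),
                     np.zeros(ts.negatives[caller].size, dtype=int)]
                )
                model = grid_search_train(
                    X_train,
                    y,
                    grid,
                    caller_id=caller,
                    variant_class=vclass,
                    columns=fm.columns,
                )
            models[(caller, vclass)] = model
            per_caller[caller][fm.row_indices] = model.predict_probability(fm.X)

    p_svm = np.array(
        [
            fuse_probabilities(
                [per_caller[c][i] for c in table.caller_ids
                 if not np.isnan(per_caller[c][i])],
                n,
                mean_over_calling=mean_over_calling,
            )
            for i in range(len(table.rows))
        ]
    )
    order = rank_variants(table, p_svm)
    curve = expected_precision_curve(p_svm[order], order)
    return FusionResult(
        table=table,
        p_svm=p_svm,
        per_caller_probs=per_caller,
        training=training,
        models=models,
        order=order,
        curve=curve,
    )
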