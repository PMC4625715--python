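"""Concordance-based weak labels for training.

Positives: variants called simultaneously by at least ``t`` callers, where
``t`` starts at the number of callers (or a user threshold) and is
decremented until the set is non-empty and every caller contributes at
least one member.  Negatives, per caller: the variants that caller called
which were found by at most ``singleton_max`` callers.  When any caller
has no such singly-called variants the run falls back to one-class mode,
training on positives only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from vcfuse.io_merge import MergedVariantTable

log = logging.getLogger(__name__)

TWO_CLASS = "two_class"
ONE_CLASS = "one_class"


@dataclass
class TrainingSets:
    variant_class: str
    t_used: int
    positives: np.ndarray                    # table row indices
    negatives: dict[str, np.ndarray]         # caller id -> table row indices
    mode: str                                # two_class | one_class


def build_training_sets(
    table: MergedVariantTable,
    variant_class: str,
    t_init: int | None = None,
    singleton_max: int = 1,
) -> TrainingSets:
    """Construct the heuristic training sets for one variant class.

    A "proper" positive set is non-empty with every caller contributing;
    ``t`` is decremented from ``t_init`` (default: the number of callers)
    until one is found, and the search failing for every t >= 2 is fatal.
    """
    n_callers = table.n_callers
    if t_init is None:
        t_init = n_callers
    t_init = min(t_init, n_callers)
    if t_init < 2:
        raise ValueError("positive threshold t must start at >= 2")

    class_idx = table.class_indices(variant_class)
    if class_idx.size == 0:
        raise ValueError(f"no {variant_class} variants in the merged table")
    support = table.support_counts()

    positives = None
    t_used = None
    for t in range(t_init, 1, -1):
        cand = class_idx[support[class_idx] >= t]
        if cand.size == 0:
            continue
        contributing = set()
        for i in cand:
            contributing.update(table.rows[int(i)].per_caller)
        if len(contributing) == n_callers:
            positives, t_used = cand, t
            break
    if positives is None:
        counts = {
            t: int((support[class_idx] >= t).sum()) for t in range(2, t_init + 1)
        }
        raise ValueError(
            f"no proper positive training set for {variant_class}: variants "
            f"with support >= t, by t: {counts}; every t in [2, {t_init}] "
            f"fails the non-empty/all-contribute conditions"
        )

    pos_set = set(positives.tolist())
    negatives: dict[str, np.ndarray] = {}
    for caller in table.caller_ids:
        neg = [
            int(i)
            for i in class_idx
            if caller in table.rows[int(i)].per_caller
            and table.rows[int(i)].support_count <= singleton_max
            and int(i) not in pos_set
        ]
        negatives[caller] = np.array(neg, dtype=int)

    mode = ONE_CLASS if any(v.size == 0 for v in negatives.values()) else TWO_CLASS
    log.info(
        "%s labels: t=%d, %d positives, negatives per caller %s, mode=%s",
        variant_class,
        t_used,
        positives.size,
        {c: int(v.size) for c, v in negatives.items()},
        mode,
    )
    return TrainingSets(
        variant_class=variant_class,
        t_used=t_used,
        positives=positives,
        negatives=negatives,
        mode=mode,
    )
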