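"""Ranking and the expected-precision / FDR surface.

Variants are ordered by decreasing fused probability, ties broken by
decreasing mean read depth and finally by genomic coordinate.  Along that
ordering the expected precision at index i is the running mean of the
fused probabilities — equivalently TP(i)/(TP(i)+FP(i)) with TP(i) the sum
of the top-i probabilities — and the expected FDR is its complement.
Choosing a target precision and cutting the ranked list where the
expected precision falls below it is the quantitative, precision-based
filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from vcfuse.io_merge import MergedVariantTable


@dataclass
class PrecisionCurve:
    order: np.ndarray        # permutation of variant indices, best first
    p_sorted: np.ndarray     # fused probabilities along the ordering
    e_prec: np.ndarray       # running expected precision
    e_fdr: np.ndarray        # 1 - e_prec
    tp_est: np.ndarray       # estimated true positives at each index
    fp_est: np.ndarray       # estimated false positives at each index

    def __len__(self):
        return len(self.p_sorted)


def rank_variants(
    table: MergedVariantTable, p_svm: Sequence[float]
) -> np.ndarray:
    """Ordering of table rows: fused probability desc, mean depth desc,
    then (chrom, pos, ref, alt) asc as a deterministic final tie-break."""
    p = np.asarray(p_svm, dtype=float)
    if len(p) != len(table.rows):
        raise ValueError("one probability per table row required")
    keyed = sorted(
        range(len(p)),
        key=lambda i: (
            -p[i],
            -table.rows[i].mean_depth,
            table.rows[i].key.chrom,
            table.rows[i].key.pos,
            table.rows[i].key.ref,
            table.rows[i].key.alt,
        ),
    )
    return np.array(keyed, dtype=int)


def expected_precision_curve(p_sorted: Sequence[float],
                             order: Sequence[int] | None = None) -> PrecisionCurve:
    """Running expected precision over probabilities sorted decreasingly."""
    p = np.asarray(p_sorted, dtype=float)
    if p.size and np.any(np.diff(p) > 1e-9):
        raise ValueError("input probabilities must be sorted decreasingly")
    idx = np.arange(1, p.size + 1, dtype=float)
    tp = np.cumsum(p)
    e_prec = tp / idx if p.size else np.array([])
    return PrecisionCurve(
        order=np.asarray(order if order is not None else np.arange(p.size), dtype=int),
        p_sorted=p,
        e_prec=e_prec,
        e_fdr=1.0 - e_prec if p.size else np.array([]),
        tp_est=tp,
        fp_est=idx - tp if p.size else np.array([]),
    )


def filter_at_precision(
    curve: PrecisionCurve, target_precision: float
) -> tuple[int, float]:
    """Largest cutoff index i with expected precision >= target.

    Returns ``(i, threshold)`` where ``threshold`` is the fused probability
    of the last variant kept (1.0 when nothing passes, so nothing is kept).
    """
    if not 0 < target_precision <= 1:
        raise ValueError("target precision must be in (0, 1]")
    ok = np.flatnonzero(curve.e_prec >= target_precision - 1e-12)
    if ok.size == 0:
        return 0, 1.0
    i = int(ok[-1]) + 1
    return i, float(curve.p_sorted[i - 1])


def adjust_probabilities(
    p_svm: Sequence[float],
    calibration: Callable[[np.ndarray], np.ndarray],
    probe_points: int = 101,
) -> np.ndarray:
    """Apply a user-supplied monotone calibration map elementwise.

    The map is probed on a grid over [0, 1]; a detected decrease or an
    escape from [0, 1] is fatal.  Monotonicity means variant rank order is
    preserved.
    """
    probe = np.linspace(0.0, 1.0, probe_points)
    vals = np.asarray(calibration(probe), dtype=float)
    if np.any(np.diff(vals) < -1e-9):
        raise ValueError("calibration map is not monotone non-decreasing")
    if vals.min() < -1e-9 or vals.max() > 1 + 1e-9:
        raise ValueError("calibration map must stay within [0, 1]")
    out = np.asarray(calibration(np.asarray(p_svm, dtype=float)), dtype=float)
    return np.clip(out, 0.0, 1.0)


def fit_exponential_calibration(
    estimated: Sequence[float], true: Sequence[float]
) -> tuple[Callable[[np.ndarray], np.ndarray], tuple[float, float, float]]:
    """Least-squares fit of a*exp(b*x)+c mapping estimated to true precision.

    Intended for a labeled calibration run: feed the expected-precision
    values and the matched true precision along the same ordering, get back
    a calibration map usable with :func:`adjust_probabilities` (clipped to
    [0, 1]) together with the fitted (a, b, c).
    """
    from scipy.optimize import curve_fit

    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(true, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimated and true vectors must have equal length")

    def f(x, a, b, c):
        return a * np.exp(b * x) + c

    popt, _ = curve_fit(f, est, tru, p0=(0.1, 1.0, 0.0), maxfev=20000)
    a, b, c = (float(v) for v in popt)

    def cal(x):
        return np.clip(f(np.asarray(x, dtype=float), a, b, c), 0.0, 1.0)

    return cal, (a, b, c)
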