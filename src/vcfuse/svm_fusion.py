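"""Per-caller SVM training, probability calibration and fusion.

For each caller (and separately for SNPs and indels) an RBF-kernel SVM is
trained on the weakly labeled feature matrix.  (C, gamma) come from a
two-level grid search under stratified 5-fold cross-validated accuracy:
a coarse grid of C in 2^-5..2^17 by 2^2 and gamma in 2^-17..2^3 by 2^2,
then a fine grid of step 2^0.2 around the coarse optimum.  The winning
pair is refit on the whole training set with Platt probability
calibration.  When a caller has no negative examples a one-class SVM is
trained on positives only, with decision values squashed to [0, 1] by a
logistic anchored so the median training decision value maps to 0.9.

Fused score: the mean over *all* N callers of the per-caller probability
that the variant is real, a caller that did not call the variant
contributing zero, so low-support calls are penalized consistently with
the labeling heuristic.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC, OneClassSVM

log = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass
class GridConfig:
    """Two-level (C, gamma) search grid, exponents base 2."""

    c_exp_min: float = -5.0
    c_exp_max: float = 17.0
    gamma_exp_min: float = -17.0
    gamma_exp_max: float = 3.0
    coarse_step: float = 2.0
    fine_step: float = 0.2
    fine_halfwidth: float = 4.0   # exponent units (= 2^2 around the optimum)
    folds: int = 5
    seed: int = 42
    search_subsample: int = 600   # CV selection subsample cap; 0 disables
    nu: float = 0.1               # one-class SVM nu

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not self.level1_c_exponents() or not self.level1_gamma_exponents():
            raise ValueError("empty parameter grid")

    def level1_c_exponents(self) -> list[float]:
        return _exp_range(self.c_exp_min, self.c_exp_max, self.coarse_step)

    def level1_gamma_exponents(self) -> list[float]:
        return _exp_range(self.gamma_exp_min, self.gamma_exp_max, self.coarse_step)

    def level2_exponents(self, center: float, lo: float, hi: float) -> list[float]:
        raw = _exp_range(
            center - self.fine_halfwidth, center + self.fine_halfwidth, self.fine_step
        )
        return [e for e in raw if lo - 1e-9 <= e <= hi + 1e-9]


def _exp_range(lo: float, hi: float, step: float) -> list[float]:
    n = int(round((hi - lo) / step))
    return [round(lo + i * step, 10) for i in range(n + 1) if lo + i * step <= hi + 1e-9]


@dataclass
class TrainedCallerModel:
    caller_id: str
    variant_class: str
    mode: str                      # two_class | one_class
    best_c_exp: float | None       # None in one-class mode
    best_gamma_exp: float
    cv_score: float
    estimator: object              # fitted SVC or OneClassSVM
    squash_slope: float | None = None   # one-class logistic slope
    columns: list[str] = field(default_factory=list)
    format_version: int = MODEL_FORMAT_VERSION

    @property
    def best_c(self) -> float | None:
        return None if self.best_c_exp is None else 2.0 ** self.best_c_exp

    @property
    def best_gamma(self) -> float:
        return 2.0 ** self.best_gamma_exp

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        """P(real variant) for each row of the (already scaled) matrix."""
        X = np.asarray(X, dtype=float)
        if self.mode == "two_class":
            proba = self.estimator.predict_proba(X)
            pos_col = int(np.flatnonzero(self.estimator.classes_ == 1)[0])
            return proba[:, pos_col]
        d = self.estimator.decision_function(X)
        return expit(self.squash_slope * d)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "TrainedCallerModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if model.format_version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model format {model.format_version} != {MODEL_FORMAT_VERSION}"
            )
        return model


# ---------------------------------------------------------------------------
# Grid search, two-class


def _cv_accuracy(X, y, c_exp, gamma_exp, splits) -> float:
    correct = 0
    for train, test in splits:
        clf = SVC(C=2.0 ** c_exp, gamma=2.0 ** gamma_exp, kernel="rbf")
        clf.fit(X[train], y[train])
        correct += int((clf.predict(X[test]) == y[test]).sum())
    return correct / len(y)


def _search(X, y, pairs, folds, seed):
    """Best (c_exp, gamma_exp) by CV accuracy; ties go to the pair seen
    first, so iterate pairs in (C, gamma) ascending order."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best = None
    best_acc = -1.0
    for c_exp, g_exp in pairs:
        acc = _cv_accuracy(X, y, c_exp, g_exp, splits)
        if acc > best_acc + 1e-12:
            best_acc = acc
            best = (c_exp, g_exp)
    return best, best_acc


def _subsample_for_search(X, y, cap, seed):
    if cap <= 0 or len(y) <= cap:
        return X, y
    rng = np.random.default_rng(seed)
    idx = []
    for cls in np.unique(y):
        cls_idx = np.flatnonzero(y == cls)
        n = max(2, int(round(cap * cls_idx.size / len(y))))
        n = min(n, cls_idx.size)
        idx.append(rng.choice(cls_idx, size=n, replace=False))
    idx = np.sort(np.concatenate(idx))
    return X[idx], y[idx]


def grid_search_train(
    X: np.ndarray,
    labels: Sequence[int],
    grid: GridConfig,
    caller_id: str = "",
    variant_class: str = "",
    columns: Sequence[str] = (),
) -> TrainedCallerModel:
    """Two-level grid search + final Platt-calibrated RBF SVM.

    ``labels`` are 0/1; both classes must be present.  Model selection runs
    on a stratified subsample (``grid.search_subsample`` cap) for speed; the
    final model is refit on every training row at the winning (C, gamma).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise AssertionError(
            "grid_search_train requires two classes; one-class data must be "
            "routed to train_one_class"
        )

    Xs, ys = _subsample_for_search(X, y, grid.search_subsample, grid.seed)
    folds = min(grid.folds, int(np.bincount(ys).min()))
    if folds < grid.folds:
        log.warning("reducing CV folds to %d (smallest class too small)", folds)
    folds = max(folds, 2)

    c1 = grid.level1_c_exponents()
    g1 = grid.level1_gamma_exponents()
    pairs1 = [(c, g) for c in c1 for g in g1]
    (c_best, g_best), acc1 = _search(Xs, ys, pairs1, folds, grid.seed)

    c2 = grid.level2_exponents(c_best, grid.c_exp_min, grid.c_exp_max)
    g2 = grid.level2_exponents(g_best, grid.gamma_exp_min, grid.gamma_exp_max)
    pairs2 = [(c, g) for c in c2 for g in g2]
    (c_fin, g_fin), acc2 = _search(Xs, ys, pairs2, folds, grid.seed)
    if acc2 < acc1:  # keep the coarse optimum if the fine grid never beat it
        c_fin, g_fin, acc2 = c_best, g_best, acc1

    # Platt sigmoid calibration fit via internal CV; the base SVM itself is
    # refit on the whole training set at the winning (C, gamma).
    cal_folds = max(2, min(grid.folds, int(counts.min())))
    final = CalibratedClassifierCV(
        SVC(C=2.0 ** c_fin, gamma=2.0 ** g_fin, kernel="rbf"),
        method="sigmoid",
        cv=StratifiedKFold(n_splits=cal_folds, shuffle=True,
                           random_state=grid.seed),
        ensemble=False,
    )
    final.fit(X, y)
    log.info(
        "%s/%s: best C=2^%.1f gamma=2^%.1f (CV accuracy %.4f, n_train=%d)",
        caller_id, variant_class, c_fin, g_fin, acc2, len(y),
    )
    return TrainedCallerModel(
        caller_id=caller_id,
        variant_class=variant_class,
        mode="two_class",
        best_c_exp=c_fin,
        best_gamma_exp=g_fin,
        cv_score=acc2,
        estimator=final,
        columns=list(columns),
    )


# ---------------------------------------------------------------------------
# One-class fallback


def _squash_slope(decisions: np.ndarray) -> float:
    """Logistic slope mapping the median training decision value to 0.9."""
    m = float(np.median(decisions))
    m = max(m, 1e-6)
    return float(np.log(9.0) / m)


def train_one_class(
    X_pos: np.ndarray,
    grid: GridConfig,
    caller_id: str = "",
    variant_class: str = "",
    columns: Sequence[str] = (),
    min_positives: int = 10,
) -> TrainedCallerModel:
    """One-class RBF SVM on positives only.

    gamma is picked from the coarse gamma grid by maximizing the fraction
    of held-out positives scored above 0.5 under 5-fold CV; nu is fixed
    (``grid.nu``).  Decision values are mapped to [0, 1] by a logistic
    whose slope anchors the median training decision value at 0.9.
    """
    X = np.asarray(X_pos, dtype=float)
    if len(X) < min_positives:
        raise ValueError(
            f"{caller_id}/{variant_class}: {len(X)} positives < minimum "
            f"{min_positives} required to fit a one-class SVM"
        )
    folds = min(grid.folds, len(X))
    kf = KFold(n_splits=folds, shuffle=True, random_state=grid.seed)
    best_g, best_frac = None, -1.0
    for g_exp in grid.level1_gamma_exponents():
        inliers = 0
        for train, test in kf.split(X):
            oc = OneClassSVM(kernel="rbf", nu=grid.nu, gamma=2.0 ** g_exp)
            oc.fit(X[train])
            # score > 0.5 under the logistic squash <=> decision value > 0
            inliers += int((oc.decision_function(X[test]) > 0).sum())
        frac = inliers / len(X)
        if frac > best_frac + 1e-12:
            best_frac, best_g = frac, g_exp

    final = OneClassSVM(kernel="rbf", nu=grid.nu, gamma=2.0 ** best_g)
    final.fit(X)
    slope = _squash_slope(final.decision_function(X))
    log.info(
        "%s/%s: one-class gamma=2^%.1f (held-out inlier fraction %.3f, n=%d)",
        caller_id, variant_class, best_g, best_frac, len(X),
    )
    return TrainedCallerModel(
        caller_id=caller_id,
        variant_class=variant_class,
        mode="one_class",
        best_c_exp=None,
        best_gamma_exp=best_g,
        cv_score=best_frac,
        estimator=final,
        squash_slope=slope,
        columns=list(columns),
    )


# ---------------------------------------------------------------------------
# Fusion


def fuse_probabilities(
    caller_probs: Sequence[float],
    n_callers: int,
    mean_over_calling: bool = False,
) -> float:
    """Fused per-variant probability.

    ``caller_probs`` holds one probability per caller that called the
    variant.  With the default fixed denominator the fused score is
    sum(probs) / N over all N callers, non-calling callers contributing 0;
    ``mean_over_calling`` averages over the calling callers instead.
    """
    probs = np.asarray(list(caller_probs), dtype=float)
    if probs.size and (probs.min() < -1e-9 or probs.max() > 1 + 1e-9):
        raise ValueError("caller probabilities must lie in [0, 1]")
    if len(probs) > n_callers:
        raise ValueError("more probabilities than callers")
    if probs.size == 0:
        return 0.0
    denom = len(probs) if mean_over_calling else n_callers
    return float(probs.sum() / denom)
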