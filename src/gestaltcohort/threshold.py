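"""ROC analysis, Youden-index threshold selection, and cohort statistics.

Given resampled "same-syndrome" and "random" distance samples, a distance
cutoff ``c`` classifies a sub-cohort as same-disorder when its mean pairwise
distance is ``<= c``.  Candidate cutoffs are the midpoints between consecutive
distinct pooled sample values (plus sentinels outside the data range), so the
inclusive rule is unambiguous.  The operating point maximizes the Youden index
J = sensitivity + specificity - 1; generalization is estimated by stratified
k-fold cross-validation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "RocResult",
    "FoldResult",
    "CvReport",
    "roc_from_samples",
    "youden_threshold",
    "crossvalidate",
    "fraction_below",
]


@dataclasses.dataclass
class RocResult:
    """ROC curve over candidate thresholds plus the Youden operating point.

    ``sensitivity[i]`` is the fraction of same-samples <= ``thresholds[i]``;
    ``specificity[i]`` the fraction of random-samples > it.  ``auc`` is the
    rank statistic P(same < random) with ties counted half.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_threshold: float
    youden_sensitivity: float
    youden_specificity: float

    @property
    def youden_index(self) -> float:
        return self.youden_sensitivity + self.youden_specificity - 1.0


@dataclasses.dataclass
class FoldResult:
    threshold: float
    sensitivity: float
    specificity: float


@dataclasses.dataclass
class CvReport:
    k: int
    per_fold: list[FoldResult]
    mean_sensitivity: float
    mean_specificity: float
    seed: int


def _as_clean_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} sample array is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} sample array contains non-finite values")
    return arr


def _candidate_thresholds(pooled: np.ndarray) -> np.ndarray:
    v = np.unique(pooled)
    mids = (v[:-1] + v[1:]) / 2.0
    return np.concatenate(([v[0] - 1.0], mids, [v[-1] + 1.0]))


def roc_from_samples(same, random) -> RocResult:
    """Build the ROC over all candidate cutoffs and pick the Youden point.

    Ties in the Youden index are broken toward the smallest threshold, so
    indistinguishable samples yield the sentinel cutoff below the data
    (J = 0, nothing classified as same-disorder).
    """
    same = _as_clean_array(same, "same")
    random = _as_clean_array(random, "random")
    thr = _candidate_thresholds(np.concatenate([same, random]))
    n_same_le = (same[:, None] <= thr[None, :]).sum(axis=0)
    n_random_gt = (random[:, None] > thr[None, :]).sum(axis=0)
    sens = n_same_le / same.size
    spec = n_random_gt / random.size

    # AUC as the Wilcoxon–Mann–Whitney statistic: P(same < random) + P(tie)/2
    ranks = rankdata(np.concatenate([same, random]))
    n, m = same.size, random.size
    u_random_greater = ranks[n:].sum() - m * (m + 1) / 2.0
    auc = float(u_random_greater / (n * m))

    # maximize J = sens + spec - 1 via the exact integer score m*TP + n*TN so
    # ties break toward the smallest threshold without float noise
    score = random.size * n_same_le + same.size * n_random_gt
    i = int(np.argmax(score))  # thresholds ascending; first max = smallest cutoff
    return RocResult(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_threshold=float(thr[i]),
        youden_sensitivity=float(sens[i]),
        youden_specificity=float(spec[i]),
    )


def youden_threshold(roc: RocResult) -> tuple[float, float, float]:
    """The Youden-optimal ``(c, sensitivity, specificity)`` of a fitted ROC."""
    return roc.youden_threshold, roc.youden_sensitivity, roc.youden_specificity


def crossvalidate(same, random, k: int = 5, seed: int | None = None) -> CvReport:
    """Stratified k-fold CV of the Youden threshold.

    Both sample arrays are shuffled and split into ``k`` folds; per fold the
    cutoff fitted on the training folds is applied to the held-out fold.
    """
    same = _as_clean_array(same, "same")
    random = _as_clean_array(random, "random")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > min(same.size, random.size):
        raise ValueError(
            f"k={k} exceeds the smaller sample size {min(same.size, random.size)}"
        )
    rng = np.random.default_rng(seed)
    same_folds = np.array_split(rng.permutation(same.size), k)
    random_folds = np.array_split(rng.permutation(random.size), k)
    per_fold: list[FoldResult] = []
    for fs, fr in zip(same_folds, random_folds):
        train_same = np.delete(same, fs)
        train_random = np.delete(random, fr)
        c, _, _ = youden_threshold(roc_from_samples(train_same, train_random))
        sens = float((same[fs] <= c).mean())
        spec = float((random[fr] > c).mean())
        per_fold.append(FoldResult(threshold=c, sensitivity=sens, specificity=spec))
    return CvReport(
        k=k,
        per_fold=per_fold,
        mean_sensitivity=float(np.mean([f.sensitivity for f in per_fold])),
        mean_specificity=float(np.mean([f.specificity for f in per_fold])),
        seed=-1 if seed is None else int(seed),
    )


def fraction_below(values, c: float) -> float:
    """Fraction of values at or below the cutoff (inclusive, matching sensitivity)."""
    values = _as_clean_array(values, "values")
    return float((values <= c).mean())
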