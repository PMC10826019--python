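"""Per-gene group comparison and diagnostic-model evaluation.

Three tools sized for the tiny two-group designs this pipeline targets
(4 vs 4 and 5 vs 6 samples):

* an exact Wilcoxon rank-sum test — the p-value enumerates all
  C(n1+n2, n1) assignments of the (mid)ranks, so with 4 vs 4 samples the
  smallest achievable two-sided p is 2/70 ~ 0.0286;
* ROC/AUC via the Mann-Whitney pair-counting identity, with the swept
  curve for plotting (the AUC is reported as-is for the raw gene
  expression; callers may also use max(auc, 1-auc) since the relevant hub
  genes are *down* in unstable plaques);
* a soft-margin linear SVM (through scikit-learn) with leave-one-out
  scoring.  A linear kernel is deliberate: with 8 samples and 5 features
  an RBF fit is unidentifiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.svm import SVC

from .errors import InputError

EXACT_LIMIT = 20  # combined size above which the normal approximation kicks in


def wilcoxon_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank sum of ``x`` over midranks of the
    combined sample.  Exact mode enumerates every group assignment of the
    rank multiset; above a combined size of 20 a tie-corrected normal
    approximation is used instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    ranks = rankdata(np.concatenate([x, y]))
    w_obs = float(ranks[:n1].sum())
    if n1 + n2 <= EXACT_LIMIT:
        total = 0
        lo = 0
        hi = 0
        eps = 1e-9
        for idx in combinations(range(n1 + n2), n1):
            w = ranks[list(idx)].sum()
            total += 1
            if w <= w_obs + eps:
                lo += 1
            if w >= w_obs - eps:
                hi += 1
        p = min(1.0, 2.0 * min(lo, hi) / total)
        return w_obs, p
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w_obs, 1.0
    z = (w_obs - mu) / math.sqrt(var)
    return w_obs, float(min(1.0, 2.0 * norm.sf(abs(z))))


@dataclass
class RocResult:
    auc: float
    curve: list[tuple[float, float]]  # (FPR, TPR) points, (0,0) .. (1,1)


def roc_auc(scores, labels) -> RocResult:
    """AUC by pair counting plus the descending-threshold ROC curve.

    ``labels`` are binary with 1 = case; the AUC is
    (#{case>control} + 0.5 * #{ties}) / (n_case * n_control), reported
    as-is (no orientation flip).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise InputError("labels must contain both classes (0 and 1)")
    case = scores[labels == 1]
    ctrl = scores[labels == 0]
    gt = (case[:, None] > ctrl[None, :]).sum()
    ties = (case[:, None] == ctrl[None, :]).sum()
    auc = float((gt + 0.5 * ties) / (case.size * ctrl.size))

    curve = [(0.0, 0.0)]
    order = np.argsort(-scores, kind="mergesort")
    tp = fp = 0
    i = 0
    n = scores.size
    while i < n:
        j = i
        while j < n and scores[order[j]] == scores[order[i]]:
            tp += labels[order[j]] == 1
            fp += labels[order[j]] == 0
            j += 1
        curve.append((fp / ctrl.size, tp / case.size))
        i = j
    if curve[-1] != (1.0, 1.0):
        curve.append((1.0, 1.0))
    return RocResult(auc=auc, curve=curve)


@dataclass
class SvmModel:
    weights: np.ndarray  # on standardized features
    bias: float
    dual_coef: np.ndarray  # alpha_i in [0, C], one per training sample
    C: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    converged: bool = True

    def decision(self, features) -> np.ndarray:
        x = (np.asarray(features, dtype=float) - self.feature_mean) / self.feature_sd
        return x @ self.weights + self.bias


def svm_train(features, labels, C: float = 1.0, tol: float = 1e-3, max_passes: int = 50) -> SvmModel:
    """Soft-margin linear SVM on internally standardized features."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or not np.all(np.isfinite(X)):
        raise InputError("features must be a finite 2-D matrix")
    if len(set(y)) < 2:
        raise InputError("need both classes present")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd
    clf = SVC(kernel="linear", C=C, tol=tol, max_iter=max(1000, max_passes * 100))
    clf.fit(Xs, y)
    alpha = np.zeros(len(y))
    alpha[clf.support_] = np.abs(clf.dual_coef_[0])
    return SvmModel(
        weights=clf.coef_[0].copy(),
        bias=float(clf.intercept_[0]),
        dual_coef=alpha,
        C=C,
        feature_mean=mean,
        feature_sd=sd,
        converged=bool(clf.fit_status_ == 0),
    )


def kkt_violations(model: SvmModel, features, labels, tol: float = 1e-2) -> int:
    """Count training samples violating the KKT conditions beyond tol."""
    y = np.where(np.asarray(labels, dtype=int) == 1, 1.0, -1.0)
    f = model.decision(features)
    margins = y * f
    bad = 0
    for a, m in zip(model.dual_coef, margins):
        if a < tol * model.C:  # alpha ~ 0 -> margin >= 1
            bad += m < 1 - tol
        elif a > (1 - 1e-6) * model.C:  # alpha at bound -> margin <= 1
            bad += m > 1 + tol
        else:  # free SV -> margin ~ 1
            bad += abs(m - 1) > tol
    return int(bad)


def loocv_scores(features, labels, C: float = 1.0) -> np.ndarray:
    """Leave-one-out decision scores from refit SVMs."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(y) < 3:
        raise InputError("need at least 3 samples for leave-one-out")
    out = np.empty(len(y))
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        if len(set(y[mask])) < 2:
            raise InputError("leaving one sample out empties a class")
        model = svm_train(X[mask], y[mask], C=C)
        out[i] = model.decision(X[i : i + 1])[0]
    return out
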