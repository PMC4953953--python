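"""Relevance ranking, label construction and leave-one-out SVM evaluation.

Feature relevance is scored from the eigenstructure of the feature
correlation matrix: keeping the leading principal components that reach
a target explained variance (90% by default), each feature's score is
the eigenvalue-weighted sum of its absolute loadings, so features most
correlated with the dominant components rank first.  Ratings on the
9-point affective scale are binarized at the midpoint (high iff
rating > 5).  Classification performance is estimated by leave-one-out
cross-validation of a soft-margin RBF SVM, where standardization,
relevance ranking, feature selection and training are all refit on each
fold's training split so the held-out trial never leaks into the model.
Accuracy and the F1 score of the "high" class (robust under class
imbalance) are reported as percentages, and methods are compared with a
one-sided paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "RelevanceRanking", "LabelSet", "EvaluationResult", "SVMConfig",
    "pca_relevance", "select_features", "make_labels", "loo_evaluate",
    "paired_onesided_ttest",
]


@dataclass(frozen=True)
class RelevanceRanking:
    """Per-feature relevance scores and the induced ranking."""

    relevance: np.ndarray
    order: np.ndarray
    n_components_kept: int
    var_explained: float


@dataclass(frozen=True)
class LabelSet:
    """Binary low/high labels from 9-point affective ratings."""

    ratings: np.ndarray
    labels: np.ndarray          # bool, True = high
    dimension: str


@dataclass(frozen=True)
class SVMConfig:
    """Soft-margin RBF SVM settings (no inner hyperparameter search)."""

    C: float = 1.0
    gamma: str | float = "scale"
    relevance_var_explained: float = 0.90
    relevance_mass: float = 0.90


@dataclass(frozen=True)
class EvaluationResult:
    """Leave-one-out confusion counts with derived percentage metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    predictions: np.ndarray
    dimension: str = ""
    method: str = ""

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 100.0 * 2 * self.tp / denom if denom else 0.0

    def summary(self) -> dict:
        return {
            "dimension": self.dimension, "method": self.method,
            "accuracy": self.accuracy, "f1": self.f1,
            "confusion": {"tp": self.tp, "fp": self.fp,
                          "tn": self.tn, "fn": self.fn},
        }


def _as_array(Xi) -> np.ndarray:
    if isinstance(Xi, pd.DataFrame):
        return Xi.values
    return np.asarray(Xi, dtype=float)


def pca_relevance(Xi, var_explained: float = 0.90) -> RelevanceRanking:
    """Eigen-based feature relevance at a target explained variance.

    Columns are standardized internally (constant columns score 0); the
    correlation-matrix eigendecomposition is truncated at the smallest
    number of components whose cumulative eigenvalue share reaches
    ``var_explained``, and feature j scores sum_i lambda_i * |v_ij| over
    the kept components.
    """
    X = _as_array(Xi)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 trials")
    sd = X.std(axis=0)
    keep = sd > 0
    scores = np.zeros(p)
    k = 0
    if np.any(keep):
        Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        q = int(keep.sum())
        if q <= n:
            R = (Z.T @ Z) / n
            w, V = np.linalg.eigh(R)
            w, V = w[::-1], V[:, ::-1]
        else:
            # Gram trick: eigenpairs of Z'Z/n from the n x n matrix ZZ'/n
            G = (Z @ Z.T) / n
            w, U = np.linalg.eigh(G)
            w, U = w[::-1], U[:, ::-1]
            pos = w > 1e-12 * max(w[0], 1.0)
            V = np.zeros((q, n))
            V[:, pos] = Z.T @ (U[:, pos] / np.sqrt(n * w[pos]))
        w = np.clip(w, 0.0, None)
        share = np.cumsum(w) / w.sum()
        k = int(np.searchsorted(share, var_explained - 1e-12) + 1)
        scores[keep] = (np.abs(V[:, :k]) * w[:k]).sum(axis=1)
    order = np.argsort(-scores, kind="stable")
    return RelevanceRanking(relevance=scores, order=order,
                            n_components_kept=k, var_explained=var_explained)


def select_features(Xi, ranking: RelevanceRanking,
                    k: int | None = None, mass: float = 0.90):
    """Columns in decreasing relevance order, truncated by count or mass.

    With ``k`` given, the top-k features are returned; otherwise the
    smallest prefix of the ranking holding ``mass`` of the total
    relevance.  DataFrames keep their column names.
    """
    X = _as_array(Xi)
    p = X.shape[1]
    if k is not None:
        if not 1 <= k <= p:
            raise ValueError(f"k must be in [1, {p}]")
        idx = ranking.order[:k]
    else:
        sorted_scores = ranking.relevance[ranking.order]
        total = sorted_scores.sum()
        if total <= 0:
            raise ValueError("empty selection: all relevance scores are zero")
        cum = np.cumsum(sorted_scores) / total
        idx = ranking.order[: int(np.searchsorted(cum, mass - 1e-12) + 1)]
    if idx.size == 0:
        raise ValueError("empty selection")
    if isinstance(Xi, pd.DataFrame):
        return Xi.iloc[:, idx]
    return X[:, idx]


def make_labels(ratings, dimension: str = "valence") -> LabelSet:
    """Binarize 9-point ratings at the midpoint: high iff rating > 5.

    A rating of exactly 5 counts as low.
    """
    r = np.asarray(ratings, dtype=float)
    if np.any(r < 1.0) or np.any(r > 9.0) or not np.all(np.isfinite(r)):
        raise ValueError("ratings must lie in [1, 9]")
    return LabelSet(ratings=r, labels=r > 5.0, dimension=dimension)


def loo_evaluate(Xi, labels: LabelSet | np.ndarray,
                 svm_config: SVMConfig | None = None,
                 dimension: str = "", method: str = "") -> EvaluationResult:
    """Leave-one-out evaluation of the relevance-ranked RBF SVM.

    For each held-out trial, standardization, PCA relevance ranking,
    feature selection and the SVM are fit on the remaining trials only;
    the held-out trial is then transformed and predicted.  Aggregated
    confusion counts yield accuracy and the F1 score of the positive
    ("high") class.
    """
    cfg = svm_config or SVMConfig()
    X = _as_array(Xi)
    y = labels.labels if isinstance(labels, LabelSet) else np.asarray(labels, bool)
    if isinstance(labels, LabelSet) and not dimension:
        dimension = labels.dimension
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 trials for leave-one-out")
    if y.all() or not y.any():
        raise ValueError("degenerate labels: only one class present")
    preds = np.zeros(n, dtype=bool)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        Xtr, ytr = X[tr], y[tr]
        if ytr.all() or not ytr.any():
            # the fold's training split lost one class: predict its only class
            preds[i] = ytr[0]
            continue
        scaler = StandardScaler().fit(Xtr)
        Ztr = scaler.transform(Xtr)
        ranking = pca_relevance(Ztr, cfg.relevance_var_explained)
        sel = select_features(Ztr, ranking, mass=cfg.relevance_mass)
        idx = ranking.order[: sel.shape[1]]
        clf = SVC(C=cfg.C, kernel="rbf", gamma=cfg.gamma)
        clf.fit(sel, ytr)
        z = scaler.transform(X[i:i + 1])[:, idx]
        preds[i] = bool(clf.predict(z)[0])
    tp = int(np.sum(preds & y))
    fp = int(np.sum(preds & ~y))
    tn = int(np.sum(~preds & ~y))
    fn = int(np.sum(~preds & y))
    return EvaluationResult(tp=tp, fp=fp, tn=tn, fn=fn, predictions=preds,
                            dimension=dimension, method=method)


def paired_onesided_ttest(scores_a, scores_b) -> tuple[float, float]:
    """Paired t-test of mean(a) > mean(b); returns (t, one-sided p).

    Identical inputs give (0.0, 0.5); a constant nonzero difference has
    zero variance and is rejected as degenerate.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    d = a - b
    if np.all(d == 0.0):
        return 0.0, 0.5
    if np.var(d) == 0.0:
        raise ValueError("zero-variance differences: paired t-test undefined")
    res = scipy.stats.ttest_rel(a, b, alternative="greater")
    return float(res.statistic), float(res.pvalue)
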