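"""Wilcoxon rank-sum feature ranking and dimensionality selection.

Features are ranked by the two-sided Wilcoxon rank-sum (Mann-Whitney U)
p-value comparing positive against negative samples; smaller p means
stronger class discrimination. The test is used purely for ranking, so
no multiple-testing correction is applied. The optimal number of
retained features per encoding is chosen by sweeping a grid of k values
and scoring each with mean 10-fold cross-validated AUC of a random
forest, with the ranking recomputed inside each training fold to avoid
selection leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass
class FeatureRanking:
    """Feature indices ordered best-first with their p-values."""

    scheme: str
    order: np.ndarray          # feature indices, ascending p, ties by index
    p_values: np.ndarray       # aligned with the original feature order

    def __post_init__(self):
        if np.any((self.p_values < 0) | (self.p_values > 1)):
            raise ValueError("p-values outside [0, 1]")


@dataclass
class SelectedFeatureSet:
    """The first k indices of a ranking."""

    scheme: str
    k: int
    indices: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self):
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("retained indices not unique")


def wilcoxon_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature two-sided rank-sum p-values (positives vs negatives).

    Uses the normal approximation with tie correction. A feature that is
    constant across all samples carries no rank information; its p-value
    is set to 1 by convention.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    pos, neg = X[y == classes.max()], X[y == classes.min()]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 samples per class")
    p = np.ones(X.shape[1])
    constant = np.ptp(X, axis=0) == 0
    if constant.any():
        logger.info("%d constant features assigned p=1", constant.sum())
    varying = ~constant
    if varying.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.mannwhitneyu(pos[:, varying], neg[:, varying],
                                     alternative="two-sided",
                                     method="asymptotic", axis=0)
        pv = np.atleast_1d(res.pvalue)
        pv = np.where(np.isnan(pv), 1.0, pv)
        p[varying] = np.clip(pv, 0.0, 1.0)
    return p


def rank_features_wilcoxon(matrix, y=None) -> FeatureRanking:
    """Rank the features of a FeatureMatrix (or array) by rank-sum p-value.

    Sorting is ascending in p; ties are broken by original feature index
    (numpy stable sort).
    """
    if hasattr(matrix, "values") and hasattr(matrix, "scheme"):
        X, scheme = matrix.values, matrix.scheme
        if y is None:
            y = matrix.labels
    else:
        X, scheme = np.asarray(matrix), "generic"
    if y is None:
        raise ValueError("labels required for ranking")
    p = wilcoxon_pvalues(X, y)
    order = np.argsort(p, kind="stable")
    return FeatureRanking(scheme, order, p)


def select_top_k(ranking: FeatureRanking, k: int) -> SelectedFeatureSet:
    """Retain the first k indices of a ranking."""
    dim = len(ranking.p_values)
    if not 1 <= k <= dim:
        raise ValueError(f"k={k} out of range [1, {dim}]")
    return SelectedFeatureSet(ranking.scheme, k, ranking.order[:k].copy())


class WilcoxonFeatureSelector(SelectorMixin, BaseEstimator):
    """sklearn selector keeping the top-k rank-sum-ranked features.

    Parameters
    ----------
    k : int or None
        Number of features to retain; None keeps all (the control).
    """

    def __init__(self, k: int | None = None):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.p_values_ = wilcoxon_pvalues(X, y)
        self.order_ = np.argsort(self.p_values_, kind="stable")
        k = X.shape[1] if self.k is None else self.k
        if not 1 <= k <= X.shape[1]:
            raise ValueError(f"k={k} out of range [1, {X.shape[1]}]")
        self.selected_ = np.sort(self.order_[:k])
        return self

    def _get_support_mask(self):
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask


def default_k_grid(dim: int, step: int = 10) -> list[int]:
    """Grid of candidate dimensionalities: step, 2*step, ..., plus dim."""
    grid = list(range(step, dim, step))
    if dim not in grid:
        grid.append(dim)
    return grid


def sweep_k(matrix, k_grid=None, y=None, n_splits: int = 10,
            n_estimators: int = 500, seed: int = 0,
            ) -> tuple[SelectedFeatureSet, pd.DataFrame]:
    """Choose the dimensionality maximizing fold-internal CV AUC.

    For each candidate k the features are re-ranked inside every
    training fold (no selection leakage), a random forest is fit on the
    top-k features, and held-out AUC is averaged over folds. Returns the
    winning :class:`SelectedFeatureSet` — recomputed on the full data at
    the chosen k — plus the per-k AUC table including the full-dimension
    control. Ties favor the smallest k.
    """
    if hasattr(matrix, "values") and hasattr(matrix, "scheme"):
        X, scheme = matrix.values, matrix.scheme
        if y is None:
            y = matrix.labels
    else:
        X, scheme = np.asarray(matrix, dtype=float), "generic"
    if y is None:
        raise ValueError("labels required")
    y = np.asarray(y)
    dim = X.shape[1]
    if k_grid is None:
        k_grid = default_k_grid(dim)
    k_grid = sorted(set(int(k) for k in k_grid) | {dim})
    if min(k_grid) < 1 or max(k_grid) > dim:
        raise ValueError(f"k_grid outside [1, {dim}]")

    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))
    fold_orders = []
    for tr, _ in folds:
        fold_orders.append(np.argsort(wilcoxon_pvalues(X[tr], y[tr]),
                                      kind="stable"))
    rows = []
    for k in k_grid:
        aucs = []
        for (tr, te), order in zip(folds, fold_orders):
            cols = order[:k]
            rf = RandomForestClassifier(n_estimators=n_estimators,
                                        random_state=seed, n_jobs=1)
            rf.fit(X[np.ix_(tr, cols)], y[tr])
            scores = rf.predict_proba(X[np.ix_(te, cols)])[:, 1]
            aucs.append(roc_auc_score(y[te], scores))
        rows.append({"k": k, "mean_auc": float(np.mean(aucs)),
                     "std_auc": float(np.std(aucs)),
                     "control": k == dim})
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["mean_auc"].idxmax(), "k"])  # ties: first=min k
    ranking = rank_features_wilcoxon(matrix if hasattr(matrix, "scheme")
                                     else X, y)
    selected = select_top_k(ranking, best_k)
    selected.scheme = scheme
    return selected, table
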