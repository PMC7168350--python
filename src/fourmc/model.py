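"""Per-encoding random-forest models and cross-validated scoring.

One :class:`EncodingClassifier` handles a single encoding scheme: it
encodes raw sequences, optionally keeps the top-k Wilcoxon-ranked
features, and fits a random forest whose positive-class probability is
the scheme's score. Defaults mirror the classic randomForest R package:
500 trees, sqrt(p) features per split, unlimited depth.

:func:`cross_validate_scores` produces the out-of-fold probability
scores under stratified 10-fold CV that downstream weight fitting and
AUC reporting are based on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .encoders import SequenceEncoder
from .feature_selection import SelectedFeatureSet, WilcoxonFeatureSelector

DEFAULT_N_TREES = 500
DEFAULT_N_FOLDS = 10


def make_forest(n_estimators: int = DEFAULT_N_TREES, seed: int = 0,
                **kwargs) -> RandomForestClassifier:
    """Random forest with randomForest-style defaults."""
    return RandomForestClassifier(n_estimators=n_estimators,
                                  max_features="sqrt", random_state=seed,
                                  n_jobs=1, **kwargs)


class EncodingClassifier(ClassifierMixin, BaseEstimator):
    """Encoder -> (optional Wilcoxon top-k) -> random forest.

    Accepts either raw sequence strings (``encoded=False``, default) or
    an already-encoded feature matrix of the scheme's full dimension
    (``encoded=True``); in both cases prediction internally subsets to
    the selected features.

    Parameters
    ----------
    scheme : str
        Encoding scheme name (KMER, KSNC, MBE, DBE, EIIP, DPC).
    k : int or None
        Retained feature count; None disables selection (the control).
    n_estimators : int
        Forest size.
    seed : int
        Seeds the forest bootstrap.
    encoded : bool
        Whether fit/predict inputs are already encoded matrices.
    """

    def __init__(self, scheme: str = "KMER", k: int | None = None,
                 n_estimators: int = DEFAULT_N_TREES, seed: int = 0,
                 encoded: bool = False):
        self.scheme = scheme
        self.k = k
        self.n_estimators = n_estimators
        self.seed = seed
        self.encoded = encoded

    def _encode(self, X, fitting: bool = False) -> np.ndarray:
        if self.encoded:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise ValueError("expected a 2-D feature matrix")
            if not fitting and X.shape[1] != self.n_features_in_:
                raise ValueError(
                    f"{self.scheme}: expected the full {self.n_features_in_}"
                    f"-column matrix, got {X.shape[1]} columns")
            return X
        return SequenceEncoder(scheme=self.scheme).fit(X).transform(X)

    def fit(self, X, y):
        y = np.asarray(y)
        if len(np.unique(y)) != 2:
            raise ValueError("need both classes to train")
        Xe = self._encode(X, fitting=True)
        self.n_features_in_ = Xe.shape[1]
        if self.k is not None:
            self.selector_ = WilcoxonFeatureSelector(k=self.k).fit(Xe, y)
            Xs = self.selector_.transform(Xe)
            self.selected_ = SelectedFeatureSet(
                self.scheme, self.k, self.selector_.selected_.copy())
        else:
            self.selector_ = None
            Xs = Xe
            self.selected_ = SelectedFeatureSet(
                self.scheme, Xe.shape[1], np.arange(Xe.shape[1]))
        self.forest_ = make_forest(self.n_estimators, self.seed).fit(Xs, y)
        self.classes_ = self.forest_.classes_
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        Xe = self._encode(X)
        if self.selector_ is not None:
            Xe = self.selector_.transform(Xe)
        return self.forest_.predict_proba(Xe)

    def predict(self, X) -> np.ndarray:
        return self.classes_[
            np.argmax(self.predict_proba(X), axis=1)]

    def score_samples(self, X) -> np.ndarray:
        """Positive-class probability per sample."""
        return self.predict_proba(X)[:, list(self.classes_).index(1)]


def train_rf(matrix, selected: SelectedFeatureSet | None = None, y=None,
             n_estimators: int = DEFAULT_N_TREES,
             seed: int = 0) -> EncodingClassifier:
    """Fit an :class:`EncodingClassifier` on an encoded FeatureMatrix."""
    if hasattr(matrix, "values") and hasattr(matrix, "scheme"):
        X, scheme = matrix.values, matrix.scheme
        if y is None:
            y = matrix.labels
    else:
        X, scheme = np.asarray(matrix, dtype=float), "KMER"
    if y is None:
        raise ValueError("labels required")
    k = None if selected is None else selected.k
    model = EncodingClassifier(scheme=scheme, k=k,
                               n_estimators=n_estimators, seed=seed,
                               encoded=True)
    return model.fit(X, y)


def predict_proba(model: EncodingClassifier, matrix) -> np.ndarray:
    """Positive-class probability scores in input order."""
    X = matrix.values if hasattr(matrix, "values") else np.asarray(matrix)
    return model.score_samples(X)


@dataclass
class CVScores:
    """Out-of-fold scores from stratified k-fold CV."""

    scores: np.ndarray          # one out-of-fold score per sample
    fold: np.ndarray            # fold index per sample
    fold_auc: np.ndarray        # AUC of each fold's held-out scores

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))


def stratified_folds(y, n_splits: int = DEFAULT_N_FOLDS, seed: int = 0):
    """Reproducible stratified fold assignment shared across encodings."""
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros(len(y)), y))


def cross_validate_scores(estimator, X, y, n_splits: int = DEFAULT_N_FOLDS,
                          seed: int = 0, folds=None) -> CVScores:
    """Out-of-fold positive-class scores for any sklearn-style classifier.

    The estimator is cloned and refit per fold, so any fold-internal
    steps it contains (e.g. Wilcoxon selection) are re-run on each
    training fold. Every sample is scored exactly once.
    """
    y = np.asarray(y)
    X_arr = np.asarray(X) if not hasattr(X, "shape") else X
    counts = np.bincount(y)
    if counts.min() < n_splits:
        raise ValueError(
            f"need >= {n_splits} samples per class for {n_splits} folds")
    if folds is None:
        folds = stratified_folds(y, n_splits, seed)
    scores = np.full(len(y), np.nan)
    fold_id = np.full(len(y), -1, dtype=int)
    fold_auc = []
    for i, (tr, te) in enumerate(folds):
        est = clone(estimator).fit(_take(X_arr, tr), y[tr])
        proba = est.predict_proba(_take(X_arr, te))
        pos_col = list(est.classes_).index(1)
        scores[te] = proba[:, pos_col]
        fold_id[te] = i
        fold_auc.append(roc_auc_score(y[te], scores[te]))
    assert not np.isnan(scores).any()
    return CVScores(scores, fold_id, np.asarray(fold_auc))


def cross_validate(matrix, y=None, n_splits: int = DEFAULT_N_FOLDS,
                   seed: int = 0, k: int | None = None,
                   n_estimators: int = DEFAULT_N_TREES,
                   folds=None) -> CVScores:
    """10-fold CV of a per-encoding RF on an encoded FeatureMatrix."""
    if hasattr(matrix, "values") and hasattr(matrix, "scheme"):
        X, scheme = matrix.values, matrix.scheme
        if y is None:
            y = matrix.labels
    else:
        X, scheme = np.asarray(matrix, dtype=float), "KMER"
    if y is None:
        raise ValueError("labels required")
    est = EncodingClassifier(scheme=scheme, k=k, n_estimators=n_estimators,
                             seed=seed, encoded=True)
    return cross_validate_scores(est, X, np.asarray(y), n_splits=n_splits,
                                 seed=seed, folds=folds)


def _take(X, idx):
    if hasattr(X, "iloc"):
        return X.iloc[idx]
    return X[idx]
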