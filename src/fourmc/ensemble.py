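"""Weighted linear fusion of per-encoding probability scores.

The final predictor combines the six per-encoding random-forest scores
x_i(s) into a single probability

    combined(s) = sum_i w_i * x_i(s),   w_i >= 0,  sum_i w_i = 1,

with the weight vector chosen by exhaustive search over the 6-simplex
discretized at a fixed grid step (default 0.05, ~53k grid points),
maximizing the AUC of the combined out-of-fold CV score. Fitting the
weights on out-of-fold rather than resubstitution scores guards against
overfitting the fusion step.

:class:`FusionClassifier` is the end-to-end estimator: sequences in,
per-scheme forests + fused weights out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted

from .encoders import SCHEMES, SequenceEncoder
from .feature_selection import sweep_k
from .model import (DEFAULT_N_FOLDS, DEFAULT_N_TREES, EncodingClassifier,
                    cross_validate, stratified_folds)

#: optimal retained dimensionalities for the schemes where Wilcoxon
#: selection beats the full-dimension control (others keep all features)
DEFAULT_K = {"KMER": 160, "KSNC": 80, "DPC": 110}


@dataclass
class EnsembleWeights:
    """A point on the probability simplex over the encoding schemes."""

    weights: np.ndarray
    schemes: tuple[str, ...] = SCHEMES
    grid_step: float = 0.05

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.schemes):
            raise ValueError("one weight per scheme required")
        if (self.weights < 0).any() or abs(self.weights.sum() - 1) > 1e-9:
            raise ValueError("weights must be >= 0 and sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {s: float(w) for s, w in zip(self.schemes, self.weights)}


def combine_scores(score_table, weights) -> np.ndarray:
    """Per-sample dot product of aligned per-scheme scores with weights.

    ``score_table`` is an (n_samples, n_schemes) array or a mapping
    scheme -> score vector; columns must follow the weights' scheme
    order.
    """
    if isinstance(weights, EnsembleWeights):
        w = weights.weights
        schemes = weights.schemes
    else:
        w = np.asarray(weights, dtype=float)
        schemes = SCHEMES[: len(w)]
        if (w < 0).any() or abs(w.sum() - 1) > 1e-9:
            raise ValueError("weights must be >= 0 and sum to 1")
    if isinstance(score_table, dict):
        missing = [s for s in schemes if s not in score_table]
        if missing:
            raise ValueError(f"missing scheme scores: {missing}")
        S = np.column_stack([score_table[s] for s in schemes])
    else:
        S = np.asarray(score_table, dtype=float)
    if S.shape[1] != len(w):
        raise ValueError(
            f"score table has {S.shape[1]} columns for {len(w)} weights")
    return S @ w


def _simplex_grid(n: int, steps: int):
    """All compositions of `steps` into n parts, lexicographic order."""
    def rec(prefix, remaining, parts_left):
        if parts_left == 1:
            yield prefix + (remaining,)
            return
        for v in range(remaining + 1):
            yield from rec(prefix + (v,), remaining - v, parts_left - 1)
    yield from rec((), steps, n)


def _auc_columns(S: np.ndarray, pos_mask: np.ndarray) -> np.ndarray:
    """Mann-Whitney AUC of every column of S (ties get half credit)."""
    ranks = rankdata(S, axis=0)
    n_pos = int(pos_mask.sum())
    n_neg = len(pos_mask) - n_pos
    rank_sum = ranks[pos_mask].sum(axis=0)
    return (rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def optimize_weights(cv_score_table, labels, grid_step: float = 0.05,
                     schemes: tuple[str, ...] = SCHEMES,
                     chunk: int = 4096) -> tuple[EnsembleWeights, float]:
    """Exhaustive simplex grid search maximizing combined-score AUC.

    Ties in AUC (to 1e-12) are broken toward fewer nonzero weights,
    then toward the lexicographically smallest weight vector. Returns
    the winning weights and their combined AUC.
    """
    if isinstance(cv_score_table, dict):
        S = np.column_stack([cv_score_table[s] for s in schemes])
    else:
        S = np.asarray(cv_score_table, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes required to optimize weights")
    pos_mask = y == y.max()
    steps = int(round(1.0 / grid_step))
    if abs(steps * grid_step - 1.0) > 1e-9:
        raise ValueError("grid_step must divide 1 exactly")
    n = S.shape[1]

    best_auc, best_w, best_nnz = -np.inf, None, None
    buffer: list[tuple[int, ...]] = []

    def flush():
        nonlocal best_auc, best_w, best_nnz
        if not buffer:
            return
        W = np.asarray(buffer, dtype=float) / steps
        aucs = _auc_columns(S @ W.T, pos_mask)
        for w_int, auc in zip(buffer, aucs):
            nnz = sum(1 for v in w_int if v)
            better = auc > best_auc + 1e-12
            tied = abs(auc - best_auc) <= 1e-12 and nnz < best_nnz
            if better or tied:
                best_auc, best_w, best_nnz = float(auc), w_int, nnz
        buffer.clear()

    for w_int in _simplex_grid(n, steps):
        buffer.append(w_int)
        if len(buffer) >= chunk:
            flush()
    flush()
    weights = EnsembleWeights(np.asarray(best_w, float) / steps,
                              schemes=schemes, grid_step=grid_step)
    return weights, best_auc


class FusionClassifier(ClassifierMixin, BaseEstimator):
    """End-to-end 4mC site predictor over 41-bp windows.

    Fit takes an array of sequence strings and binary labels. For each
    encoding scheme it computes out-of-fold random-forest scores under
    shared stratified 10-fold CV (with fold-internal Wilcoxon selection
    where a retained dimensionality is configured), fits the fusion
    weights on the out-of-fold score table, then refits each scheme's
    model on the full training data.

    Parameters
    ----------
    schemes : tuple of str
        Encoding schemes to fuse.
    k_per_scheme : dict or None
        scheme -> retained dimensionality. Defaults to
        :data:`DEFAULT_K`; schemes not listed keep all features.
        Pass ``{}`` to disable selection everywhere.
    sweep : bool
        Choose each scheme's dimensionality by a fold-internal CV sweep
        instead of ``k_per_scheme``.
    n_estimators, n_splits, grid_step, seed :
        Forest size, CV folds, simplex grid resolution, master seed.
    target_sp : float or None
        If set, the decision threshold is calibrated on the combined
        out-of-fold scores so specificity >= target_sp; otherwise 0.5.

    Attributes
    ----------
    weights_ : EnsembleWeights
        Fitted simplex weights.
    cv_auc_ : dict
        Mean out-of-fold AUC per scheme.
    combined_cv_auc_ : float
        AUC of the fused out-of-fold score.
    models_ : dict
        Refit :class:`EncodingClassifier` per scheme.
    threshold_ : float
        Decision threshold used by :meth:`predict`.
    """

    def __init__(self, schemes: tuple[str, ...] = SCHEMES,
                 k_per_scheme: dict | None = None, sweep: bool = False,
                 k_grids: dict | None = None,
                 n_estimators: int = DEFAULT_N_TREES,
                 n_splits: int = DEFAULT_N_FOLDS,
                 grid_step: float = 0.05, seed: int = 0,
                 target_sp: float | None = None):
        self.schemes = schemes
        self.k_per_scheme = k_per_scheme
        self.sweep = sweep
        self.k_grids = k_grids
        self.n_estimators = n_estimators
        self.n_splits = n_splits
        self.grid_step = grid_step
        self.seed = seed
        self.target_sp = target_sp

    def fit(self, X, y):
        from .evaluation import threshold_at_specificity

        y = np.asarray(y)
        if len(np.unique(y)) != 2:
            raise ValueError("need both classes")
        seqs = np.asarray(X, dtype=object).ravel()
        k_map = dict(DEFAULT_K) if self.k_per_scheme is None \
            else dict(self.k_per_scheme)

        folds = stratified_folds(y, self.n_splits, self.seed)
        self.encoded_ = {}
        self.oof_scores_ = {}
        self.cv_auc_ = {}
        self.fold_auc_ = {}
        self.chosen_k_ = {}
        self.sweep_tables_ = {}
        for scheme in self.schemes:
            Xe = SequenceEncoder(scheme=scheme).fit(seqs).transform(seqs)
            self.encoded_[scheme] = Xe
            k = k_map.get(scheme)
            if self.sweep:
                grid = (self.k_grids or {}).get(scheme)
                selected, table = sweep_k(
                    Xe, k_grid=grid, y=y, n_splits=self.n_splits,
                    n_estimators=self.n_estimators, seed=self.seed)
                k = selected.k if selected.k < Xe.shape[1] else None
                self.sweep_tables_[scheme] = table
            self.chosen_k_[scheme] = k
            cv = cross_validate(Xe, y=y, n_splits=self.n_splits,
                                seed=self.seed, k=k,
                                n_estimators=self.n_estimators, folds=folds)
            self.oof_scores_[scheme] = cv.scores
            self.cv_auc_[scheme] = cv.mean_auc
            self.fold_auc_[scheme] = cv.fold_auc

        self.weights_, _ = optimize_weights(
            self.oof_scores_, y, grid_step=self.grid_step,
            schemes=tuple(self.schemes))
        self.combined_oof_ = combine_scores(self.oof_scores_, self.weights_)
        self.combined_cv_auc_ = float(roc_auc_score(y, self.combined_oof_))
        self.combined_fold_auc_ = np.array([
            roc_auc_score(y[te], self.combined_oof_[te])
            for _, te in folds])

        self.models_ = {}
        for scheme in self.schemes:
            est = EncodingClassifier(scheme=scheme,
                                     k=self.chosen_k_[scheme],
                                     n_estimators=self.n_estimators,
                                     seed=self.seed, encoded=True)
            self.models_[scheme] = est.fit(self.encoded_[scheme], y)

        if self.target_sp is not None:
            self.threshold_, self.achieved_sp_, self.achieved_sn_ = \
                threshold_at_specificity(self.combined_oof_, y,
                                         self.target_sp)
        else:
            self.threshold_ = 0.5
        self.classes_ = np.array([0, 1])
        del self.encoded_  # free training matrices
        return self

    def score_table(self, X) -> dict[str, np.ndarray]:
        """Per-scheme positive-class scores for new sequences.

        Zero-weight schemes are still scored (for reporting); the fused
        probability ignores them by construction.
        """
        check_is_fitted(self, "models_")
        seqs = np.asarray(X, dtype=object).ravel()
        table = {}
        for scheme in self.schemes:
            Xe = SequenceEncoder(scheme=scheme).fit(seqs).transform(seqs)
            table[scheme] = self.models_[scheme].score_samples(Xe)
        return table

    def decision_scores(self, X) -> np.ndarray:
        """Fused probability score, skipping zero-weight schemes."""
        check_is_fitted(self, "models_")
        seqs = np.asarray(X, dtype=object).ravel()
        w = self.weights_.as_dict()
        total = np.zeros(len(seqs))
        for scheme in self.schemes:
            if w[scheme] == 0.0:
                continue
            Xe = SequenceEncoder(scheme=scheme).fit(seqs).transform(seqs)
            total += w[scheme] * self.models_[scheme].score_samples(Xe)
        return total

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_scores(X)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= self.threshold_).astype(int)
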