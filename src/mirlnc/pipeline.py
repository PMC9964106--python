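"""End-to-end pipeline helpers: CV over the neural classifier and
GTO feature selection on pair features.

These glue the stage modules together the way the CLI and the
reproduction script drive them; everything is seeded explicitly.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .dataset import EncodedPairBatch, encode_pairs
from .evaluate import kfold_cv
from .gto import GTOConfig, select_features
from .model import CnnIndRnnModel, ModelConfig
from .records import InteractionPair, SequenceRecord


def _best_threshold(probs: np.ndarray, labels: np.ndarray) -> float:
    """Accuracy-maximizing decision threshold; ties resolved toward 0.5."""
    grid = np.unique(np.concatenate([[0.5], np.round(np.linspace(0.05, 0.95, 91), 3)]))
    accs = np.array([((probs > t).astype(int) == labels).mean() for t in grid])
    best = accs.max()
    cands = grid[accs == best]
    return float(cands[np.argmin(np.abs(cands - 0.5))])


def cv_neural_pipeline(
    pairs: Sequence[InteractionPair],
    sequences: dict[str, SequenceRecord],
    model_config: ModelConfig,
    k: int = 10,
    seed: int = 0,
    epochs: int | None = None,
    inner_val_fraction: float = 0.0,
    calibration_sample: int | None = None,
    n_models: int = 1,
):
    """Stratified k-fold CV of the CNN+IndRNN classifier.

    One shared token matrix is encoded up front; each fold trains a fresh
    model on its training rows and scores the held-out rows.  With a nonzero
    ``inner_val_fraction`` each fold carves that fraction out of its
    *training* rows as an inner validation split, keeps the parameters of
    the best inner-validation epoch, and calibrates the decision threshold
    on the same split (test probabilities are shifted so the calibrated
    threshold maps onto the 0.5 decision rule); no test rows are touched
    before scoring.  ``n_models`` > 1 averages the probabilities of that
    many differently-initialized models per fold (a small ensemble damps
    run-to-run training variance).  Returns (per-fold reports, summary
    frame).
    """
    batch = encode_pairs(pairs, sequences)
    labels = batch.labels
    rng = np.random.default_rng(seed)

    def pipeline_fn(train_idx: list[int], test_idx: list[int]) -> np.ndarray:
        train_idx = np.asarray(train_idx)
        validation = None
        if inner_val_fraction > 0.0:
            n_val = max(1, int(round(inner_val_fraction * len(train_idx))))
            order = rng.permutation(len(train_idx))
            val_rows = train_idx[order[:n_val]]
            train_rows = train_idx[order[n_val:]]
            validation = (batch.tokens[val_rows], labels[val_rows])
        else:
            train_rows = train_idx
        sub = EncodedPairBatch(
            batch.tokens[train_rows], batch.lengths[train_rows], labels[train_rows], batch.max_len
        )
        probs = np.zeros(len(test_idx))
        val_probs = np.zeros(len(validation[0])) if validation is not None else None
        for j in range(n_models):
            cfg_j = replace(model_config, seed=model_config.seed + 1000 * j)
            model = CnnIndRnnModel(sub, cfg_j)
            results = model.fit(
                epochs=epochs,
                validation=validation,
                restore_best=validation is not None,
                track_train_accuracy=False,
                calibration_sample=calibration_sample,
            )
            probs += results.predict(batch.tokens[test_idx]) / n_models
            if validation is not None:
                val_probs += results.predict(validation[0]) / n_models
        if validation is not None:
            thr = _best_threshold(val_probs, validation[1])
            probs = np.clip(probs + (0.5 - thr), 0.0, 1.0)
        return probs

    return kfold_cv(pairs, labels, pipeline_fn, k=k, seed=seed)


def _subset_error(
    X_tr: np.ndarray, y_tr: np.ndarray, X_va: np.ndarray, y_va: np.ndarray
) -> float:
    clf = LogisticRegression(max_iter=200, solver="liblinear")
    clf.fit(X_tr, y_tr)
    return float(1.0 - clf.score(X_va, y_va))


def gto_feature_selection(
    X: np.ndarray,
    y: np.ndarray,
    gto_config: GTOConfig,
    alpha: float = 0.99,
    val_fraction: float = 0.3,
    seed: int = 0,
):
    """Binary GTO over feature-subset masks of the pair-feature matrix.

    The wrapped error is the hold-out error of an L2 logistic regression on
    the selected (standardized) columns.  Returns (mask, OF_selected,
    OF_all_features, history).
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    order = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    scaler = StandardScaler().fit(X[tr_idx])
    Xs = scaler.transform(X)
    X_tr, y_tr = Xs[tr_idx], y[tr_idx]
    X_va, y_va = Xs[val_idx], y[val_idx]

    def error_fn(bits: np.ndarray) -> float:
        cols = np.nonzero(bits)[0]
        return _subset_error(X_tr[:, cols], y_tr, X_va[:, cols], y_va)

    mask, of_selected, history = select_features(error_fn, X.shape[1], gto_config, alpha=alpha)
    all_err = error_fn(np.ones(X.shape[1], dtype=np.int64))
    of_all = alpha * all_err + (1.0 - alpha) * 1.0
    return mask, of_selected, of_all, history
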