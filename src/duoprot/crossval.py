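"""Repeated stratified k-fold cross-validation of small protein panels.

For each feature set and each partitioning seed: the samples are split
stratified-by-group into ~70% train / 30% test; a three-class multinomial
logistic model is assessed by repeated (3x) stratified 4-fold CV on the
train side (reported, nothing is tuned), refit on the full train side, and
scored by confusion-matrix accuracy on the untouched test side.  A feature
set is "perfect" when its held-out test accuracy is 1 for every seed (a
``mean`` rule is available as an alternative).

The logistic model carries mild L2 regularization: an unpenalized
multinomial fit on ~18 samples diverges whenever a pair separates the
classes, which is exactly the interesting case.  The model is a compact
Newton (IRLS) softmax-regression solver — the pair enumeration performs
tens of thousands of fits on matrices of at most a few dozen rows, and the
solver is verified prediction-for-prediction against scikit-learn's
LogisticRegression in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold

logger = logging.getLogger(__name__)


class MultinomialLogit:
    """Softmax regression with L2 penalty (strength 1/C) on the weights
    (intercepts unpenalized), fitted by damped Newton iterations."""

    def __init__(self, C: float = 100.0, max_iter: int = 60, tol: float = 1e-8):
        self.C = C
        self.max_iter = max_iter
        self.tol = tol
        self.classes_: np.ndarray | None = None
        self.coef_: np.ndarray | None = None  # K x (d+1), intercept last

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MultinomialLogit":
        X = np.asarray(X, float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, d = X.shape
        K = self.classes_.size
        Xb = np.hstack([X, np.ones((n, 1))])
        D = d + 1
        W = np.zeros((K, D))
        Y = np.zeros((n, K))
        Y[np.arange(n), y_idx] = 1.0
        lam = 1.0 / self.C
        pen = np.ones(D)
        pen[-1] = 0.0
        for _ in range(self.max_iter):
            Z = Xb @ W.T
            Z -= Z.max(axis=1, keepdims=True)
            P = np.exp(Z)
            P /= P.sum(axis=1, keepdims=True)
            G = (P - Y).T @ Xb + lam * W * pen
            if np.abs(G).max() < self.tol:
                break
            H = np.empty((K * D, K * D))
            for k in range(K):
                for m in range(K):
                    w = P[:, k] * ((k == m) - P[:, m])
                    H[k * D:(k + 1) * D, m * D:(m + 1) * D] = (Xb * w[:, None]).T @ Xb
            H += np.diag(np.tile(lam * pen, K))
            # tiny ridge absorbs the softmax gauge direction (intercepts
            # are only identified up to a shared constant)
            H += 1e-10 * np.eye(K * D)
            W = W - np.linalg.solve(H, G.ravel()).reshape(K, D)
        self.coef_ = W
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xb = np.hstack([np.asarray(X, float), np.ones((len(X), 1))])
        return self.classes_[np.argmax(Xb @ self.coef_.T, axis=1)]


@dataclass
class CvSpec:
    folds: int = 4
    repeats: int = 3
    train_fraction: float = 0.70
    n_seeds: int = 10
    base_seed: int = 0
    perfect_rule: str = "all_seeds"  # or "mean"
    l2_c: float = 100.0              # inverse regularization strength

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_seeds < 1:
            raise ValueError("need >= 1 partitioning seed")
        if self.perfect_rule not in ("all_seeds", "mean"):
            raise ValueError("perfect_rule must be 'all_seeds' or 'mean'")

    @property
    def seeds(self) -> list[int]:
        return [self.base_seed + i for i in range(self.n_seeds)]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_partition(labels: np.ndarray, train_fraction: float, seed: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-class round(train_fraction * n_g) samples to train, rest to test.

    Every class keeps at least one sample on each side.  Disjoint and
    exhaustive; deterministic for a given seed.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in dict.fromkeys(labels):  # stable class order
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            raise ValueError(f"class {c!r} has {idx.size} samples; "
                             "cannot place one on each side of the split")
        n_train = _round_half_up(train_fraction * idx.size)
        n_train = min(max(n_train, 1), idx.size - 1)
        perm = rng.permutation(idx)
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def _fit_accuracy(spec: CvSpec, X_tr, y_tr, X_te, y_te) -> float:
    model = MultinomialLogit(C=spec.l2_c).fit(X_tr, y_tr)
    return float(np.mean(model.predict(X_te) == y_te))


def evaluate_feature_set(X: np.ndarray, labels: np.ndarray,
                         feature_idx: tuple[int, ...], spec: CvSpec, seed: int
                         ) -> dict[str, float]:
    """One feature set, one partitioning seed: inner repeated-CV accuracy on
    the train side plus the held-out test accuracy."""
    X = np.asarray(X, float)[:, list(feature_idx)]
    labels = np.asarray(labels)
    tr, te = stratified_partition(labels, spec.train_fraction, seed)
    X_tr, y_tr, X_te, y_te = X[tr], labels[tr], X[te], labels[te]

    rkf = RepeatedStratifiedKFold(n_splits=spec.folds, n_repeats=spec.repeats,
                                  random_state=seed)
    fold_acc = [
        _fit_accuracy(spec, X_tr[i], y_tr[i], X_tr[j], y_tr[j])
        for i, j in rkf.split(X_tr, y_tr)
    ]
    test_acc = _fit_accuracy(spec, X_tr, y_tr, X_te, y_te)
    return {"inner_cv_accuracy": float(np.mean(fold_acc)),
            "test_accuracy": test_acc}


def evaluate_across_seeds(X: np.ndarray, labels: np.ndarray,
                          feature_idx: tuple[int, ...], spec: CvSpec
                          ) -> dict[str, float | bool]:
    per_seed = [evaluate_feature_set(X, labels, feature_idx, spec, s)
                for s in spec.seeds]
    test = np.array([r["test_accuracy"] for r in per_seed])
    inner = np.array([r["inner_cv_accuracy"] for r in per_seed])
    perfect = bool(test.min() == 1.0) if spec.perfect_rule == "all_seeds" \
        else bool(test.mean() == 1.0)
    return {"mean_inner_cv_accuracy": float(inner.mean()),
            "mean_test_accuracy": float(test.mean()),
            "min_test_accuracy": float(test.min()),
            "perfect": perfect}


def enumerate_pairs_and_count_perfect(
    X: np.ndarray, labels: np.ndarray, candidates: list[str],
    spec: CvSpec | None = None, include_singles: bool = False,
) -> tuple[pd.DataFrame, int, dict[str, int]]:
    """Evaluate every candidate pair (optionally every single) across all
    partitioning seeds; count feature sets perfect under the spec's rule and
    tally per-protein occurrence among perfect pairs."""
    spec = spec or CvSpec()
    if len(candidates) < 2:
        raise ValueError("need >= 2 candidate proteins")
    X = np.asarray(X, float)
    if X.shape[1] != len(candidates):
        raise ValueError("candidates length must match X columns")

    feature_sets: list[tuple[int, ...]] = []
    if include_singles:
        feature_sets += [(i,) for i in range(len(candidates))]
    feature_sets += list(combinations(range(len(candidates)), 2))

    rows = []
    for fs in feature_sets:
        res = evaluate_across_seeds(X, labels, fs, spec)
        rows.append({"features": "+".join(candidates[i] for i in fs),
                     "n_features": len(fs), **res})
    outcomes = pd.DataFrame(rows)

    perfect_pairs = outcomes[(outcomes["n_features"] == 2) & outcomes["perfect"]]
    freq: dict[str, int] = {}
    for feats in perfect_pairs["features"]:
        for pid in feats.split("+"):
            freq[pid] = freq.get(pid, 0) + 1
    n_perfect = int(len(perfect_pairs))
    logger.info("%d of %d pairs perfect under rule %s",
                n_perfect, sum(outcomes["n_features"] == 2), spec.perfect_rule)
    return outcomes, n_perfect, freq
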