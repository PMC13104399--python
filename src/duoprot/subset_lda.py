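"""Exhaustive linear-discriminant subset search and frequency ranking.

The classifier is classic multi-class LDA: Gaussian classes with a shared
(pooled within-class) covariance and priors equal to the observed class
proportions.  "Accuracy" throughout this module is resubstitution accuracy:
the trace of the confusion matrix of the model applied to its own training
samples, divided by n.  The search enumerates every feature subset of the
requested sizes, records each subset's accuracy, and reports the minimal
subset size at which perfect (accuracy = 1) classification is achieved
together with every perfect subset.

"% separation by LD1" is the first eigenvalue of the between/within
generalized eigenproblem as a fraction of the eigenvalue sum (the
proportion-of-trace statistic standard LDA implementations print).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)

#: ridge multiplier applied to a singular within-class scatter
RIDGE_EPS = 1e-8


def comb_count(n: int, k: int) -> int:
    """Binomial coefficient with exact integer arithmetic."""
    if k < 0 or n < 0:
        raise ValueError("n and k must be non-negative")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    return math.comb(n, k)


@dataclass
class LdaFit:
    classes: list[str]
    class_means: np.ndarray        # n_classes x n_features
    scalings: np.ndarray           # n_features x n_discriminants
    eigenvalues: np.ndarray        # n_discriminants, descending
    ld_proportions: np.ndarray     # eigenvalue / trace, sums to 1
    scores: np.ndarray             # n_samples x n_discriminants
    confusion: np.ndarray          # n_classes x n_classes (rows = truth)
    accuracy: float
    ridged: bool = False


def _class_layout(labels: np.ndarray) -> tuple[list[str], list[np.ndarray]]:
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels))  # first-appearance order, stable
    idx = [np.flatnonzero(labels == c) for c in classes]
    for c, ix in zip(classes, idx):
        if ix.size < 2:
            raise ValueError(f"class {c!r} has {ix.size} samples; need >= 2")
    return classes, idx


def _pooled_scatter(X: np.ndarray, idx: list[np.ndarray]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Class means and pooled within-class covariance (divisor n - g)."""
    n, p = X.shape
    g = len(idx)
    means = np.empty((g, p))
    W = np.zeros((p, p))
    for k, ix in enumerate(idx):
        Xg = X[ix]
        means[k] = Xg.mean(axis=0)
        d = Xg - means[k]
        W += d.T @ d
    return means, W / (n - g)


def _classify(X: np.ndarray, means: np.ndarray, W: np.ndarray,
              priors: np.ndarray) -> tuple[np.ndarray, bool]:
    """Gaussian LDA rule with shared covariance; returns (argmax class index,
    whether a ridge was needed to invert W)."""
    ridged = False
    try:
        A = linalg.solve(W, means.T, assume_a="pos")
    except linalg.LinAlgError:
        ridged = True
        W = W + RIDGE_EPS * max(np.trace(W), 1.0) * np.eye(W.shape[0])
        A = linalg.solve(W, means.T, assume_a="pos")
    # discriminant: x W^-1 mu_k - 0.5 mu_k W^-1 mu_k + log pi_k
    scores = X @ A - 0.5 * np.einsum("kp,pk->k", means, A) + np.log(priors)
    return np.argmax(scores, axis=1), ridged


def resubstitution_accuracy(X: np.ndarray, labels: np.ndarray) -> float:
    """Fast path: accuracy of the LDA rule on its own training samples."""
    X = np.atleast_2d(np.asarray(X, float))
    classes, idx = _class_layout(labels)
    means, W = _pooled_scatter(X, idx)
    priors = np.array([ix.size for ix in idx], dtype=float) / X.shape[0]
    y_true = np.empty(X.shape[0], dtype=int)
    for k, ix in enumerate(idx):
        y_true[ix] = k
    pred, _ = _classify(X, means, W, priors)
    return float(np.mean(pred == y_true))


def fit_lda(X: np.ndarray, labels: np.ndarray) -> LdaFit:
    """Full LDA fit: discriminant directions, trace proportions, scores and
    the resubstitution confusion matrix.

    Singular within-class scatter is ridge-regularized (epsilon 1e-8 of the
    trace) and flagged, so an exhaustive search never aborts mid-run.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be n_samples x n_features with >= 1 feature")
    classes, idx = _class_layout(labels)
    n, p = X.shape
    g = len(classes)
    if g < 2:
        raise ValueError("need >= 2 classes")
    means, W = _pooled_scatter(X, idx)
    priors = np.array([ix.size for ix in idx], dtype=float) / n

    grand = X.mean(axis=0)
    B = np.zeros((p, p))
    for k, ix in enumerate(idx):
        d = (means[k] - grand)[:, None]
        B += ix.size * (d @ d.T)
    B /= n - g

    ridged = False
    try:
        evals, evecs = linalg.eigh(B, W)
    except linalg.LinAlgError:
        ridged = True
        W = W + RIDGE_EPS * max(np.trace(W), 1.0) * np.eye(p)
        evals, evecs = linalg.eigh(B, W)
    order = np.argsort(evals)[::-1]
    r = min(p, g - 1)
    evals = np.clip(evals[order][:r], 0.0, None)
    evecs = evecs[:, order][:, :r]
    total = evals.sum()
    proportions = evals / total if total > 0 else np.full(r, 1.0 / r)

    scores = (X - grand) @ evecs
    y_true = np.empty(n, dtype=int)
    for k, ix in enumerate(idx):
        y_true[ix] = k
    pred, clf_ridged = _classify(X, means, W, priors)
    ridged = ridged or clf_ridged
    if ridged:
        logger.warning("singular within-class scatter; ridge %g applied", RIDGE_EPS)
    confusion = np.zeros((g, g), dtype=int)
    np.add.at(confusion, (y_true, pred), 1)
    return LdaFit(
        classes=classes, class_means=means, scalings=evecs, eigenvalues=evals,
        ld_proportions=proportions, scores=scores, confusion=confusion,
        accuracy=float(np.trace(confusion) / n), ridged=ridged,
    )


@dataclass
class SubsetRanking:
    """All evaluated subsets, the perfect ones, and the minimal perfect size."""

    sizes: tuple[int, ...]
    evaluated: dict[tuple[str, ...], float]
    perfect_by_size: dict[int, list[tuple[str, ...]]]
    minimal_size: int | None

    @property
    def perfect_at_minimal(self) -> list[tuple[str, ...]]:
        if self.minimal_size is None:
            return []
        return self.perfect_by_size[self.minimal_size]

    def n_evaluated(self, k: int) -> int:
        return sum(1 for s in self.evaluated if len(s) == k)

    def to_frame(self, only_perfect: bool = False) -> pd.DataFrame:
        rows = [{"size": len(s), "subset": "+".join(s), "accuracy": a}
                for s, a in self.evaluated.items()
                if not only_perfect or a == 1.0]
        return pd.DataFrame(rows, columns=["size", "subset", "accuracy"])


def subset_search(X: np.ndarray, labels: np.ndarray, feature_ids: list[str],
                  sizes: tuple[int, ...] = (2, 3, 4, 5)) -> SubsetRanking:
    """Evaluate every feature subset of each requested size by resubstitution
    LDA accuracy.

    Enumeration is lexicographic over the stable feature order, so the
    output is deterministic.  The search covers the full requested size
    range even after a perfect subset is found; ``minimal_size`` is the
    smallest size with at least one perfect subset (None if none).
    """
    X = np.asarray(X, float)
    feature_ids = list(feature_ids)
    if X.shape[1] != len(feature_ids):
        raise ValueError("feature_ids length must match X columns")
    sizes = tuple(sorted(set(int(k) for k in sizes)))
    if any(k < 1 or k > len(feature_ids) for k in sizes):
        raise ValueError(f"sizes {sizes} outside 1..{len(feature_ids)}")

    classes, idx = _class_layout(labels)
    priors = np.array([ix.size for ix in idx], dtype=float) / X.shape[0]
    y_true = np.empty(X.shape[0], dtype=int)
    for k, ix in enumerate(idx):
        y_true[ix] = k

    evaluated: dict[tuple[str, ...], float] = {}
    perfect_by_size: dict[int, list[tuple[str, ...]]] = {k: [] for k in sizes}
    for k in sizes:
        for combo in combinations(range(len(feature_ids)), k):
            Xs = X[:, combo]
            means, W = _pooled_scatter(Xs, idx)
            pred, _ = _classify(Xs, means, W, priors)
            acc = float(np.mean(pred == y_true))
            key = tuple(feature_ids[i] for i in combo)
            evaluated[key] = acc
            if acc == 1.0:
                perfect_by_size[k].append(key)
    minimal = next((k for k in sizes if perfect_by_size[k]), None)
    if minimal is None:
        logger.warning("no perfect subset in sizes %s", sizes)
    return SubsetRanking(sizes=sizes, evaluated=evaluated,
                         perfect_by_size=perfect_by_size, minimal_size=minimal)


@dataclass
class FrequencyRanking:
    table: pd.DataFrame              # protein, count (sorted)
    union: list[str]
    more_than_once: list[str]
    frequency: dict[str, int] = field(default_factory=dict)


def rank_by_frequency(perfect_subsets: list[tuple[str, ...]],
                      tiebreak_p: dict[str, float] | None = None
                      ) -> FrequencyRanking:
    """Rank proteins by how many perfect subsets contain them.

    Ties are broken by ascending omnibus p-value when provided, then by
    name, so the ranking is fully deterministic.
    """
    if not perfect_subsets:
        raise ValueError("no perfect subsets to rank")
    freq: dict[str, int] = {}
    for s in perfect_subsets:
        for pid in s:
            freq[pid] = freq.get(pid, 0) + 1
    tiebreak_p = tiebreak_p or {}
    ordered = sorted(freq, key=lambda p: (-freq[p], tiebreak_p.get(p, np.inf), p))
    table = pd.DataFrame({"protein_id": ordered,
                          "count": [freq[p] for p in ordered]})
    return FrequencyRanking(
        table=table,
        union=ordered,
        more_than_once=[p for p in ordered if freq[p] > 1],
        frequency=freq,
    )


def biplot_export(fit: LdaFit, labels: np.ndarray,
                  sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-sample LD1 (and LD2 for >= 3 classes) coordinates with labels."""
    n = fit.scores.shape[0]
    out = pd.DataFrame({
        "sample_id": sample_ids if sample_ids is not None else list(range(n)),
        "group": np.asarray(labels),
        "LD1": fit.scores[:, 0],
    })
    if fit.scores.shape[1] >= 2:
        out["LD2"] = fit.scores[:, 1]
    return out


def centroid_separation(fit: LdaFit, labels: np.ndarray) -> pd.DataFrame:
    """Pairwise distances between group centroids in discriminant space —
    a numeric stand-in for eyeballing bi-plot overlap."""
    labels = np.asarray(labels)
    cent = {c: fit.scores[labels == c].mean(axis=0) for c in fit.classes}
    rows = []
    for a, b in combinations(fit.classes, 2):
        rows.append({"pair": f"{a}-{b}",
                     "distance": float(np.linalg.norm(cent[a] - cent[b]))})
    return pd.DataFrame(rows)
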