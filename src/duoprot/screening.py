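"""Per-protein ROC screening and Pearson pair-correlation screen.

AUC is computed with the rank (Mann-Whitney) statistic, ties counting one
half: it equals the probability that a random positive-class sample
outranks a random negative one.  Orientation is fixed — positive class =
disease group, score = abundance — and is deliberately NOT flipped to
max(AUC, 1 - AUC): a protein whose abundance falls with disease genuinely
scores below 0.5 under this convention.

"Accuracy" for a single protein is the best confusion-matrix accuracy over
all midpoint thresholds of its abundance, trying both orientations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ProteinMatrix

logger = logging.getLogger(__name__)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank statistic; ties contribute one half.

    ``labels`` is boolean (True = positive class).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def accuracy_at_best_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Best two-class accuracy over midpoint thresholds, both orientations."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    n = scores.size
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    cuts = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0,
                           [uniq[-1] + 1.0]])
    best = 0.0
    for t in cuts:
        above = scores > t
        acc_hi = np.mean(above == labels)       # positive class scores high
        acc_lo = np.mean(~above == labels)      # positive class scores low
        best = max(best, acc_hi, acc_lo)
    return float(best)


@dataclass
class CorrelationScreen:
    corr: pd.DataFrame          # symmetric protein x protein Pearson r
    strong_pairs: pd.DataFrame  # columns protein_a, protein_b, r (descending)
    threshold: float


def pearson_pair_screen(matrix: ProteinMatrix, candidates: list[str],
                        threshold: float = 0.6) -> CorrelationScreen:
    """All pairwise Pearson correlations among candidate proteins, over the
    pooled (all groups) imputed samples.

    Strong pairs are those with signed r above the threshold — an r of -0.9
    does not qualify.  Zero-variance proteins yield undefined correlations,
    reported as missing with a warning.
    """
    if matrix.n_samples < 3:
        raise ValueError("need >= 3 samples for a correlation screen")
    sub = matrix.subset_proteins(candidates)
    X = sub.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("correlation screen requires a complete (imputed) matrix")
    sd = X.std(axis=1)
    flat = [pid for pid, s in zip(candidates, sd) if s == 0]
    if flat:
        logger.warning("zero-variance protein(s), correlations undefined: %s", flat)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(X)
    np.fill_diagonal(r, 1.0)
    corr = pd.DataFrame(r, index=candidates, columns=candidates)
    rows = []
    for i, j in combinations(range(len(candidates)), 2):
        rij = r[i, j]
        if np.isfinite(rij) and rij > threshold:
            rows.append({"protein_a": candidates[i], "protein_b": candidates[j],
                         "r": float(rij)})
    strong = pd.DataFrame(rows, columns=["protein_a", "protein_b", "r"])
    strong = strong.sort_values("r", ascending=False, kind="stable").reset_index(drop=True)
    return CorrelationScreen(corr=corr, strong_pairs=strong, threshold=threshold)


#: ROC contrasts: (name, negative/control group, positive/disease group)
ROC_CONTRASTS = (("N_vs_D", "N", "D"), ("N_vs_P", "N", "P"))


def screening_table(matrix: ProteinMatrix, candidates: list[str]) -> pd.DataFrame:
    """Per-candidate two-class accuracy and AUC for N-vs-D and N-vs-P.

    Positive class is the disease group; the score is protein abundance.
    """
    sub = matrix.subset_proteins(candidates)  # raises on absent candidate
    design = matrix.design
    rows = []
    for pid in candidates:
        row: dict[str, object] = {"protein_id": pid}
        for name, neg, pos in ROC_CONTRASTS:
            samples = design.samples_in(neg) + design.samples_in(pos)
            scores = sub.values.loc[pid, samples].to_numpy(dtype=float)
            labels = np.array([False] * len(design.samples_in(neg))
                              + [True] * len(design.samples_in(pos)))
            row[f"accuracy_{name}"] = accuracy_at_best_threshold(scores, labels)
            row[f"auc_{name}"] = roc_auc(scores, labels)
        rows.append(row)
    return pd.DataFrame(rows)
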