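"""Distribution-aware three-group differential testing with Holm pairwise.

For each protein the omnibus test is chosen from the observed data:

* all groups pass Shapiro-Wilk normality (p > 0.05) and Levene's test finds
  homogeneous variances (p > 0.05)  -> one-way (Fisher) ANOVA, with pooled
  Student t tests pairwise;
* all groups normal but variances heterogeneous -> Welch ANOVA, with
  Games-Howell pairwise;
* any group non-normal -> Kruskal-Wallis, with Dunn pairwise.

The three pairwise p-values per protein are Holm step-down adjusted within
the protein (family of m = 3 contrasts).  Fold changes are differences of
group means on the log2 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .matrix import ProteinMatrix

logger = logging.getLogger(__name__)

FISHER = "fisher_anova"
WELCH = "welch_anova"
KRUSKAL = "kruskal_wallis"

CONTRAST_SEP = "_vs_"


def contrast_name(a: str, b: str) -> str:
    return f"{a}{CONTRAST_SEP}{b}"


@dataclass(frozen=True)
class SignificanceRule:
    """Selection rule: omnibus p < alpha and, optionally, at least one
    Holm-adjusted pairwise p < alpha."""

    alpha: float = 0.05
    require_pairwise: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class TestChoice:
    test: str
    shapiro_p: dict[str, float]
    levene_p: float


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values.

    Sorted ascending, p_(i) is multiplied by (m - i); a running maximum
    enforces monotonicity and values are capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = p[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


class DegenerateProtein(ValueError):
    """Raised for data on which none of the tests is defined (e.g. a single
    shared constant value)."""


def _shapiro_p(x: np.ndarray) -> float:
    # Shapiro-Wilk is undefined for constant input; a constant sample is
    # treated as maximally non-normal so the rank branch is used.
    if np.ptp(x) == 0:
        return 0.0
    return float(stats.shapiro(x).pvalue)


def choose_tests(values_by_group: dict[str, np.ndarray], alpha: float = 0.05) -> TestChoice:
    """Pick the omnibus/pairwise family from normality and variance checks."""
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has {v.size} values; need >= 2")
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        raise DegenerateProtein("identical values in every group")

    shapiro_p = {g: _shapiro_p(v) for g, v in groups.items()}
    levene_p = float(stats.levene(*groups.values(), center="median").pvalue)
    if all(p > alpha for p in shapiro_p.values()):
        test = FISHER if levene_p > alpha else WELCH
    else:
        test = KRUSKAL
    return TestChoice(test=test, shapiro_p=shapiro_p, levene_p=levene_p)


def omnibus_pvalue(values_by_group: dict[str, np.ndarray], test: str) -> float:
    """P-value of the named three-group omnibus test."""
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) != 3:
        raise ValueError(f"omnibus test expects exactly 3 groups, got {len(groups)}")
    if test == FISHER:
        return float(stats.f_oneway(*groups).pvalue)
    if test == WELCH:
        df = _long_frame(values_by_group)
        return float(pg.welch_anova(data=df, dv="y", between="g")["p_unc"].iloc[0])
    if test == KRUSKAL:
        return float(stats.kruskal(*groups).pvalue)
    raise ValueError(f"unknown test {test!r}")


def _long_frame(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.DataFrame({
        "y": np.concatenate([np.asarray(v, float) for v in values_by_group.values()]),
        "g": np.concatenate([[g] * len(v) for g, v in values_by_group.items()]),
    })


def dunn_pairwise_p(values_by_group: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunn's rank-based post hoc z test with ties correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups; two-sided normal p.
    """
    names = list(values_by_group)
    pooled = np.concatenate([np.asarray(values_by_group[g], float) for g in names])
    n = {g: len(values_by_group[g]) for g in names}
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank, start = {}, 0
    for g in names:
        mean_rank[g] = ranks[start:start + n[g]].mean()
        start += n[g]
    _, counts = np.unique(pooled, return_counts=True)
    ties = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1))
    var_term = N * (N + 1) / 12.0 - ties
    out = {}
    for a, b in combinations(names, 2):
        se = np.sqrt(var_term * (1.0 / n[a] + 1.0 / n[b]))
        if se == 0:
            out[(a, b)] = 1.0
            continue
        z = (mean_rank[a] - mean_rank[b]) / se
        out[(a, b)] = float(2 * stats.norm.sf(abs(z)))
    return out


def _pairwise_raw_p(values_by_group: dict[str, np.ndarray], test: str
                    ) -> dict[tuple[str, str], float]:
    names = list(values_by_group)
    if test == FISHER:
        return {
            (a, b): float(stats.ttest_ind(values_by_group[a], values_by_group[b],
                                          equal_var=True).pvalue)
            for a, b in combinations(names, 2)
        }
    if test == WELCH:
        gh = pg.pairwise_gameshowell(data=_long_frame(values_by_group),
                                     dv="y", between="g")
        out = {}
        for _, row in gh.iterrows():
            a, b = str(row["A"]), str(row["B"])
            key = (a, b) if names.index(a) < names.index(b) else (b, a)
            out[key] = float(row["pval"])
        return out
    if test == KRUSKAL:
        return dunn_pairwise_p(values_by_group)
    raise ValueError(f"unknown test {test!r}")


def pairwise_holm(values_by_group: dict[str, np.ndarray], test: str) -> pd.DataFrame:
    """All pairwise contrasts for one protein, Holm-adjusted within the protein.

    Returns one row per contrast with raw p, Holm p and log2 fold change
    (second group mean minus first, on the log2 scale).
    """
    raw = _pairwise_raw_p(values_by_group, test)
    pairs = list(raw)
    holm = holm_adjust([raw[p] for p in pairs])
    rows = []
    for (a, b), rp, hp in zip(pairs, (raw[p] for p in pairs), holm):
        fc = float(np.mean(values_by_group[b]) - np.mean(values_by_group[a]))
        rows.append({"contrast": contrast_name(a, b), "raw_p": float(rp),
                     "holm_p": float(hp), "log2_fc": fc})
    return pd.DataFrame(rows)


def test_protein(values_by_group: dict[str, np.ndarray], alpha: float = 0.05
                 ) -> tuple[TestChoice, float, pd.DataFrame]:
    choice = choose_tests(values_by_group, alpha=alpha)
    p = omnibus_pvalue(values_by_group, choice.test)
    pw = pairwise_holm(values_by_group, choice.test)
    return choice, p, pw


def run_differential(matrix: ProteinMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Per-protein omnibus + pairwise table over a complete (imputed) matrix.

    Degenerate proteins (no variation anywhere) are excluded and logged, not
    assigned NaN p-values.
    """
    if not matrix.log2_scale:
        raise ValueError("differential testing expects a log2-scale matrix")
    design = matrix.design
    design.require_min_per_group(2)
    rows, skipped = [], []
    values = matrix.values
    group_cols = {g: [values.columns.get_loc(s) for s in design.samples_in(g)]
                  for g in design.groups}
    arr = values.to_numpy(dtype=float)
    for i, pid in enumerate(values.index):
        by_group = {g: arr[i, cols] for g, cols in group_cols.items()}
        try:
            choice, p, pw = test_protein(by_group, alpha=alpha)
        except DegenerateProtein:
            skipped.append(pid)
            continue
        row = {"protein_id": pid, "test": choice.test, "omnibus_p": p,
               "levene_p": choice.levene_p}
        for g, sp in choice.shapiro_p.items():
            row[f"shapiro_p_{g}"] = sp
        for _, c in pw.iterrows():
            row[f"raw_p_{c['contrast']}"] = c["raw_p"]
            row[f"holm_p_{c['contrast']}"] = c["holm_p"]
            row[f"log2_fc_{c['contrast']}"] = c["log2_fc"]
        rows.append(row)
    if skipped:
        logger.warning("skipped %d degenerate protein(s): %s", len(skipped),
                       skipped[:5])
    table = pd.DataFrame(rows)
    table.attrs["skipped_degenerate"] = skipped
    return table


def holm_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("holm_p_")]


def select_significant(table: pd.DataFrame, rule: SignificanceRule | None = None
                       ) -> pd.DataFrame:
    """Proteins with omnibus p < alpha and (optionally) >= 1 Holm pairwise
    p < alpha, sorted by ascending omnibus p."""
    rule = rule or SignificanceRule()
    keep = table["omnibus_p"] < rule.alpha
    if rule.require_pairwise:
        hc = holm_columns(table)
        keep &= (table[hc] < rule.alpha).any(axis=1)
    out = table.loc[keep].sort_values("omnibus_p", kind="stable")
    return out.reset_index(drop=True)


def volcano_table(table: pd.DataFrame, contrast: str, alpha: float = 0.05,
                  fc_cutoff: float = 1.0) -> pd.DataFrame:
    """Volcano export for one contrast: log2 FC, -log10 raw p, and the
    colour category (raw p < alpha with |log2 FC| > cutoff)."""
    raw_col, fc_col = f"raw_p_{contrast}", f"log2_fc_{contrast}"
    if raw_col not in table.columns:
        known = sorted(c[len("raw_p_"):] for c in table.columns
                       if c.startswith("raw_p_"))
        raise ValueError(f"unknown contrast {contrast!r}; available: {known}")
    p = table[raw_col].to_numpy(dtype=float)
    fc = table[fc_col].to_numpy(dtype=float)
    category = np.where((p < alpha) & (fc > fc_cutoff), "significant & up",
               np.where((p < alpha) & (fc < -fc_cutoff), "significant & down",
                        "ns"))
    return pd.DataFrame({
        "protein_id": table["protein_id"],
        "log2_fc": fc,
        "neg_log10_p": -np.log10(p),
        "category": category,
    })


def two_group_test(a: np.ndarray, b: np.ndarray, alpha: float = 0.05
                   ) -> tuple[str, float]:
    """Two-group analogue of the decision tree (for qPCR follow-up):
    pooled t / Welch t / Mann-Whitney, returning (test name, p-value)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if min(a.size, b.size) < 2:
        raise ValueError("need >= 2 values per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise DegenerateProtein("identical values in both groups")
    normal = _shapiro_p(a) > alpha and _shapiro_p(b) > alpha
    if normal:
        levene_p = float(stats.levene(a, b, center="median").pvalue)
        if levene_p > alpha:
            return "student_t", float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        return "welch_t", float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return "mann_whitney", float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
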