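"""Perseus-style preprocessing of the abundance matrix.

Four stages, applied in order: (1) removal of rows flagged as reverse
sequences, potential contaminants, or only-identified-by-site; (2) column
normalization to a common total intensity followed by log2 transform;
(3) the group-validity filter (a protein is kept if at least a fraction
``min_valid_fraction`` of one group's samples observed it); (4) per-sample
imputation of missing cells from a downshifted normal distribution.

The downshifted normal is the standard model for left-censored label-free
missingness: for a sample with observed log2 mean m and sd s, missing cells
are drawn from Normal(m - downshift*s, (width*s)^2).  Defaults (downshift
1.8, width 0.3) are the long-standing Perseus defaults.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import FLAG_COLUMNS, GroupDesign, ProteinMatrix

logger = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    scale_total: float = 1e11
    min_valid_fraction: float = 0.90
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_total <= 0:
            raise ValueError("scale_total must be positive")
        if not (0 < self.min_valid_fraction <= 1):
            raise ValueError("min_valid_fraction must be in (0, 1]")
        if self.impute_width <= 0:
            raise ValueError("impute_width must be positive")
        if self.impute_downshift <= 0:
            raise ValueError("impute_downshift must be positive")


@dataclass
class PreprocessReport:
    n_input: int
    n_after_flag_removal: int
    n_after_filter: int
    removed_by_flag: dict[str, int] = field(default_factory=dict)
    missing_before_imputation: dict[str, int] = field(default_factory=dict)
    imputation_params: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_flag_removal": self.n_after_flag_removal,
            "n_after_filter": self.n_after_filter,
            "removed_by_flag": self.removed_by_flag,
            "missing_before_imputation": self.missing_before_imputation,
            "imputation_params": self.imputation_params,
        }


def remove_flagged(matrix: ProteinMatrix) -> tuple[ProteinMatrix, dict[str, int]]:
    """Drop rows carrying any artifact flag; report per-flag counts.

    A row with several flags is removed once; the per-category counts may
    overlap (their sum can exceed the number of rows removed).
    """
    flags = matrix.flags
    counts = {name: int(flags[name].sum()) for name in FLAG_COLUMNS}
    any_flag = flags[list(FLAG_COLUMNS)].any(axis=1)
    counts["total_removed"] = int(any_flag.sum())
    keep = ~any_flag
    if not keep.any():
        logger.warning("flag removal left an empty matrix")
    out = ProteinMatrix(
        values=matrix.values.loc[keep].copy(),
        flags=matrix.flags.loc[keep].copy(),
        design=matrix.design,
        gene_names=None if matrix.gene_names is None else matrix.gene_names.loc[keep].copy(),
        log2_scale=matrix.log2_scale,
    )
    return out, counts


def normalize_and_log(matrix: ProteinMatrix, scale_total: float = 1e11) -> ProteinMatrix:
    """Scale each column so its non-missing sum equals ``scale_total``; log2.

    Missing cells are excluded from the column sums and stay missing.
    """
    if matrix.log2_scale:
        raise ValueError("matrix is already log2-scale")
    if scale_total <= 0:
        raise ValueError("scale_total must be positive")
    values = matrix.values.to_numpy(dtype=float).copy()
    col_sums = np.nansum(values, axis=0)
    n_valid = (~np.isnan(values)).sum(axis=0)
    dead = (n_valid == 0) | (col_sums <= 0)
    if dead.any():
        bad = [s for s, d in zip(matrix.design.samples, dead) if d]
        raise ValueError(f"column(s) with no valid positive values: {bad}")
    values = values / (col_sums / scale_total)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.log2(values)
    out = matrix.copy()
    out.values = pd.DataFrame(values, index=matrix.values.index,
                              columns=matrix.values.columns)
    out.log2_scale = True
    return out


def min_valid_counts(design: GroupDesign, min_valid_fraction: float) -> dict[str, int]:
    """Per-group minimum valid-value counts: ceil(fraction * n_g).

    "At least 90% non-missing" is a lower bound on the observed fraction,
    hence the ceiling.
    """
    return {g: math.ceil(min_valid_fraction * n) for g, n in design.counts().items()}


def filter_min_valid(
    matrix: ProteinMatrix, min_valid_fraction: float = 0.90
) -> tuple[ProteinMatrix, int]:
    """Keep proteins observed in >= ceil(fraction*n_g) samples of some group."""
    if not (0 < min_valid_fraction <= 1):
        raise ValueError("min_valid_fraction must be in (0, 1]")
    design = matrix.design
    need = min_valid_counts(design, min_valid_fraction)
    valid = ~matrix.values.isna()
    keep = pd.Series(False, index=matrix.values.index)
    for g in design.groups:
        cols = design.samples_in(g)
        keep |= valid[cols].sum(axis=1) >= need[g]
    out = ProteinMatrix(
        values=matrix.values.loc[keep].copy(),
        flags=matrix.flags.loc[keep].copy(),
        design=design,
        gene_names=None if matrix.gene_names is None else matrix.gene_names.loc[keep].copy(),
        log2_scale=matrix.log2_scale,
    )
    return out, int(keep.sum())


def impute_downshifted_normal(
    matrix: ProteinMatrix, params: PreprocessParams
) -> tuple[ProteinMatrix, dict[str, dict[str, float]]]:
    """Replace each sample's missing cells with draws from its downshifted normal.

    For sample s with observed mean m_s and sd sigma_s (over its non-missing
    log2 values), missing cells are independent draws from
    Normal(m_s - downshift*sigma_s, (width*sigma_s)^2).  Observed cells are
    untouched.  Deterministic for a fixed params.seed.
    """
    if not matrix.log2_scale:
        raise ValueError("imputation expects a log2-scale matrix")
    values = matrix.values.to_numpy(dtype=float).copy()
    ss = np.random.SeedSequence(params.seed)
    sub = ss.spawn(values.shape[1])
    used: dict[str, dict[str, float]] = {}
    for j, sample in enumerate(matrix.design.samples):
        col = values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size < 2:
            raise ValueError(f"sample {sample!r} has {obs.size} valid values; "
                             "need >= 2 to estimate its distribution")
        m, sd = float(obs.mean()), float(obs.std(ddof=1))
        mu = m - params.impute_downshift * sd
        width = params.impute_width * sd
        miss = np.isnan(col)
        if miss.any():
            rng = np.random.default_rng(sub[j])
            col[miss] = rng.normal(mu, width, int(miss.sum()))
        used[sample] = {"observed_mean": m, "observed_sd": sd,
                        "impute_mean": mu, "impute_sd": width,
                        "n_imputed": int(miss.sum())}
    out = matrix.copy()
    out.values = pd.DataFrame(values, index=matrix.values.index,
                              columns=matrix.values.columns)
    return out, used


def preprocess_pipeline(
    matrix: ProteinMatrix, params: PreprocessParams | None = None
) -> tuple[ProteinMatrix, PreprocessReport]:
    """Run flags -> normalize/log2 -> validity filter -> impute, with a report.

    Imputation comes after the filter, so imputed values can never rescue a
    protein past the validity threshold.
    """
    params = params or PreprocessParams()
    n_input = matrix.n_proteins
    flagless, flag_counts = remove_flagged(matrix)
    normed = normalize_and_log(flagless, params.scale_total)
    filtered, n_kept = filter_min_valid(normed, params.min_valid_fraction)
    missing_counts = {s: int(filtered.values[s].isna().sum())
                      for s in filtered.design.samples}
    imputed, impute_params = impute_downshifted_normal(filtered, params)
    report = PreprocessReport(
        n_input=n_input,
        n_after_flag_removal=flagless.n_proteins,
        n_after_filter=n_kept,
        removed_by_flag=flag_counts,
        missing_before_imputation=missing_counts,
        imputation_params=impute_params,
    )
    logger.info("preprocess: %d -> %d (flags) -> %d (validity filter)",
                n_input, flagless.n_proteins, n_kept)
    return imputed, report
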