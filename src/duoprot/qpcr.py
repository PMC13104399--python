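"""Relative qPCR expression by the 2^-ΔΔCt method.

ΔCt per sample is mean target Ct minus mean reference-gene Ct (two
technical replicates each, averaged before differencing).  The calibrator
is the arithmetic mean ΔCt of the control group, so ΔΔCt averages to zero
over controls and the control-group geometric mean of 2^-ΔΔCt is exactly 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .differential import two_group_test

logger = logging.getLogger(__name__)

CT_RANGE = (0.0, 45.0)

REQUIRED_COLUMNS = ("sample_id", "group", "ct_rep1", "ct_rep2",
                    "ref_rep1", "ref_rep2")


def ddct_fold_change(records: pd.DataFrame, control_group: str = "N") -> pd.DataFrame:
    """Per-sample relative expression 2^-ΔΔCt calibrated to a control group.

    Samples with a missing reference (or target) Ct are excluded with a
    warning rather than propagating NaN into the calibrator.
    """
    missing_cols = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing_cols:
        raise ValueError(f"Ct table lacks column(s) {sorted(missing_cols)}")
    df = records.copy()
    ct_cols = ["ct_rep1", "ct_rep2", "ref_rep1", "ref_rep2"]
    incomplete = df[ct_cols].isna().any(axis=1)
    if incomplete.any():
        logger.warning("excluding %d sample(s) with missing Ct values: %s",
                       int(incomplete.sum()),
                       list(df.loc[incomplete, "sample_id"])[:5])
        df = df.loc[~incomplete]
    vals = df[ct_cols].to_numpy(dtype=float)
    lo, hi = CT_RANGE
    if ((vals <= lo) | (vals >= hi)).any():
        raise ValueError(f"Ct value outside plausible range ({lo}, {hi})")
    if not (df["group"] == control_group).any():
        raise ValueError(f"control group {control_group!r} has no samples")

    target_ct = df[["ct_rep1", "ct_rep2"]].mean(axis=1)
    reference_ct = df[["ref_rep1", "ref_rep2"]].mean(axis=1)
    delta_ct = target_ct - reference_ct
    calibrator = delta_ct[df["group"] == control_group].mean()
    ddct = delta_ct - calibrator
    out = pd.DataFrame({
        "sample_id": df["sample_id"],
        "group": df["group"],
        "delta_ct": delta_ct,
        "delta_delta_ct": ddct,
        "fold_change": np.exp2(-ddct),
    }).reset_index(drop=True)
    return out


def compare_groups(fold_changes: pd.DataFrame, group_a: str, group_b: str,
                   alpha: float = 0.05) -> dict[str, float | str]:
    """Two-group comparison of per-sample fold changes, reusing the
    distribution-aware two-sample branch (t / Welch t / Mann-Whitney)."""
    a = fold_changes.loc[fold_changes["group"] == group_a, "fold_change"].to_numpy()
    b = fold_changes.loc[fold_changes["group"] == group_b, "fold_change"].to_numpy()
    test, p = two_group_test(a, b, alpha=alpha)
    return {"groups": f"{group_a}_vs_{group_b}", "test": test, "p_value": p,
            "mean_fold_a": float(a.mean()), "mean_fold_b": float(b.mean())}
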