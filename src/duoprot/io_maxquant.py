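"""Readers/writers for the MaxQuant proteinGroups dialect and pipeline tables.

The proteinGroups table is tab-separated with one row per protein group.
Artifact flags ("Reverse", "Potential contaminant", "Only identified by
site") carry "+" markers; per-sample abundances live in "iBAQ <sample>"
columns.  MaxQuant writes 0 for a non-detected iBAQ value, so 0 and empty
cells are both recorded as missing (log2(0) is undefined and downstream
Perseus-style processing treats them as NaN).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import GROUP_LABELS, GroupDesign, ProteinMatrix

logger = logging.getLogger(__name__)

PROTEIN_ID_COLUMN = "Protein IDs"
GENE_NAMES_COLUMN = "Gene names"

#: proteinGroups header -> internal flag name
FLAG_HEADERS = {
    "Reverse": "reverse",
    "Potential contaminant": "potential_contaminant",
    "Only identified by site": "only_identified_by_site",
}

IBAQ_PREFIX = "iBAQ "


def read_protein_groups(path: str | Path, design: GroupDesign) -> ProteinMatrix:
    """Read a proteinGroups TSV into a :class:`ProteinMatrix`.

    Every sample in ``design`` must have a matching ``iBAQ <sample>``
    column.  Cells equal to 0 or empty are recorded as missing.  Row order
    is preserved; no row is dropped.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if PROTEIN_ID_COLUMN not in raw.columns:
        raise ValueError(f"{path}: missing required column {PROTEIN_ID_COLUMN!r}")

    ids = raw[PROTEIN_ID_COLUMN]
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate protein group id {dup.iloc[0]!r}")

    absent = [s for s in design.samples if IBAQ_PREFIX + s not in raw.columns]
    if absent:
        raise ValueError(
            f"{path}: no iBAQ column for design sample(s) {absent}; "
            f"expected headers like {IBAQ_PREFIX + absent[0]!r}"
        )

    values = pd.DataFrame(index=pd.Index(ids, name=PROTEIN_ID_COLUMN))
    for s in design.samples:
        col = raw[IBAQ_PREFIX + s].replace("", np.nan).astype(float).to_numpy()
        col[col == 0.0] = np.nan  # MaxQuant writes 0 for non-detected
        values[s] = col
    if (values.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative iBAQ value encountered")

    flags = pd.DataFrame(index=values.index)
    for header, name in FLAG_HEADERS.items():
        if header in raw.columns:
            flags[name] = (raw[header].str.strip() == "+").to_numpy()
        else:
            flags[name] = False

    gene_names = None
    if GENE_NAMES_COLUMN in raw.columns:
        gene_names = pd.Series(
            raw[GENE_NAMES_COLUMN].to_numpy(), index=values.index, name="gene_names"
        )

    logger.info("read %d protein groups x %d samples from %s",
                values.shape[0], values.shape[1], path)
    return ProteinMatrix(values=values, flags=flags, design=design,
                         gene_names=gene_names, log2_scale=False)


def write_protein_groups(matrix: ProteinMatrix, path: str | Path) -> None:
    """Write a matrix back out in the proteinGroups dialect (0 = missing)."""
    if matrix.log2_scale:
        raise ValueError("proteinGroups dialect stores linear intensities; "
                         "matrix is log2-scale")
    out = pd.DataFrame({PROTEIN_ID_COLUMN: matrix.protein_ids})
    if matrix.gene_names is not None:
        out[GENE_NAMES_COLUMN] = matrix.gene_names.to_numpy()
    for header, name in FLAG_HEADERS.items():
        out[header] = np.where(matrix.flags[name].to_numpy(), "+", "")
    for s in matrix.design.samples:
        col = matrix.values[s].to_numpy(dtype=float).copy()
        col[np.isnan(col)] = 0.0
        out[IBAQ_PREFIX + s] = col
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_sample_sheet(path: str | Path) -> GroupDesign:
    """Read a two-column TSV (sample_id, group) into a validated design."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: sample sheet is empty")
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise ValueError(
            f"{path}: expected header 'sample_id\\tgroup', got {list(df.columns[:2])}"
        )
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate sample id {dup.iloc[0]!r}")
    bad = sorted(set(df["group"]) - set(GROUP_LABELS))
    if bad:
        raise ValueError(
            f"{path}: unknown group label(s) {bad}; expected one of {list(GROUP_LABELS)}"
        )
    return GroupDesign.from_pairs(list(zip(df["sample_id"], df["group"])))


def write_sample_sheet(design: GroupDesign, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(design.samples),
         "group": [design.group_of[s] for s in design.samples]}
    ).to_csv(path, sep="\t", index=False)


def write_table(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any tabular result as TSV: headers, NA for missing, 6 significant
    digits, deterministic column order (as given)."""
    table.to_csv(path, sep="\t", index=index, na_rep="NA", float_format="%.6g")


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], index_col=index_col)
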