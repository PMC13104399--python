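"""Core in-memory containers: the protein abundance matrix and the sample design.

The matrix is held as a pandas DataFrame (proteins as rows, samples as
columns) with NaN marking non-detected cells, alongside the MaxQuant
artifact flags and the sample-to-group assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_LABELS = ("N", "P", "D")

FLAG_COLUMNS = ("reverse", "potential_contaminant", "only_identified_by_site")


@dataclass(frozen=True)
class GroupDesign:
    """Ordered sample list plus the sample -> disease-group mapping.

    Groups follow the study convention: N (non-diabetic), P (pre-diabetic),
    D (type 2 diabetic).
    """

    samples: tuple[str, ...]
    group_of: dict[str, str] = field(compare=False)

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            dupes = [s for s in self.samples if list(self.samples).count(s) > 1]
            raise ValueError(f"duplicate sample id(s): {sorted(set(dupes))}")
        for s in self.samples:
            g = self.group_of.get(s)
            if g is None:
                raise ValueError(f"sample {s!r} has no group assignment")
            if g not in GROUP_LABELS:
                raise ValueError(
                    f"unknown group label {g!r} for sample {s!r}; "
                    f"expected one of {GROUP_LABELS}"
                )

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]]) -> "GroupDesign":
        return cls(samples=tuple(s for s, _ in pairs), group_of=dict(pairs))

    @property
    def labels(self) -> np.ndarray:
        """Per-sample group labels, in sample order."""
        return np.array([self.group_of[s] for s in self.samples])

    @property
    def groups(self) -> tuple[str, ...]:
        """Group labels present, in canonical N, P, D order."""
        present = set(self.group_of.values())
        return tuple(g for g in GROUP_LABELS if g in present)

    def counts(self) -> dict[str, int]:
        labels = self.labels
        return {g: int(np.sum(labels == g)) for g in self.groups}

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.samples if self.group_of[s] == group]

    def require_min_per_group(self, k: int) -> None:
        for g, n in self.counts().items():
            if n < k:
                raise ValueError(f"group {g!r} has {n} samples; need >= {k}")


@dataclass
class ProteinMatrix:
    """Proteins x samples abundance table with metadata flags and design.

    ``values`` uses NaN for missing (non-detected) cells.  ``log2_scale``
    records whether values are raw linear intensities or log2-transformed.
    """

    values: pd.DataFrame
    flags: pd.DataFrame
    design: GroupDesign
    gene_names: pd.Series | None = None
    log2_scale: bool = False

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.design.samples):
            raise ValueError("matrix columns do not match design sample order")
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate protein id(s): {list(dupes)[:5]}")
        missing_flag_cols = set(FLAG_COLUMNS) - set(self.flags.columns)
        if missing_flag_cols:
            raise ValueError(f"flags table lacks columns {sorted(missing_flag_cols)}")

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean proteins x samples mask, True where not detected."""
        return self.values.isna()

    def subset_proteins(self, ids) -> "ProteinMatrix":
        ids = list(ids)
        absent = [i for i in ids if i not in self.values.index]
        if absent:
            raise KeyError(f"protein id(s) not in matrix: {absent[:5]}")
        return ProteinMatrix(
            values=self.values.loc[ids].copy(),
            flags=self.flags.loc[ids].copy(),
            design=self.design,
            gene_names=None if self.gene_names is None else self.gene_names.loc[ids].copy(),
            log2_scale=self.log2_scale,
        )

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(
            values=self.values.copy(),
            flags=self.flags.copy(),
            design=self.design,
            gene_names=None if self.gene_names is None else self.gene_names.copy(),
            log2_scale=self.log2_scale,
        )

    def group_values(self, protein_id: str) -> dict[str, np.ndarray]:
        """Per-group observed values (NaN dropped) for one protein."""
        row = self.values.loc[protein_id]
        out: dict[str, np.ndarray] = {}
        for g in self.design.groups:
            v = row[self.design.samples_in(g)].to_numpy(dtype=float)
            out[g] = v[~np.isnan(v)]
        return out


def empty_flags(index: pd.Index) -> pd.DataFrame:
    """All-False flag table for matrices that carry no MaxQuant artifacts."""
    return pd.DataFrame(False, index=index, columns=list(FLAG_COLUMNS))
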