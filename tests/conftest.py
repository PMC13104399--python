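import numpy as np
import pandas as pd
import pytest

from duoprot.matrix import GroupDesign, ProteinMatrix, empty_flags

PROTEIN_GROUPS_FIXTURE = """\
Protein IDs\tGene names\tReverse\tPotential contaminant\tOnly identified by site\tiBAQ S1\tiBAQ S2\tiBAQ S3\tiBAQ S4\tiBAQ S5\tiBAQ S6
P00001\tGENE1\t\t\t\t1e9\t2e9\t1.5e9\t3e9\t2.5e9\t1e9
P00002;Q00002\tGENE2\t\t+\t\t4e8\t0\t5e8\t6e8\t0\t7e8
P00003\tGENE3\t\t\t\t0\t0\t2e8\t\t1e8\t3e8
"""


@pytest.fixture
def six_sample_design() -> GroupDesign:
    return GroupDesign.from_pairs(
        [("S1", "N"), ("S2", "N"), ("S3", "P"), ("S4", "P"), ("S5", "D"), ("S6", "D")]
    )


@pytest.fixture
def protein_groups_file(tmp_path):
    path = tmp_path / "proteinGroups.txt"
    path.write_text(PROTEIN_GROUPS_FIXTURE)
    return path


def make_matrix(values: np.ndarray, design: GroupDesign, ids=None,
                log2_scale: bool = False) -> ProteinMatrix:
    """Assemble a ProteinMatrix from a raw array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    if ids is None:
        ids = [f"P{i:05d}" for i in range(values.shape[0])]
    index = pd.Index(ids, name="Protein IDs")
    frame = pd.DataFrame(values, index=index, columns=list(design.samples))
    return ProteinMatrix(values=frame, flags=empty_flags(index), design=design,
                         log2_scale=log2_scale)


@pytest.fixture
def study_design() -> GroupDesign:
    """The 11/6/9 three-group layout."""
    pairs = ([(f"N{i:02d}", "N") for i in range(1, 12)]
             + [(f"P{i:02d}", "P") for i in range(1, 7)]
             + [(f"D{i:02d}", "D") for i in range(1, 10)])
    return GroupDesign.from_pairs(pairs)
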