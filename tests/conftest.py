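import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from vap_triage.matrices import (
    AMINO_ACIDS,
    POSITIONS,
    MotifClass,
    PenaltyMatrix,
    default_matrix_path,
    load_default_matrices,
    load_matrix,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_matrices():
    return load_default_matrices()


@pytest.fixture(scope="session")
def phospho_matrix(default_matrices):
    return default_matrices[MotifClass.PHOSPHO]


@pytest.fixture(scope="session")
def conventional_matrix(default_matrices):
    return default_matrices[MotifClass.CONVENTIONAL]


@pytest.fixture(scope="session")
def table1_path():
    return default_matrix_path(MotifClass.PHOSPHO).parent / "table1_screen.tsv"


def make_matrix(values, motif_class=MotifClass.CONVENTIONAL, name="toy"):
    """Build a PenaltyMatrix from a (20 aa x 19 pos) array-like."""
    table = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=list(AMINO_ACIDS),
        columns=list(POSITIONS),
    )
    return PenaltyMatrix(name=name, motif_class=motif_class, table=table)


@pytest.fixture
def zero_matrix():
    return make_matrix(np.zeros((20, 19)))


def oracle_score(window, matrix):
    """Independent per-cell summation: plain dict lookups, no numpy."""
    total = 0.0
    for pos_label, residue in zip(POSITIONS, window):
        total += float(matrix.table.at[residue, pos_label])
    return total


def oracle_scan(seq, matrix):
    """Independent brute-force window enumeration (plain dict lookups)."""
    penalties = [matrix.table[pos].to_dict() for pos in POSITIONS]
    out = []
    for start0 in range(len(seq) - 19 + 1):
        window = seq[start0 : start0 + 19]
        total = 0.0
        for j in range(19):
            total += penalties[j][window[j]]
        out.append((start0 + 1, total))
    return out
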