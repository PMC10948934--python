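"""Penalty matrices for FFAT and Phospho-FFAT motif scoring.

A motif is scored over 19 contiguous residues: six upstream flank
positions (U1..U6), a seven-residue core (C1..C7) and six downstream
flank positions (D1..D6). Each matrix cell holds a non-negative penalty
for observing a given amino acid at a given position; an ideal motif
sequence accumulates a penalty of exactly zero.

The conventional-FFAT matrix is derived from the Phospho-FFAT matrix by
a single edit at core position C4 (the acidic / phospho-acceptor
position): serine and threonine are penalised with 4, aspartate and
glutamate drop to 0. Everything else is shared between the two classes.

Matrix values are data, not code: they ship as TSV files under
``vap_triage/data`` and are loaded with :func:`load_matrix`. The files
bundled with this package are a synthetic reconstruction built around
the FFAT consensus (see the file headers); any matrix obeying the
validation rules below can be substituted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "POSITIONS",
    "CORE_POSITIONS",
    "WINDOW_LENGTH",
    "MotifClass",
    "PenaltyMatrix",
    "MatrixValidationError",
    "load_matrix",
    "write_matrix",
    "make_conventional",
    "ideal_sequence",
    "default_matrix_path",
    "load_default_matrices",
]

#: The 20 canonical amino acids, alphabetical by one-letter code.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Ordered position labels: upstream flank, core, downstream flank.
POSITIONS: tuple[str, ...] = (
    tuple(f"U{i}" for i in range(1, 7))
    + tuple(f"C{i}" for i in range(1, 8))
    + tuple(f"D{i}" for i in range(1, 7))
)

CORE_POSITIONS: tuple[str, ...] = tuple(f"C{i}" for i in range(1, 8))

WINDOW_LENGTH: int = len(POSITIONS)  # 19

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# C4 edit defining the conventional matrix, per the position-4 transform.
_C4_CONVENTIONAL = {"S": 4.0, "T": 4.0, "D": 0.0, "E": 0.0}


class MotifClass(str, enum.Enum):
    """Motif class a penalty matrix (or a hit) belongs to."""

    CONVENTIONAL = "conventional"
    PHOSPHO = "phospho"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class MatrixValidationError(ValueError):
    """Raised when a penalty matrix violates its invariants.

    ``violations`` lists every problem found, each naming the offending
    row and/or column, so a malformed file can be fixed in one pass.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "invalid penalty matrix:\n  " + "\n  ".join(self.violations)
        )


class UnknownResiduePolicy(str, enum.Enum):
    """How scoring treats residues outside the 20 canonical letters.

    ``max_penalty`` charges the column maximum at that position
    (conservative: an ambiguous residue can never create a false ideal
    hit). ``skip_window`` drops any window containing such a residue.
    """

    MAX_PENALTY = "max_penalty"
    SKIP_WINDOW = "skip_window"


@dataclass(frozen=True)
class PenaltyMatrix:
    """A validated 19-position x 20-residue penalty matrix.

    Parameters
    ----------
    name
        Identifier, e.g. ``"phospho_ffat_synthetic"``.
    motif_class
        Which motif class this matrix scores.
    table
        DataFrame indexed by amino-acid letter (rows, 20) with the 19
        position labels as columns, float penalties >= 0.
    unknown_residue_policy
        See :class:`UnknownResiduePolicy`.
    """

    name: str
    motif_class: MotifClass
    table: pd.DataFrame = field(repr=False)
    unknown_residue_policy: UnknownResiduePolicy = (
        UnknownResiduePolicy.MAX_PENALTY
    )

    def __post_init__(self) -> None:
        violations = _validate_table(self.table)
        if violations:
            raise MatrixValidationError(violations)
        # Canonical row/column order + float dtype; frozen dataclass, so
        # go through object.__setattr__.
        tbl = (
            self.table.loc[list(AMINO_ACIDS), list(POSITIONS)]
            .astype(float)
        )
        object.__setattr__(self, "table", tbl)
        object.__setattr__(self, "motif_class", MotifClass(self.motif_class))
        object.__setattr__(
            self,
            "unknown_residue_policy",
            UnknownResiduePolicy(self.unknown_residue_policy),
        )

    # -- lookups ---------------------------------------------------------

    def penalty(self, position: str, residue: str) -> float:
        """Penalty for ``residue`` at ``position`` (e.g. ``("C4", "S")``)."""
        return float(self.table.at[residue, position])

    def as_array(self) -> np.ndarray:
        """Penalties as a (19 positions, 20 residues) float array.

        Rows follow :data:`POSITIONS`, columns :data:`AMINO_ACIDS`.
        Cached; treat as read-only.
        """
        cached = self.__dict__.get("_array")
        if cached is None:
            cached = self.table.to_numpy().T.copy()
            cached.setflags(write=False)
            object.__setattr__(self, "_array", cached)
        return cached

    def column_max(self) -> np.ndarray:
        """Per-position maximum penalty (length 19)."""
        return self.as_array().max(axis=1)

    def with_name(self, name: str) -> "PenaltyMatrix":
        return replace(self, name=name)


def _validate_table(table: pd.DataFrame) -> list[str]:
    violations: list[str] = []
    rows = list(table.index)
    cols = list(table.columns)

    dup_rows = {r for r in rows if rows.count(r) > 1}
    for r in sorted(dup_rows):
        violations.append(f"duplicate residue row '{r}'")
    missing_rows = sorted(set(AMINO_ACIDS) - set(rows))
    for r in missing_rows:
        violations.append(f"missing residue row '{r}'")
    extra_rows = sorted(set(rows) - set(AMINO_ACIDS))
    for r in extra_rows:
        violations.append(f"unexpected residue row '{r}'")

    missing_cols = [p for p in POSITIONS if p not in cols]
    for c in missing_cols:
        violations.append(f"missing position column '{c}'")
    extra_cols = [c for c in cols if c not in POSITIONS]
    for c in extra_cols:
        violations.append(f"unexpected position column '{c}'")

    if violations:
        return violations  # shape wrong; cell checks would misfire

    sub = table.loc[list(AMINO_ACIDS), list(POSITIONS)]
    vals = sub.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    nan = np.isnan(vals)
    neg = vals < 0
    # fast path: clean numeric matrix with a zero in every column
    if (
        not nan.any()
        and not neg.any()
        and bool((vals == 0).any(axis=0).all())
    ):
        return violations
    for j, pos in enumerate(POSITIONS):
        for i, aa in enumerate(AMINO_ACIDS):
            if nan[i, j]:
                violations.append(f"missing or non-numeric cell ({pos}, {aa})")
            elif neg[i, j]:
                violations.append(
                    f"negative penalty {vals[i, j]} at ({pos}, {aa})"
                )
        if not nan[:, j].all() and (vals[~nan[:, j], j] > 0).all():
            violations.append(
                f"position {pos} has no zero-penalty residue "
                "(an ideal sequence could not score 0)"
            )
    return violations


# -- file I/O ------------------------------------------------------------


def load_matrix(
    path: str | Path,
    *,
    name: str | None = None,
    motif_class: MotifClass | str | None = None,
    unknown_residue_policy: UnknownResiduePolicy | str = (
        UnknownResiduePolicy.MAX_PENALTY
    ),
) -> PenaltyMatrix:
    """Load and validate a penalty matrix from its TSV file.

    The dialect is a plain TSV: optional ``#`` comment lines (the shipped
    files record ``# name:`` and ``# motif_class:`` there), then a header
    row of the 19 position labels, then 20 rows keyed by one-letter
    amino-acid code. Validation failures raise a single
    :class:`MatrixValidationError` enumerating every violated invariant.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    lines = path.read_text().splitlines()
    body: list[str] = []
    for line in lines:
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, val = stripped.partition(":")
                meta[key.strip()] = val.strip()
        elif line.strip():
            body.append(line)
    if not body:
        raise MatrixValidationError([f"{path}: empty matrix file"])

    header = body[0].split("\t")
    if header and header[0] in ("", "residue", "aa"):
        header = header[1:]
    rows: dict[str, list[str]] = {}
    for line in body[1:]:
        fields = line.split("\t")
        key, values = fields[0], fields[1:]
        if key in rows:
            raise MatrixValidationError([f"duplicate residue row '{key}'"])
        rows[key] = values

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.columns = header[: table.shape[1]]
    table = table.apply(pd.to_numeric, errors="coerce")

    if motif_class is None:
        motif_class = meta.get("motif_class")
    if motif_class is None:
        raise MatrixValidationError(
            [f"{path}: motif_class not given and no '# motif_class:' header"]
        )
    if name is None:
        name = meta.get("name", path.stem)
    return PenaltyMatrix(
        name=name,
        motif_class=MotifClass(motif_class),
        table=table,
        unknown_residue_policy=UnknownResiduePolicy(unknown_residue_policy),
    )


def write_matrix(matrix: PenaltyMatrix, path: str | Path) -> None:
    """Write ``matrix`` in the same TSV dialect :func:`load_matrix` reads.

    Round-trips cell-for-cell (penalties are formatted with ``repr``-exact
    floats via pandas' default float formatting).
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# name: {matrix.name}\n")
        fh.write(f"# motif_class: {matrix.motif_class.value}\n")
        fh.write("residue\t" + "\t".join(POSITIONS) + "\n")
        for aa in AMINO_ACIDS:
            vals = "\t".join(
                _format_penalty(matrix.table.at[aa, p]) for p in POSITIONS
            )
            fh.write(f"{aa}\t{vals}\n")


def _format_penalty(v: float) -> str:
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


# -- transforms ----------------------------------------------------------


def make_conventional(matrix: PenaltyMatrix) -> PenaltyMatrix:
    """Derive the conventional-FFAT matrix from a Phospho-FFAT matrix.

    Exactly four cells change, all in core position C4: S and T are set
    to 4, D and E to 0. Every other cell is copied unchanged.

    Raises
    ------
    ValueError
        If ``matrix`` is not a phospho-class matrix.
    """
    if matrix.motif_class is not MotifClass.PHOSPHO:
        raise ValueError(
            "make_conventional expects a phospho-class matrix, got "
            f"motif_class={matrix.motif_class.value!r}"
        )
    table = matrix.table.copy()
    for aa, pen in _C4_CONVENTIONAL.items():
        table.at[aa, "C4"] = pen
    name = matrix.name.replace("phospho", "conventional")
    if name == matrix.name:
        name = matrix.name + "_conventional"
    return PenaltyMatrix(
        name=name,
        motif_class=MotifClass.CONVENTIONAL,
        table=table,
        unknown_residue_policy=matrix.unknown_residue_policy,
    )


def ideal_sequence(matrix: PenaltyMatrix) -> str:
    """A 19-mer scoring exactly 0 under ``matrix``.

    At each position the zero-penalty residue with the alphabetically
    smallest one-letter code is chosen (deterministic tie-break). The
    validation invariant guarantees such a residue exists everywhere.
    """
    arr = matrix.as_array()  # (19 positions, 20 residues, alphabetical)
    first_zero = (arr == 0.0).argmax(axis=1)
    return "".join(AMINO_ACIDS[i] for i in first_zero)


# -- shipped defaults ----------------------------------------------------


def default_matrix_path(motif_class: MotifClass | str) -> Path:
    """Path of the bundled matrix file for ``motif_class``."""
    from importlib.resources import files

    motif_class = MotifClass(motif_class)
    fname = {
        MotifClass.PHOSPHO: "phospho_ffat_synthetic.tsv",
        MotifClass.CONVENTIONAL: "conventional_ffat_synthetic.tsv",
    }[motif_class]
    return Path(str(files("vap_triage").joinpath("data", fname)))


def load_default_matrices() -> dict[MotifClass, PenaltyMatrix]:
    """Load the bundled conventional and phospho matrices."""
    return {
        mc: load_matrix(default_matrix_path(mc))
        for mc in (MotifClass.CONVENTIONAL, MotifClass.PHOSPHO)
    }


def matrices_equal(a: PenaltyMatrix, b: PenaltyMatrix) -> bool:
    """Cell-for-cell equality of two matrices (names ignored)."""
    return bool((a.table.values == b.table.values).all())


def diff_cells(
    a: PenaltyMatrix, b: PenaltyMatrix
) -> list[tuple[str, str, float, float]]:
    """Cells where ``a`` and ``b`` differ, as (position, residue, a, b)."""
    out = []
    for pos in POSITIONS:
        for aa in AMINO_ACIDS:
            va, vb = a.table.at[aa, pos], b.table.at[aa, pos]
            if va != vb:
                out.append((pos, aa, float(va), float(vb)))
    return out
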