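"""Sliding-window FFAT / Phospho-FFAT scoring of protein sequences.

Every fully contained 19-residue window of a protein is scored as the
sum of the 19 per-position penalties looked up in a
:class:`~vap_triage.matrices.PenaltyMatrix`; lower scores are better and
0 is an ideal motif. A hit with score in the closed band [0, 2.5]
(default threshold) is called significant, matching the scoring band
used to triage VAP interactors.

Windows overhanging a terminus are never scored (no padding), so motifs
whose 19-mer extends within 6 residues of a terminus are undetectable —
a documented limitation of the window architecture.

Coordinates are 1-based and inclusive on the protein, the convention of
UniProt feature tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrices import (
    AMINO_ACIDS,
    WINDOW_LENGTH,
    MotifClass,
    PenaltyMatrix,
    UnknownResiduePolicy,
)

__all__ = [
    "MotifHit",
    "ProteinScanResult",
    "score_window",
    "scan_sequence",
    "best_hits",
    "scan_proteome",
    "classify_significant",
    "results_to_table",
    "hits_to_table",
    "DEFAULT_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Upper end of the closed significance band [0, 2.5].
DEFAULT_THRESHOLD: float = 2.5

#: Offset of the first core position (C1) within the 19-mer window.
CORE_OFFSET: int = 6
CORE_LENGTH: int = 7

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class MotifHit:
    """One scored 19-residue window on one protein.

    ``start`` and ``core_start`` are 1-based; ``core_start`` is the
    position of C1, i.e. ``start + 6``. ``score`` is the exact sum of
    the 19 looked-up penalties.
    """

    protein_id: str
    motif_class: MotifClass
    start: int
    window_seq: str
    score: float

    @property
    def core_start(self) -> int:
        return self.start + CORE_OFFSET

    @property
    def core_interval(self) -> tuple[int, int]:
        """1-based inclusive (first, last) residue of the core C1..C7."""
        return (self.core_start, self.core_start + CORE_LENGTH - 1)


@dataclass(frozen=True)
class ProteinScanResult:
    """Best hits per motif class for one protein.

    ``best`` maps motif class to the (up to) k best core-disjoint hits;
    ``best_score`` to the single best window score of that class (None
    when the protein is too short to hold a window). ``significant`` is
    true when the minimum best score over classes lies in [0, threshold].
    """

    protein_id: str
    best: Mapping[MotifClass, tuple[MotifHit, ...]]
    best_score: Mapping[MotifClass, float | None]
    significant: bool
    threshold: float

    def min_best_score(self) -> float | None:
        scores = [s for s in self.best_score.values() if s is not None]
        return min(scores) if scores else None


def classify_significant(
    score: float, threshold: float = DEFAULT_THRESHOLD
) -> bool:
    """True iff ``score`` lies in the closed band [0, threshold].

    The band is closed at both ends: 0 is the ideal score and must
    count, and a score exactly at the threshold is still significant.
    """
    if score < 0:
        raise ValueError(f"motif scores are non-negative, got {score}")
    return score <= threshold


def score_window(window: str, matrix: PenaltyMatrix) -> float:
    """Score one 19-residue window: the sum of per-position penalties.

    Residues outside the 20 canonical letters are handled per the
    matrix's ``unknown_residue_policy``: ``max_penalty`` charges the
    position's column maximum, ``skip_window`` returns ``None``.
    """
    if len(window) != WINDOW_LENGTH:
        raise ValueError(
            f"window must be exactly {WINDOW_LENGTH} residues, "
            f"got {len(window)}"
        )
    window = window.upper()
    if not window.isalpha():
        raise ValueError(f"window contains non-letter characters: {window!r}")
    arr = matrix.as_array()  # (19, 20)
    colmax = matrix.column_max()
    total = 0.0
    for j, aa in enumerate(window):
        idx = _AA_INDEX.get(aa)
        if idx is None:
            if (
                matrix.unknown_residue_policy
                is UnknownResiduePolicy.SKIP_WINDOW
            ):
                return None  # type: ignore[return-value]
            total += float(colmax[j])
        else:
            total += float(arr[j, idx])
    return total


def _encode(seq: str) -> np.ndarray:
    """Residues -> column indices; unknown letters -> 20 (sentinel)."""
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(128, 20, dtype=np.int64)
    for aa, i in _AA_INDEX.items():
        lut[ord(aa)] = i
    return lut[codes]


def scan_sequence(
    seq: str,
    matrix: PenaltyMatrix,
    protein_id: str = "",
) -> list[MotifHit]:
    """Score every fully contained 19-mer window of ``seq``.

    Returns one :class:`MotifHit` per admissible window start in
    ascending start order. A sequence shorter than 19 residues yields an
    empty list with a logged warning rather than an error, so bulk scans
    do not abort on peptide-length records.
    """
    seq = seq.upper()
    if "*" in seq:
        logger.warning(
            "protein %s: stripping %d stop character(s)",
            protein_id or "<anon>",
            seq.count("*"),
        )
        seq = seq.replace("*", "")
    if not seq.isalpha():
        raise ValueError(
            f"protein {protein_id or '<anon>'}: sequence contains "
            "non-letter characters"
        )
    n = len(seq)
    if n < WINDOW_LENGTH:
        logger.warning(
            "protein %s: length %d < window length %d; no windows scored",
            protein_id or "<anon>",
            n,
            WINDOW_LENGTH,
        )
        return []

    idx = _encode(seq)
    n_windows = n - WINDOW_LENGTH + 1
    arr = matrix.as_array()  # (19, 20)
    colmax = matrix.column_max()
    # Append the per-position max as a 21st column so the unknown
    # sentinel (20) indexes the conservative penalty directly.
    arr_ext = np.concatenate([arr, colmax[:, None]], axis=1)  # (19, 21)

    scores = np.zeros(n_windows, dtype=np.float64)
    has_unknown = np.zeros(n_windows, dtype=bool)
    for j in range(WINDOW_LENGTH):
        col_idx = idx[j : j + n_windows]
        scores += arr_ext[j, col_idx]
        has_unknown |= col_idx == 20

    skip = (
        matrix.unknown_residue_policy is UnknownResiduePolicy.SKIP_WINDOW
    )
    hits: list[MotifHit] = []
    for w in range(n_windows):
        if skip and has_unknown[w]:
            continue
        hits.append(
            MotifHit(
                protein_id=protein_id,
                motif_class=matrix.motif_class,
                start=w + 1,
                window_seq=seq[w : w + WINDOW_LENGTH],
                score=float(scores[w]),
            )
        )
    return hits


def best_hits(hits: Sequence[MotifHit], k: int = 2) -> list[MotifHit]:
    """The up-to-k best-scoring hits with mutually disjoint cores.

    Hits are ranked by (score, start): ties go to the more N-terminal
    window. A hit is skipped when its core C1..C7 interval overlaps the
    core of an already selected hit, so the shifted windows of a single
    motif cannot occupy two report slots.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if hits:
        ids = {h.protein_id for h in hits}
        classes = {h.motif_class for h in hits}
        if len(ids) > 1 or len(classes) > 1:
            raise ValueError(
                "best_hits expects hits from one protein and one motif "
                f"class, got proteins={sorted(ids)} classes="
                f"{sorted(c.value for c in classes)}"
            )
    chosen: list[MotifHit] = []
    for hit in sorted(hits, key=lambda h: (h.score, h.start)):
        lo, hi = hit.core_interval
        if any(
            not (hi < c.core_interval[0] or lo > c.core_interval[1])
            for c in chosen
        ):
            continue
        chosen.append(hit)
        if len(chosen) == k:
            break
    return chosen


def scan_protein(
    protein_id: str,
    seq: str,
    matrices: Mapping[MotifClass, PenaltyMatrix],
    threshold: float = DEFAULT_THRESHOLD,
    top_k: int = 2,
) -> ProteinScanResult:
    """Scan one protein under each matrix and summarise best hits."""
    best: dict[MotifClass, tuple[MotifHit, ...]] = {}
    best_score: dict[MotifClass, float | None] = {}
    for mc, matrix in matrices.items():
        mc = MotifClass(mc)
        hits = scan_sequence(seq, matrix, protein_id=protein_id)
        top = tuple(best_hits(hits, k=top_k))
        best[mc] = top
        best_score[mc] = top[0].score if top else None
    scores = [s for s in best_score.values() if s is not None]
    significant = bool(scores) and classify_significant(
        min(scores), threshold
    )
    return ProteinScanResult(
        protein_id=protein_id,
        best=best,
        best_score=best_score,
        significant=significant,
        threshold=threshold,
    )


def scan_proteome(
    records: Iterable[tuple[str, str]] | str | Path,
    matrices: Mapping[MotifClass, PenaltyMatrix],
    threshold: float = DEFAULT_THRESHOLD,
    top_k: int = 2,
) -> list[ProteinScanResult]:
    """Scan every protein of a proteome under each matrix.

    ``records`` is either an iterable of ``(id, sequence)`` pairs or a
    FASTA path (read via :func:`vap_triage.io.read_fasta`). Output order
    follows input order; duplicate IDs are an error. An empty input
    yields an empty list with a warning.
    """
    if isinstance(records, (str, Path)):
        from .io import read_fasta

        records = read_fasta(records)
    records = list(records)
    if not records:
        logger.warning("scan_proteome: no records in input")
        return []
    seen: set[str] = set()
    results = []
    for pid, seq in records:
        if pid in seen:
            raise ValueError(f"duplicate protein ID in proteome: {pid!r}")
        seen.add(pid)
        results.append(
            scan_protein(pid, seq, matrices, threshold=threshold, top_k=top_k)
        )
    return results


def results_to_table(results: Sequence[ProteinScanResult]) -> pd.DataFrame:
    """Wide per-protein summary: best-2 score/start/sequence per class.

    Mirrors the shape of an interactor annotation table: one row per
    protein; for each motif class, rank-1 and rank-2 score, start and
    window sequence; plus the per-class best score and the significance
    flag.
    """
    rows = []
    for r in results:
        row: dict[str, object] = {"protein_id": r.protein_id}
        for mc in (MotifClass.CONVENTIONAL, MotifClass.PHOSPHO):
            if mc not in r.best:
                continue
            for rank in (1, 2):
                hit = r.best[mc][rank - 1] if len(r.best[mc]) >= rank else None
                prefix = f"{mc.value}_{rank}"
                row[f"{prefix}_score"] = hit.score if hit else np.nan
                row[f"{prefix}_start"] = hit.start if hit else pd.NA
                row[f"{prefix}_seq"] = hit.window_seq if hit else ""
            bs = r.best_score.get(mc)
            row[f"best_{mc.value}"] = np.nan if bs is None else bs
        row["significant"] = r.significant
        rows.append(row)
    return pd.DataFrame(rows)


def hits_to_table(results: Sequence[ProteinScanResult]) -> pd.DataFrame:
    """Long hit table: protein_id, class, rank, start, core_start,
    window_seq, score, significant (per-hit significance)."""
    rows = []
    for r in results:
        for mc, hits in r.best.items():
            for rank, hit in enumerate(hits, start=1):
                rows.append(
                    {
                        "protein_id": r.protein_id,
                        "class": MotifClass(mc).value,
                        "rank": rank,
                        "start": hit.start,
                        "core_start": hit.core_start,
                        "window_seq": hit.window_seq,
                        "score": hit.score,
                        "significant": classify_significant(
                            hit.score, r.threshold
                        ),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "class",
            "rank",
            "start",
            "core_start",
            "window_seq",
            "score",
            "significant",
        ],
    )
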