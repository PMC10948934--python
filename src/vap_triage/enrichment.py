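"""IP-MS enrichment ranking of VAP pull-down proteins.

Proteins pulled down by the wild-type MSP bait but not by the
FFAT-binding-dead (KD/MD) mutant bait are candidate FFAT-dependent
interactors. The evidence is spectral counts: each protein's
peptide-spectrum matches (PSMs) in the WT and mutant samples of each
bait (VAP-A, VAP-B). The ratio score

    ratio = (psm_wt + c) / (psm_mut + c)

with Laplace pseudocount c (default 1) ranks WT-over-mutant enrichment
while staying finite when the mutant sample has zero counts. Selection
additionally requires a minimum peptide count, a crude identification-
quality gate standing in for the search-engine score whose scale is
instrument-specific.

Selected sets from the two baits are combined into union/intersection
with per-protein bait membership, then annotated with the best FFAT /
Phospho-FFAT motif scores from the sequence scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import read_tsv
from .matrices import MotifClass
from .scanner import DEFAULT_THRESHOLD, ProteinScanResult, classify_significant

__all__ = [
    "BAITS",
    "ratio_score",
    "read_psm_table",
    "pivot_psm",
    "select_candidates",
    "combine_baits",
    "BaitCombination",
    "build_candidates",
    "annotate_ffat",
    "DEFAULT_RATIO_MIN",
    "DEFAULT_PEPTIDE_MIN",
    "DEFAULT_PSEUDOCOUNT",
]

BAITS: tuple[str, ...] = ("VAP_A", "VAP_B")
CONDITIONS: tuple[str, ...] = ("WT", "MUT")

DEFAULT_RATIO_MIN: float = 2.0
DEFAULT_PEPTIDE_MIN: int = 2
DEFAULT_PSEUDOCOUNT: float = 1.0


def ratio_score(
    psm_wt: float, psm_mut: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """WT-over-mutant PSM ratio with a Laplace pseudocount.

    Strictly increasing in ``psm_wt`` and strictly decreasing in
    ``psm_mut``; equals 1 when the counts are equal; finite even when
    the mutant sample has zero counts.
    """
    if psm_wt < 0 or psm_mut < 0:
        raise ValueError(
            f"PSM counts must be non-negative, got ({psm_wt}, {psm_mut})"
        )
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    return (psm_wt + pseudocount) / (psm_mut + pseudocount)


def read_psm_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format PSM table TSV.

    Expected columns: protein_id, description, bait, condition (WT/MUT),
    score, coverage, peptides, psm. A protein absent from a sample
    simply has no row there; it is treated as count 0 on pivot.
    """
    df = read_tsv(path)
    required = {"protein_id", "bait", "condition", "psm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: PSM table missing columns {sorted(missing)}")
    bad_baits = set(df["bait"]) - set(BAITS)
    if bad_baits:
        raise ValueError(f"{path}: unknown bait label(s) {sorted(bad_baits)}")
    bad_cond = set(df["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"{path}: unknown condition(s) {sorted(bad_cond)}")
    if (df["psm"] < 0).any():
        raise ValueError(f"{path}: negative PSM counts")
    return df


def pivot_psm(table: pd.DataFrame) -> pd.DataFrame:
    """Long PSM table -> one row per protein with per-bait columns.

    Output columns per bait b: ``psm_wt_b``, ``psm_mut_b``,
    ``peptides_b``, ``score_b``. Missing (protein, bait, condition)
    combinations are filled with 0 — absence from a sample is a zero
    count, not missing data.
    """
    out: dict[str, pd.Series] = {}
    proteins = pd.Index(table["protein_id"].unique(), name="protein_id")
    for bait in BAITS:
        sub = table[table["bait"] == bait]
        for cond, label in (("WT", "wt"), ("MUT", "mut")):
            s = (
                sub[sub["condition"] == cond]
                .set_index("protein_id")["psm"]
                .reindex(proteins)
                .fillna(0)
            )
            out[f"psm_{label}_{bait}"] = s
        if "peptides" in sub.columns:
            pep = (
                sub[sub["condition"] == "WT"]
                .set_index("protein_id")
                .get("peptides")
            )
            out[f"peptides_{bait}"] = (
                pep.reindex(proteins).fillna(0)
                if pep is not None
                else pd.Series(0, index=proteins)
            )
    wide = pd.DataFrame(out)
    wide.index = proteins
    return wide.reset_index()


def select_candidates(
    table: pd.DataFrame,
    bait: str,
    ratio_min: float = DEFAULT_RATIO_MIN,
    peptide_min: int = DEFAULT_PEPTIDE_MIN,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> set[str]:
    """FFAT-dependent candidates for one bait.

    A protein is selected when its WT-over-mutant ratio score is at
    least ``ratio_min`` and its WT peptide count is at least
    ``peptide_min``. ``table`` may be the long TSV format (it is pivoted
    on the fly) or an already pivoted wide table.
    """
    if bait not in BAITS:
        raise ValueError(f"unknown bait {bait!r}; expected one of {BAITS}")
    if "bait" in table.columns:
        table = pivot_psm(table)
    wt = table[f"psm_wt_{bait}"].to_numpy(dtype=float)
    mut = table[f"psm_mut_{bait}"].to_numpy(dtype=float)
    pep_col = f"peptides_{bait}"
    peptides = (
        table[pep_col].to_numpy(dtype=float)
        if pep_col in table.columns
        else np.full(len(table), np.inf)
    )
    if math.isinf(ratio_min):
        return set()
    ratios = (wt + pseudocount) / (mut + pseudocount)
    keep = (ratios >= ratio_min) & (peptides >= peptide_min)
    return set(table.loc[keep, "protein_id"])


@dataclass(frozen=True)
class BaitCombination:
    """Union / intersection of per-bait selections with membership labels."""

    union: frozenset[str]
    intersection: frozenset[str]
    membership: Mapping[str, str]  # id -> "A_only" | "B_only" | "both"


def combine_baits(sel_a: Iterable[str], sel_b: Iterable[str]) -> BaitCombination:
    """Combine the VAP-A and VAP-B selections.

    Satisfies inclusion-exclusion exactly: |union| = |A| + |B| - |A∩B|,
    and the membership labels partition the union.
    """
    a, b = set(sel_a), set(sel_b)
    inter = a & b
    membership = {pid: "both" for pid in inter}
    membership.update({pid: "A_only" for pid in a - b})
    membership.update({pid: "B_only" for pid in b - a})
    return BaitCombination(
        union=frozenset(a | b),
        intersection=frozenset(inter),
        membership=membership,
    )


def build_candidates(
    psm_table: pd.DataFrame,
    ratio_min: float = DEFAULT_RATIO_MIN,
    peptide_min: int = DEFAULT_PEPTIDE_MIN,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Full candidate table from a long PSM table.

    One row per selected protein (union over baits) with per-bait ratio
    scores, selection flags, and the bait membership label. Row order is
    descending best ratio score then protein_id, for a stable ranking.
    """
    wide = pivot_psm(psm_table)
    selections = {
        bait: select_candidates(
            wide, bait, ratio_min=ratio_min,
            peptide_min=peptide_min, pseudocount=pseudocount,
        )
        for bait in BAITS
    }
    combo = combine_baits(selections["VAP_A"], selections["VAP_B"])
    wide = wide.set_index("protein_id")
    rows = []
    for pid in sorted(combo.union):
        row: dict[str, object] = {"protein_id": pid}
        for bait in BAITS:
            row[f"ratio_score_{bait}"] = ratio_score(
                float(wide.at[pid, f"psm_wt_{bait}"]),
                float(wide.at[pid, f"psm_mut_{bait}"]),
                pseudocount,
            )
            row[f"selected_{bait}"] = pid in selections[bait]
        row["bait_membership"] = combo.membership[pid]
        rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "ratio_score_VAP_A",
            "ratio_score_VAP_B",
            "selected_VAP_A",
            "selected_VAP_B",
            "bait_membership",
        ],
    )
    if len(df):
        df["_best"] = df[["ratio_score_VAP_A", "ratio_score_VAP_B"]].max(axis=1)
        df = (
            df.sort_values(["_best", "protein_id"], ascending=[False, True])
            .drop(columns="_best")
            .reset_index(drop=True)
        )
    return df


def annotate_ffat(
    candidates: pd.DataFrame,
    scan_results: Sequence[ProteinScanResult] | Mapping[str, ProteinScanResult],
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[pd.DataFrame, int]:
    """Attach best FFAT / Phospho-FFAT scores and a significance flag.

    A candidate is FFAT-significant when the minimum of its best
    conventional and best phospho score lies in [0, threshold].
    Candidates missing from the scan are flagged (``ffat_scanned``
    False), never dropped. Returns the annotated table and the count of
    significant candidates.
    """
    if not isinstance(scan_results, Mapping):
        scan_results = {r.protein_id: r for r in scan_results}
    df = candidates.copy()
    conv, phos, scanned, signif = [], [], [], []
    for pid in df["protein_id"]:
        res = scan_results.get(pid)
        if res is None:
            conv.append(np.nan)
            phos.append(np.nan)
            scanned.append(False)
            signif.append(False)
            continue
        c = res.best_score.get(MotifClass.CONVENTIONAL)
        p = res.best_score.get(MotifClass.PHOSPHO)
        conv.append(np.nan if c is None else c)
        phos.append(np.nan if p is None else p)
        scanned.append(True)
        scores = [s for s in (c, p) if s is not None]
        signif.append(
            bool(scores) and classify_significant(min(scores), threshold)
        )
    df["best_conventional"] = conv
    df["best_phospho"] = phos
    df["ffat_scanned"] = scanned
    df["ffat_significant"] = signif
    return df, int(sum(signif))
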