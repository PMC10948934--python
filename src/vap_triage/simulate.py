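"""Seeded synthetic inputs with machine-readable truth records.

Three generators emulate the three data layers of the triage pipeline:

* :func:`gen_proteome` — a FASTA of random-background proteins with
  19-residue motifs planted at known positions. Each plant starts from
  the matrix's ideal sequence and is degraded by substitutions whose
  penalties sum *exactly* to a requested budget, so the expected score
  is known without tolerance. Background windows are rejection-sampled
  to score strictly above ``budget + margin`` under every matrix in
  play, making each planted window the unique minimum in its protein.
* :func:`gen_psm_experiment` — a long-format PSM count table in which
  true interactors draw Poisson(lambda_wt) counts in the WT sample and
  Poisson(lambda_mut) in the binding-dead mutant sample, while
  background proteins draw Poisson(lambda_background) in both. Counts
  are drawn independently per bait.
* :func:`gen_screen_tables` — a line-level RNAi screen table with
  planted confirmed / single-line suppressors, norpA-positive effectors,
  ERG abnormalities and inviable crosses.

Every generator takes an integer seed and is reproducible bit-for-bit.
A single pipeline-level seed fans out to the three generators through
:func:`split_seed`, which derives independent substreams with
``numpy.random.SeedSequence(seed, spawn_key=(index,))`` — proteome uses
index 0, IP-MS index 1, screen index 2 — so adding one generator never
perturbs the draws of another.

Each artifact is returned (and optionally written) together with a
truth record sufficient to decide pass/fail of every downstream stage
without re-reading generator code.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrices import (
    AMINO_ACIDS,
    POSITIONS,
    WINDOW_LENGTH,
    MotifClass,
    PenaltyMatrix,
    ideal_sequence,
)
from .scanner import scan_sequence

__all__ = [
    "split_seed",
    "random_matrix",
    "ProteomeTruth",
    "PlantedMotif",
    "gen_proteome",
    "PsmTruth",
    "gen_psm_experiment",
    "ScreenTruth",
    "gen_screen_tables",
]


def split_seed(seed: int, index: int) -> np.random.Generator:
    """Substream ``index`` of the global ``seed`` (documented fan-out)."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(index,))
    )


# -- random toy matrices (for property tests and oracle sweeps) ----------


def random_matrix(
    rng: np.random.Generator,
    motif_class: MotifClass = MotifClass.CONVENTIONAL,
    max_penalty: float = 5.0,
    name: str = "toy",
) -> PenaltyMatrix:
    """A random *valid* penalty matrix.

    Penalties are drawn on a 0.5 grid in [0, max_penalty]; one residue
    per position is then forced to 0 so the ideal-sequence invariant
    holds. Intended for property tests, not biology.
    """
    n_steps = int(max_penalty / 0.5)
    vals = rng.integers(0, n_steps + 1, size=(20, 19)) * 0.5
    zero_rows = rng.integers(0, 20, size=19)
    vals[zero_rows, np.arange(19)] = 0.0
    table = pd.DataFrame(
        vals, index=list(AMINO_ACIDS), columns=list(POSITIONS)
    )
    return PenaltyMatrix(name=name, motif_class=motif_class, table=table)


# -- proteome with planted motifs ---------------------------------------


@dataclass(frozen=True)
class PlantedMotif:
    protein_id: str
    motif_class: str
    start: int  # 1-based
    expected_score: float
    window_seq: str


@dataclass(frozen=True)
class ProteomeTruth:
    seed: int
    params: dict
    planted: tuple[PlantedMotif, ...]
    n_proteins: int
    significance_threshold: float

    @property
    def planted_protein_ids(self) -> frozenset[str]:
        return frozenset(p.protein_id for p in self.planted)

    def n_significant(self) -> int:
        """Planted proteins whose expected score is within the band."""
        ids = {
            p.protein_id
            for p in self.planted
            if p.expected_score <= self.significance_threshold
        }
        return len(ids)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "proteome",
                "seed": self.seed,
                "params": self.params,
                "n_proteins": self.n_proteins,
                "significance_threshold": self.significance_threshold,
                "planted": [dataclasses.asdict(p) for p in self.planted],
            },
            indent=2,
        )


def _degrade_to_budget(
    window: list[str],
    matrix: PenaltyMatrix,
    budget: float,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> tuple[list[str], float]:
    """Substitute residues so the window's score rises by exactly
    ``budget`` relative to ideal (= scores exactly ``budget``).

    Randomised greedy over matrix cells with restarts; raises when no
    combination of available single-cell penalties sums to the budget.
    """
    if budget < 0:
        raise ValueError(f"degradation budget must be >= 0, got {budget}")
    if budget == 0:
        return list(window), 0.0
    arr = matrix.table  # residues x positions
    base = list(window)
    for _ in range(max_tries):
        cur = list(base)
        remaining = budget
        order = rng.permutation(WINDOW_LENGTH)
        for pos_i in order:
            if remaining <= 0:
                break
            pos = POSITIONS[pos_i]
            ideal_res = cur[pos_i]
            # candidate substitutions at this position
            cands = [
                (aa, float(arr.at[aa, pos]))
                for aa in AMINO_ACIDS
                if aa != ideal_res and 0 < float(arr.at[aa, pos]) <= remaining
            ]
            if not cands:
                continue
            exact = [c for c in cands if c[1] == remaining]
            if exact:
                aa, p = exact[rng.integers(len(exact))]
            else:
                aa, p = cands[rng.integers(len(cands))]
            cur[pos_i] = aa
            remaining -= p
        if abs(remaining) < 1e-12:
            return cur, budget
    raise ValueError(
        f"degradation budget {budget} not reachable with substitutions "
        f"available in matrix {matrix.name!r}"
    )


def _window_scores(seq: str, matrix: PenaltyMatrix) -> np.ndarray:
    hits = scan_sequence(seq, matrix)
    return np.array([h.score for h in hits])


def gen_proteome(
    n_proteins: int = 100,
    length_range: tuple[int, int] = (150, 400),
    n_planted_conventional: int = 18,
    n_planted_phospho: int = 18,
    degradation_penalty_budget: float = 2.5,
    matrix_pair: Mapping[MotifClass, PenaltyMatrix] | None = None,
    seed: int = 0,
    margin: float = 2.0,
    significance_threshold: float = 2.5,
    background_composition: Sequence[float] | None = None,
    max_rounds: int = 200,
) -> tuple[list[tuple[str, str]], ProteomeTruth]:
    """Synthetic proteome with planted FFAT / Phospho-FFAT motifs.

    One motif is planted per planted protein (conventional plants first,
    then phospho, assigned to distinct proteins chosen at random). Each
    plant is the matrix's ideal 19-mer degraded by substitutions summing
    exactly to ``degradation_penalty_budget``. All other windows of
    every protein — under *both* matrices — are rejection-resampled
    until they score strictly above ``budget + margin``, so each planted
    start is the unique minimum and downstream recovery is guaranteed by
    construction, not chance.

    Returns FASTA-ready ``(id, sequence)`` records and the truth record.
    """
    if matrix_pair is None:
        from .matrices import load_default_matrices

        matrix_pair = load_default_matrices()
    matrix_pair = {MotifClass(k): v for k, v in matrix_pair.items()}
    n_planted = n_planted_conventional + n_planted_phospho
    if n_planted > n_proteins:
        raise ValueError(
            f"cannot plant {n_planted} motifs into {n_proteins} proteins"
        )
    lo, hi = length_range
    if lo < WINDOW_LENGTH:
        raise ValueError(
            f"minimum protein length {lo} is below the window length "
            f"{WINDOW_LENGTH}"
        )
    rng = np.random.default_rng(seed)
    probs = None
    if background_composition is not None:
        probs = np.asarray(background_composition, dtype=float)
        probs = probs / probs.sum()

    aa_arr = np.array(list(AMINO_ACIDS))
    plant_classes = [MotifClass.CONVENTIONAL] * n_planted_conventional + [
        MotifClass.PHOSPHO
    ] * n_planted_phospho
    planted_idx = rng.choice(n_proteins, size=n_planted, replace=False)

    floor = degradation_penalty_budget + margin
    records: list[tuple[str, str]] = []
    planted: list[PlantedMotif] = []
    plant_for: dict[int, MotifClass] = {
        int(i): mc for i, mc in zip(planted_idx, plant_classes)
    }

    for i in range(n_proteins):
        pid = f"SYN{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        seq = list(aa_arr[rng.choice(20, size=length, p=probs)])
        plant_span: tuple[int, int] | None = None
        if i in plant_for:
            mc = plant_for[i]
            matrix = matrix_pair[mc]
            window, score = _degrade_to_budget(
                list(ideal_sequence(matrix)),
                matrix,
                degradation_penalty_budget,
                rng,
            )
            start0 = int(rng.integers(0, length - WINDOW_LENGTH + 1))
            seq[start0 : start0 + WINDOW_LENGTH] = window
            plant_span = (start0, start0 + WINDOW_LENGTH)
            planted.append(
                PlantedMotif(
                    protein_id=pid,
                    motif_class=mc.value,
                    start=start0 + 1,
                    expected_score=score,
                    window_seq="".join(window),
                )
            )

        # Rejection-resample background so every non-planted window
        # scores above the floor under every matrix.
        for _ in range(max_rounds):
            offending: set[int] = set()
            s = "".join(seq)
            for matrix in matrix_pair.values():
                scores = _window_scores(s, matrix)
                for w in np.flatnonzero(scores <= floor):
                    w = int(w)
                    if plant_span is not None and w == plant_span[0]:
                        continue  # the plant itself
                    offending.add(w)
            if not offending:
                break
            resample: set[int] = set()
            for w in offending:
                for j in range(w, w + WINDOW_LENGTH):
                    if plant_span is None or not (
                        plant_span[0] <= j < plant_span[1]
                    ):
                        resample.add(j)
            if not resample:
                raise ValueError(
                    f"protein {pid}: cannot enforce background margin "
                    "(offending window has no background residue)"
                )
            for j in sorted(resample):
                seq[j] = str(aa_arr[rng.choice(20, p=probs)])
        else:
            raise ValueError(
                f"protein {pid}: background margin not achieved after "
                f"{max_rounds} resampling rounds"
            )
        records.append((pid, "".join(seq)))

    truth = ProteomeTruth(
        seed=seed,
        params={
            "n_proteins": n_proteins,
            "length_range": list(length_range),
            "n_planted_conventional": n_planted_conventional,
            "n_planted_phospho": n_planted_phospho,
            "degradation_penalty_budget": degradation_penalty_budget,
            "margin": margin,
            "matrices": {
                mc.value: m.name for mc, m in matrix_pair.items()
            },
        },
        planted=tuple(planted),
        n_proteins=n_proteins,
        significance_threshold=significance_threshold,
    )
    return records, truth


# -- IP-MS PSM tables ----------------------------------------------------


@dataclass(frozen=True)
class PsmTruth:
    seed: int
    params: dict
    true_interactors: tuple[str, ...]
    background: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "ipms",
                "seed": self.seed,
                "params": self.params,
                "true_interactors": list(self.true_interactors),
                "background": list(self.background),
            },
            indent=2,
        )


def gen_psm_experiment(
    n_true: int = 50,
    n_background: int = 200,
    lambda_wt: float = 20.0,
    lambda_mut: float = 1.0,
    lambda_background: float = 50.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, PsmTruth]:
    """Synthetic long-format PSM table for both baits.

    True interactors draw WT counts from Poisson(lambda_wt) and mutant
    counts from Poisson(lambda_mut); background proteins draw
    Poisson(lambda_background) in both conditions — abundant
    nonspecific binders that stick to WT and binding-dead bait alike,
    so their WT/mutant ratio concentrates tightly around 1. All draws are
    independent per bait. Peptide counts are a deterministic function of
    the PSM count (``ceil(psm / 3)``), mimicking the usual
    several-spectra-per-peptide redundancy; the opaque search-engine
    score column is ``10 * psm`` and is not used by selection defaults.
    """
    if lambda_wt <= 0 or lambda_background <= 0:
        raise ValueError("lambda_wt and lambda_background must be > 0")
    if lambda_mut < 0:
        raise ValueError("lambda_mut must be >= 0")
    rng = np.random.default_rng(seed)
    true_ids = [f"TRUE{i:04d}" for i in range(n_true)]
    bg_ids = [f"BG{i:04d}" for i in range(n_background)]

    rows = []
    for bait in ("VAP_A", "VAP_B"):
        for pid in true_ids:
            wt = int(rng.poisson(lambda_wt))
            mut = int(rng.poisson(lambda_mut))
            rows.append((pid, "synthetic true interactor", bait, "WT", wt))
            rows.append((pid, "synthetic true interactor", bait, "MUT", mut))
        for pid in bg_ids:
            wt = int(rng.poisson(lambda_background))
            mut = int(rng.poisson(lambda_background))
            rows.append((pid, "synthetic background", bait, "WT", wt))
            rows.append((pid, "synthetic background", bait, "MUT", mut))
    df = pd.DataFrame(
        rows, columns=["protein_id", "description", "bait", "condition", "psm"]
    )
    df["peptides"] = np.ceil(df["psm"] / 3).astype(int)
    df["score"] = 10.0 * df["psm"]
    df["coverage"] = (2.0 * df["peptides"]).clip(upper=100.0)
    df = df[
        ["protein_id", "description", "bait", "condition",
         "score", "coverage", "peptides", "psm"]
    ]
    truth = PsmTruth(
        seed=seed,
        params={
            "n_true": n_true,
            "n_background": n_background,
            "lambda_wt": lambda_wt,
            "lambda_mut": lambda_mut,
            "lambda_background": lambda_background,
        },
        true_interactors=tuple(true_ids),
        background=tuple(bg_ids),
    )
    return df, truth


# -- screen tables -------------------------------------------------------


@dataclass(frozen=True)
class ScreenTruth:
    seed: int
    params: dict
    suppressors: tuple[str, ...]
    confirmed: tuple[str, ...]
    single_line: tuple[str, ...]
    effectors: tuple[str, ...]
    trigger_specific: tuple[str, ...]
    erg_flagged: tuple[str, ...]
    inviable: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(
            {"kind": "screen", "seed": self.seed, "params": self.params}
            | {
                k: list(getattr(self, k))
                for k in (
                    "suppressors",
                    "confirmed",
                    "single_line",
                    "effectors",
                    "trigger_specific",
                    "erg_flagged",
                    "inviable",
                )
            },
            indent=2,
        )


def gen_screen_tables(
    n_genes: int = 388,
    n_suppressors: int = 52,
    n_effectors: int = 13,
    n_single_line: int = 3,
    n_erg_abnormal: int = 6,
    seed: int = 0,
    n_inviable: int = 15,
) -> tuple[pd.DataFrame, ScreenTruth]:
    """Synthetic line-level screen table with planted structure.

    ``n_suppressors`` genes score positive (``n_single_line`` of them
    via a single available RNAi line, the rest via two independent
    lines); ``n_effectors`` of the suppressors also suppress *norpA*;
    ``n_erg_abnormal`` of the suppressors show a consistent ERG
    abnormality (the last one planted is ``higher``, the rest
    ``lower``). ``n_inviable`` non-suppressor genes have a single line
    whose cross is inviable. The defaults mirror the screen funnel this
    pipeline tabulates (388 screened, 52 suppressors, 13 effectors,
    3 single-line entries, 6 ERG-abnormal, 15 inviable).
    """
    if n_effectors > n_suppressors:
        raise ValueError("n_effectors cannot exceed n_suppressors")
    if n_single_line > n_suppressors:
        raise ValueError("n_single_line cannot exceed n_suppressors")
    if n_erg_abnormal > n_suppressors:
        raise ValueError("n_erg_abnormal cannot exceed n_suppressors")
    if n_suppressors + n_inviable > n_genes:
        raise ValueError(
            "n_suppressors + n_inviable cannot exceed n_genes"
        )
    rng = np.random.default_rng(seed)
    genes = [f"CGS{i:04d}" for i in range(n_genes)]
    order = rng.permutation(n_genes)
    supp = [genes[i] for i in order[:n_suppressors]]
    inviable = [
        genes[i] for i in order[n_suppressors : n_suppressors + n_inviable]
    ]
    single = supp[:n_single_line]
    effectors = supp[-n_effectors:] if n_effectors else []
    erg_abnormal = supp[n_single_line : n_single_line + n_erg_abnormal]
    erg_kind = {g: "lower" for g in erg_abnormal}
    if erg_abnormal:
        erg_kind[erg_abnormal[-1]] = "higher"

    rows = []
    line_counter = 0

    def new_line() -> str:
        nonlocal line_counter
        line_counter += 1
        return f"L{line_counter:05d}"

    for gene in genes:
        is_supp = gene in set(supp)
        n_lines = 1 if (gene in set(single) or gene in set(inviable)) else 2
        for _ in range(n_lines):
            if gene in set(inviable):
                grade, viable = "none", False
            elif is_supp:
                grade = "++" if rng.random() < 0.6 else "+"
                viable = True
            else:
                grade, viable = "none", True
            erg = erg_kind.get(gene, "normal") if is_supp else "untested"
            rows.append(
                {
                    "gene": gene,
                    "line_id": new_line(),
                    "source": "SYN",
                    "suppression": grade,
                    "viable": viable,
                    "norpA": gene in set(effectors) if is_supp else False,
                    "erg": erg,
                }
            )
    df = pd.DataFrame(rows)
    truth = ScreenTruth(
        seed=seed,
        params={
            "n_genes": n_genes,
            "n_suppressors": n_suppressors,
            "n_effectors": n_effectors,
            "n_single_line": n_single_line,
            "n_erg_abnormal": n_erg_abnormal,
            "n_inviable": n_inviable,
        },
        suppressors=tuple(sorted(supp)),
        confirmed=tuple(sorted(set(supp) - set(single))),
        single_line=tuple(sorted(single)),
        effectors=tuple(sorted(effectors)),
        trigger_specific=tuple(sorted(set(supp) - set(effectors))),
        erg_flagged=tuple(sorted(erg_abnormal)),
        inviable=tuple(sorted(inviable)),
    )
    return df, truth
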