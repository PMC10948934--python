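"""Genetic modifier screen tabulation and trigger/effector triage.

Candidate VAP interactors are mapped to their fly orthologs, each
ortholog is depleted by RNAi in the sensitised *rdgB* hypomorph
background, and suppression of retinal degeneration is graded per RNAi
line: "++" definite, "+" partial, or none. A gene is a *confirmed*
suppressor when two independent RNAi lines both score positive; genes
with only a single available line that scored positive are tabulated
too, carried with an explicit unconfirmed status. Crosses that produced
no adult progeny (inviable) are reported separately and never counted
as tested lines.

Tabulated suppressors are then partitioned by an epistasis test in an
independent degeneration mutant (*norpA*): suppressors that also rescue
*norpA* act on shared downstream degeneration machinery (effectors);
the remainder are specific to the *rdgB* lesion (trigger-specific).
Finally, electroretinogram (ERG) outcomes in an otherwise wild-type
background flag suppressors that alter the light response itself; an
abnormality (lower/higher amplitude) must agree across all tested lines
of a gene to be flagged, and rough-eye developmental phenotypes are
segregated into their own list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import read_tsv

__all__ = [
    "SUPPRESSION_GRADES",
    "ERG_OUTCOMES",
    "OrthologMap",
    "read_ortholog_map",
    "join_orthologs",
    "screenable_genes",
    "read_screen_table",
    "SuppressorTabulation",
    "tabulate_suppressors",
    "classify_trigger_effector",
    "flag_phototransduction",
    "TriageReport",
    "summary_report",
]

#: Per-line suppression vocabulary: none, partial, definite.
SUPPRESSION_GRADES: tuple[str, ...] = ("none", "+", "++")
POSITIVE_GRADES: tuple[str, ...] = ("+", "++")

ERG_OUTCOMES: tuple[str, ...] = (
    "normal",
    "lower",
    "higher",
    "rough_eye",
    "untested",
)


# -- ortholog mapping ----------------------------------------------------


@dataclass(frozen=True)
class OrthologEntry:
    fly_gene_id: str
    diopt_score: float
    coverage_ok: bool


#: human protein id -> best fly ortholog entry
OrthologMap = Mapping[str, OrthologEntry]


def read_ortholog_map(path: str | Path) -> dict[str, OrthologEntry]:
    """Read a human->fly ortholog map TSV.

    Columns: human_id, fly_cg, diopt_score, coverage_pct. One best fly
    gene per human protein; a duplicate human_id is an error. Coverage
    is considered adequate at >90%.
    """
    df = read_tsv(path, dtype={"human_id": str, "fly_cg": str})
    dups = df["human_id"][df["human_id"].duplicated()].unique()
    if len(dups):
        raise ValueError(
            f"{path}: duplicate fly assignments for human id(s) "
            f"{sorted(dups)}"
        )
    out = {}
    for row in df.itertuples(index=False):
        out[row.human_id] = OrthologEntry(
            fly_gene_id=row.fly_cg,
            diopt_score=float(getattr(row, "diopt_score", 0.0)),
            coverage_ok=float(getattr(row, "coverage_pct", 100.0)) > 90.0,
        )
    return out


def join_orthologs(
    candidates: pd.DataFrame, ortholog_map: OrthologMap
) -> tuple[pd.DataFrame, int]:
    """Attach fly orthologs to the candidate table.

    Every candidate gains a ``fly_gene_id`` (or <NA>) and a ``mapped``
    flag; returns the annotated table and the number mapped.
    """
    df = candidates.copy()
    fly, mapped, diopt = [], [], []
    for pid in df["protein_id"]:
        entry = ortholog_map.get(pid)
        if entry is None or not entry.coverage_ok:
            fly.append(pd.NA)
            mapped.append(False)
            diopt.append(pd.NA)
        else:
            fly.append(entry.fly_gene_id)
            mapped.append(True)
            diopt.append(entry.diopt_score)
    df["fly_gene_id"] = fly
    df["mapped"] = mapped
    df["diopt_score"] = diopt
    return df, int(sum(mapped))


def screenable_genes(records: pd.DataFrame) -> set[str]:
    """Fly genes with at least one available RNAi line.

    ``records`` needs columns ``fly_gene_id`` and ``rnai_available``.
    """
    avail = records[records["rnai_available"].astype(bool)]
    return set(avail["fly_gene_id"])


# -- screen table --------------------------------------------------------


def read_screen_table(path: str | Path) -> pd.DataFrame:
    """Read a line-level screen outcome TSV.

    Columns: gene, line_id, source, suppression (none/+/++), viable
    (bool), norpA (bool, blank allowed for untested), erg (outcome
    vocabulary). One row per (gene, RNAi line).
    """
    df = read_tsv(
        path,
        dtype={"gene": str, "line_id": str, "source": str, "suppression": str,
               "erg": str},
    )
    required = {"gene", "line_id", "suppression", "viable"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: screen table missing columns {sorted(missing)}"
        )
    df["suppression"] = df["suppression"].fillna("none")
    bad = set(df["suppression"]) - set(SUPPRESSION_GRADES)
    if bad:
        raise ValueError(
            f"{path}: suppression grades outside vocabulary "
            f"{SUPPRESSION_GRADES}: {sorted(bad)}"
        )
    if "erg" in df.columns:
        df["erg"] = df["erg"].fillna("untested")
        bad = set(df["erg"]) - set(ERG_OUTCOMES)
        if bad:
            raise ValueError(
                f"{path}: ERG outcomes outside vocabulary {ERG_OUTCOMES}: "
                f"{sorted(bad)}"
            )
    df["viable"] = df["viable"].astype(bool)
    if "norpA" in df.columns:
        df["norpA"] = df["norpA"].map(
            {True: True, False: False, "True": True, "False": False,
             "Yes": True, "No": False, "yes": True, "no": False}
        )
    return df


@dataclass(frozen=True)
class SuppressorTabulation:
    """Outcome of suppressor tabulation.

    ``tabulated`` = confirmed (>=2 positive independent lines) plus
    single-line positives; ``inviable`` genes had no viable tested line
    and are reported separately, outside the tabulation.
    """

    tabulated: frozenset[str]
    confirmed: frozenset[str]
    single_line: frozenset[str]
    inviable: frozenset[str]
    table: pd.DataFrame = field(repr=False)


def tabulate_suppressors(screen: pd.DataFrame) -> SuppressorTabulation:
    """Tabulate suppressors from a line-level screen table.

    A gene is a confirmed suppressor when at least two independent
    viable lines each scored "+" or "++"; a single-line suppressor when
    exactly one viable line exists and it scored positive. Both enter
    the tabulated set (confirmation status carried). Genes whose every
    cross was inviable go to the ``inviable`` set. A gene present with
    no line at all is an error — availability bookkeeping belongs
    upstream (see :func:`screenable_genes`).

    The result is invariant to the order of lines within a gene.
    """
    rows = []
    tabulated, confirmed, single, inviable = set(), set(), set(), set()
    for gene, grp in screen.groupby("gene", sort=True):
        lines = grp[grp["line_id"].notna() & (grp["line_id"] != "")]
        if lines.empty:
            raise ValueError(
                f"gene {gene!r} has zero tested lines in the screen table"
            )
        viable = lines[lines["viable"]]
        if viable.empty:
            inviable.add(gene)
            rows.append(
                {"gene": gene, "n_lines": len(lines), "n_positive": 0,
                 "status": "inviable"}
            )
            continue
        n_pos = int(viable["suppression"].isin(POSITIVE_GRADES).sum())
        if n_pos >= 2:
            confirmed.add(gene)
            tabulated.add(gene)
            status = "confirmed"
        elif n_pos == 1 and len(viable) == 1:
            single.add(gene)
            tabulated.add(gene)
            status = "single_line"
        elif n_pos >= 1:
            status = "not_confirmed"  # one positive, one negative line
        else:
            status = "no_suppression"
        rows.append(
            {"gene": gene, "n_lines": len(viable), "n_positive": n_pos,
             "status": status}
        )
    table = pd.DataFrame(
        rows, columns=["gene", "n_lines", "n_positive", "status"]
    )
    return SuppressorTabulation(
        tabulated=frozenset(tabulated),
        confirmed=frozenset(confirmed),
        single_line=frozenset(single),
        inviable=frozenset(inviable),
        table=table,
    )


def classify_trigger_effector(
    suppressors: Iterable[str], norpa_flags: Mapping[str, bool]
) -> tuple[set[str], set[str]]:
    """Partition suppressors into effectors vs trigger-specific.

    Effectors also suppress degeneration in the independent *norpA*
    background; trigger-specific suppressors do not. The two sets are
    disjoint and their union is the input. Every suppressor must carry a
    flag; a missing one is an error naming the gene.
    """
    suppressors = set(suppressors)
    missing = sorted(g for g in suppressors if g not in norpa_flags)
    if missing:
        raise ValueError(
            f"missing norpA suppression flag for gene(s): {missing}"
        )
    effectors = {g for g in suppressors if bool(norpa_flags[g])}
    trigger_specific = suppressors - effectors
    return effectors, trigger_specific


def flag_phototransduction(
    suppressors: Iterable[str],
    erg_outcomes: Mapping[str, Sequence[str]] | pd.DataFrame,
) -> tuple[list[str], list[str]]:
    """Flag suppressors whose depletion alters the light response.

    ``erg_outcomes`` maps gene -> per-line ERG outcomes (or a DataFrame
    with ``gene`` and ``erg`` columns). A gene is flagged when every
    tested (non-``untested``) line agrees on ``lower``, or every line on
    ``higher``; where two lines were tested the abnormality must be
    seen in both. Genes with a rough-eye phenotype in any line are
    returned in a separate list (developmental confound, not flagged).
    Untested genes are allowed and simply not flagged.
    """
    if isinstance(erg_outcomes, pd.DataFrame):
        mapping: dict[str, list[str]] = {}
        for gene, grp in erg_outcomes.groupby("gene"):
            mapping[gene] = list(grp["erg"])
        erg_outcomes = mapping
    flagged, rough = [], []
    for gene in sorted(set(suppressors)):
        outcomes = [
            o for o in erg_outcomes.get(gene, []) if o != "untested"
        ]
        if not outcomes:
            continue
        if "rough_eye" in outcomes:
            rough.append(gene)
            continue
        if all(o == "lower" for o in outcomes) or all(
            o == "higher" for o in outcomes
        ):
            flagged.append(gene)
    return flagged, rough


# -- report --------------------------------------------------------------


@dataclass(frozen=True)
class TriageReport:
    """End-of-pipeline counts, one per funnel stage."""

    n_candidates: int
    n_orthologs: int
    n_screenable: int
    n_suppressors: int
    n_confirmed: int
    n_single_line: int
    n_inviable: int
    n_effectors: int
    n_trigger_specific: int
    erg_flagged: tuple[str, ...]
    rough_eye: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_trigger_specific != self.n_suppressors - self.n_effectors:
            raise AssertionError(
                "inconsistent counts: trigger_specific "
                f"({self.n_trigger_specific}) != suppressors "
                f"({self.n_suppressors}) - effectors ({self.n_effectors})"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("candidates", "ipms_enrichment", self.n_candidates),
            ("orthologs_mapped", "ortholog_join", self.n_orthologs),
            ("screenable", "rnai_availability", self.n_screenable),
            ("suppressors_tabulated", "primary_screen", self.n_suppressors),
            ("suppressors_confirmed", "primary_screen", self.n_confirmed),
            ("suppressors_single_line", "primary_screen", self.n_single_line),
            ("inviable_crosses", "primary_screen", self.n_inviable),
            ("effectors", "norpA_screen", self.n_effectors),
            ("trigger_specific", "norpA_screen", self.n_trigger_specific),
            ("erg_flagged", "erg_screen", len(self.erg_flagged)),
            ("rough_eye", "erg_screen", len(self.rough_eye)),
        ]
        return pd.DataFrame(rows, columns=["quantity", "stage", "count"])

    def to_text(self) -> str:
        lines = ["VAP interactor triage report", "=" * 28]
        for row in self.to_frame().itertuples(index=False):
            lines.append(f"{row.quantity:<24s} [{row.stage}] {row.count}")
        if self.erg_flagged:
            lines.append("ERG-flagged genes: " + ", ".join(self.erg_flagged))
        if self.rough_eye:
            lines.append("Rough-eye genes:   " + ", ".join(self.rough_eye))
        return "\n".join(lines) + "\n"


def summary_report(
    *,
    n_candidates: int,
    n_orthologs: int,
    n_screenable: int,
    tabulation: SuppressorTabulation,
    effectors: set[str],
    trigger_specific: set[str],
    erg_flagged: Sequence[str],
    rough_eye: Sequence[str],
) -> TriageReport:
    """Assemble the final report; inconsistent counts raise."""
    if effectors & trigger_specific:
        raise AssertionError(
            "effector and trigger-specific sets overlap: "
            f"{sorted(effectors & trigger_specific)}"
        )
    if (effectors | trigger_specific) != set(tabulation.tabulated):
        raise AssertionError(
            "effector/trigger partition does not cover the tabulated set"
        )
    bad = set(erg_flagged) - set(tabulation.tabulated)
    if bad:
        raise AssertionError(
            f"ERG-flagged genes outside the suppressor set: {sorted(bad)}"
        )
    return TriageReport(
        n_candidates=n_candidates,
        n_orthologs=n_orthologs,
        n_screenable=n_screenable,
        n_suppressors=len(tabulation.tabulated),
        n_confirmed=len(tabulation.confirmed),
        n_single_line=len(tabulation.single_line),
        n_inviable=len(tabulation.inviable),
        n_effectors=len(effectors),
        n_trigger_specific=len(trigger_specific),
        erg_flagged=tuple(erg_flagged),
        rough_eye=tuple(rough_eye),
    )
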