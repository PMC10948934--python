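"""Top-level pipeline: rank -> scan -> annotate -> join -> tabulate ->
classify -> report.

Each stage logs its record counts in and out, so a run reads as the
same funnel the triage itself follows (candidates -> orthologs ->
screenable -> suppressors -> trigger/effector). All outputs are TSV
plus a JSON manifest hashing every input and output; re-running with
identical inputs reproduces byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .enrichment import annotate_ffat, build_candidates, read_psm_table
from .io import read_fasta, write_manifest, write_tsv
from .matrices import MotifClass, default_matrix_path, load_matrix
from .scanner import hits_to_table, results_to_table, scan_proteome
from .screen import (
    classify_trigger_effector,
    flag_phototransduction,
    join_orthologs,
    read_ortholog_map,
    read_screen_table,
    summary_report,
    tabulate_suppressors,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offence."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise annotated
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest dict.

    Required inputs: ``psm_table`` and ``fasta``. ``ortholog_map`` and
    ``screen_table`` are optional — without them the run stops after
    FFAT annotation and the report carries zeros for the later stages.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}
    outputs: dict[str, str] = {}
    counts: dict[str, int] = {}

    for name in ("psm_table", "fasta"):
        val = getattr(config, name)
        if val is None:
            raise PipelineError(f"stage 'configure': missing input {name!r}")
    for name in ("psm_table", "fasta", "ortholog_map", "screen_table",
                 "conventional_matrix", "phospho_matrix"):
        val = getattr(config, name)
        if val is not None:
            if not Path(val).exists():
                raise PipelineError(
                    f"stage 'configure': input file not found: {val}"
                )
            inputs[name] = val

    conv_path = config.conventional_matrix or default_matrix_path(
        MotifClass.CONVENTIONAL
    )
    phos_path = config.phospho_matrix or default_matrix_path(
        MotifClass.PHOSPHO
    )
    inputs.setdefault("conventional_matrix", str(conv_path))
    inputs.setdefault("phospho_matrix", str(phos_path))
    matrices = _load_matrices(conv_path, phos_path)

    # -- rank ------------------------------------------------------------
    psm = _read_psm(config.psm_table)
    candidates = _rank(psm, config)
    counts["candidates"] = len(candidates)
    logger.info("rank: %d PSM rows in, %d candidates out",
                len(psm), len(candidates))

    # -- scan ------------------------------------------------------------
    records = _read_proteome(config.fasta)
    results = _scan(records, matrices, config)
    counts["proteins_scanned"] = len(results)
    scan_path = out_dir / "scan_hits.tsv"
    write_tsv(hits_to_table(results), scan_path)
    outputs["scan_hits"] = str(scan_path)
    wide_path = out_dir / "scan_summary.tsv"
    write_tsv(results_to_table(results), wide_path)
    outputs["scan_summary"] = str(wide_path)

    # -- annotate --------------------------------------------------------
    candidates, n_significant = _annotate(candidates, results, config)
    counts["ffat_significant"] = n_significant
    logger.info("annotate: %d of %d candidates FFAT-significant",
                n_significant, len(candidates))

    # -- join ------------------------------------------------------------
    n_mapped = 0
    if config.ortholog_map:
        candidates, n_mapped = _join(candidates, config.ortholog_map)
        counts["orthologs_mapped"] = n_mapped
        logger.info("join: %d of %d candidates mapped to fly genes",
                    n_mapped, len(candidates))
    cand_path = out_dir / "candidates.tsv"
    write_tsv(candidates, cand_path)
    outputs["candidates"] = str(cand_path)

    # -- tabulate / classify / report -----------------------------------
    if config.screen_table:
        screen = _read_screen(config.screen_table)
        tab = _tabulate(screen)
        counts["suppressors_tabulated"] = len(tab.tabulated)
        norpa = {
            gene: bool(flag)
            for gene, flag in screen.groupby("gene")["norpA"]
            .any()
            .items()
        }
        effectors, trigger = _classify(tab.tabulated, norpa)
        counts["effectors"] = len(effectors)
        counts["trigger_specific"] = len(trigger)
        erg_flagged, rough = _flag_erg(tab.tabulated, screen)
        n_screenable = screen["gene"].nunique()
        counts["screen_genes"] = n_screenable
        report = summary_report(
            n_candidates=len(candidates),
            n_orthologs=n_mapped,
            n_screenable=n_screenable,
            tabulation=tab,
            effectors=effectors,
            trigger_specific=trigger,
            erg_flagged=erg_flagged,
            rough_eye=rough,
        )
        report_path = out_dir / "report.tsv"
        write_tsv(report.to_frame(), report_path)
        outputs["report"] = str(report_path)
        text_path = out_dir / "report.txt"
        text_path.write_text(report.to_text())
        outputs["report_text"] = str(text_path)
        pergene_path = out_dir / "suppressors.tsv"
        write_tsv(tab.table, pergene_path)
        outputs["suppressors"] = str(pergene_path)

    manifest_path = out_dir / "manifest.json"
    manifest = write_manifest(
        manifest_path,
        inputs=inputs,
        outputs=outputs,
        config=config.to_dict(),
        counts=counts,
    )
    return manifest


_read_psm = _stage("rank")(read_psm_table)
_read_proteome = _stage("scan")(read_fasta)
_read_screen = _stage("tabulate")(read_screen_table)
_tabulate = _stage("tabulate")(tabulate_suppressors)
_classify = _stage("classify")(classify_trigger_effector)
_flag_erg = _stage("classify")(flag_phototransduction)
_join = _stage("join")(
    lambda cands, path: join_orthologs(cands, read_ortholog_map(path))
)


@_stage("configure")
def _load_matrices(conv_path, phos_path):
    return {
        MotifClass.CONVENTIONAL: load_matrix(conv_path),
        MotifClass.PHOSPHO: load_matrix(phos_path),
    }


@_stage("rank")
def _rank(psm: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    return build_candidates(
        psm,
        ratio_min=config.ratio_min,
        peptide_min=config.peptide_min,
        pseudocount=config.pseudocount,
    )


@_stage("scan")
def _scan(records, matrices, config: PipelineConfig):
    return scan_proteome(
        records,
        matrices,
        threshold=config.significance_threshold,
        top_k=config.top_k,
    )


@_stage("annotate")
def _annotate(candidates, results, config: PipelineConfig):
    return annotate_ffat(
        candidates, results, threshold=config.significance_threshold
    )
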