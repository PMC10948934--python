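"""Shared readers/writers: FASTA, TSV tables, run manifests.

All tabular formats are plain TSV so that every intermediate of the
pipeline is diff-able and spreadsheet-compatible. Lines starting with
``#`` are treated as comments in every TSV this package reads.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_tsv",
    "write_tsv",
    "file_sha256",
    "write_manifest",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ordered ``(id, sequence)`` pairs.

    The record ID is the first whitespace-delimited token of the header
    (Biopython's convention). Sequences are upper-cased; ``*`` stop
    characters are stripped with a warning. Duplicate IDs and empty
    sequences are errors.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"{path}: duplicate FASTA ID {pid!r}")
        seen.add(pid)
        seq = str(rec.seq).upper()
        if "*" in seq:
            logger.warning(
                "%s: record %s: stripping %d stop character(s)",
                path,
                pid,
                seq.count("*"),
            )
            seq = seq.replace("*", "")
        if not seq:
            raise ValueError(f"{path}: record {pid!r} has an empty sequence")
        records.append((pid, seq))
    return records


def write_fasta(
    records: list[tuple[str, str]], path: str | Path, width: int = 60
) -> None:
    """Write ``(id, sequence)`` pairs as wrapped FASTA."""
    path = Path(path)
    with path.open("w") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV with ``#`` comment lines skipped."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV, deterministic column/row order as given."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    *,
    inputs: dict[str, str | Path],
    outputs: dict[str, str | Path],
    config: dict,
    counts: dict[str, int] | None = None,
) -> dict:
    """Write a JSON run manifest: hashed inputs/outputs, echoed config,
    package version, and per-stage record counts.

    The manifest is the reproducibility contract: re-running with inputs
    of the same hashes and the echoed config reproduces the outputs.
    """
    from . import __version__

    manifest = {
        "package": "vap-triage",
        "version": __version__,
        "config": config,
        "inputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in inputs.items()
        },
        "outputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in outputs.items()
        },
        "counts": counts or {},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
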