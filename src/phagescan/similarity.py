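"""From protein similarity hits to the set of phage-like genes.

A gene is phage-like when its translated product matches a phage reference
protein with e-value strictly below the cutoff (default 1e-5). The aligner
itself sits behind a thin subprocess contract: any tool that takes a query
FASTA plus a formatted protein database and emits the de-facto standard
12-column tabular output ("outfmt 6") works, and a precomputed hit file
bypasses it entirely so the pipeline runs offline.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .io_formats import FormatError

logger = logging.getLogger(__name__)

#: Strict upper bound on e-value for a phage-like match.
DEFAULT_EVALUE_CUTOFF = 1e-5

TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


@dataclass(frozen=True)
class SimilarityHit:
    """One aligner hit row: query gene vs phage reference protein."""

    gene_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue} for {self.gene_id}")


def load_hits(path: str | Path) -> list[SimilarityHit]:
    """Parse a 12-column tab-separated alignment file.

    Malformed rows (wrong column count, non-numeric e-value/bitscore) are
    rejected with their line number; comment lines starting '#' and blank
    lines are skipped.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(cols)}"
                )
            try:
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric e-value or bitscore") from exc
            hits.append(SimilarityHit(cols[0], cols[1], evalue, bitscore))
    return hits


def flag_phage_genes(
    hits: Iterable[SimilarityHit],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    known_genes: Optional[set[str]] = None,
) -> set[str]:
    """The set of gene ids with at least one hit at e-value < cutoff.

    The bound is strict: a hit at exactly the cutoff does not qualify.
    Each gene enters the set at most once however many hits it has. When
    ``known_genes`` is given, hits naming unknown queries are dropped with
    a warning (they cannot be mapped onto the annotation).
    """
    flagged = {h.gene_id for h in hits if h.evalue < evalue_cutoff}
    if known_genes is not None:
        unknown = flagged - known_genes
        if unknown:
            logger.warning(
                "%d hit query id(s) absent from the annotation ignored (e.g. %s)",
                len(unknown),
                sorted(unknown)[0],
            )
            flagged &= known_genes
    return flagged


def run_external_search(
    proteome_fasta: str | Path,
    db_path: str | Path,
    out_path: str | Path,
    threads: int = 1,
    executable: str = "blastp",
    evalue_ceiling: float = 10.0,
) -> Path:
    """Run the external protein aligner and return the tabular hit file.

    Contract: the executable accepts ``-query -db -out -outfmt 6`` and
    writes 12-column tabular output (BLAST+ ``blastp`` fits). Command line,
    version and exit status are logged for the run record.
    """
    exe = shutil.which(executable)
    if exe is None:
        raise FileNotFoundError(
            f"protein aligner {executable!r} not found on PATH; either install it "
            "or supply a precomputed 12-column tabular hit file (--hits FILE)"
        )
    try:
        version = subprocess.run(
            [exe, "-version"], capture_output=True, text=True, check=False
        ).stdout.strip().splitlines()
        logger.info("aligner version: %s", version[0] if version else "unknown")
    except OSError:
        pass
    cmd = [
        exe,
        "-query", str(proteome_fasta),
        "-db", str(db_path),
        "-out", str(out_path),
        "-outfmt", "6",
        "-evalue", str(evalue_ceiling),
        "-num_threads", str(threads),
    ]
    logger.info("running: %s", " ".join(cmd))
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(
            f"{executable} exited with status {proc.returncode}:\n{proc.stderr.strip()}"
        )
    return Path(out_path)


def format_protein_db(db_fasta: str | Path, executable: str = "makeblastdb") -> Path:
    """Index a protein FASTA for the aligner (BLAST+ ``makeblastdb`` contract)."""
    exe = shutil.which(executable)
    if exe is None:
        raise FileNotFoundError(
            f"database formatter {executable!r} not found on PATH; format the "
            "reference FASTA manually or run with a precomputed hit file"
        )
    cmd = [exe, "-dbtype", "prot", "-in", str(db_fasta)]
    logger.info("running: %s", " ".join(cmd))
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(
            f"{executable} exited with status {proc.returncode}:\n{proc.stderr.strip()}"
        )
    return Path(db_fasta)
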