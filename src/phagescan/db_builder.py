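"""Build the phage-protein reference database from local proteome files.

Input is a directory (or list) of per-phage protein FASTA files plus a
metadata table assigning each phage to a taxonomic family. Proteins whose
product annotation matches an exclusion term are dropped and logged —
ABC transporters by default, because they are equally conserved outside
prophages and would seed false-positive predictions. The build is purely
local and dated, so a prediction run can record exactly which reference
it searched.
"""

from __future__ import annotations

import datetime as _dt
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

from .io_formats import FormatError, write_fasta

logger = logging.getLogger(__name__)

DEFAULT_EXCLUSION_TERMS = ("ABC transporter",)


@dataclass(frozen=True)
class DBProtein:
    protein_id: str
    phage_id: str
    family: str
    product: str
    aa_sequence: str


@dataclass
class ReferenceDB:
    """The filtered reference proteome plus its reproducibility record."""

    proteins: list[DBProtein]
    build_date: _dt.date
    per_family_counts: dict[str, int]
    excluded_log: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.proteins)


def read_metadata(path: str | Path) -> dict[str, str]:
    """Read the phage metadata table (TSV: phage_id, family, ...)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(f"{path}:{lineno}: metadata row needs phage_id and family")
            mapping[cols[0]] = cols[1]
    if not mapping:
        raise FormatError(f"no metadata rows in {path}")
    return mapping


def build_db(
    proteome_files: Iterable[str | Path],
    metadata: Mapping[str, str] | str | Path,
    exclusion_terms: Sequence[str] = DEFAULT_EXCLUSION_TERMS,
    build_date: Optional[_dt.date] = None,
) -> ReferenceDB:
    """Assemble and filter the reference database.

    Each proteome file holds one phage's proteins (phage id = file stem);
    the record description after the id is taken as the product annotation.
    A record is excluded when any exclusion term occurs case-insensitively
    in its product, and every exclusion is logged so that
    ``|input| == |kept| + |excluded|`` always holds.
    """
    if not isinstance(metadata, Mapping):
        metadata = read_metadata(metadata)
    terms = [t.lower() for t in exclusion_terms]
    proteins: list[DBProtein] = []
    excluded: list[tuple[str, str]] = []
    for path in sorted(Path(p) for p in proteome_files):
        phage_id = path.stem
        if phage_id not in metadata:
            raise FormatError(f"phage {phage_id!r} ({path}) missing from metadata table")
        family = metadata[phage_id]
        for rec in SeqIO.parse(str(path), "fasta"):
            product = rec.description[len(rec.id):].strip()
            hit_term = next((t for t in terms if t in product.lower()), None)
            if hit_term is not None:
                excluded.append((rec.id, f"product matches exclusion term {hit_term!r}"))
                continue
            proteins.append(DBProtein(rec.id, phage_id, family, product, str(rec.seq).upper()))
    if not proteins:
        raise FormatError(
            "reference database is empty after filtering; a prediction run "
            "against it could flag nothing"
        )
    counts = Counter(p.family for p in proteins)
    logger.info(
        "reference DB built: %d proteins kept, %d excluded, %d families",
        len(proteins), len(excluded), len(counts),
    )
    return ReferenceDB(
        proteins=proteins,
        build_date=build_date or _dt.date.today(),
        per_family_counts=dict(sorted(counts.items())),
        excluded_log=excluded,
    )


def db_report(db: ReferenceDB) -> str:
    """Plain-text reproducibility record: build date, totals, per-family counts."""
    lines = [
        f"build_date\t{db.build_date.isoformat()}",
        f"total_proteins\t{len(db.proteins)}",
        f"total_phages\t{len({p.phage_id for p in db.proteins})}",
        f"excluded_proteins\t{len(db.excluded_log)}",
    ]
    for family, n in db.per_family_counts.items():
        lines.append(f"family\t{family}\t{n}")
    return "\n".join(lines) + "\n"


def write_db(db: ReferenceDB, outdir: str | Path) -> Path:
    """Write the DB directory: reference FASTA, report, and exclusion log.

    Returns the path of the reference FASTA (the aligner's ``-db`` target,
    after formatting).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "phage_proteins.faa"
    write_fasta(((p.protein_id, p.aa_sequence) for p in db.proteins), fasta)
    (outdir / "db_report.txt").write_text(db_report(db))
    with open(outdir / "excluded_proteins.tsv", "w") as fh:
        for pid, reason in db.excluded_log:
            fh.write(f"{pid}\t{reason}\n")
    return fasta
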