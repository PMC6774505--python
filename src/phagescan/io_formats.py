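"""Readers and writers for the formats the pipeline touches.

FASTA and GFF3 come in; BED and per-region FASTA go out. Internally every
coordinate is 0-based half-open; GFF3's 1-based inclusive coordinates are
converted at this boundary and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from gffutils.feature import feature_from_line

from .intervals import Interval

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes accepted on FASTA read (after upper-casing).
_VALID_RESIDUES = frozenset("ACGTNRYSWKMBDHV")

_COUNTED_TYPES = {"CDS", "tRNA", "gene"}


class FormatError(ValueError):
    """A file violates its format contract (names the offending record)."""


class CoordinateError(FormatError):
    """A feature lies outside its contig or on an unknown contig."""


@dataclass(frozen=True)
class ContigSeq:
    """One contig of a genome: id plus upper-cased DNA sequence."""

    contig_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """An annotated interval (CDS/tRNA/gene/other) on a contig.

    ``start``/``end`` are internal 0-based half-open. ``phase`` is the GFF
    CDS phase (bases to skip before the first complete codon), 0 when
    unspecified.
    """

    feature_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    ftype: str = "CDS"
    product: str = ""
    phase: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise CoordinateError(
                f"feature {self.feature_id}: invalid interval "
                f"{self.contig_id}:{self.start}-{self.end}"
            )

    @property
    def interval(self) -> Interval:
        return Interval(self.contig_id, self.start, self.end)

    def overlaps(self, iv: Interval) -> bool:
        return self.contig_id == iv.contig_id and self.start < iv.end and iv.start < self.end


def read_fasta(path: str | Path) -> list[ContigSeq]:
    """Read a (multi-record) nucleotide FASTA into :class:`ContigSeq` records.

    Sequences are upper-cased. Duplicate ids and residues outside the IUPAC
    nucleotide alphabet are rejected with the offending record named.
    """
    contigs: list[ContigSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_RESIDUES
        if bad:
            raise FormatError(
                f"record {rec.id!r} in {path} contains non-nucleotide "
                f"characters: {sorted(bad)}"
            )
        contigs.append(ContigSeq(rec.id, seq))
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return contigs


def read_gff3(path: str | Path, contigs: Sequence[ContigSeq]) -> list[GeneFeature]:
    """Parse a GFF3 annotation against known contigs.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    CDS, tRNA and gene features are typed; anything else is kept with
    ``ftype='other'`` (and ignored by the density scan). A trailing
    ``##FASTA`` section is tolerated and skipped. CDS rows without an ID or
    Parent attribute are skipped with a warning; features on unknown contigs
    or beyond the contig end raise :class:`CoordinateError`.
    """
    lengths = {c.contig_id: c.length for c in contigs}
    feats: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            try:
                f = feature_from_line(line)
            except Exception as exc:  # gffutils raises bare exceptions on bad rows
                raise FormatError(f"{path}:{lineno}: malformed GFF3 row ({exc})") from exc
            if f.seqid not in lengths:
                raise CoordinateError(
                    f"{path}:{lineno}: feature on unknown contig {f.seqid!r}"
                )
            if f.end > lengths[f.seqid]:
                raise CoordinateError(
                    f"{path}:{lineno}: feature end {f.end} exceeds contig "
                    f"{f.seqid!r} length {lengths[f.seqid]}"
                )
            ftype = f.featuretype if f.featuretype in _COUNTED_TYPES else "other"
            fid = _first(f.attributes, "ID") or _first(f.attributes, "Parent")
            if fid is None:
                if ftype == "CDS":
                    logger.warning("%s:%d: CDS without ID or Parent skipped", path, lineno)
                    continue
                fid = f"{f.featuretype}_{f.seqid}_{f.start}"
            if ftype == "CDS" and f.strand not in "+-":
                raise FormatError(f"{path}:{lineno}: CDS {fid!r} lacks a strand")
            phase = int(f.frame) if ftype == "CDS" and f.frame in ("0", "1", "2") else 0
            feats.append(
                GeneFeature(
                    feature_id=fid,
                    contig_id=f.seqid,
                    start=f.start - 1,  # 1-based inclusive -> 0-based half-open
                    end=f.end,
                    strand=f.strand if f.strand in "+-" else "+",
                    ftype=ftype,
                    product=_first(f.attributes, "product") or "",
                    phase=phase,
                )
            )
    return feats


def _first(attrs, key: str) -> str | None:
    vals = attrs.get(key, [])
    return vals[0] if vals else None


def group_cds_by_gene(features: Iterable[GeneFeature]) -> dict[str, list[GeneFeature]]:
    """Group CDS segments by gene id (ID, or Parent for multi-segment genes).

    Segment order within each gene follows genomic position.
    """
    groups: dict[str, list[GeneFeature]] = {}
    for f in features:
        if f.ftype == "CDS":
            groups.setdefault(f.feature_id, []).append(f)
    for segs in groups.values():
        segs.sort(key=lambda f: f.start)
    return groups


def gene_hulls(features: Iterable[GeneFeature]) -> list[GeneFeature]:
    """One interval per gene: the hull of its CDS segments.

    This is the unit the density scan counts. For the prokaryotic common
    case (single-segment CDS) the hull is the CDS itself.
    """
    hulls = []
    for gid, segs in group_cds_by_gene(features).items():
        hulls.append(
            GeneFeature(
                feature_id=gid,
                contig_id=segs[0].contig_id,
                start=min(s.start for s in segs),
                end=max(s.end for s in segs),
                strand=segs[0].strand,
                ftype="CDS",
                product=segs[0].product,
                phase=segs[0].phase,
            )
        )
    hulls.sort(key=lambda f: (f.contig_id, f.start))
    return hulls


def trna_features(features: Iterable[GeneFeature]) -> list[GeneFeature]:
    return sorted(
        (f for f in features if f.ftype == "tRNA"),
        key=lambda f: (f.contig_id, f.start),
    )


def write_bed(predictions, path: str | Path) -> None:
    """Write predictions (or bare intervals) as BED4, sorted and deterministic."""
    rows = []
    for i, p in enumerate(predictions, 1):
        iv = p if isinstance(p, Interval) else p.region
        name = getattr(p, "name", None) or f"prophage_{i}"
        rows.append((iv.contig_id, iv.start, iv.end, name))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for contig, start, end, name in rows:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\n")


def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3+ into intervals (extra columns ignored)."""
    ivs: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: BED row has fewer than 3 columns")
            try:
                ivs.append(Interval(cols[0], int(cols[1]), int(cols[2])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return ivs


def write_region_fasta(
    contigs: Sequence[ContigSeq], predictions, path: str | Path, width: int = 70
) -> None:
    """Write the nucleotide sequence of each predicted region as FASTA."""
    seqs = {c.contig_id: c.sequence for c in contigs}
    with open(path, "w") as fh:
        for i, p in enumerate(predictions, 1):
            iv = p if isinstance(p, Interval) else p.region
            name = getattr(p, "name", None) or f"prophage_{i}"
            if iv.contig_id not in seqs:
                raise CoordinateError(f"region {name} on unknown contig {iv.contig_id!r}")
            seq = seqs[iv.contig_id]
            if iv.end > len(seq):
                raise CoordinateError(
                    f"region {name} ({iv.contig_id}:{iv.start}-{iv.end}) exceeds "
                    f"contig length {len(seq)}"
                )
            fh.write(f">{name} {iv.contig_id}:{iv.start}-{iv.end}\n")
            sub = seq[iv.start : iv.end]
            for k in range(0, len(sub), width):
                fh.write(sub[k : k + width] + "\n")


def write_gff3(
    features: Sequence[GeneFeature], contigs: Sequence[ContigSeq], path: str | Path
) -> None:
    """Write features as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in contigs:
            fh.write(f"##sequence-region {c.contig_id} 1 {c.length}\n")
        for f in sorted(features, key=lambda f: (f.contig_id, f.start, f.end)):
            attrs = f"ID={f.feature_id}"
            if f.product:
                attrs += f";product={f.product}"
            phase = str(f.phase) if f.ftype == "CDS" else "."
            fh.write(
                f"{f.contig_id}\tphagescan\t{f.ftype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t{phase}\t{attrs}\n"
            )


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write (id, sequence) pairs as FASTA (nucleotide or protein)."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")
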