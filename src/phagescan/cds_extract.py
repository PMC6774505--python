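"""Extract coding sequences from the genome and translate them to proteins.

The detector needs the host proteome to search against the phage reference
database: each annotated CDS is sliced out of the genome, oriented, phase-
trimmed and translated with the bacterial/archaeal genetic code (NCBI
translation table 11). Pseudogene-like artefacts (internal stops) are kept
with stops masked to 'X' rather than dropped — silently removing them would
change the gene density the scan measures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .intervals import Interval
from .io_formats import ContigSeq, CoordinateError, GeneFeature, group_cds_by_gene

logger = logging.getLogger(__name__)

#: Genetic code used throughout; the tool targets prokaryotes.
GENETIC_CODE_TABLE = 11

_RC = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(dna: str) -> str:
    return dna.translate(_RC)[::-1]


@dataclass(frozen=True)
class ProteinRecord:
    """A translated gene product tied back to its genomic source."""

    gene_id: str
    contig_id: str
    aa_sequence: str
    source_interval: Interval
    strand: str


def extract_cds(genome: ContigSeq | Mapping[str, ContigSeq], feature: GeneFeature) -> str:
    """Slice a CDS feature out of the genome, oriented to the coding strand.

    Minus-strand features are reverse-complemented. Phase is *not* applied
    here; :func:`translate_gene` trims it before translation.
    """
    contig = genome[feature.contig_id] if isinstance(genome, Mapping) else genome
    if feature.contig_id != contig.contig_id:
        raise CoordinateError(
            f"feature {feature.feature_id} on {feature.contig_id!r}, "
            f"not {contig.contig_id!r}"
        )
    if feature.end > contig.length:
        raise CoordinateError(
            f"feature {feature.feature_id} ends at {feature.end}, beyond contig "
            f"{contig.contig_id!r} length {contig.length}"
        )
    seq = contig.sequence[feature.start : feature.end]
    return reverse_complement(seq) if feature.strand == "-" else seq


def translate(dna: str, table: int = GENETIC_CODE_TABLE) -> str:
    """Translate an oriented CDS to protein.

    Trailing stop removed; a trailing partial codon is dropped with a
    warning; codons containing ambiguity become 'X'; internal stops are
    masked to 'X' with a warning (pseudogenes occur in real annotations and
    the similarity search decides their fate).
    """
    if len(dna) < 3:
        raise ValueError(f"CDS of length {len(dna)} is shorter than one codon")
    rem = len(dna) % 3
    if rem:
        logger.warning("CDS length %d not a multiple of 3; trailing %d nt ignored", len(dna), rem)
        dna = dna[: len(dna) - rem]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # partial-codon warning already handled above
        aa = str(Seq(dna).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        logger.warning("internal stop codon(s) masked to 'X' (%d occurrences)", aa.count("*"))
        aa = aa.replace("*", "X")
    return aa


def translate_gene(
    genome: Mapping[str, ContigSeq], gene_id: str, segments: Sequence[GeneFeature]
) -> ProteinRecord:
    """Translate one gene given its CDS segment(s).

    Multi-segment genes are spliced in genomic order then oriented; the
    phase of the first coding segment (last genomic segment on the minus
    strand) is trimmed before translation.
    """
    segs = sorted(segments, key=lambda f: f.start)
    strand = segs[0].strand
    dna = "".join(genome[s.contig_id].sequence[s.start : s.end] for s in segs)
    if strand == "-":
        dna = reverse_complement(dna)
        phase = segs[-1].phase
    else:
        phase = segs[0].phase
    aa = translate(dna[phase:])
    hull = Interval(segs[0].contig_id, min(s.start for s in segs), max(s.end for s in segs))
    return ProteinRecord(gene_id, segs[0].contig_id, aa, hull, strand)


def translate_genome(
    contigs: Sequence[ContigSeq], features: Iterable[GeneFeature]
) -> list[ProteinRecord]:
    """Translate every annotated gene; the query proteome for the search."""
    genome = {c.contig_id: c for c in contigs}
    records = []
    for gid, segs in group_cds_by_gene(features).items():
        try:
            records.append(translate_gene(genome, gid, segs))
        except ValueError as exc:
            logger.warning("gene %s skipped: %s", gid, exc)
    records.sort(key=lambda r: (r.contig_id, r.source_interval.start))
    return records
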