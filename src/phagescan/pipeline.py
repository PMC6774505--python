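"""End-to-end orchestration: annotation + phage gene set -> final predictions.

Each contig is scanned independently (prophages wholly contained within a
contig of a fragmented assembly are still found); window selection, window
merging, gene-boundary trimming and tRNA adjustment run per contig, and
finalization assigns ids across the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .density_scan import (
    ProphagePrediction,
    ScanParams,
    WindowCount,
    merge_windows,
    scan_windows,
    select_windows,
)
from .edge_refine import DEFAULT_TRNA_FLANK, adjust_to_trna, finalize, trim_to_phage_genes
from .io_formats import ContigSeq, GeneFeature, gene_hulls, trna_features


@dataclass
class PipelineResult:
    """Final predictions plus the per-window intermediates worth keeping."""

    predictions: list[ProphagePrediction]
    window_counts: dict[str, list[WindowCount]] = field(default_factory=dict)


def predict_prophages(
    contigs: Sequence[ContigSeq],
    features: Sequence[GeneFeature],
    phage_set: set[str],
    params: ScanParams = ScanParams(),
    trna_flank: int = DEFAULT_TRNA_FLANK,
) -> PipelineResult:
    """Run scan -> select -> merge -> trim -> tRNA-adjust -> finalize.

    ``features`` is the parsed annotation (CDS segments and tRNAs);
    ``phage_set`` the gene ids flagged by the similarity filter.
    """
    hulls = gene_hulls(features)
    trnas = trna_features(features)
    refined: list[ProphagePrediction] = []
    counts_by_contig: dict[str, list[WindowCount]] = {}
    for contig in contigs:
        cf = [f for f in hulls if f.contig_id == contig.contig_id]
        ct = [t for t in trnas if t.contig_id == contig.contig_id]
        counts = scan_windows(cf, phage_set, contig.length, params)
        counts_by_contig[contig.contig_id] = counts
        selected = select_windows(counts, params, features=cf)
        for prelim in merge_windows(selected) if selected else []:
            trimmed = trim_to_phage_genes(prelim, cf, phage_set)
            if trimmed is not None:
                refined.append(adjust_to_trna(trimmed, ct, trna_flank))
    return PipelineResult(finalize(refined), counts_by_contig)
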