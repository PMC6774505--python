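"""Edge refinement of preliminary prophage predictions.

Merged windows overhang the true prophage by up to a window length on
each side, so borders are first trimmed to the outermost phage-like genes
inside the region. Because tRNA genes are hotspots of phage integration,
each trimmed border is then compared against tRNA genes within 3 kb on
either side: if any are present, the border moves to the most outward
tRNA coordinate (minimum start on the left, maximum end on the right),
which may extend or contract the prediction. Predictions that come to
overlap after extension are merged, and ids are assigned by position.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from .density_scan import (
    STAGE_FINAL,
    STAGE_PRELIMINARY,
    STAGE_TRIMMED,
    ProphagePrediction,
)
from .intervals import Interval
from .io_formats import GeneFeature

logger = logging.getLogger(__name__)

#: How far (bp) beyond each trimmed border to look for tRNA genes.
DEFAULT_TRNA_FLANK = 3_000


def trim_to_phage_genes(
    prediction: ProphagePrediction,
    features: Sequence[GeneFeature],
    phage_set: set[str],
) -> Optional[ProphagePrediction]:
    """Trim a preliminary region to its first and last phage-like gene.

    The new region runs from the start of the leftmost to the end of the
    rightmost phage-like gene overlapping the region, clipped to the
    preliminary region so trimming never enlarges. Returns ``None`` (with
    a warning) if no phage-like gene overlaps — impossible for predictions
    produced by window selection with a positive gene threshold.
    """
    if prediction.stage != STAGE_PRELIMINARY:
        raise ValueError(f"expected a preliminary prediction, got stage {prediction.stage!r}")
    region = prediction.region
    inside = [
        f for f in features if f.feature_id in phage_set and f.overlaps(region)
    ]
    if not inside:
        logger.warning(
            "prediction %s:%d-%d overlaps no phage-like gene; discarded",
            region.contig_id, region.start, region.end,
        )
        return None
    new_start = max(region.start, min(f.start for f in inside))
    new_end = min(region.end, max(f.end for f in inside))
    return prediction.advanced(
        region=Interval(region.contig_id, new_start, new_end),
        stage=STAGE_TRIMMED,
        supporting_gene_ids=frozenset(f.feature_id for f in inside),
    )


def adjust_to_trna(
    prediction: ProphagePrediction,
    trnas: Sequence[GeneFeature],
    flank: int = DEFAULT_TRNA_FLANK,
) -> ProphagePrediction:
    """Move each trimmed border to the most outward nearby tRNA coordinate.

    For the left border ``b`` all tRNAs overlapping ``[b - flank, b + flank)``
    are considered and the border becomes their minimum start; the right
    border symmetrically becomes the maximum end. A border with no tRNA in
    range is unchanged. An adjustment that would invert the interval (a
    tiny prediction squeezed between two tRNAs) is abandoned with a
    warning, keeping the trimmed borders.
    """
    if prediction.stage != STAGE_TRIMMED:
        raise ValueError(f"expected a trimmed prediction, got stage {prediction.stage!r}")
    region = prediction.region
    same_contig = [t for t in trnas if t.contig_id == region.contig_id]

    def in_flank(border: int):
        lo, hi = border - flank, border + flank
        return [t for t in same_contig if t.start < hi and t.end > lo]

    left = in_flank(region.start)
    right = in_flank(region.end)
    new_start = min(t.start for t in left) if left else region.start
    new_end = max(t.end for t in right) if right else region.end
    anchored = tuple(
        t.feature_id
        for t in sorted(set(left) | set(right), key=lambda t: t.start)
    )
    if new_start >= new_end:
        logger.warning(
            "tRNA adjustment would invert %s:%d-%d; keeping trimmed borders",
            region.contig_id, region.start, region.end,
        )
        return prediction.advanced(stage=STAGE_FINAL)
    return prediction.advanced(
        region=Interval(region.contig_id, max(0, new_start), new_end),
        stage=STAGE_FINAL,
        anchored_trnas=anchored,
    )


def finalize(predictions: Sequence[ProphagePrediction]) -> list[ProphagePrediction]:
    """Sort, merge any overlaps created by tRNA extension, and assign ids.

    Output predictions are pairwise disjoint, ordered by (contig, start)
    and named ``prophage_1..n`` in that order.
    """
    for p in predictions:
        if p.stage != STAGE_FINAL:
            raise ValueError(f"finalize expects stage-final predictions, got {p.stage!r}")
    by_contig: dict[str, list[ProphagePrediction]] = {}
    for p in predictions:
        by_contig.setdefault(p.region.contig_id, []).append(p)

    merged: list[ProphagePrediction] = []
    for contig in sorted(by_contig):
        preds = sorted(by_contig[contig], key=lambda p: (p.region.start, p.region.end))
        cur = preds[0]
        for p in preds[1:]:
            if p.region.start <= cur.region.end:  # overlap or book-ended
                cur = ProphagePrediction(
                    Interval(contig, cur.region.start, max(cur.region.end, p.region.end)),
                    STAGE_FINAL,
                    cur.supporting_gene_ids | p.supporting_gene_ids,
                    tuple(dict.fromkeys(cur.anchored_trnas + p.anchored_trnas)),
                )
            else:
                merged.append(cur)
                cur = p
        merged.append(cur)
    return [p.advanced(name=f"prophage_{i}") for i, p in enumerate(merged, 1)]
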