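"""Sliding-window phage-gene density scan.

The detector's core signal is local density of phage-like genes: a window
of 10 kb slides across each contig in 1 kb steps; windows holding at least
8 phage-like genes (and longer than half the window length, which only
bites for truncated terminal windows) are selected, and overlapping
selected windows merge into preliminary prophage predictions.

The 10 kb / 8-gene defaults reflect the size distribution of sequenced
phage genomes: very few are shorter than 10 kb, and even those carry more
than 8 genes, so a genuine prophage should saturate at least one window.

Window membership is any overlap of at least 1 bp between the gene's
interval and the window; overhang beyond the true prophage is removed
later by edge refinement, so the permissive rule costs nothing and is the
most sensitive choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .intervals import Interval
from .io_formats import GeneFeature

logger = logging.getLogger(__name__)

STAGE_PRELIMINARY = "preliminary"
STAGE_TRIMMED = "trimmed"
STAGE_FINAL = "final"
_STAGE_ORDER = (STAGE_PRELIMINARY, STAGE_TRIMMED, STAGE_FINAL)


@dataclass(frozen=True)
class ScanParams:
    """Tunables of the density scan.

    ``min_span`` defaults to half the window length; under the default
    ``span_rule='window'`` it is a strict lower bound on a window
    instance's own length and therefore only excludes truncated terminal
    windows. The alternative rule ``'genespan'`` instead requires the span
    covered by phage-like genes inside the window to exceed ``min_span``.
    """

    window_len: int = 10_000
    step: int = 1_000
    min_genes: int = 8
    min_span: Optional[int] = None
    span_rule: str = "window"

    def __post_init__(self) -> None:
        if self.min_span is None:
            object.__setattr__(self, "min_span", self.window_len // 2)
        if not (0 < self.step <= self.window_len):
            raise ValueError(f"step must be in (0, window_len], got {self.step}")
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")
        if not (0 <= self.min_span <= self.window_len):
            raise ValueError("min_span must be in [0, window_len]")
        if self.span_rule not in ("window", "genespan"):
            raise ValueError(f"unknown span_rule {self.span_rule!r}")


@dataclass(frozen=True)
class WindowCount:
    """One window instance with its phage-like gene tally."""

    window: Interval
    n_phage_genes: int
    phage_gene_ids: frozenset[str]


@dataclass(frozen=True)
class ProphagePrediction:
    """A predicted prophage at one of three refinement stages.

    Stages advance strictly preliminary -> trimmed -> final; ``name`` is
    assigned only at finalization.
    """

    region: Interval
    stage: str = STAGE_PRELIMINARY
    supporting_gene_ids: frozenset[str] = field(default_factory=frozenset)
    anchored_trnas: tuple[str, ...] = ()
    name: Optional[str] = None

    def advanced(self, **changes) -> "ProphagePrediction":
        new = replace(self, **changes)
        if _STAGE_ORDER.index(new.stage) < _STAGE_ORDER.index(self.stage):
            raise ValueError(f"stage cannot move back from {self.stage} to {new.stage}")
        return new


def scan_windows(
    features: Sequence[GeneFeature],
    phage_set: set[str],
    contig_len: int,
    params: ScanParams = ScanParams(),
) -> list[WindowCount]:
    """Count phage-like genes in every window of one contig.

    Windows start at 0, step, 2*step, ...; a window starting at ``s`` spans
    ``[s, min(s + window_len, contig_len))`` and the last start is the
    largest multiple of ``step`` below ``contig_len`` (terminal windows are
    truncated). A contig shorter than the window yields the single
    truncated window ``[0, contig_len)``. A gene is counted in a window iff
    the two intervals share at least 1 bp.

    Rather than testing every (window, gene) pair, each phage-like gene is
    mapped arithmetically onto the contiguous range of window indices it
    overlaps.
    """
    if contig_len <= 0:
        raise ValueError(f"contig length must be positive, got {contig_len}")
    contig_ids = {f.contig_id for f in features}
    if len(contig_ids) > 1:
        raise ValueError(f"features span several contigs: {sorted(contig_ids)}")
    contig_id = contig_ids.pop() if contig_ids else "unknown"

    W, step = params.window_len, params.step
    if contig_len <= W:
        window = Interval(contig_id, 0, contig_len)
        ids = frozenset(
            f.feature_id for f in features if f.feature_id in phage_set and f.start < contig_len
        )
        return [WindowCount(window, len(ids), ids)]

    n_windows = (contig_len - 1) // step + 1
    counts = np.zeros(n_windows, dtype=np.int64)
    members: list[list[str]] = [[] for _ in range(n_windows)]
    for f in features:
        if f.feature_id not in phage_set:
            continue
        # window k overlaps gene [gs, ge) iff k*step > gs - W and k*step < ge
        k_lo = max(0, (f.start - W) // step + 1)
        k_hi = min(n_windows, -(-f.end // step))
        if k_lo < k_hi:
            counts[k_lo:k_hi] += 1
            for k in range(k_lo, k_hi):
                members[k].append(f.feature_id)

    out = []
    for k in range(n_windows):
        s = k * step
        window = Interval(contig_id, s, min(s + W, contig_len))
        ids = frozenset(members[k])
        # a gene id can appear once per window only (hulls are unique per gene)
        out.append(WindowCount(window, len(ids), ids))
    return out


def select_windows(
    counts: Iterable[WindowCount],
    params: ScanParams = ScanParams(),
    features: Optional[Sequence[GeneFeature]] = None,
) -> list[WindowCount]:
    """Keep windows with enough phage-like genes and enough length.

    The gene threshold is inclusive (>= min_genes); the span threshold is
    strict (> min_span). Under ``span_rule='genespan'`` the span is the
    extent covered by the window's phage-like genes, clipped to the window,
    and ``features`` must be supplied to resolve gene coordinates.
    """
    if params.span_rule == "genespan":
        if features is None:
            raise ValueError("span_rule='genespan' needs the feature list")
        by_id = {f.feature_id: f for f in features}
    selected = []
    for wc in counts:
        if wc.n_phage_genes < params.min_genes:
            continue
        if params.span_rule == "window":
            span = wc.window.length
        else:
            genes = [by_id[g] for g in wc.phage_gene_ids]
            span = (
                max(min(g.end, wc.window.end) for g in genes)
                - min(max(g.start, wc.window.start) for g in genes)
            )
        if span > params.min_span:
            selected.append(wc)
    return selected


def merge_windows(selected: Sequence[WindowCount]) -> list[ProphagePrediction]:
    """Merge transitively overlapping (or book-ended) selected windows.

    Each maximal union becomes one preliminary prediction carrying the
    union of its member windows' phage-like gene ids. Output is sorted by
    start and pairwise disjoint.
    """
    if not selected:
        return []
    contigs = {wc.window.contig_id for wc in selected}
    if len(contigs) > 1:
        raise ValueError(f"selected windows span several contigs: {sorted(contigs)}")
    wins = sorted(selected, key=lambda wc: (wc.window.start, wc.window.end))
    preds: list[ProphagePrediction] = []
    cur_s, cur_e = wins[0].window.start, wins[0].window.end
    cur_ids: set[str] = set(wins[0].phage_gene_ids)
    for wc in wins[1:]:
        if wc.window.start <= cur_e:
            cur_e = max(cur_e, wc.window.end)
            cur_ids |= wc.phage_gene_ids
        else:
            preds.append(
                ProphagePrediction(
                    Interval(wc.window.contig_id, cur_s, cur_e),
                    STAGE_PRELIMINARY,
                    frozenset(cur_ids),
                )
            )
            cur_s, cur_e, cur_ids = wc.window.start, wc.window.end, set(wc.phage_gene_ids)
    preds.append(
        ProphagePrediction(
            Interval(wins[0].window.contig_id, cur_s, cur_e),
            STAGE_PRELIMINARY,
            frozenset(cur_ids),
        )
    )
    return preds


def window_table(counts: Iterable[WindowCount]) -> str:
    """Per-window counts as a TSV block (contig, start, end, count) for debugging."""
    lines = ["contig\tstart\tend\tn_phage_genes"]
    for wc in counts:
        w = wc.window
        lines.append(f"{w.contig_id}\t{w.start}\t{w.end}\t{wc.n_phage_genes}")
    return "\n".join(lines) + "\n"
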