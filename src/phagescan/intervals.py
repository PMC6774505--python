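"""Interval algebra on 0-based half-open genomic intervals.

All coordinates in this package are 0-based half-open ``[start, end)``,
the BED convention. GFF3 I/O converts at the boundary; nothing else does
coordinate arithmetic in 1-based space.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval on one contig, 0-based half-open."""

    contig_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.contig_id}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.contig_id}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )


def _by_contig(ivs: Iterable[Interval]) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in sorted(ivs):
        out.setdefault(iv.contig_id, []).append((iv.start, iv.end))
    return out


def merge_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    """Disjoint union: merge overlapping or book-ended intervals per contig.

    Output is sorted by (contig, start) and pairwise disjoint with gaps
    of at least 1 bp between neighbours on the same contig.
    """
    merged: list[Interval] = []
    for contig, pairs in sorted(_by_contig(ivs).items()):
        cur_s, cur_e = pairs[0]
        for s, e in pairs[1:]:
            if s <= cur_e:  # overlap or touch -> absorb
                cur_e = max(cur_e, e)
            else:
                merged.append(Interval(contig, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(Interval(contig, cur_s, cur_e))
    return merged


def total_length(ivs: Iterable[Interval]) -> int:
    """Total bp covered by the union of ``ivs``."""
    return sum(iv.length for iv in merge_intervals(ivs))


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection of the unions of two interval sets (sorted, disjoint)."""
    am, bm = _by_contig(merge_intervals(a)), _by_contig(merge_intervals(b))
    out: list[Interval] = []
    for contig in sorted(set(am) & set(bm)):
        xs, ys = am[contig], bm[contig]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i][0], ys[j][0])
            e = min(xs[i][1], ys[j][1])
            if s < e:
                out.append(Interval(contig, s, e))
            if xs[i][1] < ys[j][1]:
                i += 1
            else:
                j += 1
    return out


def subtract(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Parts of union(a) not covered by union(b) (sorted, disjoint)."""
    am, bm = _by_contig(merge_intervals(a)), _by_contig(merge_intervals(b))
    out: list[Interval] = []
    for contig, xs in sorted(am.items()):
        ys = bm.get(contig, [])
        for s, e in xs:
            cur = s
            for bs, be in ys:
                if be <= cur:
                    continue
                if bs >= e:
                    break
                if bs > cur:
                    out.append(Interval(contig, cur, bs))
                cur = max(cur, be)
                if cur >= e:
                    break
            if cur < e:
                out.append(Interval(contig, cur, e))
    return out
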