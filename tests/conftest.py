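"""Shared fixtures: small genomes, features and random fixture builders."""

from __future__ import annotations

import numpy as np
import pytest

from phagescan.intervals import Interval
from phagescan.io_formats import ContigSeq, GeneFeature


def gf(fid, start, end, contig="chr1", strand="+", ftype="CDS", product="", phase=0):
    """Terse GeneFeature constructor for tests."""
    return GeneFeature(fid, contig, start, end, strand, ftype, product, phase)


def iv(start, end, contig="chr1"):
    return Interval(contig, start, end)


def random_gene_fixture(rng, contig_len=None, n_genes=None, contig="chr1"):
    """A random single-contig gene layout plus a random phage subset."""
    if contig_len is None:
        contig_len = int(rng.integers(50_000, 500_001))
    if n_genes is None:
        n_genes = int(rng.integers(20, 2_001))
    starts = rng.integers(0, contig_len - 100, n_genes)
    lens = rng.integers(100, 2_001, n_genes)
    feats = [
        gf(f"g{i}", int(s), int(min(s + l, contig_len)), contig=contig)
        for i, (s, l) in enumerate(zip(starts, lens))
    ]
    phage = {f.feature_id for f in feats if rng.random() < 0.3}
    return contig_len, feats, phage


def random_interval_set(rng, contigs=("c1", "c2"), max_n=20, span=100_000):
    out = []
    for _ in range(int(rng.integers(0, max_n))):
        c = contigs[int(rng.integers(0, len(contigs)))]
        s = int(rng.integers(0, span - 2))
        e = s + int(rng.integers(1, min(20_000, span - s)))
        out.append(Interval(c, s, e))
    return out


@pytest.fixture
def tiny_genome():
    rng = np.random.default_rng(7)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2_000))
    return [ContigSeq("chr1", seq)]
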