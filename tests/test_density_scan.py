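"""Sliding-window scan, selection thresholds and window merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagescan.density_scan import (
    ScanParams,
    merge_windows,
    scan_windows,
    select_windows,
)
from phagescan.intervals import Interval

from conftest import gf, random_gene_fixture


def oracle_counts(feats, phage_set, contig_len, params):
    """Brute force: test every (window, gene) pair for >=1 bp overlap."""
    genes = [(f.start, f.end) for f in feats if f.feature_id in phage_set]
    gs = np.array([g[0] for g in genes]) if genes else np.empty(0, int)
    ge = np.array([g[1] for g in genes]) if genes else np.empty(0, int)
    if contig_len <= params.window_len:
        starts = [0]
    else:
        starts = range(0, contig_len, params.step)
    out = []
    for s in starts:
        e = min(s + params.window_len, contig_len)
        out.append(int(np.sum((gs < e) & (ge > s))))
    return out


class TestScanWindows:
    def test_window_grid_and_terminal_truncation(self):
        counts = scan_windows([], set(), 12_000, ScanParams())
        spans = [(w.window.start, w.window.end) for w in counts]
        assert spans[0] == (0, 10_000)
        assert spans[-1] == (11_000, 12_000)
        assert len(spans) == 12
        assert all(e - s <= 10_000 for s, e in spans)

    def test_contig_shorter_than_window_gives_single_truncated_window(self):
        feats = [gf("g1", 100, 800)]
        counts = scan_windows(feats, {"g1"}, 4_000, ScanParams())
        assert [(w.window.start, w.window.end, w.n_phage_genes) for w in counts] == [
            (0, 4_000, 1)
        ]

    def test_empty_phage_set_gives_all_zero(self):
        feats = [gf(f"g{i}", 1_000 * i, 1_000 * i + 500) for i in range(20)]
        counts = scan_windows(feats, set(), 25_000, ScanParams())
        assert all(w.n_phage_genes == 0 for w in counts)

    def test_counts_equal_membership_sets(self):
        rng = np.random.default_rng(3)
        _, feats, phage = random_gene_fixture(rng, contig_len=60_000, n_genes=120)
        for w in scan_windows(feats, phage, 60_000, ScanParams()):
            assert w.n_phage_genes == len(w.phage_gene_ids)
            assert w.phage_gene_ids <= phage

    @pytest.mark.parametrize("seed", range(8))
    def test_counts_match_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        contig_len, feats, phage = random_gene_fixture(
            rng, contig_len=int(rng.integers(5_000, 80_000)), n_genes=200
        )
        params = ScanParams()
        got = [w.n_phage_genes for w in scan_windows(feats, phage, contig_len, params)]
        assert got == oracle_counts(feats, phage, contig_len, params)

    def test_monotone_in_phage_set(self):
        rng = np.random.default_rng(5)
        contig_len, feats, phage = random_gene_fixture(rng, contig_len=40_000, n_genes=80)
        small = set(list(phage)[: len(phage) // 2])
        c_small = scan_windows(feats, small, contig_len, ScanParams())
        c_full = scan_windows(feats, phage, contig_len, ScanParams())
        assert all(a.n_phage_genes <= b.n_phage_genes for a, b in zip(c_small, c_full))

    def test_multi_contig_features_rejected(self):
        feats = [gf("g1", 0, 100, contig="c1"), gf("g2", 0, 100, contig="c2")]
        with pytest.raises(ValueError, match="several contigs"):
            scan_windows(feats, set(), 10_000, ScanParams())


def window(s, e, n, contig="chr1"):
    from phagescan.density_scan import WindowCount

    ids = frozenset(f"g{i}" for i in range(n))
    return WindowCount(Interval(contig, s, e), n, ids)


class TestSelectWindows:
    def test_gene_threshold_is_inclusive_at_eight(self):
        kept = select_windows([window(0, 10_000, 8), window(10_000, 20_000, 7)])
        assert [(w.window.start, w.n_phage_genes) for w in kept] == [(0, 8)]

    def test_truncated_terminal_window_below_span_dropped(self):
        # 4.8 kb < the strict 5 kb bound, however many genes it holds
        kept = select_windows([window(95_000, 99_800, 9)])
        assert kept == []
        # exactly 5 kb is still not *longer than* 5 kb
        assert select_windows([window(95_000, 100_000, 9)]) == []
        assert len(select_windows([window(94_000, 99_100, 9)])) == 1

    def test_genespan_rule_requires_gene_extent(self):
        feats = [gf(f"g{i}", 2_000 + 150 * i, 2_100 + 150 * i) for i in range(10)]
        counts = scan_windows(feats, {f.feature_id for f in feats}, 20_000, ScanParams())
        params = ScanParams(span_rule="genespan")
        # 10 genes packed into ~1.5 kb: dense enough but too short a span
        assert select_windows(counts, params, features=feats) == []
        assert len(select_windows(counts, ScanParams(), features=feats)) > 0


class TestMergeWindows:
    def test_overlapping_windows_merge_to_one(self):
        preds = merge_windows([window(0, 10_000, 8), window(1_000, 11_000, 8)])
        assert [(p.region.start, p.region.end) for p in preds] == [(0, 11_000)]
        assert preds[0].stage == "preliminary"

    def test_disjoint_windows_stay_separate(self):
        preds = merge_windows([window(0, 10_000, 8), window(30_000, 40_000, 9)])
        assert [(p.region.start, p.region.end) for p in preds] == [
            (0, 10_000), (30_000, 40_000)
        ]

    def test_supporting_ids_are_union_of_members(self):
        from phagescan.density_scan import WindowCount

        a = WindowCount(Interval("chr1", 0, 10_000), 2, frozenset({"a", "b"}))
        b = WindowCount(Interval("chr1", 5_000, 15_000), 2, frozenset({"b", "c"}))
        (p,) = merge_windows([a, b])
        assert p.supporting_gene_ids == {"a", "b", "c"}

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(st.integers(0, 200), st.integers(1, 15)), min_size=1, max_size=30
        )
    )
    def test_merge_matches_paint_oracle_and_is_idempotent(self, raw):
        wins = [window(s * 1_000, (s + l) * 1_000, 8) for s, l in raw]
        preds = merge_windows(wins)
        # paint-and-extract oracle
        paint = np.zeros(max(w.window.end for w in wins) // 1_000 + 1, bool)
        for w in wins:
            paint[w.window.start // 1_000 : w.window.end // 1_000] = True
        runs = []
        in_run = False
        for i, v in enumerate(paint):
            if v and not in_run:
                start, in_run = i, True
            elif not v and in_run:
                runs.append((start * 1_000, i * 1_000))
                in_run = False
        if in_run:
            runs.append((start * 1_000, len(paint) * 1_000))
        got = [(p.region.start, p.region.end) for p in preds]
        assert got == runs
        # disjoint, sorted, idempotent; every window inside exactly one prediction
        assert got == sorted(got)
        assert all(a[1] < b[0] for a, b in zip(got, got[1:]))
        for w in wins:
            containing = [
                p for p in preds
                if p.region.start <= w.window.start and w.window.end <= p.region.end
            ]
            assert len(containing) == 1
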