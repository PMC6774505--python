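"""Border trimming, tRNA adjustment and finalization."""

import numpy as np
import pytest

from phagescan.density_scan import ProphagePrediction, STAGE_FINAL, STAGE_TRIMMED
from phagescan.edge_refine import adjust_to_trna, finalize, trim_to_phage_genes
from phagescan.intervals import Interval

from conftest import gf


def prelim(s, e, contig="chr1", ids=frozenset()):
    return ProphagePrediction(Interval(contig, s, e), "preliminary", frozenset(ids))


def trimmed(s, e, contig="chr1"):
    return ProphagePrediction(Interval(contig, s, e), STAGE_TRIMMED)


def trna(fid, s, e, contig="chr1"):
    return gf(fid, s, e, contig=contig, ftype="tRNA")


class TestTrim:
    def test_borders_move_to_outermost_phage_genes(self):
        feats = [gf("a", 2_000, 2_500), gf("b", 8_000, 9_000), gf("x", 500, 900)]
        t = trim_to_phage_genes(prelim(0, 11_000), feats, {"a", "b"})
        assert (t.region.start, t.region.end) == (2_000, 9_000)
        assert t.stage == STAGE_TRIMMED
        assert t.supporting_gene_ids == {"a", "b"}

    def test_fixed_point_when_genes_touch_both_edges(self):
        feats = [gf("a", 0, 500), gf("b", 10_500, 11_000)]
        t = trim_to_phage_genes(prelim(0, 11_000), feats, {"a", "b"})
        assert (t.region.start, t.region.end) == (0, 11_000)

    def test_overhanging_gene_clipped_so_trim_never_enlarges(self):
        feats = [gf("a", 500, 1_500), gf("b", 10_500, 11_500)]
        t = trim_to_phage_genes(prelim(1_000, 11_000), feats, {"a", "b"})
        assert (t.region.start, t.region.end) == (1_000, 11_000)

    def test_no_phage_gene_discards_with_warning(self, caplog):
        assert trim_to_phage_genes(prelim(0, 5_000), [gf("a", 6_000, 7_000)], {"a"}) is None
        assert any("discarded" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_min_start_max_end_oracle(self, seed):
        rng = np.random.default_rng(seed)
        region = prelim(10_000, 30_000)
        feats, phage = [], set()
        for i in range(int(rng.integers(1, 40))):
            s = int(rng.integers(0, 40_000))
            f = gf(f"g{i}", s, s + int(rng.integers(100, 2_000)))
            feats.append(f)
            if rng.random() < 0.5:
                phage.add(f.feature_id)
        inside = [
            f for f in feats
            if f.feature_id in phage and f.start < 30_000 and f.end > 10_000
        ]
        t = trim_to_phage_genes(region, feats, phage)
        if not inside:
            assert t is None
        else:
            assert t.region.start == max(10_000, min(f.start for f in inside))
            assert t.region.end == min(30_000, max(f.end for f in inside))
            # trim never enlarges
            assert t.region.start >= 10_000 and t.region.end <= 30_000


class TestAdjustToTrna:
    def test_upstream_trna_extends_left_border(self):
        p = adjust_to_trna(trimmed(2_000, 9_000), [trna("t", 500, 580)])
        assert (p.region.start, p.region.end) == (500, 9_000)
        assert p.anchored_trnas == ("t",)
        assert p.stage == STAGE_FINAL

    def test_inner_trna_contracts_left_border(self):
        p = adjust_to_trna(trimmed(2_000, 9_000), [trna("t", 2_600, 2_680)])
        assert (p.region.start, p.region.end) == (2_600, 9_000)

    def test_no_trna_in_flank_leaves_borders(self):
        p = adjust_to_trna(trimmed(2_000, 9_000), [trna("t", 12_100, 12_175)])
        assert (p.region.start, p.region.end) == (2_000, 9_000)
        assert p.anchored_trnas == ()

    def test_outermost_of_several_trnas_wins(self):
        p = adjust_to_trna(
            trimmed(5_000, 20_000),
            [trna("near", 4_000, 4_075), trna("far", 2_200, 2_275),
             trna("right", 22_000, 22_075)],
        )
        assert (p.region.start, p.region.end) == (2_200, 22_075)
        assert set(p.anchored_trnas) == {"near", "far", "right"}

    def test_border_move_bounded_by_flank_plus_trna_length(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            s = int(rng.integers(5_000, 20_000))
            e = s + int(rng.integers(6_000, 20_000))
            trnas = []
            for i in range(int(rng.integers(0, 5))):
                ts = int(rng.integers(0, 40_000))
                trnas.append(trna(f"t{i}", ts, ts + 75))
            p = adjust_to_trna(trimmed(s, e), trnas)
            assert abs(p.region.start - s) <= 3_000 + 75
            assert abs(p.region.end - e) <= 3_000 + 75

    def test_trna_in_both_flanks_of_short_prediction(self):
        # a prediction shorter than the flank sees the same tRNAs at both
        # borders; the outward rule still yields a consistent interval
        p = adjust_to_trna(
            trimmed(1_000, 1_200),
            [trna("a", 1_150, 1_190), trna("b", 1_010, 1_050)],
        )
        assert (p.region.start, p.region.end) == (1_010, 1_190)
        assert p.stage == STAGE_FINAL


class TestFinalize:
    def _final(self, s, e, contig="chr1", ids=frozenset()):
        return ProphagePrediction(Interval(contig, s, e), STAGE_FINAL, frozenset(ids))

    def test_overlap_created_by_extension_is_merged(self):
        out = finalize([self._final(500, 9_000), self._final(8_800, 15_000)])
        assert [(p.region.start, p.region.end) for p in out] == [(500, 15_000)]
        assert out[0].name == "prophage_1"

    def test_disjoint_predictions_keep_order_and_count(self):
        out = finalize([self._final(30_000, 40_000), self._final(500, 9_000)])
        assert [(p.name, p.region.start) for p in out] == [
            ("prophage_1", 500), ("prophage_2", 30_000)
        ]

    def test_names_ordered_across_contigs(self):
        out = finalize([self._final(0, 5_000, contig="c2"), self._final(0, 5_000, contig="c1")])
        assert [(p.name, p.region.contig_id) for p in out] == [
            ("prophage_1", "c1"), ("prophage_2", "c2")
        ]

    @pytest.mark.parametrize("seed", range(10))
    def test_output_pairwise_disjoint(self, seed):
        rng = np.random.default_rng(seed)
        preds = []
        for _ in range(int(rng.integers(1, 20))):
            s = int(rng.integers(0, 100_000))
            preds.append(self._final(s, s + int(rng.integers(1_000, 20_000))))
        out = finalize(preds)
        regions = [(p.region.start, p.region.end) for p in out]
        assert regions == sorted(regions)
        assert all(a[1] < b[0] for a, b in zip(regions, regions[1:]))

    def test_supporting_sets_united_on_merge(self):
        out = finalize([
            self._final(0, 10_000, ids={"a"}), self._final(9_000, 20_000, ids={"b"})
        ])
        assert out[0].supporting_gene_ids == {"a", "b"}
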