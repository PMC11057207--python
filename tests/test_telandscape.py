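"""TE window occupancy, region ratios, gene proximity, family clustering,
and X/Y copy asymmetry."""

import numpy as np
import pytest

from oracle_helpers import UnionFind, bitmap_coverage
from sexchrom.model import GenomicInterval, GeneRecord, RegionMap, TERecord
from sexchrom.telandscape import (
    FamilyRuleConfig,
    cluster_families,
    family_xy_asymmetry,
    gene_te_proximity,
    make_windows,
    region_repeat_ratio,
    window_occupancy,
)


def _te(chrom, start, end, fam="RLG_001"):
    return TERecord(GenomicInterval(chrom, start, end), fam[:3], fam)


def _gene(gid, chrom, start, end, strand="+", exons=None, region=None):
    iv = GenomicInterval(chrom, start, end, strand)
    exons = exons or [iv]
    return GeneRecord(gid, iv, exons, region)


class TestWindowOccupancy:
    def test_merged_union_within_window(self):
        tes = [_te("c", 0, 300_000), _te("c", 200_000, 600_000)]
        (occ,) = window_occupancy(tes, [], [GenomicInterval("c", 0, 1_000_000)])
        assert occ.te_fraction == pytest.approx(0.6)

    def test_gene_tiling_window_gives_one(self):
        genes = [_gene("g", "c", 0, 1000)]
        (occ,) = window_occupancy([], genes, [GenomicInterval("c", 0, 1000)])
        assert occ.gene_fraction == 1.0

    def test_matches_bitmap_oracle(self, rng):
        starts = rng.integers(0, 95_000, size=2000)
        lens = rng.integers(1, 4000, size=2000)
        tes = [_te("c", int(s), int(s + l)) for s, l in zip(starts, lens)]
        windows = make_windows("c", 100_000, 10_000)
        occs = window_occupancy(tes, [], windows)
        spans = [(t.interval.start, t.interval.end) for t in tes]
        for w, occ in zip(windows, occs):
            expected = bitmap_coverage(spans, w.start, w.end) / len(w)
            assert occ.te_fraction == pytest.approx(expected)


class TestRegionRepeatRatio:
    def test_nested_repeats_exceed_one(self):
        rm = RegionMap([("c", GenomicInterval("c", 0, 100_000), "oldSLR")])
        tes = [_te("c", 0, 100_000), _te("c", 0, 100_000)]
        assert region_repeat_ratio(tes, rm)["oldSLR"].ratio == pytest.approx(2.0)

    def test_no_tes_zero(self):
        rm = RegionMap([("c", GenomicInterval("c", 0, 1000), "autosome")])
        assert region_repeat_ratio([], rm)["autosome"].ratio == 0.0

    def test_matches_summation_oracle(self, rng):
        rm = RegionMap(
            [
                ("c", GenomicInterval("c", 0, 40_000), "PAR1"),
                ("c", GenomicInterval("c", 40_000, 90_000), "oldSLR"),
            ]
        )
        starts = rng.integers(0, 95_000, size=3000)
        lens = rng.integers(1, 3000, size=3000)
        tes = [_te("c", int(s), int(s + l)) for s, l in zip(starts, lens)]
        spans = [(t.interval.start, t.interval.end) for t in tes]
        got = region_repeat_ratio(tes, rm)
        for label, (lo, hi) in (("PAR1", (0, 40_000)), ("oldSLR", (40_000, 90_000))):
            expected = bitmap_coverage(spans, lo, hi, merged=False) / (hi - lo)
            assert got[label].ratio == pytest.approx(expected)


class TestGeneTEProximity:
    def test_plus_strand_upstream(self):
        genes = [_gene("g", "c", 5000, 8000, "+")]
        res, _ = gene_te_proximity(genes, [_te("c", 4500, 4700)])
        assert res[0].proportions["upstream_1kb"] == pytest.approx(0.2)
        assert res[0].proportions["downstream_1kb"] == 0.0

    def test_minus_strand_upstream_flipped(self):
        genes = [_gene("g", "c", 5000, 8000, "-")]
        res, _ = gene_te_proximity(genes, [_te("c", 8100, 8600)])
        assert res[0].proportions["upstream_1kb"] == pytest.approx(0.5)

    def test_intron_and_exon_compartments(self):
        iv = GenomicInterval("c", 1000, 2000, "+")
        exons = [GenomicInterval("c", 1000, 1400, "+"),
                 GenomicInterval("c", 1800, 2000, "+")]
        genes = [GeneRecord("g", iv, exons)]
        # TE covering the whole intron [1400, 1800)
        res, _ = gene_te_proximity(genes, [_te("c", 1400, 1800)])
        assert res[0].proportions["introns"] == pytest.approx(1.0)
        assert res[0].proportions["exons"] == 0.0

    def test_flank_clipped_at_chromosome_end(self):
        genes = [_gene("g", "c", 100, 500, "+")]
        res, _ = gene_te_proximity(genes, [_te("c", 0, 50)],
                                   chrom_lengths={"c": 600})
        assert res[0].proportions["upstream_1kb"] == pytest.approx(0.5)

    def test_proportions_bounded(self, rng):
        genes = [
            _gene(f"g{i}", "c", int(s), int(s) + 500,
                  "+" if i % 2 else "-", region="autosome")
            for i, s in enumerate(rng.integers(1000, 90_000, size=50))
        ]
        tes = [_te("c", int(s), int(s + l))
               for s, l in zip(rng.integers(0, 95_000, size=2000),
                               rng.integers(1, 2000, size=2000))]
        res, means = gene_te_proximity(genes, tes)
        for r in res:
            for v in r.proportions.values():
                assert np.isnan(v) or 0.0 <= v <= 1.0
        for m in means.values():
            for v in m.values():
                assert np.isnan(v) or 0.0 <= v <= 1.0

    def test_old_y_flanks_accumulate_more_than_old_x(self, default_bundle):
        cfg = default_bundle.config
        ann_a = default_bundle.annotations["haplotypeA"]
        ann_b = default_bundle.annotations["haplotypeB"]
        for ann, rmap in ((ann_a, default_bundle.region_map_a),
                          (ann_b, default_bundle.region_map_b)):
            ann.apply_region_map(rmap)
        _, means_a = gene_te_proximity(
            ann_a.genes, default_bundle.tes["A"], chrom_lengths=ann_a.chrom_lengths
        )
        _, means_b = gene_te_proximity(
            ann_b.genes, default_bundle.tes["B"], chrom_lengths=ann_b.chrom_lengths
        )
        for comp in ("upstream_1kb", "exons", "introns", "downstream_1kb"):
            assert means_b["oldSLR"][comp] > means_a["oldSLR"][comp], comp


class TestClusterFamilies:
    def test_identical_sequences_cluster(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=100))
        fams = cluster_families({"a": seq, "b": seq})
        assert fams["a"] == fams["b"] is not None

    def test_low_identity_pair_split(self, rng):
        s1 = "".join(rng.choice(list("ACGT"), size=100))
        s2 = "".join(rng.choice(list("ACGT"), size=100))
        fams = cluster_families({"a": s1, "b": s2})
        assert fams["a"] != fams["b"]

    def test_short_elements_unassigned(self):
        fams = cluster_families({"a": "ACGT" * 10})  # 40 bp < 80
        assert fams["a"] is None

    def test_components_match_union_find_oracle(self, rng):
        n = 30
        names = [f"te{i:02d}" for i in range(n)]
        # unique sequences let the scorer recover element identity
        seqs = {
            name: "".join(rng.choice(list("ACGT"), size=100)) for name in names
        }
        by_seq = {seq: name for name, seq in seqs.items()}
        assert len(by_seq) == n
        edges = {
            frozenset((a, b)): bool(rng.random() < 0.1)
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        }

        def scorer(s1, s2):
            key = frozenset((by_seq[s1], by_seq[s2]))
            return (1.0, 1.0) if edges[key] else (0.0, 0.0)

        fams = cluster_families(seqs, scorer=scorer)
        uf = UnionFind(names)
        for key, ok in edges.items():
            if ok:
                uf.union(*sorted(key))
        groups = {frozenset(g) for g in uf.groups()}
        got = {}
        for name, fam in fams.items():
            got.setdefault(fam, set()).add(name)
        assert {frozenset(g) for g in got.values()} == groups


class TestFamilyXYAsymmetry:
    def _regions(self):
        return ([("X", GenomicInterval("X", 0, 100_000))],
                [("Y", GenomicInterval("Y", 0, 100_000))])

    def test_copy_ratio_arithmetic(self, rng):
        xr, yr = self._regions()
        tes = [_te("X", int(s), int(s) + 100) for s in rng.integers(0, 99_000, 10)]
        tes += [_te("Y", int(s), int(s) + 100) for s in rng.integers(0, 99_000, 29)]
        res = family_xy_asymmetry(tes, xr, yr)
        assert res.copy_ratio_y_over_x == pytest.approx(2.9)

    def test_equal_counts_equal_lengths_chi2_zero(self):
        xr, yr = self._regions()
        tes = [_te("X", 10, 110), _te("Y", 10, 110)]
        res = family_xy_asymmetry(tes, xr, yr)
        assert res.copy_ratio_y_over_x == 1.0
        assert res.chi2 == pytest.approx(0.0)

    def test_empty_region_set_rejected(self):
        with pytest.raises(ValueError):
            family_xy_asymmetry([], [], [("Y", GenomicInterval("Y", 0, 10))])

    def test_planted_threefold_multiplier_recovered(self, default_bundle):
        cfg = default_bundle.config
        span = cfg.slr_layout["oldSLR"]
        res = family_xy_asymmetry(
            default_bundle.tes["A"] + default_bundle.tes["B"],
            [("X", GenomicInterval("X", *span))],
            [("Y", GenomicInterval("Y", *span))],
        )
        assert res.copy_ratio_y_over_x == pytest.approx(
            cfg.old_y_te_multiplier, abs=0.3
        )
        assert res.p_value < 0.001
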