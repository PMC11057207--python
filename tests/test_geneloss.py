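"""Gene-loss triangulation, classification, rates, and windows."""

import numpy as np
import pytest

from sexchrom.geneloss import (
    Candidate,
    LossCall,
    candidate_losses,
    classify_loss,
    filter_ortho_rows,
    loss_rates,
    windowed_loss,
)
from sexchrom.model import GenomicInterval, HitRecord, OrthoEntry, OrthoRow


def _row(og_id, og, a, b, syntenic=True, rep=True):
    def entry(flag, name):
        if not flag:
            return None
        return OrthoEntry(name, "c", 100, syntenic, rep)

    return OrthoRow(
        og_id,
        outgroup=entry(og, f"og_{og_id}"),
        haplotypeA=entry(a, f"ha_{og_id}"),
        haplotypeB=entry(b, f"hb_{og_id}"),
    )


def _hit(query, chrom, qcov, pident=99.0, start=0):
    return HitRecord(query, chrom, GenomicInterval(chrom, start, start + 100),
                     pident, qcov)


class TestCandidateLosses:
    def test_outgroup_and_other_present_focal_absent(self):
        rows = [_row("1", True, True, False)]
        (c,) = candidate_losses(rows, focal="B")
        assert c.gene_id == "ha_1"

    def test_outgroup_absent_not_candidate(self):
        assert candidate_losses([_row("2", False, True, False)], "B") == []

    def test_matches_set_algebra_oracle(self, rng):
        rows = []
        for i in range(500):
            og, a, b = rng.random(3) < 0.7
            if not (og or a or b):
                a = True
            rows.append(_row(str(i), bool(og), bool(a), bool(b)))
        got = {c.orthogroup_id for c in candidate_losses(rows, "B")}
        with_og = {r.orthogroup_id for r in rows if r.outgroup}
        with_a = {r.orthogroup_id for r in rows if r.haplotypeA}
        with_b = {r.orthogroup_id for r in rows if r.haplotypeB}
        assert got == (with_og & with_a) - with_b

    def test_nonsyntenic_rows_removed_by_filter(self):
        rows = [_row("1", True, True, True, syntenic=False),
                _row("2", True, True, True, rep=False),
                _row("3", True, True, True)]
        assert [r.orthogroup_id for r in filter_ortho_rows(rows)] == ["3"]


CMAP = {"X": {"Y"}}


class TestClassifyLoss:
    def _cand(self):
        return [Candidate("g1", "OG1", "X", 100)]

    @pytest.mark.parametrize(
        "hits,expected",
        [
            ([_hit("g1", "Y", 0.8)], "present"),
            ([_hit("g1", "Y", 0.5)], "present"),  # boundary: exactly 50% aligned
            ([_hit("g1", "Y", 0.3)], "partial_loss"),
            ([], "full_loss"),
            ([_hit("g1", "A1", 0.9)], "full_loss"),  # top hit off-chromosome
            # top hit elsewhere by identity, fragment on the Y decides partial
            ([_hit("g1", "A1", 0.9, pident=99), _hit("g1", "Y", 0.2, pident=90)],
             "partial_loss"),
        ],
    )
    def test_status_rules(self, hits, expected):
        (call,) = classify_loss(self._cand(), hits, CMAP, "B")
        assert call.status == expected

    def test_top_hit_tie_breaking(self):
        # equal identity: larger coverage wins; then smaller subject start
        hits = [
            _hit("g1", "A1", 0.9, pident=99, start=500),
            _hit("g1", "Y", 0.9, pident=99, start=100),
        ]
        hits2 = list(reversed(hits))
        for hs in (hits, hits2):
            (call,) = classify_loss(self._cand(), hs, CMAP, "B")
            assert call.status == "present"
            assert call.evidence[0] == "Y"

    def test_every_candidate_gets_exactly_one_status(self, default_bundle):
        from sexchrom.geneloss import candidate_losses, filter_ortho_rows

        rows = filter_ortho_rows(default_bundle.ortho_rows)
        cands = candidate_losses(rows, "B", default_bundle.region_map_a)
        calls = classify_loss(
            cands, default_bundle.hits_b, default_bundle.corresponding_chrom_map, "B"
        )
        assert len(calls) == len(cands)
        assert all(c.status in ("present", "partial_loss", "full_loss")
                   for c in calls)

    def test_simulated_truth_recovered_exactly(self, default_bundle):
        rows = filter_ortho_rows(default_bundle.ortho_rows)
        cands = candidate_losses(rows, "B", default_bundle.region_map_a)
        calls = classify_loss(
            cands, default_bundle.hits_b, default_bundle.corresponding_chrom_map, "B"
        )
        truth = default_bundle.truth.loss_status
        status_map = {"present": "present", "partial": "partial_loss",
                      "full": "full_loss"}
        assert len(calls) == len(truth)
        for call in calls:
            assert call.status == status_map[truth[call.gene_id]]


def _call(status, region="oldSLR", pos=0, ogc="S7"):
    return LossCall(f"g{pos}", "B", status, None, region, "X", pos, ogc, pos)


class TestLossRates:
    def test_worked_proportions_and_excess(self):
        calls = [_call("full_loss", pos=i) for i in range(422)]
        calls += [_call("partial_loss", pos=1000 + i) for i in range(258)]
        calls += [_call("full_loss", "autosome", 2000 + i) for i in range(40)]
        rates = loss_rates(
            calls, {"oldSLR": 1320, "autosome": 960}
        )
        old = rates["oldSLR"]
        assert old.proportion_lost == pytest.approx(680 / 2000)
        assert old.partial_fraction_of_lost == pytest.approx(258 / 680)
        assert old.excess_over_baseline == pytest.approx(0.34 - 0.04)

    def test_zero_losses(self):
        calls = [_call("present", pos=i) for i in range(10)]
        rates = loss_rates(calls, {"autosome": 5})
        assert rates["oldSLR"].proportion_lost == 0.0
        assert rates["oldSLR"].partial_fraction_of_lost is None

    def test_region_without_candidates_undefined(self):
        rates = loss_rates([], {"autosome": 0})
        assert rates["autosome"].proportion_lost is None


class TestWindowedLoss:
    def test_first_window_quarter_lost(self):
        calls = [
            _call("full_loss" if i < 5 else "present", pos=i) for i in range(40)
        ]
        windows, skipped = windowed_loss(calls, anchor_order="X", window_genes=20)
        assert skipped == 0
        assert [w.proportion for w in windows] == [0.25, 0.0]
        assert not windows[0].is_remainder

    def test_all_lost_and_remainder_flag(self):
        calls = [_call("full_loss", pos=i) for i in range(25)]
        windows, _ = windowed_loss(calls, window_genes=20)
        assert [w.proportion for w in windows] == [1.0, 1.0]
        assert windows[1].is_remainder and windows[1].n_candidates == 5

    def test_lost_sum_preserved(self, rng):
        calls = [
            _call(rng.choice(["present", "full_loss", "partial_loss"]), pos=i)
            for i in range(137)
        ]
        windows, _ = windowed_loss(calls, window_genes=20)
        assert sum(w.n_lost for w in windows) == sum(
            1 for c in calls if c.status != "present"
        )

    def test_outgroup_anchor_highlights_planted_loss_segment(self, default_bundle):
        rows = filter_ortho_rows(default_bundle.ortho_rows)
        cands = candidate_losses(rows, "B", default_bundle.region_map_a)
        calls = classify_loss(
            cands, default_bundle.hits_b, default_bundle.corresponding_chrom_map, "B"
        )
        # candidates live almost entirely on the old SLR, whose outgroup
        # scaffolds are S7/S8; window proportions there are high
        windows, skipped = windowed_loss(calls, anchor_order="outgroup")
        assert skipped == 0
        old = [w for w in windows if w.anchor_chrom in ("S7", "S8")]
        assert old and np.mean([w.proportion for w in old]) > 0.8
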