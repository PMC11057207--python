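"""End-to-end orchestration: simulate (or load) -> sexlink -> synteny ->
geneloss -> divergence -> te, with one machine-readable JSON summary.

One top-level seed fans out deterministically to per-stage child seeds, so a
stage can be rerun in isolation and a rerun of the whole pipeline with the
same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional


from . import geneloss as gl
from . import sexlink as sl
from . import synteny as syn
from . import telandscape as te
from .divergence import KsWindowConfig, StrataConfig, sliding_median_ks, strata_test
from .model import ValidationError
from .simulate import SimulationConfig, TrioBundle, simulate_trio

log = logging.getLogger(__name__)

STAGES = ("sexlink", "coverage", "geneloss", "synteny", "divergence", "te")

SUMMARY_SCHEMA = {
    "seed": int,
    "sexlink": dict,
    "coverage": dict,
    "geneloss": dict,
    "synteny": dict,
    "divergence": dict,
    "te": dict,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: Optional[SimulationConfig] = None
    ks_window: KsWindowConfig = field(default_factory=KsWindowConfig)
    strata: StrataConfig = field(default_factory=StrataConfig)
    chain_max_gap_ranks: int = 5
    chain_min_block_anchors: int = 3
    outdir: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.simulate is None:
            self.simulate = SimulationConfig(seed=child_seed(self.seed, "simulate"))


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the root seed."""
    import hashlib

    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def validate_summary(summary: dict) -> None:
    for key, typ in SUMMARY_SCHEMA.items():
        if key not in summary:
            raise ValidationError(f"summary missing section {key!r}")
        if not isinstance(summary[key], typ):
            raise ValidationError(f"summary section {key!r} has wrong type")


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run every stage on a simulated bundle and return the JSON-ready
    summary (also written to ``outdir/summary.json`` when set)."""
    bundle = simulate_trio(cfg.simulate)
    summary: dict[str, Any] = {"seed": cfg.seed, "simulate_seed": cfg.simulate.seed}

    try:
        summary["sexlink"] = _stage_sexlink(bundle)
        summary["coverage"] = _stage_coverage(bundle)
        summary["geneloss"] = _stage_geneloss(bundle)
        summary["synteny"] = _stage_synteny(bundle, cfg)
        summary["divergence"] = _stage_divergence(bundle, cfg)
        summary["te"] = _stage_te(bundle)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    validate_summary(summary)
    if cfg.outdir is not None:
        cfg.outdir.mkdir(parents=True, exist_ok=True)
        (cfg.outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    return summary


def _stage_sexlink(bundle: TrioBundle) -> dict:
    variants = sl.find_fixed_sex_variants(bundle.genotypes)
    summ = sl.summarize_assignment(variants, target_chroms=["X"])
    truth = bundle.truth.sexlinked_sites
    found = {(v.site.chrom, v.site.pos) for v in variants}
    tp = len(found & truth)
    span = sl.delimit_sex_linked_span(
        variants, "X", bundle.annotations["haplotypeA"]
    )
    return {
        "n_fixed_variants": summ.n_total,
        "per_chrom_counts": summ.per_chrom_counts,
        "pct_on_target": summ.pct_on_target,
        "pct_female_hom_ref": summ.pct_expected_ref_pattern,
        "recall": tp / len(truth) if truth else None,
        "precision": tp / len(found) if found else None,
        "span": None if span.span is None else [span.span.start, span.span.end],
        "n_par_candidates": len(span.par_candidates),
    }


def _stage_coverage(bundle: TrioBundle) -> dict:
    reports = sl.coverage_ratios(bundle.coverage_windows, "male1", "female1")
    return {
        label: {
            "female_male_ratio": r.median_female_male_ratio,
            "male_norm_depth": r.median_male_norm_depth,
            "y_linked": r.y_linked,
            "hemizygous": r.hemizygous,
            "n_windows": r.n_windows,
        }
        for label, r in reports.items()
    }


def _stage_geneloss(bundle: TrioBundle) -> dict:
    rows = gl.filter_ortho_rows(bundle.ortho_rows)
    candidates = gl.candidate_losses(rows, focal="B", region_map_other=bundle.region_map_a)
    calls = gl.classify_loss(
        candidates, bundle.hits_b, bundle.corresponding_chrom_map, focal="B"
    )
    # retained (non-candidate) genes per region: both haplotypes present
    n_present: dict[str, int] = {}
    for row in rows:
        if row.haplotypeA is not None and row.haplotypeB is not None and row.outgroup is not None:
            label = bundle.region_map_a.label_at(row.haplotypeA.chrom, row.haplotypeA.pos)
            if label:
                n_present[label] = n_present.get(label, 0) + 1
    rates = gl.loss_rates(calls, n_present)
    windows, skipped = gl.windowed_loss(calls, anchor_order="outgroup")
    return {
        "n_candidates": len(candidates),
        "per_region": {
            r.region_label: {
                "n_candidates": r.n_candidates,
                "n_lost": r.n_lost,
                "proportion_lost": r.proportion_lost,
                "partial_fraction_of_lost": r.partial_fraction_of_lost,
                "excess_over_baseline": r.excess_over_baseline,
            }
            for r in rates.values()
        },
        "n_windows": len(windows),
        "n_window_skipped": skipped,
    }


def _stage_synteny(bundle: TrioBundle, cfg: PipelineConfig) -> dict:
    anchors = syn.anchors_from_table(bundle.anchors)
    blocks = syn.chain_anchors(
        anchors, cfg.chain_max_gap_ranks, cfg.chain_min_block_anchors
    )
    out: dict[str, Any] = {"n_blocks": len(blocks)}

    lengths = {
        "X": bundle.config.sex_chrom_length,
        **bundle.config.autosome_lengths,
    }
    inv_by_chrom = {}
    for chrom, length in lengths.items():
        cblocks = [b for b in blocks if b.anchors[0].chrom_a == chrom]
        if not cblocks:
            continue
        summ = syn.call_inversions(cblocks, length)
        inv_by_chrom[chrom] = {
            "n_inversions": summ.n_inversions,
            "fraction": summ.total_fraction,
        }
        if chrom == "X":
            lo, hi = bundle.config.slr_layout["newSLR"]
            in_new = [
                c for c in summ.calls
                if lo <= c.interval_a.start and c.interval_a.end <= hi
            ]
            inv_by_chrom["newSLR"] = {
                "n_inversions": len(in_new),
                "fraction": sum(len(c.interval_a) for c in in_new) / (hi - lo),
            }
    out["inversions"] = inv_by_chrom

    asym = syn.nonsyntenic_asymmetry(
        bundle.ortho_rows, bundle.region_map_a, bundle.region_map_b
    )
    out["nonsyntenic_asymmetry"] = {
        "counts": asym.counts.tolist(),
        "chi2": asym.chi2,
        "p_value": asym.p_value,
    }
    return out


def _stage_divergence(bundle: TrioBundle, cfg: PipelineConfig) -> dict:
    windows = sliding_median_ks(bundle.ks_pairs, cfg.ks_window)
    old_pairs = [
        p
        for p in bundle.ks_pairs
        if p.origin_chrom in ("S7", "S8") and p.ks is not None
    ]
    strata: dict[str, Any]
    if old_pairs:
        res = strata_test(old_pairs, cfg.strata)
        strata = {
            "origins": list(res.origins),
            "counts": res.counts.tolist(),
            "chi2": res.chi2,
            "p_value": res.p_value,
            "n_ties_excluded": res.n_ties_excluded,
        }
    else:
        strata = {"note": "no labeled pairs"}
    med = [w.median_ks for w in windows]
    return {
        "n_pairs": len(bundle.ks_pairs),
        "n_windows": len(windows),
        "median_ks_min": min(med) if med else None,
        "median_ks_max": max(med) if med else None,
        "strata": strata,
    }


def _stage_te(bundle: TrioBundle) -> dict:
    cfgsim = bundle.config
    old_span = cfgsim.slr_layout["oldSLR"]
    from .model import GenomicInterval

    x_regions = [("X", GenomicInterval("X", *old_span))]
    y_regions = [("Y", GenomicInterval("Y", *old_span))]
    all_tes = bundle.tes["A"] + bundle.tes["B"]
    asym = te.family_xy_asymmetry(all_tes, x_regions, y_regions)

    ratios_a = te.region_repeat_ratio(bundle.tes["A"], bundle.region_map_a)
    genes_a = bundle.annotations["haplotypeA"].genes
    for g in genes_a:
        if g.region_label is None:
            g.region_label = bundle.region_map_a.label_at(
                g.interval.chrom, g.interval.midpoint
            )
    _, prox_means = te.gene_te_proximity(
        genes_a, bundle.tes["A"], chrom_lengths=bundle.annotations["haplotypeA"].chrom_lengths
    )
    return {
        "old_y_x_copy_ratio": asym.copy_ratio_y_over_x,
        "old_y_count": asym.y_total,
        "old_x_count": asym.x_total,
        "asymmetry_chi2": asym.chi2,
        "asymmetry_p": asym.p_value,
        "region_repeat_ratio_A": {k: v.ratio for k, v in ratios_a.items()},
        "proximity_means_A": prox_means,
    }
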