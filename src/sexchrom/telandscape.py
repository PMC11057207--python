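"""Transposable-element landscape statistics.

Recombination suppression lets TEs accumulate: the old sex-linked Y region
carries roughly 3-fold the copy number of its X counterpart, while young
sex-linked regions and PARs differ only marginally.  This module quantifies
that landscape: genic/TE occupancy of genomic windows (merged coverage),
per-region repeat ratios (summed, so nesting can push ratios above one), TE
occupancy in and near genes (1-kb flanks, exons, introns), 80-80-80 family
clustering, and X-versus-Y family copy asymmetry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import edlib
import networkx as nx
import numpy as np
from scipy.stats import chisquare

from .model import (
    GeneRecord,
    GenomicInterval,
    RegionMap,
    TERecord,
    merge_spans,
    merged_coverage,
    summed_coverage,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowOccupancy:
    window: GenomicInterval
    gene_fraction: float
    te_fraction: float


def make_windows(chrom: str, length: int, window_size: int) -> list[GenomicInterval]:
    """Non-overlapping windows tiling [0, length); last window may be short."""
    return [
        GenomicInterval(chrom, s, min(s + window_size, length))
        for s in range(0, length, window_size)
    ]


def window_occupancy(
    tes: Sequence[TERecord],
    genes: Sequence[GeneRecord],
    windows: Sequence[GenomicInterval],
) -> list[WindowOccupancy]:
    """Fraction of each window occupied by genes and by TEs (merged union
    coverage, clipped to the window)."""
    te_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for te in tes:
        te_by_chrom.setdefault(te.interval.chrom, []).append(
            (te.interval.start, te.interval.end)
        )
    gene_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        gene_by_chrom.setdefault(g.interval.chrom, []).append(
            (g.interval.start, g.interval.end)
        )
    # pre-merge per chromosome once; clipping merged spans preserves the union
    te_merged = {c: merge_spans(v) for c, v in te_by_chrom.items()}
    gene_merged = {c: merge_spans(v) for c, v in gene_by_chrom.items()}

    out = []
    for w in windows:
        wl = len(w)
        te_cov = merged_coverage(te_merged.get(w.chrom, []), w.start, w.end)
        gene_cov = merged_coverage(gene_merged.get(w.chrom, []), w.start, w.end)
        out.append(WindowOccupancy(w, gene_cov / wl, te_cov / wl))
    return out


@dataclass(frozen=True)
class RegionRepeatRatio:
    region_label: str
    summed_te_length: int
    region_length: int
    ratio: float


def region_repeat_ratio(
    tes: Sequence[TERecord], region_map: RegionMap
) -> dict[str, RegionRepeatRatio]:
    """Summed (unmerged) TE bp per region divided by region length.

    Nested and overlapping repeats are counted repeatedly, so the ratio can
    exceed one — it measures repeat load, not occupancy.
    """
    labels = sorted({label for _, _, label in region_map.entries})
    out = {}
    for label in labels:
        intervals = region_map.intervals_for(label)
        region_len = sum(len(iv) for _, iv in intervals)
        if region_len == 0:
            raise ValueError(f"zero-length region {label}")
        total = 0
        for chrom, iv in intervals:
            spans = [
                (t.interval.start, t.interval.end)
                for t in tes
                if t.interval.chrom == chrom
            ]
            total += summed_coverage(spans, iv.start, iv.end)
        out[label] = RegionRepeatRatio(label, total, region_len, total / region_len)
    return out


COMPARTMENTS = ("upstream_1kb", "exons", "introns", "downstream_1kb")


@dataclass
class GeneTEProximity:
    gene_id: str
    region_label: Optional[str]
    proportions: dict  # compartment -> merged TE coverage fraction (NaN if absent)


def gene_te_proximity(
    genes: Sequence[GeneRecord],
    tes: Sequence[TERecord],
    flank: int = 1000,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> tuple[list[GeneTEProximity], dict[str, dict[str, float]]]:
    """Merged TE coverage fraction in each gene compartment, plus per-region
    unweighted means over genes.

    Upstream/downstream flanks are strand-aware (upstream = 5' of the gene in
    transcription orientation) and clipped at chromosome ends.  Genes without
    introns get NaN for the intron compartment and are excluded from that
    compartment's mean.
    """
    te_merged: dict[str, list[tuple[int, int]]] = {}
    for te in tes:
        te_merged.setdefault(te.interval.chrom, []).append(
            (te.interval.start, te.interval.end)
        )
    te_merged = {c: merge_spans(v) for c, v in te_merged.items()}

    results = []
    for g in genes:
        chrom = g.interval.chrom
        chrom_len = (chrom_lengths or {}).get(chrom)
        spans = te_merged.get(chrom, [])
        if g.strand == "-":
            up = (g.interval.end, g.interval.end + flank)
            down = (g.interval.start - flank, g.interval.start)
        else:
            up = (g.interval.start - flank, g.interval.start)
            down = (g.interval.end, g.interval.end + flank)

        def frac_span(span: tuple[int, int]) -> float:
            s = max(0, span[0])
            e = span[1] if chrom_len is None else min(span[1], chrom_len)
            if e <= s:
                return float("nan")
            return merged_coverage(spans, s, e) / (e - s)

        def frac_set(ivs: list[GenomicInterval]) -> float:
            total = sum(len(iv) for iv in ivs)
            if total == 0:
                return float("nan")
            cov = sum(merged_coverage(spans, iv.start, iv.end) for iv in ivs)
            return cov / total

        props = {
            "upstream_1kb": frac_span(up),
            "exons": frac_set(g.exons),
            "introns": frac_set(g.introns),
            "downstream_1kb": frac_span(down),
        }
        results.append(GeneTEProximity(g.gene_id, g.region_label, props))

    means: dict[str, dict[str, float]] = {}
    regions = sorted({r.region_label for r in results if r.region_label})
    for region in regions:
        sub = [r for r in results if r.region_label == region]
        means[region] = {}
        for comp in COMPARTMENTS:
            vals = [r.proportions[comp] for r in sub if not np.isnan(r.proportions[comp])]
            means[region][comp] = float(np.mean(vals)) if vals else float("nan")
    return results, means


# ---------------------------------------------------------------------------
# 80-80-80 family clustering

@dataclass(frozen=True)
class FamilyRuleConfig:
    """Wicker-style family rule: >=80 bp, >=80% identity over >=80% of the
    aligned span."""

    min_length: int = 80
    min_identity: float = 0.80
    min_coverage: float = 0.80

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1 and 0 < self.min_coverage <= 1):
            raise ValueError("identity and coverage must be in (0, 1]")
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")


def edlib_scorer(seq1: str, seq2: str) -> tuple[float, float]:
    """Default pairwise scorer: infix alignment of the shorter sequence into
    the longer; identity over the shorter length, coverage = aligned fraction
    of the shorter sequence (1.0 for a full infix alignment)."""
    short, long_ = (seq1, seq2) if len(seq1) <= len(seq2) else (seq2, seq1)
    res = edlib.align(short, long_, mode="HW", task="distance")
    dist = res["editDistance"]
    if dist < 0:
        return 0.0, 0.0
    return 1.0 - dist / len(short), 1.0

def cluster_families(
    te_sequences: dict[str, str],
    scorer: Callable[[str, str], tuple[float, float]] = edlib_scorer,
    cfg: FamilyRuleConfig = FamilyRuleConfig(),
) -> dict[str, Optional[str]]:
    """Group TE sequences into families by the 80-80-80 rule.

    Elements shorter than ``min_length`` stay unassigned (None).  An edge
    joins two elements when identity >= min_identity over coverage >=
    min_coverage (coverage denominator: the shorter sequence); families are
    connected components (single linkage), named FAM0001... by order of the
    smallest member id.  A scorer failure on a pair is treated as no edge.
    """
    eligible = sorted(k for k, s in te_sequences.items() if len(s) >= cfg.min_length)
    graph = nx.Graph()
    graph.add_nodes_from(eligible)
    for i, a in enumerate(eligible):
        for b in eligible[i + 1 :]:
            try:
                ident, cov = scorer(te_sequences[a], te_sequences[b])
            except Exception as exc:  # scorer failure => no edge
                log.warning("scorer failed on (%s, %s): %s", a, b, exc)
                continue
            if ident >= cfg.min_identity and cov >= cfg.min_coverage:
                graph.add_edge(a, b)
    assignment: dict[str, Optional[str]] = {
        k: None for k in te_sequences if k not in set(eligible)
    }
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    for idx, comp in enumerate(components, 1):
        for member in comp:
            assignment[member] = f"FAM{idx:04d}"
    return assignment


# ---------------------------------------------------------------------------
# X vs Y family copy asymmetry

@dataclass
class FamilyAsymmetry:
    family_id: str
    x_count: int
    y_count: int
    x_mb: float
    y_mb: float


@dataclass
class XYAsymmetryResult:
    per_family: list[FamilyAsymmetry]
    x_total: int
    y_total: int
    copy_ratio_y_over_x: float
    chi2: float
    p_value: float
    x_region_bp: int
    y_region_bp: int


def _in_regions(te: TERecord, regions: list[tuple[str, GenomicInterval]]) -> bool:
    mid = te.interval.midpoint
    return any(
        c == te.interval.chrom and iv.start <= mid < iv.end for c, iv in regions
    )


def family_xy_asymmetry(
    tes: Sequence[TERecord],
    x_regions: list[tuple[str, GenomicInterval]],
    y_regions: list[tuple[str, GenomicInterval]],
) -> XYAsymmetryResult:
    """Per-family copy counts on the X versus Y region sets and the aggregate
    copy-number asymmetry.

    A TE belongs to a region when its midpoint falls inside.  Families fall
    back to the superfamily code when unassigned.  The chi-square compares
    observed (X total, Y total) against expectation proportional to the
    region lengths in bp — the defensible null when the two regions differ in
    size.
    """
    if not x_regions or not y_regions:
        raise ValueError("empty region set")
    fams: dict[str, FamilyAsymmetry] = {}
    for te in tes:
        fam = te.family_id or te.superfamily_code
        on_x = _in_regions(te, x_regions)
        on_y = _in_regions(te, y_regions)
        if not (on_x or on_y):
            continue
        rec = fams.setdefault(fam, FamilyAsymmetry(fam, 0, 0, 0.0, 0.0))
        if on_x:
            rec.x_count += 1
            rec.x_mb += len(te.interval) / 1e6
        else:
            rec.y_count += 1
            rec.y_mb += len(te.interval) / 1e6
    per_family = sorted(fams.values(), key=lambda f: f.family_id)
    x_total = sum(f.x_count for f in per_family)
    y_total = sum(f.y_count for f in per_family)
    x_bp = sum(len(iv) for _, iv in x_regions)
    y_bp = sum(len(iv) for _, iv in y_regions)
    ratio = y_total / x_total if x_total else float("inf")
    n = x_total + y_total
    expected = np.array([x_bp, y_bp], dtype=float) / (x_bp + y_bp) * n
    if n > 0 and (expected > 0).all():
        chi2, p = chisquare([x_total, y_total], f_exp=expected)
    else:
        chi2, p = float("nan"), float("nan")
    return XYAsymmetryResult(
        per_family, x_total, y_total, ratio, float(chi2), float(p), x_bp, y_bp
    )
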