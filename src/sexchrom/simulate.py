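"""Synthetic annotated trio generator with known ground truth.

Emulates the statistical structure of a phased XY male genome (haplotype A
carrying the X, haplotype B carrying the Y) plus a hermaphroditic outgroup:
a sex chromosome with PAR1 / old SLR / new SLR / PAR2 regions, fixed X/Y
variants segregating as all-males-heterozygous / all-females-homozygous,
Y gene loss at a configurable rate with a configurable partial-loss
fraction, region-specific TE insertion multipliers, per-gametolog Ks drawn
from region mixtures, heterozygous inversions realized as reversed anchor
runs, and male/female coverage tracks.  Every stochastic draw flows from one
seeded generator, so identical configs give identical outputs.

The region sizes are scaled to roughly 1/1000 of a real ~1.5 Gb genome so a
full simulation runs in seconds; gene "sequences" for Ks are synthetic
codon strings evolved to a target divergence, and alignment-hit tables are
emitted directly rather than produced by a search tool, because the
pipeline under test consumes tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .divergence import GametologPair
from .model import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GenomeAnnotation,
    GenomicInterval,
    GenotypeMatrix,
    GeneRecord,
    HitRecord,
    OrthoEntry,
    OrthoRow,
    RegionMap,
    Site,
    TERecord,
    TE_SUPERFAMILIES,
    ValidationError,
)
from .sexlink import CoverageWindow


def _default_slr_layout() -> dict[str, tuple[int, int]]:
    return {
        "PAR1": (0, 60_000),
        "oldSLR": (60_000, 360_000),
        "newSLR": (360_000, 660_000),
        "PAR2": (660_000, 720_000),
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic trio.

    Defaults mirror the degeneration statistics the analysis is built to
    recover: 30% Y gene loss on the old SLR with 38% of losses partial, a
    3-fold old-Y TE excess over the old X, marginal (1.09x / 1.02x)
    differences on the new regions and PARs, 6 males and 6 females with 50
    fixed sex-linked sites, and 4 new-SLR inversions spanning 31% of the
    region.
    """

    seed: int = 0
    # layout (bp); the sex chromosome layout is shared by X and Y
    autosome_lengths: dict = field(
        default_factory=lambda: {"A1": 400_000, "A2": 300_000}
    )
    slr_layout: dict = field(default_factory=_default_slr_layout)
    genes_per_region: dict = field(
        default_factory=lambda: {"PAR1": 60, "oldSLR": 2000, "newSLR": 400, "PAR2": 60}
    )
    genes_per_autosome: dict = field(default_factory=lambda: {"A1": 260, "A2": 200})
    # gene loss
    y_loss_rate: float = 0.30
    partial_fraction_of_lost: float = 0.38
    baseline_loss_rate: float = 0.04  # presence-absence / technical, non-oldSLR
    annotation_miss_rate: float = 0.02  # present in genome, absent from annotation
    # population genotypes
    n_males: int = 6
    n_females: int = 6
    n_sexlinked_sites: int = 50
    n_autosomal_sites: int = 450
    female_hom_ref_prob: float = 0.993
    indel_fraction: float = 0.1
    # TEs
    te_rate_per_kb: float = 3.0
    old_y_te_multiplier: float = 3.0  # old-Y total relative to old-X total
    new_x_te_multiplier: float = 1.09  # new-X relative to new-Y
    par_a_te_multiplier: float = 1.02  # A-PARs relative to B-PARs
    te_length_range: tuple = (80, 800)
    flank_te_prob_old_x: float = 0.1
    flank_te_prob_old_y: float = 0.3
    flank_te_prob_other: float = 0.1
    # Ks mixtures: region -> (w_young, w_old, w_tail); young U(0.001,0.03),
    # old U(0.03,0.2), tail U(0.2,0.5); unlisted regions ~ U(0,0.005)
    ks_mixture: dict = field(
        default_factory=lambda: {"oldSLR": (0.45, 0.50, 0.05)}
    )
    # inversions: key (chrom or region) -> (count, fraction of span)
    inversions: dict = field(
        default_factory=lambda: {"newSLR": (4, 0.31), "A1": (2, 0.10), "A2": (2, 0.10)}
    )
    # nonsyntenic-ortholog asymmetry: region -> (n A-syntenic-only, n B-syntenic-only)
    nonsyntenic_counts: dict = field(
        default_factory=lambda: {"oldSLR": (155, 13), "autosome": (40, 40)}
    )
    # coverage
    n_coverage_windows: int = 400
    autosomal_depth: float = 20.0
    coverage_noise: float = 0.10

    def __post_init__(self) -> None:
        for p in (
            self.y_loss_rate,
            self.partial_fraction_of_lost,
            self.baseline_loss_rate,
            self.annotation_miss_rate,
            self.female_hom_ref_prob,
            self.indel_fraction,
            self.flank_te_prob_old_x,
            self.flank_te_prob_old_y,
            self.flank_te_prob_other,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"probability out of [0,1]: {p}")
        for m in (
            self.te_rate_per_kb,
            self.old_y_te_multiplier,
            self.new_x_te_multiplier,
            self.par_a_te_multiplier,
        ):
            if m <= 0:
                raise ValidationError(f"rate/multiplier must be positive: {m}")
        spans = sorted(self.slr_layout.values())
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if e1 > s2:
                raise ValidationError("sex chromosome region spans overlap")
        self.sex_chrom_length = max(e for _, e in self.slr_layout.values())

    @property
    def sexlinked_span(self) -> tuple[int, int]:
        o = self.slr_layout["oldSLR"]
        n = self.slr_layout["newSLR"]
        return min(o[0], n[0]), max(o[1], n[1])


@dataclass
class TruthTables:
    """Ground truth for parameter-recovery checks."""

    loss_status: dict  # A gene_id -> "present" | "partial" | "full" (focal=B)
    sexlinked_sites: set  # {(chrom, pos)}
    te_counts: dict  # (haplotype, region) -> count
    inversion_intervals: dict  # span key -> list[(start, end)] in A coords
    inversion_fraction: dict  # span key -> planted bp fraction
    ks_true: dict  # x gene_id -> ks


@dataclass
class TrioBundle:
    """Everything simulate_trio produces, in memory."""

    config: SimulationConfig
    annotations: dict  # "outgroup" | "haplotypeA" | "haplotypeB" -> GenomeAnnotation
    region_map_a: RegionMap
    region_map_b: RegionMap
    ortho_rows: list
    tes: dict  # "A" | "B" -> list[TERecord]
    genotypes: GenotypeMatrix
    hits_b: list  # HitRecords of A-gene transcripts vs the B genome
    anchors: pd.DataFrame
    ks_pairs: list
    coverage_windows: list
    truth: TruthTables

    @property
    def corresponding_chrom_map(self) -> dict[str, set[str]]:
        m = {"X": {"Y"}}
        for c in self.config.autosome_lengths:
            m[c] = {c}
        return m


# ---------------------------------------------------------------------------

_FOURFOLD_PREFIXES = ("GC", "GG", "GT", "CC", "CT", "CG", "TC", "AC")


def evolve_codon_pair(
    rng: np.random.Generator, n_codons: int, target_ks: float
) -> tuple[str, str]:
    """A codon-aligned sequence pair whose NG86 Ks is the closest achievable
    to ``target_ks``.

    Sequences are built from 4-fold degenerate codons (one synonymous site
    per codon, so S = n_codons exactly) and diverged by synonymous
    third-position changes at ``round(ps * n_codons)`` distinct codons,
    where ps inverts the Jukes-Cantor correction of the target.
    """
    prefixes = rng.choice(_FOURFOLD_PREFIXES, size=n_codons)
    thirds = rng.choice(list("ACGT"), size=n_codons)
    seq1 = "".join(p + t for p, t in zip(prefixes, thirds))
    ps = 0.75 * (1.0 - np.exp(-4.0 * target_ks / 3.0))
    m = int(round(ps * n_codons))
    idx = rng.choice(n_codons, size=m, replace=False)
    thirds2 = thirds.copy()
    for i in idx:
        choices = [b for b in "ACGT" if b != thirds[i]]
        thirds2[i] = rng.choice(choices)
    seq2 = "".join(p + t for p, t in zip(prefixes, thirds2))
    return seq1, seq2


def _make_genes(
    rng: np.random.Generator,
    chrom: str,
    span: tuple[int, int],
    n: int,
    prefix: str,
) -> list[GeneRecord]:
    """Evenly spaced genes with 1-3 exons inside [span)."""
    start, end = span
    spacing = (end - start) / n
    genes = []
    for i in range(n):
        g0 = start + int(i * spacing) + 2
        glen = max(30, int(spacing * rng.uniform(0.4, 0.7)))
        g1 = min(g0 + glen, start + int((i + 1) * spacing) - 1, end)
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(chrom, g0, g1, strand)
        n_ex = int(rng.integers(1, 4))
        exons = []
        if n_ex == 1 or (g1 - g0) < 3 * n_ex + 2 * (n_ex - 1):
            exons = [iv]
        else:
            bounds = np.sort(rng.choice(
                np.arange(g0 + 1, g1 - 1), size=2 * (n_ex - 1), replace=False
            ))
            edges = [g0, *bounds.tolist(), g1]
            for e in range(n_ex):
                s_, e_ = edges[2 * e], edges[2 * e + 1]
                if e == n_ex - 1:
                    e_ = g1
                if e_ > s_:
                    exons.append(GenomicInterval(chrom, s_, e_, strand))
            if not exons:
                exons = [iv]
        genes.append(GeneRecord(f"{prefix}{i:05d}", iv, exons))
    return genes


def _region_map_for(config: SimulationConfig, sex_chrom: str) -> RegionMap:
    entries = []
    for label, (s, e) in config.slr_layout.items():
        entries.append((sex_chrom, GenomicInterval(sex_chrom, s, e), label))
    for chrom, length in config.autosome_lengths.items():
        entries.append((chrom, GenomicInterval(chrom, 0, length), "autosome"))
    return RegionMap(entries)


def _plant_inversions(
    rng: np.random.Generator,
    order: list[int],
    genes: list[GeneRecord],
    idx_range: tuple[int, int],
    n_inv: int,
    target_fraction: float,
    span_len: int,
) -> tuple[list[int], list[tuple[int, int]]]:
    """Reverse ``n_inv`` gene-index runs inside ``idx_range`` of ``order`` so
    the reversed runs' midpoint spans cover about ``target_fraction`` of the
    span.  Returns the new order and the planted (start, end) bp intervals
    measured between first and last gene midpoints (the same convention the
    anchor-based caller sees)."""
    lo, hi = idx_range
    n_genes_span = hi - lo
    density = n_genes_span / span_len  # genes per bp
    slice_size = n_genes_span // n_inv
    per_inv_bp = target_fraction * span_len / n_inv
    # a run of k genes spans k-1 inter-gene spacings midpoint-to-midpoint
    run_genes = max(3, int(round(per_inv_bp * density)) + 1)
    new_order = list(order)
    intervals = []
    for k in range(n_inv):
        slice_lo = lo + k * slice_size
        margin = max(4, (slice_size - run_genes) // 2)
        r0 = slice_lo + margin
        r1 = min(r0 + run_genes, lo + (k + 1) * slice_size - 4, hi)
        if r1 - r0 < 3:
            continue
        new_order[r0:r1] = reversed(new_order[r0:r1])
        first = genes[order[r0]].interval.midpoint
        last = genes[order[r1 - 1]].interval.midpoint
        intervals.append((first, last + 1))
    return new_order, intervals


_BASES = "ACGT"


def simulate_trio(config: SimulationConfig) -> TrioBundle:
    """Generate the full synthetic trio bundle (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    X, Y = "X", "Y"
    layout = config.slr_layout

    rmap_a = _region_map_for(config, X)
    rmap_b = _region_map_for(config, Y)

    # --- haplotype A annotation (X-bearing) --------------------------------
    a_genes: list[GeneRecord] = []
    gene_region: dict[str, str] = {}
    for label in ("PAR1", "oldSLR", "newSLR", "PAR2"):
        gs = _make_genes(
            rng, X, layout[label], config.genes_per_region[label], f"ha_X_{label}_"
        )
        for g in gs:
            gene_region[g.gene_id] = label
        a_genes.extend(gs)
    for chrom, length in config.autosome_lengths.items():
        gs = _make_genes(
            rng, chrom, (0, length), config.genes_per_autosome[chrom], f"ha_{chrom}_"
        )
        for g in gs:
            gene_region[g.gene_id] = "autosome"
        a_genes.extend(gs)
    chrom_lengths_a = {X: config.sex_chrom_length, **config.autosome_lengths}
    ann_a = GenomeAnnotation(a_genes, chrom_lengths_a)

    # --- Y loss truth ------------------------------------------------------
    loss_status: dict[str, str] = {}
    for g in a_genes:
        region = gene_region[g.gene_id]
        if region in ("PAR1", "PAR2"):
            p_loss = 0.0  # PARs recombine; no hemizygous loss
        elif region == "oldSLR":
            p_loss = config.y_loss_rate
        else:
            p_loss = config.baseline_loss_rate
        if rng.random() < p_loss:
            loss_status[g.gene_id] = (
                "partial"
                if rng.random() < config.partial_fraction_of_lost
                else "full"
            )
        elif rng.random() < config.annotation_miss_rate:
            loss_status[g.gene_id] = "present"  # present in genome, unannotated
        # genes absent from loss_status are present and annotated on B

    # --- haplotype B annotation with inversions ----------------------------
    # B gene order = A order with planted reversed runs; lost / unannotated
    # genes are then dropped and survivors re-spaced on the B chromosome.
    b_genes: list[GeneRecord] = []
    a_to_b: dict[str, str] = {}
    b_pos: dict[str, int] = {}
    inversion_intervals: dict[str, list[tuple[int, int]]] = {}
    inversion_fraction: dict[str, float] = {}

    def b_chrom_of(a_chrom: str) -> str:
        return Y if a_chrom == X else a_chrom

    for a_chrom, length in [(X, config.sex_chrom_length)] + list(
        config.autosome_lengths.items()
    ):
        chrom_genes = ann_a.genes_on(a_chrom)
        order = list(range(len(chrom_genes)))
        if a_chrom == X and "newSLR" in config.inversions:
            lo = next(
                i for i, g in enumerate(chrom_genes)
                if gene_region[g.gene_id] == "newSLR"
            )
            hi = 1 + max(
                i for i, g in enumerate(chrom_genes)
                if gene_region[g.gene_id] == "newSLR"
            )
            n_inv, frac = config.inversions["newSLR"]
            span_len = layout["newSLR"][1] - layout["newSLR"][0]
            order, ivs = _plant_inversions(
                rng, order, chrom_genes, (lo, hi), n_inv, frac, span_len
            )
            inversion_intervals["newSLR"] = ivs
            inversion_fraction["newSLR"] = (
                sum(e - s for s, e in ivs) / span_len
            )
        elif a_chrom in config.inversions:
            n_inv, frac = config.inversions[a_chrom]
            order, ivs = _plant_inversions(
                rng, order, chrom_genes, (0, len(chrom_genes)), n_inv, frac, length
            )
            inversion_intervals[a_chrom] = ivs
            inversion_fraction[a_chrom] = sum(e - s for s, e in ivs) / length

        surviving = [
            chrom_genes[i]
            for i in order
            if loss_status.get(chrom_genes[i].gene_id) is None
        ]
        bc = b_chrom_of(a_chrom)
        # re-space survivors within their own region span so the B genome
        # keeps the region structure (lost genes free their slots)
        if a_chrom == X:
            region_spans = dict(layout)
        else:
            region_spans = {"autosome": (0, length)}
        for region, (rs, re_) in region_spans.items():
            members = [g for g in surviving if gene_region[g.gene_id] == region]
            if not members:
                continue
            spacing = (re_ - rs) / len(members)
            for j, ag in enumerate(members):
                b0 = rs + int(j * spacing) + 2
                b1 = min(b0 + max(30, len(ag.interval)),
                         rs + int((j + 1) * spacing) - 1)
                if b1 <= b0:
                    b1 = b0 + 10
                bid = "hb_" + ag.gene_id[3:]
                iv = GenomicInterval(bc, b0, b1, ag.strand)
                if len(ag.exons) > 1 and (b1 - b0) >= 30:
                    mid = (b0 + b1) // 2
                    exons = [GenomicInterval(bc, b0, mid - 4, ag.strand),
                             GenomicInterval(bc, mid + 4, b1, ag.strand)]
                else:
                    exons = [iv]
                b_genes.append(GeneRecord(bid, iv, exons))
                a_to_b[ag.gene_id] = bid
                b_pos[bid] = iv.midpoint
    chrom_lengths_b = {Y: config.sex_chrom_length, **config.autosome_lengths}
    ann_b = GenomeAnnotation(b_genes, chrom_lengths_b)

    # --- outgroup annotation ----------------------------------------------
    # the old SLR derives from two ancestral scaffolds (S7, S8); other
    # regions map to their own scaffolds, in ancestral (= A) gene order
    og_chrom_of: dict[str, str] = {}
    og_counter: dict[str, int] = {}
    og_genes: list[GeneRecord] = []
    a_to_og: dict[str, str] = {}
    og_pos: dict[str, tuple[str, int]] = {}
    old_ids = [g.gene_id for g in a_genes if gene_region[g.gene_id] == "oldSLR"]
    half = len(old_ids) // 2
    origin_of = {gid: ("S7" if i < half else "S8") for i, gid in enumerate(old_ids)}
    for g in a_genes:
        region = gene_region[g.gene_id]
        if region == "oldSLR":
            oc = origin_of[g.gene_id]
        elif region == "newSLR":
            oc = "S5"
        elif region in ("PAR1", "PAR2"):
            oc = "S6"
        else:
            oc = {"A1": "S1", "A2": "S2"}.get(g.interval.chrom, "S3")
        k = og_counter.get(oc, 0)
        og_counter[oc] = k + 1
        pos0 = k * 150
        iv = GenomicInterval(oc, pos0, pos0 + 100, "+")
        ogid = "og_" + g.gene_id[3:]
        og_genes.append(GeneRecord(ogid, iv, [iv]))
        a_to_og[g.gene_id] = ogid
        og_pos[ogid] = (oc, iv.midpoint)
        og_chrom_of[g.gene_id] = oc
    og_lengths = {c: (n + 1) * 150 for c, n in og_counter.items()}
    ann_og = GenomeAnnotation(og_genes, og_lengths)

    # --- ortholog table ----------------------------------------------------
    ortho_rows: list[OrthoRow] = []
    for i, g in enumerate(a_genes):
        ogid = a_to_og[g.gene_id]
        oc, op = og_pos[ogid]
        entry_og = OrthoEntry(ogid, oc, op, True, True)
        entry_a = OrthoEntry(
            g.gene_id, g.interval.chrom, g.interval.midpoint, True, True
        )
        bid = a_to_b.get(g.gene_id)
        entry_b = (
            OrthoEntry(bid, b_chrom_of(g.interval.chrom), b_pos[bid], True, True)
            if bid is not None
            else None
        )
        ortho_rows.append(
            OrthoRow(f"OG{i:06d}", outgroup=entry_og, haplotypeA=entry_a,
                     haplotypeB=entry_b)
        )
    # extra one-to-one rows with exactly one syntenic haplotype, planting the
    # nonsyntenic-ortholog asymmetry; excluded from loss counting upstream
    ns_idx = len(ortho_rows)
    for region, (n_a_only, n_b_only) in config.nonsyntenic_counts.items():
        if region == "oldSLR":
            span_a = (X, layout["oldSLR"])
            span_b = (Y, layout["oldSLR"])
        else:
            c = next(iter(config.autosome_lengths))
            span_a = (c, (0, config.autosome_lengths[c]))
            span_b = (c, (0, config.autosome_lengths[c]))
        for which, count in (("A", n_a_only), ("B", n_b_only)):
            for j in range(count):
                pa = int(rng.integers(span_a[1][0], span_a[1][1]))
                pb = int(rng.integers(span_b[1][0], span_b[1][1]))
                po = int(rng.integers(0, 50_000))
                ea = OrthoEntry(
                    f"ha_ns{ns_idx:05d}", span_a[0], pa, which == "A", True
                )
                eb = OrthoEntry(
                    f"hb_ns{ns_idx:05d}", span_b[0], pb, which == "B", True
                )
                eo = OrthoEntry(f"og_ns{ns_idx:05d}", "S9", po, True, True)
                ortho_rows.append(
                    OrthoRow(f"OG{ns_idx:06d}", outgroup=eo, haplotypeA=ea,
                             haplotypeB=eb)
                )
                ns_idx += 1

    # --- hit table for candidate lost genes (queries vs the B genome) ------
    hits_b: list[HitRecord] = []
    for gid, status in loss_status.items():
        g = ann_a[gid]
        corr_chrom = b_chrom_of(g.interval.chrom)
        pos = int(rng.integers(0, chrom_lengths_b[corr_chrom] - 2000))
        if status == "present":
            cov = float(rng.uniform(0.5, 1.0))
            hits_b.append(
                HitRecord(gid, corr_chrom,
                          GenomicInterval(corr_chrom, pos, pos + 1000),
                          float(rng.uniform(95, 100)), cov)
            )
        elif status == "partial":
            cov = float(rng.uniform(0.05, 0.4999))
            hits_b.append(
                HitRecord(gid, corr_chrom,
                          GenomicInterval(corr_chrom, pos, pos + 300),
                          float(rng.uniform(85, 99)), cov)
            )
        else:  # full loss: half the genes get a spurious off-chromosome hit
            if rng.random() < 0.5:
                others = [c for c in chrom_lengths_b if c != corr_chrom]
                oc = others[int(rng.integers(0, len(others)))]
                pos2 = int(rng.integers(0, chrom_lengths_b[oc] - 2000))
                hits_b.append(
                    HitRecord(gid, oc, GenomicInterval(oc, pos2, pos2 + 500),
                              float(rng.uniform(80, 95)),
                              float(rng.uniform(0.5, 1.0)))
                )

    # --- population genotypes ---------------------------------------------
    samples = [(f"M{i+1}", "M") for i in range(config.n_males)] + [
        (f"F{i+1}", "F") for i in range(config.n_females)
    ]
    n_samples = len(samples)
    sites: list[Site] = []
    geno_rows: list[np.ndarray] = []
    sexlinked_sites: set[tuple[str, int]] = set()
    slr_lo, slr_hi = config.sexlinked_span
    sl_pos = np.sort(
        rng.choice(np.arange(slr_lo, slr_hi), size=config.n_sexlinked_sites,
                   replace=False)
    )
    for pos in sl_pos:
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        ref, alt = str(ref), str(alt)
        if rng.random() < config.indel_fraction:
            alt = alt + "".join(rng.choice(list(_BASES), size=2))
        female_ref = rng.random() < config.female_hom_ref_prob
        row = np.full(n_samples, GT_HET, dtype=np.int8)
        fem = slice(config.n_males, n_samples)
        row[fem] = GT_HOM_REF if female_ref else GT_HOM_ALT
        sites.append(Site(X, int(pos), ref, alt,
                          "SNP" if len(ref) == len(alt) else "indel"))
        geno_rows.append(row)
        sexlinked_sites.add((X, int(pos)))
    auto_chroms = list(config.autosome_lengths)
    for _ in range(config.n_autosomal_sites):
        chrom = auto_chroms[int(rng.integers(0, len(auto_chroms)))]
        pos = int(rng.integers(0, config.autosome_lengths[chrom]))
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        p = rng.uniform(0.05, 0.95)
        row = rng.binomial(2, p, size=n_samples).astype(np.int8)
        sites.append(Site(chrom, pos, str(ref), str(alt), "SNP"))
        geno_rows.append(row)
    order_idx = sorted(
        range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos)
    )
    sites = [sites[i] for i in order_idx]
    geno = np.array([geno_rows[i] for i in order_idx], dtype=np.int8)
    gm = GenotypeMatrix(sites, samples, geno)

    # --- anchors -----------------------------------------------------------
    anchor_records = []
    for a_chrom in [X] + auto_chroms:
        for g in ann_a.genes_on(a_chrom):
            bid = a_to_b.get(g.gene_id)
            if bid is None:
                continue
            anchor_records.append(
                (g.gene_id, a_chrom, g.interval.midpoint, bid,
                 b_chrom_of(a_chrom), b_pos[bid], "same")
            )
    anchors = pd.DataFrame(
        anchor_records,
        columns=["idA", "chromA", "posA", "idB", "chromB", "posB", "orientation"],
    )

    # --- TE annotations ----------------------------------------------------
    # Region multipliers are targets for the TOTAL TE count (background
    # scatter + near-gene insertions), so the background rate on the B
    # haplotype is compensated for the expected near-gene contribution and
    # for gene-loss thinning; the realized old-Y/old-X count ratio then
    # recovers old_y_te_multiplier.
    te_a: list[TERecord] = []
    te_b: list[TERecord] = []
    sf_weights = rng.dirichlet(np.ones(len(TE_SUPERFAMILIES)) * 2.0)
    te_len_lo, te_len_hi = config.te_length_range

    def scatter_tes(out: list, chrom: str, span: tuple[int, int], lam: float) -> None:
        n = int(rng.poisson(max(0.0, lam)))
        for _ in range(n):
            length = int(rng.integers(te_len_lo, te_len_hi))
            s0 = int(rng.integers(span[0], max(span[0] + 1, span[1] - length)))
            sf = TE_SUPERFAMILIES[int(rng.choice(len(TE_SUPERFAMILIES), p=sf_weights))]
            fam = f"{sf}_{int(rng.integers(0, 40)):03d}"
            out.append(TERecord(GenomicInterval(chrom, s0, s0 + length), sf, fam))

    base = config.te_rate_per_kb
    p_ox, p_oy, p_other = (
        config.flank_te_prob_old_x,
        config.flank_te_prob_old_y,
        config.flank_te_prob_other,
    )
    n_a_genes = {r: config.genes_per_region[r] for r in config.genes_per_region}
    n_b_genes: dict[str, int] = {}
    for bid in b_pos:
        agid = "ha_" + bid[3:]
        r = gene_region.get(agid, "autosome")
        n_b_genes[r] = n_b_genes.get(r, 0) + 1

    def span_kb(span: tuple[int, int]) -> float:
        return (span[1] - span[0]) / 1000.0

    # haplotype A (X-bearing)
    a_mult = {"PAR1": config.par_a_te_multiplier,
              "PAR2": config.par_a_te_multiplier,
              "oldSLR": 1.0,
              "newSLR": config.new_x_te_multiplier}
    for region, mult in a_mult.items():
        scatter_tes(te_a, X, layout[region], base * mult * span_kb(layout[region]))
    # haplotype B (Y-bearing), with near-gene compensation
    old_span = layout["oldSLR"]
    target_old_y = config.old_y_te_multiplier * (
        base * span_kb(old_span) + n_a_genes["oldSLR"] * p_ox
    )
    lam_old_y = target_old_y - n_b_genes.get("oldSLR", 0) * p_oy
    scatter_tes(te_b, Y, old_span, lam_old_y)
    for region in ("PAR1", "PAR2", "newSLR"):
        lam = base * span_kb(layout[region]) + p_other * (
            n_a_genes[region] - n_b_genes.get(region, 0)
        )
        scatter_tes(te_b, Y, layout[region], lam)
    for chrom, length in config.autosome_lengths.items():
        scatter_tes(te_a, chrom, (0, length), base * length / 1000.0)
        n_lost_auto = sum(
            1 for gid in loss_status
            if gene_region[gid] == "autosome" and ann_a[gid].interval.chrom == chrom
        )
        scatter_tes(te_b, chrom, (0, length),
                    base * length / 1000.0 + p_other * n_lost_auto)

    # near-gene insertions: one TE dropped into a random flank with the
    # region's insertion probability
    def flank_prob(hap: str, region: str) -> float:
        if region == "oldSLR":
            return p_oy if hap == "B" else p_ox
        return p_other

    for hap, ann in (("A", ann_a), ("B", ann_b)):
        out = te_a if hap == "A" else te_b
        for g in ann.genes:
            agid = g.gene_id if hap == "A" else "ha_" + g.gene_id[3:]
            region = gene_region.get(agid, "autosome")
            if rng.random() >= flank_prob(hap, region):
                continue
            length = int(rng.integers(80, 400))
            if rng.random() < 0.5:
                s0 = max(0, g.interval.start - int(rng.integers(1, 900)))
            else:
                s0 = g.interval.end + int(rng.integers(1, 500))
            sf = TE_SUPERFAMILIES[int(rng.choice(len(TE_SUPERFAMILIES), p=sf_weights))]
            out.append(
                TERecord(GenomicInterval(g.interval.chrom, s0, s0 + length), sf,
                         f"{sf}_{int(rng.integers(0, 40)):03d}")
            )

    # realized per-region counts (midpoint membership), the truth for
    # distributional checks
    te_counts: dict[tuple[str, str], int] = {}
    for hap, tes_, rmap in (("A", te_a, rmap_a), ("B", te_b, rmap_b)):
        for te in tes_:
            label = rmap.label_at(te.interval.chrom, te.interval.midpoint)
            if label is not None:
                key = (hap, label)
                te_counts[key] = te_counts.get(key, 0) + 1

    # --- Ks per gametolog pair ---------------------------------------------
    ks_pairs: list[GametologPair] = []
    ks_true: dict[str, float] = {}
    for g in ann_a.genes_on(X):
        bid = a_to_b.get(g.gene_id)
        if bid is None:
            continue
        region = gene_region[g.gene_id]
        if region in config.ks_mixture:
            w_young, w_old, w_tail = config.ks_mixture[region]
            u = rng.random()
            if u < w_young:
                ks = rng.uniform(0.001, 0.03)
            elif u < w_young + w_old:
                ks = rng.uniform(0.03, 0.2)
            else:
                ks = rng.uniform(0.2, 0.5)
        else:
            ks = rng.uniform(0.0, 0.005)
        origin = og_chrom_of[g.gene_id]
        ks_pairs.append(
            GametologPair(g.gene_id, bid, float(ks), g.interval.midpoint, origin)
        )
        ks_true[g.gene_id] = float(ks)

    # --- coverage windows --------------------------------------------------
    chrom_set = {X: rmap_a, Y: rmap_b}
    for c in auto_chroms:
        chrom_set[c] = rmap_a
    lengths = {X: config.sex_chrom_length, Y: config.sex_chrom_length,
               **config.autosome_lengths}
    total = sum(lengths.values())
    cov_windows: list[CoverageWindow] = []
    noise = config.coverage_noise
    d0 = config.autosomal_depth
    for chrom in sorted(lengths):
        n_w = max(1, int(round(config.n_coverage_windows * lengths[chrom] / total)))
        wsize = lengths[chrom] // n_w
        for wi in range(n_w):
            s = wi * wsize
            e = lengths[chrom] if wi == n_w - 1 else (wi + 1) * wsize
            label = chrom_set[chrom].label_at(chrom, (s + e) // 2)
            if chrom == Y:
                if label in ("oldSLR", "newSLR"):
                    m_mu, f_mu = d0 / 2, 0.2
                else:  # PARs collapse with the X PARs in a diploid reference
                    m_mu, f_mu = d0 / 2, d0 / 2
            elif chrom == X:
                if label in ("oldSLR", "newSLR"):
                    m_mu, f_mu = d0 / 2, d0
                else:
                    m_mu, f_mu = d0 / 2, d0 / 2
            else:
                m_mu, f_mu = d0, d0
            depth = {
                "male1": max(0.0, float(rng.normal(m_mu, noise * m_mu))),
                "female1": max(0.0, float(rng.normal(f_mu, noise * max(f_mu, 0.5)))),
            }
            # X and Y carry the same region names; qualify by chromosome so
            # per-region coverage medians never mix the two haplotypes
            if label is None or label == "autosome":
                wlabel = "autosome"
            else:
                wlabel = f"{chrom}:{label}"
            cov_windows.append(
                CoverageWindow(GenomicInterval(chrom, s, e), depth, wlabel)
            )

    truth = TruthTables(
        loss_status=loss_status,
        sexlinked_sites=sexlinked_sites,
        te_counts=te_counts,
        inversion_intervals=inversion_intervals,
        inversion_fraction=inversion_fraction,
        ks_true=ks_true,
    )
    return TrioBundle(
        config=config,
        annotations={"outgroup": ann_og, "haplotypeA": ann_a, "haplotypeB": ann_b},
        region_map_a=rmap_a,
        region_map_b=rmap_b,
        ortho_rows=ortho_rows,
        tes={"A": te_a, "B": te_b},
        genotypes=gm,
        hits_b=hits_b,
        anchors=anchors,
        ks_pairs=ks_pairs,
        coverage_windows=cov_windows,
        truth=truth,
    )


def validate_bundle(bundle: TrioBundle) -> None:
    """Internal-consistency validator: truth and emitted structures must
    never contradict."""
    ann_b = bundle.annotations["haplotypeB"]
    hit_by_query: dict[str, list[HitRecord]] = {}
    for h in bundle.hits_b:
        hit_by_query.setdefault(h.query_gene_id, []).append(h)
    corr = bundle.corresponding_chrom_map
    ann_a = bundle.annotations["haplotypeA"]
    for gid, status in bundle.truth.loss_status.items():
        bid = "hb_" + gid[3:]
        if bid in ann_b:
            raise ValidationError(f"{gid} marked {status} but annotated on B")
        expected = corr[ann_a[gid].interval.chrom]
        corr_hits = [h for h in hit_by_query.get(gid, [])
                     if h.subject_chrom in expected]
        if status == "full" and corr_hits:
            raise ValidationError(f"{gid} fully lost but has corresponding hit")
        if status == "partial" and not any(
            0 < h.query_coverage_fraction < 0.5 for h in corr_hits
        ):
            raise ValidationError(f"{gid} partial but no fragment hit")
        if status == "present" and not any(
            h.query_coverage_fraction >= 0.5 for h in corr_hits
        ):
            raise ValidationError(f"{gid} present but no >=0.5 hit")
    gm = bundle.genotypes
    males, females = gm.male_idx, gm.female_idx
    for i, s in enumerate(gm.sites):
        if (s.chrom, s.pos) in bundle.truth.sexlinked_sites:
            if not (gm.genotypes[i, males] == GT_HET).all():
                raise ValidationError(f"sex-linked site {s} not all-male-het")
            fg = gm.genotypes[i, females]
            if not ((fg == GT_HOM_REF).all() or (fg == GT_HOM_ALT).all()):
                raise ValidationError(f"sex-linked site {s} females not uniform hom")


# ---------------------------------------------------------------------------
# fixture emission

def _vcf_lines(gm: GenotypeMatrix, chrom_lengths: dict[str, int]) -> list[str]:
    lines = ["##fileformat=VCFv4.2"]
    for c in sorted(chrom_lengths):
        lines.append(f"##contig=<ID={c},length={chrom_lengths[c]}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += [sid for sid, _ in gm.samples]
    lines.append("\t".join(header))
    gt_str = {GT_HOM_REF: "0/0", GT_HET: "0/1", GT_HOM_ALT: "1/1", -1: "./."}
    for i, s in enumerate(gm.sites):
        fields = [s.chrom, str(s.pos + 1), ".", s.ref, s.alt, ".", "PASS", ".", "GT:GQ"]
        for j in range(len(gm.samples)):
            code = int(gm.genotypes[i, j])
            gq = "99" if code != -1 else "0"
            fields.append(f"{gt_str[code]}:{gq}")
        lines.append("\t".join(fields))
    return lines


def emit_fixture(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the whole bundle to ``outdir`` in the pipeline's file formats,
    plus a manifest of seeds and checksums.  Partial writes are cleaned up."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        bundle = simulate_trio(config)
        paths = {
            "outgroup_gff3": outdir / "outgroup.gff3",
            "haplotypeA_gff3": outdir / "haplotypeA.gff3",
            "haplotypeB_gff3": outdir / "haplotypeB.gff3",
            "region_map_a": outdir / "regions_A.tsv",
            "region_map_b": outdir / "regions_B.tsv",
            "ortho_table": outdir / "orthogroups.tsv",
            "te_a": outdir / "te_A.bed",
            "te_b": outdir / "te_B.bed",
            "vcf": outdir / "population.vcf",
            "hits_b": outdir / "hits_B.tsv",
            "anchors": outdir / "anchors.tsv",
            "ks_table": outdir / "ks_pairs.tsv",
            "coverage": outdir / "coverage.tsv",
            "sex_map": outdir / "sex_map.tsv",
        }
        sio.write_gff3(bundle.annotations["outgroup"], paths["outgroup_gff3"])
        sio.write_gff3(bundle.annotations["haplotypeA"], paths["haplotypeA_gff3"])
        sio.write_gff3(bundle.annotations["haplotypeB"], paths["haplotypeB_gff3"])
        sio.write_region_map(bundle.region_map_a, paths["region_map_a"])
        sio.write_region_map(bundle.region_map_b, paths["region_map_b"])
        sio.write_ortho_table(bundle.ortho_rows, paths["ortho_table"])
        sio.write_te_bed(bundle.tes["A"], paths["te_a"])
        sio.write_te_bed(bundle.tes["B"], paths["te_b"])
        all_lengths = {
            **bundle.annotations["haplotypeA"].chrom_lengths,
            **bundle.annotations["haplotypeB"].chrom_lengths,
        }
        paths["vcf"].write_text(
            "\n".join(_vcf_lines(bundle.genotypes, all_lengths)) + "\n"
        )
        sio.write_hit_table(bundle.hits_b, paths["hits_b"])
        sio.write_anchor_table(bundle.anchors, paths["anchors"])
        pd.DataFrame(
            [
                (p.x_gene_id, p.y_gene_id, p.ks, p.x_position, p.origin_chrom)
                for p in bundle.ks_pairs
            ],
            columns=["x_gene", "y_gene", "ks", "x_position", "origin_chrom"],
        ).to_csv(paths["ks_table"], sep="\t", index=False)
        pd.DataFrame(
            [
                (w.interval.chrom, w.interval.start, w.interval.end,
                 w.region_label, w.depth["male1"], w.depth["female1"])
                for w in bundle.coverage_windows
            ],
            columns=["chrom", "start", "end", "region", "male1", "female1"],
        ).to_csv(paths["coverage"], sep="\t", index=False)
        with open(paths["sex_map"], "w") as fh:
            for sid, sex in bundle.genotypes.samples:
                fh.write(f"{sid}\t{sex}\n")
        written.update(paths)

        manifest = {
            "seed": config.seed,
            "files": {
                name: hashlib.sha256(p.read_bytes()).hexdigest()
                for name, p in sorted(paths.items())
            },
        }
        mpath = outdir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written["manifest"] = mpath
        return written
    except Exception:
        for p in written.values():
            p.unlink(missing_ok=True)
        raise


def verify_manifest(outdir: str | Path) -> bool:
    """Re-hash emitted files and compare against the manifest."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    for name, digest in manifest["files"].items():
        p = outdir / {
            "outgroup_gff3": "outgroup.gff3",
            "haplotypeA_gff3": "haplotypeA.gff3",
            "haplotypeB_gff3": "haplotypeB.gff3",
            "region_map_a": "regions_A.tsv",
            "region_map_b": "regions_B.tsv",
            "ortho_table": "orthogroups.tsv",
            "te_a": "te_A.bed",
            "te_b": "te_B.bed",
            "vcf": "population.vcf",
            "hits_b": "hits_B.tsv",
            "anchors": "anchors.tsv",
            "ks_table": "ks_pairs.tsv",
            "coverage": "coverage.tsv",
            "sex_map": "sex_map.tsv",
        }[name]
        if hashlib.sha256(p.read_bytes()).hexdigest() != digest:
            return False
    return True
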