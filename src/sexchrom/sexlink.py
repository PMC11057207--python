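"""Fixed sex-linked variant discovery and phasing validation.

In an XY system, a site fully linked to the sex-determining region is
heterozygous in every male (one X and one Y allele) and homozygous for a
single shared allele in every female.  Scanning a population genotype matrix
for this pattern identifies the sex-linked region; the chromosome assignment
of the hits and the identity of the female homozygous allele (reference on an
X-bearing haplotype assembly) validate the phasing of the two haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from .model import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    GenomeAnnotation,
    GenomicInterval,
    GenotypeMatrix,
    Site,
    ValidationError,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FixedSexVariant:
    site: Site
    female_hom_allele: str  # "ref" | "alt"
    n_males_used: int
    n_females_used: int


def find_fixed_sex_variants(
    gm: GenotypeMatrix, zw_mode: bool = False
) -> list[FixedSexVariant]:
    """Scan for sites heterozygous in all males and homozygous (one shared
    allele) in all females.

    Sites with any missing call among the focal samples are excluded — the
    pattern requires the condition in *all* individuals of each sex, so a
    missing call makes the site unverifiable.  ``zw_mode`` swaps the sex
    roles (all females het, all males homozygous) for ZW systems.

    Raises
    ------
    ValidationError
        If the matrix has no males or no females.
    """
    male_idx, female_idx = gm.male_idx, gm.female_idx
    if zw_mode:
        male_idx, female_idx = female_idx, male_idx
    if male_idx.size == 0 or female_idx.size == 0:
        raise ValidationError("need at least one male and one female sample")
    if len(gm.sites) == 0:
        return []

    het = gm.genotypes[:, male_idx]
    hom = gm.genotypes[:, female_idx]
    no_missing = (gm.genotypes != GT_MISSING).all(axis=1)
    all_het = (het == GT_HET).all(axis=1)
    all_hom_ref = (hom == GT_HOM_REF).all(axis=1)
    all_hom_alt = (hom == GT_HOM_ALT).all(axis=1)
    keep = no_missing & all_het & (all_hom_ref | all_hom_alt)

    out = []
    for i in np.flatnonzero(keep):
        out.append(
            FixedSexVariant(
                gm.sites[i],
                "ref" if all_hom_ref[i] else "alt",
                int(male_idx.size),
                int(female_idx.size),
            )
        )
    return out


def percentage(count: int, denominator: int, decimals: int = 1) -> float:
    """100*count/denominator rounded half-up to ``decimals`` places."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(count) / Decimal(denominator)).quantize(
            q, rounding=ROUND_HALF_UP
        )
    )


@dataclass
class AssignmentSummary:
    """Chromosome assignment and reference-allele concordance of fixed
    sex-variants, with every percentage's denominator recorded."""

    per_chrom_counts: dict[str, int]
    n_total: int
    n_on_target: int
    pct_on_target: float
    n_expected_ref_pattern: int
    pct_expected_ref_pattern: float
    target_chroms: tuple[str, ...]
    expected_pattern: str  # "female_hom_ref" | "male_het_ref"


def summarize_assignment(
    variants: Sequence[FixedSexVariant],
    target_chroms: Sequence[str],
    expected_pattern: str = "female_hom_ref",
    known_chroms: Optional[set[str]] = None,
) -> AssignmentSummary:
    """Tally fixed sex-variants per chromosome and score phasing concordance.

    ``expected_pattern`` is the allele configuration expected when the
    assembly is correctly phased: on an X-bearing haplotype the female
    homozygous allele should be the reference base (``female_hom_ref``); on a
    Y-bearing haplotype the reference carries the male-specific allele, i.e.
    the reference is one allele of the male het and not the female homozygous
    allele (``male_het_ref``).  Percentages use the total variant count as
    denominator and round half-up to one decimal.
    """
    if expected_pattern not in ("female_hom_ref", "male_het_ref"):
        raise ValueError(f"unknown expected pattern {expected_pattern!r}")
    per_chrom: dict[str, int] = {}
    n_on_target = 0
    n_pattern = 0
    for v in variants:
        chrom = v.site.chrom
        if known_chroms is not None and chrom not in known_chroms:
            log.warning("variant on unknown chromosome %s counted as 'other'", chrom)
            chrom = "other"
        per_chrom[chrom] = per_chrom.get(chrom, 0) + 1
        if v.site.chrom in target_chroms:
            n_on_target += 1
        if expected_pattern == "female_hom_ref":
            if v.female_hom_allele == "ref":
                n_pattern += 1
        else:  # male het carries ref => female hom allele is the alt base
            if v.female_hom_allele == "alt":
                n_pattern += 1
    n = len(variants)
    return AssignmentSummary(
        per_chrom_counts=per_chrom,
        n_total=n,
        n_on_target=n_on_target,
        pct_on_target=percentage(n_on_target, n) if n else 0.0,
        n_expected_ref_pattern=n_pattern,
        pct_expected_ref_pattern=percentage(n_pattern, n) if n else 0.0,
        target_chroms=tuple(target_chroms),
        expected_pattern=expected_pattern,
    )


@dataclass
class SexLinkedSpan:
    """Inferred sex-linked interval and flanking PAR candidates."""

    span: Optional[GenomicInterval]
    par_candidates: list[GenomicInterval]
    n_variants_inside: int
    n_variants_total: int
    low_confidence: bool = False


def delimit_sex_linked_span(
    variants: Sequence[FixedSexVariant],
    chrom: str,
    annotation: Optional[GenomeAnnotation] = None,
    min_gap_genes: int = 20,
    core_quantile: float = 0.99,
) -> SexLinkedSpan:
    """Delimit the sex-linked span on one chromosome from variant positions.

    The span is the smallest interval containing at least ``core_quantile``
    of the fixed sex-variants on the chromosome (robust to isolated mismapped
    variants), snapped outward to gene boundaries when an annotation is
    given.  Chromosome tips beyond the span holding >= ``min_gap_genes``
    consecutive variant-free genes are reported as PAR candidates.
    """
    positions = sorted(v.site.pos for v in variants if v.site.chrom == chrom)
    n = len(positions)
    if n == 0:
        return SexLinkedSpan(None, [], 0, 0)
    if n == 1:
        span = GenomicInterval(chrom, positions[0], positions[0] + 1)
        return SexLinkedSpan(span, [], 1, 1, low_confidence=True)

    k = max(2, int(np.ceil(core_quantile * n)))
    k = min(k, n)
    best = (positions[k - 1] - positions[0], 0)
    for i in range(1, n - k + 1):
        width = positions[i + k - 1] - positions[i]
        if width < best[0]:
            best = (width, i)
    i0 = best[1]
    start, end = positions[i0], positions[i0 + k - 1] + 1

    par_candidates: list[GenomicInterval] = []
    if annotation is not None:
        genes = annotation.genes_on(chrom)
        # snap outward to boundaries of genes overlapping the span edges
        for g in genes:
            if g.interval.start < start <= g.interval.end:
                start = g.interval.start
            if g.interval.start <= end < g.interval.end:
                end = g.interval.end
        chrom_len = annotation.chrom_lengths.get(
            chrom, max(g.interval.end for g in genes) if genes else end
        )
        left = [g for g in genes if g.interval.end <= start]
        right = [g for g in genes if g.interval.start >= end]
        if len(left) >= min_gap_genes and start > 0:
            par_candidates.append(GenomicInterval(chrom, 0, start))
        if len(right) >= min_gap_genes and end < chrom_len:
            par_candidates.append(GenomicInterval(chrom, end, chrom_len))

    inside = sum(1 for p in positions if start <= p < end)
    return SexLinkedSpan(
        GenomicInterval(chrom, start, end), par_candidates, inside, n
    )


# ---------------------------------------------------------------------------
# coverage-based phasing validation

@dataclass(frozen=True)
class CoverageWindow:
    interval: GenomicInterval
    depth: dict  # sample_id -> mean depth
    region_label: Optional[str] = None

    def __hash__(self):  # depth dict is not hashable; identity is fine
        return id(self)


@dataclass
class RegionCoverageReport:
    region_label: str
    median_female_male_ratio: float
    median_male_norm_depth: float  # male depth / male autosomal median
    n_windows: int
    y_linked: bool
    hemizygous: bool


def coverage_ratios(
    windows: Sequence[CoverageWindow],
    male_id: str,
    female_id: str,
    y_linked_threshold: float = 0.1,
    hemizygous_band: tuple[float, float] = (0.35, 0.65),
) -> dict[str, RegionCoverageReport]:
    """Per-region female/male depth ratios and phasing-consistency flags.

    Depths are normalized per sample by the autosomal median.  A region is
    flagged Y-linked when the female/male normalized ratio falls below
    ``y_linked_threshold`` (females carry no Y) and hemizygous when the male
    normalized depth sits in ``hemizygous_band`` around 0.5 (males carry one
    copy of each SLR).
    """
    auto = [w for w in windows if w.region_label == "autosome"]
    if not auto:
        raise ValidationError("no autosomal windows for normalization")
    m_auto = float(np.median([w.depth[male_id] for w in auto]))
    f_auto = float(np.median([w.depth[female_id] for w in auto]))
    if m_auto <= 0 or f_auto <= 0:
        raise ValidationError("zero autosomal median depth; cannot normalize")

    by_region: dict[str, list[CoverageWindow]] = {}
    for w in windows:
        if w.region_label is None:
            continue
        by_region.setdefault(w.region_label, []).append(w)

    out = {}
    for label, ws in sorted(by_region.items()):
        m_norm = np.array([w.depth[male_id] / m_auto for w in ws])
        f_norm = np.array([w.depth[female_id] / f_auto for w in ws])
        with np.errstate(divide="ignore", invalid="ignore"):
            fm = np.where(m_norm > 0, f_norm / m_norm, np.inf)
        med_fm = float(np.median(fm))
        med_m = float(np.median(m_norm))
        out[label] = RegionCoverageReport(
            region_label=label,
            median_female_male_ratio=med_fm,
            median_male_norm_depth=med_m,
            n_windows=len(ws),
            y_linked=med_fm < y_linked_threshold,
            hemizygous=hemizygous_band[0] <= med_m <= hemizygous_band[1],
        )
    return out
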