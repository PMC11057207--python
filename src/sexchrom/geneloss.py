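"""Outgroup-triangulated Y/X gene-loss classification.

A gene is a loss candidate on the focal haplotype when its orthogroup has a
syntenic, array-representative member in both the hermaphroditic outgroup
and the other haplotype but none in the focal assembly.  Candidates are then
classified from alignment hits of the missing gene's transcript against the
focal genome: present if the top hit (by percent identity) lands on the
corresponding chromosome with at least half the query aligned, partially
lost if only a fragment (<50% of the query) remains there, fully lost if no
corresponding-chromosome similarity is found.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .model import HitRecord, OrthoRow, RegionMap

log = logging.getLogger(__name__)

OTHER = {"A": "haplotypeB", "B": "haplotypeA"}
FOCAL = {"A": "haplotypeA", "B": "haplotypeB"}


@dataclass(frozen=True)
class Candidate:
    """A putatively lost gene, identified by the other haplotype's gene id."""

    gene_id: str  # id in the non-focal (present) haplotype
    orthogroup_id: str
    source_chrom: str  # chromosome of the present haplotype's copy
    source_pos: int
    region_label: Optional[str] = None
    outgroup_chrom: Optional[str] = None
    outgroup_pos: Optional[int] = None


def candidate_losses(
    rows: Sequence[OrthoRow],
    focal: str,
    region_map_other: Optional[RegionMap] = None,
) -> list[Candidate]:
    """Orthogroups with outgroup and non-focal haplotype present but the
    focal haplotype absent.

    ``rows`` should be pre-filtered to syntenic, array-representative
    orthologs (see :func:`filter_ortho_rows`); region labels are taken from
    the present haplotype's gene position.
    """
    if focal not in ("A", "B"):
        raise ValueError("focal must be 'A' or 'B'")
    out = []
    for row in rows:
        og = row.outgroup
        other = row.entry(OTHER[focal])
        focal_entry = row.entry(FOCAL[focal])
        if og is not None and other is not None and focal_entry is None:
            label = (
                region_map_other.label_at(other.chrom, other.pos)
                if region_map_other is not None
                else None
            )
            out.append(
                Candidate(
                    other.gene_id, row.orthogroup_id, other.chrom, other.pos,
                    label, og.chrom, og.pos,
                )
            )
    return out


def filter_ortho_rows(rows: Sequence[OrthoRow]) -> list[OrthoRow]:
    """Keep orthogroups where every present member is syntenic and
    array-representative (genes in non-representative arrays and nonsyntenic
    orthologs are excluded from loss counting)."""
    out = []
    for row in rows:
        ok = True
        for genome in ("outgroup", "haplotypeA", "haplotypeB"):
            e = row.entry(genome)
            if e is not None and not (e.syntenic and e.array_representative):
                ok = False
                break
        if ok:
            out.append(row)
    return out


@dataclass
class LossCall:
    gene_id: str
    focal_haplotype: str  # "A" | "B"
    status: str  # "present" | "partial_loss" | "full_loss"
    evidence: Optional[tuple[str, float]]  # (top hit chrom, qcov) or None
    region_label: Optional[str]
    source_chrom: str = ""
    source_pos: int = 0
    outgroup_chrom: Optional[str] = None
    outgroup_pos: Optional[int] = None


def _top_hit(hits: list[HitRecord]) -> HitRecord:
    # percent identity desc, then coverage desc, then subject start asc
    return min(
        hits,
        key=lambda h: (
            -h.percent_identity,
            -h.query_coverage_fraction,
            h.subject_interval.start,
        ),
    )


def classify_loss(
    candidates: Sequence[Candidate],
    hits: Sequence[HitRecord],
    corresponding_chrom_map: dict[str, set[str]],
    focal: str,
) -> list[LossCall]:
    """Classify each candidate as present, partially or fully lost.

    The top hit is chosen by percent identity (ties: larger query coverage,
    then smaller subject start).  A candidate is present only when the top
    hit lies on a corresponding chromosome (``corresponding_chrom_map``:
    source chromosome -> focal chromosome set) and covers at least half the
    query.  Otherwise the best corresponding-chromosome hit decides partial
    (fragment, 0 < coverage < 0.5) versus full loss (no such hit).
    Candidates absent from the hit table are fully lost.
    """
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_query.setdefault(h.query_gene_id, []).append(h)

    calls = []
    for cand in candidates:
        expected = corresponding_chrom_map.get(cand.source_chrom, set())
        qhits = by_query.get(cand.gene_id, [])
        if not qhits:
            log.debug("candidate %s has no hits: full loss", cand.gene_id)
            calls.append(
                LossCall(cand.gene_id, focal, "full_loss", None,
                         cand.region_label, cand.source_chrom, cand.source_pos,
                         cand.outgroup_chrom, cand.outgroup_pos)
            )
            continue
        top = _top_hit(qhits)
        on_corresponding = top.subject_chrom in expected
        if on_corresponding and top.query_coverage_fraction >= 0.5:
            status = "present"
            evidence = (top.subject_chrom, top.query_coverage_fraction)
        else:
            # lost; fragment evidence sought among corresponding-chrom hits
            corr = [h for h in qhits if h.subject_chrom in expected]
            if corr:
                best = _top_hit(corr)
                if 0.0 < best.query_coverage_fraction < 0.5:
                    status = "partial_loss"
                    evidence = (best.subject_chrom, best.query_coverage_fraction)
                elif best.query_coverage_fraction >= 0.5:
                    # top hit elsewhere but >=50% of the query survives on the
                    # corresponding chromosome: secondary hits never rescue
                    # presence, so count as partial fragment evidence
                    status = "partial_loss"
                    evidence = (best.subject_chrom, best.query_coverage_fraction)
                else:
                    status = "full_loss"
                    evidence = None
            else:
                status = "full_loss"
                evidence = None
        calls.append(
            LossCall(cand.gene_id, focal, status, evidence, cand.region_label,
                     cand.source_chrom, cand.source_pos,
                     cand.outgroup_chrom, cand.outgroup_pos)
        )
    return calls


@dataclass
class RegionLossRate:
    region_label: str
    n_candidates: int
    n_lost: int
    n_partial: int
    proportion_lost: Optional[float]  # None when no candidates
    partial_fraction_of_lost: Optional[float]
    excess_over_baseline: Optional[float] = None


def loss_rates(
    calls: Sequence[LossCall],
    n_present_by_region: dict[str, int],
    baseline_region: str = "autosome",
) -> dict[str, RegionLossRate]:
    """Per-region loss proportions and excess over the autosomal baseline.

    ``n_present_by_region`` counts the retained (non-candidate) genes per
    region so proportions are lost/(lost+present) over all triangulable
    genes, mirroring a loss rate rather than a composition of calls.  The
    autosomal proportion serves as the baseline for presence-absence
    polymorphism and technical error; ``excess`` subtracts it.
    """
    regions = set(n_present_by_region) | {
        c.region_label for c in calls if c.region_label is not None
    }
    out: dict[str, RegionLossRate] = {}
    for region in sorted(regions):
        rcalls = [c for c in calls if c.region_label == region]
        n_lost = sum(1 for c in rcalls if c.status in ("partial_loss", "full_loss"))
        n_partial = sum(1 for c in rcalls if c.status == "partial_loss")
        n_present = n_present_by_region.get(region, 0) + sum(
            1 for c in rcalls if c.status == "present"
        )
        denom = n_lost + n_present
        prop = n_lost / denom if denom else None
        pfrac = n_partial / n_lost if n_lost else None
        out[region] = RegionLossRate(region, denom, n_lost, n_partial, prop, pfrac)
    base = out.get(baseline_region)
    base_prop = base.proportion_lost if base and base.proportion_lost is not None else None
    if base_prop is not None:
        for r in out.values():
            if r.proportion_lost is not None:
                r.excess_over_baseline = r.proportion_lost - base_prop
    return out


@dataclass
class LossWindow:
    window_index: int
    n_candidates: int
    n_lost: int
    proportion: float
    is_remainder: bool
    anchor_chrom: str = ""
    center_pos: float = 0.0


def windowed_loss(
    calls: Sequence[LossCall],
    anchor_order: str = "X",
    window_genes: int = 20,
) -> tuple[list[LossWindow], int]:
    """Proportion of genes lost in non-overlapping gene-count windows.

    ``anchor_order`` chooses the coordinate system: ``"X"`` orders calls by
    the present haplotype's position, ``"outgroup"`` by the outgroup
    ortholog's position (the likely ancestral gene order).  Calls without a
    position in the chosen frame are skipped and tallied.  The trailing
    remainder window (< ``window_genes`` genes) is kept but flagged.
    Returns (windows, n_skipped).
    """
    if anchor_order not in ("X", "outgroup"):
        raise ValueError("anchor_order must be 'X' or 'outgroup'")
    keyed = []
    skipped = 0
    for c in calls:
        if anchor_order == "X":
            keyed.append(((c.source_chrom, c.source_pos), c))
        else:
            if c.outgroup_chrom is None:
                skipped += 1
                continue
            keyed.append(((c.outgroup_chrom, c.outgroup_pos), c))
    keyed.sort(key=lambda kc: kc[0])
    windows = []
    for wi in range(0, len(keyed), window_genes):
        chunk = [c for _, c in keyed[wi : wi + window_genes]]
        n_lost = sum(1 for c in chunk if c.status != "present")
        positions = [k[1] for k, _ in keyed[wi : wi + window_genes]]
        chroms = {k[0] for k, _ in keyed[wi : wi + window_genes]}
        windows.append(
            LossWindow(
                wi // window_genes,
                len(chunk),
                n_lost,
                n_lost / len(chunk),
                len(chunk) < window_genes,
                anchor_chrom=",".join(sorted(str(c) for c in chroms)),
                center_pos=float(sorted(positions)[len(positions) // 2]),
            )
        )
    return windows, skipped
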