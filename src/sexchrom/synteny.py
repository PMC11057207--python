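"""Collinear anchor chaining, heterozygous inversion detection, and the
nonsyntenic-ortholog asymmetry test.

Between two phased haplotypes of one individual, an inversion heterozygote
appears as a run of syntenic gene anchors whose order in haplotype B is
reversed relative to haplotype A.  Chaining anchors into monotone blocks and
flagging reversed blocks flanked by same-orientation context yields putative
heterozygous inversions and the fraction of the chromosome they span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .model import GenomicInterval, OrthoRow, RegionMap

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Anchor:
    """A syntenic gene pair with positions and ordinal ranks in both genomes."""

    id_a: str
    id_b: str
    chrom_a: str
    pos_a: int
    rank_a: int
    chrom_b: str
    pos_b: int
    rank_b: int


@dataclass
class SyntenyBlock:
    anchors: list[Anchor]
    orientation: str  # "same" | "reversed"

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def interval_a(self) -> GenomicInterval:
        pos = [a.pos_a for a in self.anchors]
        return GenomicInterval(self.anchors[0].chrom_a, min(pos), max(pos) + 1)

    @property
    def interval_b(self) -> GenomicInterval:
        pos = [a.pos_b for a in self.anchors]
        return GenomicInterval(self.anchors[0].chrom_b, min(pos), max(pos) + 1)


def anchors_from_table(df: pd.DataFrame) -> list[Anchor]:
    """Build ranked anchors from an anchor table (idA, chromA, posA, idB,
    chromB, posB, orientation); ranks are ordinal positions within each
    genome's chromosome after sorting by bp."""
    df = df.copy()
    df["rank_a"] = df.groupby("chromA")["posA"].rank(method="first").astype(int)
    df["rank_b"] = df.groupby("chromB")["posB"].rank(method="first").astype(int)
    return [
        Anchor(
            str(r.idA), str(r.idB), str(r.chromA), int(r.posA), int(r.rank_a),
            str(r.chromB), int(r.posB), int(r.rank_b),
        )
        for r in df.itertuples(index=False)
    ]


def chain_anchors(
    anchors: Sequence[Anchor],
    max_gap_ranks: int = 5,
    min_block_anchors: int = 3,
    allow_duplicates: bool = False,
) -> list[SyntenyBlock]:
    """Chain anchors into maximal collinear blocks.

    Within each (chrom_a, chrom_b) pair, anchors sorted by A-rank are grown
    greedily into maximal runs with monotone B-ranks (increasing = same
    orientation, decreasing = reversed), allowing rank gaps up to
    ``max_gap_ranks`` in both genomes.  Runs shorter than
    ``min_block_anchors`` are discarded; retained blocks partition the
    retained anchors.
    """
    if not allow_duplicates:
        for attr in ("id_a", "id_b"):
            ids = [getattr(a, attr) for a in anchors]
            if len(set(ids)) != len(ids):
                raise ValueError(
                    f"duplicate gene in multiple anchors ({attr}); "
                    "set allow_duplicates to permit"
                )
    by_pair: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        by_pair.setdefault((a.chrom_a, a.chrom_b), []).append(a)

    blocks: list[SyntenyBlock] = []
    for pair in sorted(by_pair):
        chain = sorted(by_pair[pair], key=lambda a: a.rank_a)
        run: list[Anchor] = []
        direction = 0  # 0 undetermined, +1 increasing, -1 decreasing

        def close_run() -> None:
            nonlocal run, direction
            if len(run) >= min_block_anchors:
                blocks.append(
                    SyntenyBlock(run, "same" if direction >= 0 else "reversed")
                )
            run, direction = [], 0

        for a in chain:
            if not run:
                run.append(a)
                continue
            prev = run[-1]
            gap_a = a.rank_a - prev.rank_a
            step_b = a.rank_b - prev.rank_b
            if gap_a > max_gap_ranks or abs(step_b) > max_gap_ranks or step_b == 0:
                close_run()
                run.append(a)
                continue
            new_dir = 1 if step_b > 0 else -1
            if direction == 0 or new_dir == direction:
                direction = new_dir
                run.append(a)
            else:
                close_run()
                run.append(a)
        close_run()
    return blocks


@dataclass
class InversionCall:
    interval_a: GenomicInterval
    interval_b: GenomicInterval
    n_anchors: int
    fraction_of_chromosome: float


@dataclass
class InversionSummary:
    calls: list[InversionCall]
    n_inversions: int
    total_fraction: float


def call_inversions(
    blocks: Sequence[SyntenyBlock], chromosome_length: int
) -> InversionSummary:
    """Call heterozygous inversions from block orientations on one
    chromosome pair.

    A reversed block becomes an inversion call when every existing
    neighbouring block is same-orientation (chromosome ends count as
    context).  The summary reports the count and the summed fraction of the
    A chromosome spanned.
    """
    if chromosome_length <= 0:
        raise ValueError("chromosome_length must be positive")
    ordered = sorted(blocks, key=lambda b: b.interval_a.start)
    calls = []
    for i, b in enumerate(ordered):
        if b.orientation != "reversed":
            continue
        left_ok = i == 0 or ordered[i - 1].orientation == "same"
        right_ok = i == len(ordered) - 1 or ordered[i + 1].orientation == "same"
        if left_ok and right_ok:
            frac = len(b.interval_a) / chromosome_length
            calls.append(
                InversionCall(b.interval_a, b.interval_b, b.n_anchors, frac)
            )
    return InversionSummary(
        calls, len(calls), sum(c.fraction_of_chromosome for c in calls)
    )


# ---------------------------------------------------------------------------
# nonsyntenic-ortholog asymmetry

@dataclass
class AsymmetryResult:
    """2x2 counts of haplotype-exclusive syntenic orthologs by region."""

    counts: np.ndarray  # rows: (A-syntenic-only, B-syntenic-only); cols: (oldSLR, autosome)
    chi2: float
    p_value: float
    df: int
    continuity_correction: bool
    warning: str = ""


def nonsyntenic_asymmetry(
    rows: Sequence[OrthoRow],
    region_map_a: RegionMap,
    region_map_b: RegionMap,
    continuity_correction: bool = False,
) -> AsymmetryResult:
    """Chi-square test of independence for nonsyntenic-ortholog asymmetry.

    Considers one-to-one orthologs present in the outgroup and in both
    haplotypes where exactly one haplotype retains a syntenic outgroup
    ortholog.  Counts are cross-classified as (A-syntenic-only vs
    B-syntenic-only) x (old sex-linked region vs autosomes), the region
    taken from the syntenic haplotype's own gene position.  Pearson
    chi-square, df=1; continuity correction off by default.
    """
    counts = np.zeros((2, 2), dtype=int)
    for row in rows:
        a, b, og = row.haplotypeA, row.haplotypeB, row.outgroup
        if a is None or b is None or og is None:
            continue
        if a.syntenic == b.syntenic:
            continue  # need exactly one syntenic haplotype
        if a.syntenic:
            hap_idx, entry, rmap = 0, a, region_map_a
        else:
            hap_idx, entry, rmap = 1, b, region_map_b
        label = rmap.label_at(entry.chrom, entry.pos)
        if label == "oldSLR":
            counts[hap_idx, 0] += 1
        elif label == "autosome":
            counts[hap_idx, 1] += 1
    warning = ""
    if counts.sum() == 0 or (counts.sum(axis=0) == 0).any() or (
        counts.sum(axis=1) == 0
    ).any():
        return AsymmetryResult(
            counts, float("nan"), float("nan"), 1, continuity_correction,
            warning="degenerate table: statistic undefined",
        )
    chi2, p, dof, expected = chi2_contingency(
        counts, correction=continuity_correction
    )
    if (expected < 1).any():
        warning = "expected cell < 1"
        log.warning("nonsyntenic asymmetry: %s", warning)
    return AsymmetryResult(counts, float(chi2), float(p), int(dof),
                           continuity_correction, warning)
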