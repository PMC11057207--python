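"""Shared domain types and coordinate conventions.

All positions are 0-based half-open internally; GFF3/VCF 1-based coordinates
are converted at the I/O boundary only, so ``len(interval) == end - start``
holds everywhere without exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

REGION_LABELS = ("PAR1", "oldSLR", "newSLR", "PAR2", "autosome")

#: Closed vocabulary of TE superfamily codes (Wicker-style three-letter codes:
#: D** = DNA transposons, R** = retrotransposons).
TE_SUPERFAMILIES = (
    "DHH", "DTA", "DTC", "DTH", "DTM", "DTT", "RIX", "RLC", "RLG", "RLX",
)


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    Attributes
    ----------
    chrom : str
        Chromosome / scaffold identifier (non-empty).
    start, end : int
        0-based inclusive start, exclusive end; ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def intersection_length(self, start: int, end: int) -> int:
        """Length of overlap with the bare span [start, end) on this chrom."""
        return max(0, min(self.end, end) - max(self.start, start))

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GeneRecord:
    """A gene with exon structure and a region label.

    ``exons`` are sorted, non-overlapping and contained in ``interval``;
    introns are their complement within the gene body.  ``region_label`` is
    assigned from a :class:`RegionMap`, never free-typed.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    region_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.region_label is not None and self.region_label not in REGION_LABELS:
            raise ValidationError(f"unknown region label {self.region_label!r}")
        prev_end = None
        for exon in self.exons:
            if not self.interval.contains(exon):
                raise ValidationError(
                    f"exon {exon} outside gene {self.gene_id} {self.interval}"
                )
            if exon.strand != self.interval.strand:
                raise ValidationError(f"exon strand mismatch in {self.gene_id}")
            if prev_end is not None and exon.start < prev_end:
                raise ValidationError(f"exons overlap/unsorted in {self.gene_id}")
            prev_end = exon.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def introns(self) -> list[GenomicInterval]:
        """Complement of the exons within the gene body."""
        out = []
        pos = self.interval.start
        for exon in self.exons:
            if exon.start > pos:
                out.append(
                    GenomicInterval(self.interval.chrom, pos, exon.start, self.strand)
                )
            pos = exon.end
        if pos < self.interval.end:
            out.append(
                GenomicInterval(self.interval.chrom, pos, self.interval.end, self.strand)
            )
        return out


@dataclass
class GenomeAnnotation:
    """Gene annotations for one genome, keyed and ordered."""

    genes: list[GeneRecord]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise ValidationError("duplicate gene ids in annotation")

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def genes_on(self, chrom: str) -> list[GeneRecord]:
        out = [g for g in self.genes if g.interval.chrom == chrom]
        out.sort(key=lambda g: g.interval.start)
        return out

    def apply_region_map(self, region_map: "RegionMap") -> None:
        for g in self.genes:
            g.region_label = region_map.label_at(g.interval.chrom, g.interval.midpoint)


class RegionMap:
    """Maps (chrom, position) to a region label.

    Intervals on the same chromosome must not overlap; positions outside all
    intervals are reported as ``None`` (unlabeled).
    """

    def __init__(self, entries: Iterable[tuple[str, GenomicInterval, str]]):
        self.entries: list[tuple[str, GenomicInterval, str]] = []
        self._trees: dict[str, IntervalTree] = {}
        for chrom, interval, label in entries:
            if label not in REGION_LABELS:
                raise ValidationError(f"unknown region label {label!r}")
            tree = self._trees.setdefault(chrom, IntervalTree())
            if tree.overlap(interval.start, interval.end):
                raise ValidationError(
                    f"overlapping region intervals on {chrom} at {interval}"
                )
            tree.addi(interval.start, interval.end, label)
            self.entries.append((chrom, interval, label))

    def label_at(self, chrom: str, pos: int) -> Optional[str]:
        """Region label of a single bp position, or None if unlabeled."""
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = tree.at(pos)
        if not hits:
            return None
        # non-overlap invariant => at most one hit
        return next(iter(hits)).data

    def intervals_for(self, label: str) -> list[tuple[str, GenomicInterval]]:
        return [(c, iv) for c, iv, lab in self.entries if lab == label]

    def region_length(self, label: str) -> int:
        return sum(len(iv) for _, iv in self.intervals_for(label))

    def chroms(self) -> list[str]:
        return sorted(self._trees)


@dataclass(frozen=True)
class TERecord:
    """A transposable-element annotation interval."""

    interval: GenomicInterval
    superfamily_code: str
    family_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.superfamily_code not in TE_SUPERFAMILIES:
            raise ValidationError(
                f"unknown TE superfamily code {self.superfamily_code!r}"
            )


@dataclass(frozen=True)
class OrthoEntry:
    """Per-genome membership of one orthogroup."""

    gene_id: str
    chrom: str
    pos: int  # midpoint, bp
    syntenic: bool
    array_representative: bool


GENOME_KEYS = ("outgroup", "haplotypeA", "haplotypeB")


@dataclass
class OrthoRow:
    """One orthogroup with per-genome membership (None = absent)."""

    orthogroup_id: str
    outgroup: Optional[OrthoEntry] = None
    haplotypeA: Optional[OrthoEntry] = None
    haplotypeB: Optional[OrthoEntry] = None

    def __post_init__(self) -> None:
        if self.outgroup is None and self.haplotypeA is None and self.haplotypeB is None:
            raise ValidationError(
                f"orthogroup {self.orthogroup_id}: no genome present"
            )

    def entry(self, genome: str) -> Optional[OrthoEntry]:
        if genome not in GENOME_KEYS:
            raise KeyError(genome)
        return getattr(self, genome)


@dataclass(frozen=True)
class Site:
    """One variant site (0-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str  # "SNP" | "indel"


# genotype codes in GenotypeMatrix.genotypes
GT_HOM_REF, GT_HET, GT_HOM_ALT, GT_MISSING = 0, 1, 2, -1


@dataclass
class GenotypeMatrix:
    """Sites x samples diploid genotype matrix with sample sex labels.

    ``genotypes`` is an int8 array coded 0=hom_ref, 1=het, 2=hom_alt,
    -1=missing, shape (n_sites, n_samples).
    """

    sites: list[Site]
    samples: list[tuple[str, str]]  # (sample_id, "M"|"F")
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValidationError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        for _, sex in self.samples:
            if sex not in ("M", "F"):
                raise ValidationError(f"sample sex must be M or F, got {sex!r}")

    @property
    def male_idx(self) -> np.ndarray:
        return np.array([i for i, (_, s) in enumerate(self.samples) if s == "M"])

    @property
    def female_idx(self) -> np.ndarray:
        return np.array([i for i, (_, s) in enumerate(self.samples) if s == "F"])


@dataclass(frozen=True)
class HitRecord:
    """One alignment hit of a query gene against a subject genome."""

    query_gene_id: str
    subject_chrom: str
    subject_interval: GenomicInterval
    percent_identity: float
    query_coverage_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValidationError(f"pident out of range: {self.percent_identity}")
        if not (0.0 <= self.query_coverage_fraction <= 1.0):
            raise ValidationError(
                f"qcov out of range: {self.query_coverage_fraction}"
            )


# ---------------------------------------------------------------------------
# interval arithmetic helpers (0-based half-open throughout)

def merge_spans(spans: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open spans as a sorted list of disjoint spans."""
    if not spans:
        return []
    ordered = sorted(spans)
    out = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def merged_coverage(spans: Sequence[tuple[int, int]], start: int, end: int) -> int:
    """Total bp of the union of ``spans`` clipped to [start, end)."""
    total = 0
    for s, e in merge_spans(spans):
        total += max(0, min(e, end) - max(s, start))
    return total


def summed_coverage(spans: Sequence[tuple[int, int]], start: int, end: int) -> int:
    """Total bp of spans clipped to [start, end), overlaps counted repeatedly."""
    return sum(max(0, min(e, end) - max(s, start)) for s, e in spans)
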