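"""Readers and writers for the standard formats the pipeline touches.

GFF3 and VCF use 1-based inclusive coordinates on disk; everything is
converted to the internal 0-based half-open convention here and nowhere else.
Every reader/writer pair is a lossless round trip on the fixtures the
simulator emits.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import gffutils
import pandas as pd
import pysam

from .model import (
    GENOME_KEYS,
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
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
    ValidationError,
)

log = logging.getLogger(__name__)

ABSENT = "."


class ParseError(ValueError):
    """Raised on malformed input, naming the offending location."""


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path, region_map: Optional[RegionMap] = None) -> GenomeAnnotation:
    """Parse gene and exon features from a GFF3 file.

    1-based inclusive GFF3 coordinates become 0-based half-open; strand is
    preserved.  Chromosome lengths are taken from ``##sequence-region``
    pragmas when present.
    """
    path = Path(path)
    chrom_lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chrom_lengths[parts[1]] = int(parts[3])
            elif not line.startswith("#"):
                break
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad syntax
        raise ParseError(f"{path}: malformed GFF3: {exc}") from exc

    genes: list[GeneRecord] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        interval = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        exons = []
        for ex in db.children(feat, featuretype="exon", order_by="start"):
            ex_iv = GenomicInterval(ex.seqid, ex.start - 1, ex.end, ex.strand)
            if not interval.contains(ex_iv):
                raise ValidationError(
                    f"{path}: exon {ex_iv} outside gene {gene_id} {interval}"
                )
            exons.append(ex_iv)
        genes.append(GeneRecord(gene_id, interval, exons))
    ann = GenomeAnnotation(genes, chrom_lengths)
    if region_map is not None:
        ann.apply_region_map(region_map)
    return ann


def write_gff3(ann: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(ann.chrom_lengths):
            fh.write(f"##sequence-region {chrom} 1 {ann.chrom_lengths[chrom]}\n")
        for gene in sorted(ann.genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            iv = gene.interval
            fh.write(
                f"{iv.chrom}\tsexchrom\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={gene.gene_id}\n"
            )
            for i, ex in enumerate(gene.exons, 1):
                fh.write(
                    f"{ex.chrom}\tsexchrom\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\tID={gene.gene_id}.exon{i};Parent={gene.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# VCF

def read_vcf(
    path: str | Path,
    sex_map: dict[str, str],
    gq_threshold: int = 30,
) -> GenotypeMatrix:
    """Read a VCF into a genotype matrix, applying the site/call filters.

    Only biallelic sites are retained; calls with GQ <= ``gq_threshold``
    (strict ``> 30`` retained by default) are set to missing; sites where ref
    and alt differ in length are flagged as indels.

    Raises
    ------
    ValidationError
        If a VCF sample is missing from ``sex_map``.
    """
    vcf = pysam.VariantFile(str(path))
    sample_ids = list(vcf.header.samples)
    for s in sample_ids:
        if s not in sex_map:
            raise ValidationError(f"sample {s!r} in VCF missing from sex map")
    samples = [(s, sex_map[s]) for s in sample_ids]

    sites: list[Site] = []
    rows: list[list[int]] = []
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            continue  # biallelic only
        ref, alt = rec.ref, rec.alts[0]
        vtype = "SNP" if len(ref) == len(alt) else "indel"
        row = []
        for s in sample_ids:
            call = rec.samples[s]
            gt = call.get("GT")
            gq = call.get("GQ")
            if gt is None or None in gt:
                row.append(GT_MISSING)
            elif gq is not None and gq <= gq_threshold:
                row.append(GT_MISSING)
            else:
                n_alt = sum(1 for a in gt if a == 1)
                row.append((GT_HOM_REF, GT_HET, GT_HOM_ALT)[n_alt])
        sites.append(Site(rec.chrom, rec.pos - 1, ref, alt, vtype))
        rows.append(row)
    import numpy as np

    geno = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.zeros((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(sites, samples, geno)


# ---------------------------------------------------------------------------
# ortholog table (TSV)

_ORTHO_FIELDS = ("gene", "chrom", "pos", "syntenic", "representative")


def _ortho_cols(genome: str) -> list[str]:
    prefix = {"outgroup": "og", "haplotypeA": "a", "haplotypeB": "b"}[genome]
    return [f"{prefix}_{f}" for f in _ORTHO_FIELDS]


def read_ortho_table(path: str | Path) -> list[OrthoRow]:
    """Read the pangenome-style syntenic-ortholog table.

    Absent genome entries are represented by '.' in all five per-genome
    columns and become ``None``, never empty strings.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["orthogroup_id"] + [c for g in GENOME_KEYS for c in _ortho_cols(g)]
    if list(df.columns) != expected:
        raise ParseError(
            f"{path}: unexpected ortholog table header {list(df.columns)}"
        )
    if df["orthogroup_id"].duplicated().any():
        dup = df["orthogroup_id"][df["orthogroup_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate orthogroup_id {dup!r}")
    rows: list[OrthoRow] = []
    for rec in df.itertuples(index=False):
        kwargs: dict[str, Optional[OrthoEntry]] = {}
        vals = list(rec)
        for gi, genome in enumerate(GENOME_KEYS):
            gene, chrom, pos, syn, rep = vals[1 + gi * 5 : 6 + gi * 5]
            if gene == ABSENT:
                if syn not in (ABSENT, ""):
                    raise ValidationError(
                        f"{path}: orthogroup {vals[0]}: syntenic flag on absent gene"
                    )
                kwargs[genome] = None
            else:
                kwargs[genome] = OrthoEntry(
                    gene, chrom, int(pos), syn == "1", rep == "1"
                )
        rows.append(OrthoRow(vals[0], **kwargs))
    return rows


def write_ortho_table(rows: list[OrthoRow], path: str | Path) -> None:
    cols = ["orthogroup_id"] + [c for g in GENOME_KEYS for c in _ortho_cols(g)]
    out = []
    for row in rows:
        rec = [row.orthogroup_id]
        for genome in GENOME_KEYS:
            e = row.entry(genome)
            if e is None:
                rec += [ABSENT] * 5
            else:
                rec += [
                    e.gene_id,
                    e.chrom,
                    str(e.pos),
                    "1" if e.syntenic else "0",
                    "1" if e.array_representative else "0",
                ]
        out.append(rec)
    pd.DataFrame(out, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TE BED6 (name field: "superfamily:family")

def read_te_bed(path: str | Path) -> list[TERecord]:
    tes: list[TERecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{ln}: expected BED6, got {len(parts)} fields")
            chrom, start, end, name, _score, strand = parts[:6]
            if ":" in name:
                superfam, family = name.split(":", 1)
                family_id = None if family == ABSENT else family
            else:
                superfam, family_id = name, None
            tes.append(
                TERecord(
                    GenomicInterval(chrom, int(start), int(end), strand),
                    superfam,
                    family_id,
                )
            )
    return tes


def write_te_bed(tes: list[TERecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for te in tes:
            iv = te.interval
            name = f"{te.superfamily_code}:{te.family_id or ABSENT}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# hit table (TSV: query, subject_chrom, subject_start, subject_end, pident, qcov)

def read_hit_table(path: str | Path) -> list[HitRecord]:
    df = pd.read_csv(path, sep="\t")
    hits = []
    for rec in df.itertuples(index=False):
        hits.append(
            HitRecord(
                str(rec.query),
                str(rec.subject_chrom),
                GenomicInterval(
                    str(rec.subject_chrom), int(rec.subject_start), int(rec.subject_end)
                ),
                float(rec.pident),
                float(rec.qcov),
            )
        )
    return hits


def write_hit_table(hits: list[HitRecord], path: str | Path) -> None:
    rows = [
        (
            h.query_gene_id,
            h.subject_chrom,
            h.subject_interval.start,
            h.subject_interval.end,
            h.percent_identity,
            h.query_coverage_fraction,
        )
        for h in hits
    ]
    pd.DataFrame(
        rows,
        columns=["query", "subject_chrom", "subject_start", "subject_end", "pident", "qcov"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# region map (BED-like TSV: chrom, start, end, label)

def read_region_map(path: str | Path) -> RegionMap:
    entries = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{ln}: expected 4 fields")
            chrom, start, end, label = parts
            entries.append((chrom, GenomicInterval(chrom, int(start), int(end)), label))
    return RegionMap(entries)


def write_region_map(region_map: RegionMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, iv, label in region_map.entries:
            fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{label}\n")


# ---------------------------------------------------------------------------
# anchors (TSV: idA, chromA, posA, idB, chromB, posB, orientation)

def read_anchor_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"idA", "chromA", "posA", "idB", "chromB", "posB", "orientation"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: anchor table missing columns {required - set(df.columns)}")
    return df


def write_anchor_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ks table and coverage tracks are plain pandas TSVs

def read_ks_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_coverage_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
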