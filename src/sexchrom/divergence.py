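"""Synonymous divergence (Ks) between gametologs.

Implements the Nei–Gojobori (1986) counting estimator with Jukes–Cantor
correction: fractional synonymous/nonsynonymous site counts per codon,
pathway-averaged difference counts for multi-hit codons, and

    Ks = -(3/4) * ln(1 - (4/3) * ps)

Recombination suppression between the X and Y leaves gametologs to diverge
neutrally at synonymous sites, so Ks is the standard proxy for the time since
a gene stopped recombining; sliding-window medians along the X and young/old
contingency tests by ancestral chromosome of origin probe for evolutionary
strata.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2_contingency

BASES = "ACGT"

# standard genetic code
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in _CODON_TABLE.items() if aa == "*")


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon]


def _codon_syn_sites(codon: str) -> float:
    """Fractional number of synonymous sites in one codon.

    Each position contributes (synonymous single changes)/3; changes creating
    a stop codon count as nonsynonymous.
    """
    aa = _CODON_TABLE[codon]
    s = 0.0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if _CODON_TABLE[mut] == aa and _CODON_TABLE[mut] != "*":
                s += 1.0 / 3.0
    return s


_SYN_SITES_CACHE = {c: _codon_syn_sites(c) for c in _CODON_TABLE if c not in STOP_CODONS}


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences between two codons.

    Averages over all orderings of the differing positions; pathways passing
    through a stop codon are excluded (if every pathway does, all are kept).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        has_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODON_TABLE[nxt] == "*":
                has_stop = True
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt] and _CODON_TABLE[nxt] != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        all_paths.append((sd, nd))
        if not has_stop:
            valid.append((sd, nd))
    paths = valid if valid else all_paths
    sd_mean = sum(p[0] for p in paths) / len(paths)
    nd_mean = sum(p[1] for p in paths) / len(paths)
    return sd_mean, nd_mean


@dataclass(frozen=True)
class KsResult:
    """NG86 site/difference counts and corrected rates for one pair."""

    s_sites: float
    n_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    ps: float
    ks: Optional[float]  # None when the JC correction is out of domain

    @property
    def pn(self) -> float:
        return self.nonsyn_diffs / self.n_sites if self.n_sites > 0 else float("nan")


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 distance correction; None outside the domain p < 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ks_ng86(seq1: str, seq2: str) -> KsResult:
    """NG86 synonymous divergence between two codon-aligned sequences.

    Parameters
    ----------
    seq1, seq2 : str
        Equal-length, gap-free nucleotide sequences (length a multiple of 3,
        no internal stop codons).  Codons containing non-ACGT characters are
        dropped pairwise.

    Returns
    -------
    KsResult
        Site counts averaged over the two sequences, pathway-averaged
        difference counts, proportion of synonymous differences ps, and
        Jukes–Cantor-corrected Ks (None when 4*ps/3 >= 1).
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError(f"sequence lengths differ: {len(seq1)} vs {len(seq2)}")
    if len(seq1) % 3 != 0:
        raise ValueError(f"length {len(seq1)} not divisible by 3")

    s1 = s2 = 0.0
    sd = nd = 0.0
    n_codons_used = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if any(b not in BASES for b in c1 + c2):
            continue  # ambiguity: drop codon pairwise
        idx = i // 3
        if c1 in STOP_CODONS:
            raise ValueError(f"internal stop codon {c1} at codon index {idx} in seq1")
        if c2 in STOP_CODONS:
            raise ValueError(f"internal stop codon {c2} at codon index {idx} in seq2")
        s1 += _SYN_SITES_CACHE[c1]
        s2 += _SYN_SITES_CACHE[c2]
        d_s, d_n = _pathway_diffs(c1, c2)
        sd += d_s
        nd += d_n
        n_codons_used += 1

    s_sites = (s1 + s2) / 2.0
    n_sites = 3.0 * n_codons_used - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    ks = jukes_cantor(ps) if s_sites > 0 else None
    return KsResult(s_sites, n_sites, sd, nd, ps, ks)


# ---------------------------------------------------------------------------
# gametolog containers and windowing

@dataclass
class GametologPair:
    """An X/Y gene pair with its synonymous divergence."""

    x_gene_id: str
    y_gene_id: str
    ks: Optional[float]
    x_position: int
    origin_chrom: Optional[str] = None


@dataclass(frozen=True)
class KsWindowConfig:
    window_genes: int = 100
    step_genes: int = 1
    max_ks: float = 0.2

    def __post_init__(self) -> None:
        if not (self.window_genes >= self.step_genes >= 1):
            raise ValueError("require window >= step >= 1")
        if self.max_ks <= 0:
            raise ValueError("max_ks must be positive")


@dataclass(frozen=True)
class KsWindow:
    center_position: float  # median x_position of members
    median_ks: float
    n_genes: int


def sliding_median_ks(
    pairs: Sequence[GametologPair], cfg: KsWindowConfig = KsWindowConfig()
) -> list[KsWindow]:
    """Median Ks in gene-count sliding windows along the X.

    Pairs with undefined Ks or Ks >= ``max_ks`` are excluded before
    windowing; the window center is the median x position of its members.
    Returns an empty list (with a warning) when fewer pairs than one window
    remain.
    """
    usable = sorted(
        (p for p in pairs if p.ks is not None and p.ks < cfg.max_ks),
        key=lambda p: p.x_position,
    )
    if len(usable) < cfg.window_genes:
        import logging

        logging.getLogger(__name__).warning(
            "only %d usable pairs < window size %d; no windows",
            len(usable),
            cfg.window_genes,
        )
        return []
    ks_vals = np.array([p.ks for p in usable])
    pos_vals = np.array([p.x_position for p in usable], dtype=float)
    out = []
    for start in range(0, len(usable) - cfg.window_genes + 1, cfg.step_genes):
        sl = slice(start, start + cfg.window_genes)
        out.append(
            KsWindow(
                float(np.median(pos_vals[sl])),
                float(np.median(ks_vals[sl])),
                cfg.window_genes,
            )
        )
    return out


# ---------------------------------------------------------------------------
# strata test

@dataclass(frozen=True)
class StrataConfig:
    young_old_threshold: float = 0.03

    def __post_init__(self) -> None:
        if self.young_old_threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class StrataResult:
    """Young/old x origin-chromosome contingency test."""

    origins: tuple[str, str]
    counts: np.ndarray  # 2x2: rows=origins, cols=(young, old)
    n_ties_excluded: int
    chi2: Optional[float]
    p_value: Optional[float]
    note: str = ""


def strata_test(
    pairs: Sequence[GametologPair], cfg: StrataConfig = StrataConfig()
) -> StrataResult:
    """Test for strata: do the two ancestral origin chromosomes differ in
    their ratio of young (Ks < threshold) to old (Ks > threshold) genes?

    Ties at exactly the threshold are excluded (logged); Pearson chi-square
    with df=1, no continuity correction.
    """
    labeled = [p for p in pairs if p.origin_chrom is not None and p.ks is not None]
    origins = sorted({p.origin_chrom for p in labeled})
    if len(origins) != 2:
        raise ValueError(f"expected exactly two origin labels, got {origins}")
    counts = np.zeros((2, 2), dtype=int)
    ties = 0
    thr = cfg.young_old_threshold
    for p in labeled:
        if p.ks == thr:
            ties += 1
            continue
        row = origins.index(p.origin_chrom)
        col = 0 if p.ks < thr else 1
        counts[row, col] += 1
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        return StrataResult(
            tuple(origins), counts, ties, None, None,
            note="empty class: statistic undefined",
        )
    chi2, p, _, expected = chi2_contingency(counts, correction=False)
    note = "" if (expected >= 1).all() else "expected cell < 1"
    return StrataResult(tuple(origins), counts, ties, float(chi2), float(p), note)
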