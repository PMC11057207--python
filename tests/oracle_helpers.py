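"""Independent oracles used by the test suite.

Each function recomputes a quantity by a deliberately different route from
the implementation it checks: per-base bitmaps instead of interval merging,
recursive codon-pathway enumeration instead of permutation averaging, the
closed-form Pearson formula instead of scipy's contingency machinery.
"""

from __future__ import annotations

import itertools

import numpy as np

GENETIC_CODE = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_BASES, repeat=3)):
    GENETIC_CODE[_b1 + _b2 + _b3] = _AA[_i]


def ng86_sites_oracle(seq: str) -> float:
    """Synonymous site count by direct mutation enumeration."""
    s = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        aa = GENETIC_CODE[codon]
        for pos in range(3):
            syn = 0
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                if GENETIC_CODE[mut] == aa and GENETIC_CODE[mut] != "*":
                    syn += 1
            s += syn / 3.0
    return s


def _paths(c1: str, c2: str):
    """All mutational pathways between two codons, recursively."""
    if c1 == c2:
        yield []
        return
    for pos in range(3):
        if c1[pos] != c2[pos]:
            step = c1[:pos] + c2[pos] + c1[pos + 1 :]
            for rest in _paths(step, c2):
                yield [(c1, step)] + rest


def ng86_diffs_oracle(seq1: str, seq2: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) differences by recursive enumeration,
    excluding pathways through stop codons (kept if all pass through one)."""
    sd = nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if c1 == c2:
            continue
        scored = []
        for path in _paths(c1, c2):
            has_stop = any(GENETIC_CODE[b] == "*" for _, b in path)
            syn = sum(
                1
                for a, b in path
                if GENETIC_CODE[a] == GENETIC_CODE[b] and GENETIC_CODE[b] != "*"
            )
            scored.append((has_stop, syn, len(path) - syn))
        ok = [t for t in scored if not t[0]] or scored
        sd += sum(t[1] for t in ok) / len(ok)
        nd += sum(t[2] for t in ok) / len(ok)
    return sd, nd


def random_codon_seq(rng: np.random.Generator, n_codons: int) -> str:
    codons = [c for c, aa in GENETIC_CODE.items() if aa != "*"]
    return "".join(rng.choice(codons, size=n_codons))


def mutate_codon_seq(
    rng: np.random.Generator, seq: str, n_mut: int
) -> str:
    """Random point mutations avoiding stop codons."""
    s = list(seq)
    done = 0
    while done < n_mut:
        i = int(rng.integers(0, len(s)))
        b = "ACGT"[int(rng.integers(0, 4))]
        if s[i] == b:
            continue
        old = s[i]
        s[i] = b
        codon_start = 3 * (i // 3)
        if GENETIC_CODE["".join(s[codon_start : codon_start + 3])] == "*":
            s[i] = old
            continue
        done += 1
    return "".join(s)


def pearson_chi2_closed_form(table: np.ndarray) -> float:
    """N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) for a 2x2 table."""
    a, b = float(table[0, 0]), float(table[0, 1])
    c, d = float(table[1, 0]), float(table[1, 1])
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    return n * (a * d - b * c) ** 2 / denom


def bitmap_coverage(
    spans: list[tuple[int, int]], start: int, end: int, merged: bool = True
) -> int:
    """Per-base bitmap (or per-base counter) coverage of [start, end)."""
    if merged:
        bitmap = np.zeros(end - start, dtype=bool)
        for s, e in spans:
            s_, e_ = max(s, start), min(e, end)
            if e_ > s_:
                bitmap[s_ - start : e_ - start] = True
        return int(bitmap.sum())
    counter = np.zeros(end - start, dtype=np.int64)
    for s, e in spans:
        s_, e_ = max(s, start), min(e, end)
        if e_ > s_:
            counter[s_ - start : e_ - start] += 1
    return int(counter.sum())


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def groups(self):
        out = {}
        for x in self.parent:
            out.setdefault(self.find(x), set()).add(x)
        return sorted(out.values(), key=min)


def monotone_runs_oracle(b_ranks: list[int], max_gap: int) -> list[tuple[int, int, str]]:
    """Split a sequence of B-ranks into maximal monotone runs with bounded
    steps, by explicit breakpoint scanning (independent of the chaining
    implementation).  Returns (start_idx, end_idx_exclusive, orientation)."""
    n = len(b_ranks)
    if n == 0:
        return []
    runs = []
    start = 0
    direction = 0
    for i in range(1, n):
        step = b_ranks[i] - b_ranks[i - 1]
        ok = step != 0 and abs(step) <= max_gap
        new_dir = 0 if not ok else (1 if step > 0 else -1)
        if not ok or (direction != 0 and new_dir != direction):
            runs.append((start, i, "same" if direction >= 0 else "reversed"))
            start = i
            direction = 0
        else:
            direction = new_dir
    runs.append((start, n, "same" if direction >= 0 else "reversed"))
    return runs
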