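"""Independent brute-force oracles used to cross-check the implementation.

Kept deliberately naive and separate from the package internals: quadratic
DP alignment, concatenated-scan ORF finding via Biopython translation,
exhaustive hypergeometric enumeration, the literal BH step-up formula and
all-pairs interval scanning.
"""

from __future__ import annotations

from math import comb

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Smith-Waterman score; a gap of length k costs gap_open + k*gap_extend."""
    n, m = len(a), len(b)
    neg = -1e18
    h = np.zeros((n + 1, m + 1))
    e = np.full((n + 1, m + 1), neg)
    f = np.full((n + 1, m + 1), neg)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i, j] = max(h[i, j - 1] - (gap_open + gap_extend), e[i, j - 1] - gap_extend)
            f[i, j] = max(h[i - 1, j] - (gap_open + gap_extend), f[i - 1, j] - gap_extend)
            diag = h[i - 1, j - 1] + _BLOSUM62[a[i - 1], b[j - 1]]
            h[i, j] = max(0.0, diag, e[i, j], f[i, j])
            best = max(best, h[i, j])
    return best


def circ_orfs_brute(seq: str, min_aa: int = 1, cycle_cap: int = 3) -> dict[int, tuple[str, bool]]:
    """start -> (protein, rolling) via translation of the concatenated string."""
    L = len(seq)
    ext = seq * (cycle_cap + 1)
    out: dict[int, tuple[str, bool]] = {}
    for start in range(L):
        if ext[start : start + 3] != "ATG":
            continue
        max_nt = cycle_cap * L
        region = ext[start : start + max_nt - (max_nt % 3)]
        prot = str(Seq(region).translate(to_stop=True))
        stopped = len(prot) * 3 < len(region)
        if len(prot) >= min_aa:
            out[start] = (prot, not stopped)
    return out


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive two-sided Fisher p over all tables with the same margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k: int) -> float:
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


def bh_stepup(pvals: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up definition."""
    pvals = np.asarray(pvals, dtype=float)
    n = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, pvals[idx] * n / rank_from_top)
        adj[idx] = running
    return adj


def intervals_overlap_brute(circ: dict, peaks: list) -> dict[str, bool]:
    """All-pairs half-open interval intersection."""
    def norm(c: str) -> str:
        return c[3:] if c.lower().startswith("chr") else c

    flags = {}
    for cid, iv in circ.items():
        flags[cid] = any(
            norm(iv.chrom) == norm(p.chrom) and iv.start < p.end and p.start < iv.end
            for p in peaks
        )
    return flags


def substring_matches_brute(extensions: dict[str, str], db: dict[str, str]) -> set[tuple[str, str]]:
    """Naive O(n*m) containment scan, either direction."""
    out = set()
    for eid, ext in extensions.items():
        if not ext:
            continue
        for did, pep in db.items():
            if pep and (pep in ext or ext in pep):
                out.add((eid, did))
    return out


def domain_class_brute(c: list[str], p: list[str]) -> str:
    """Set/subsequence definition of the six pairwise domain classes."""
    from collections import Counter

    def subseq(s, t):
        it = iter(t)
        return all(x in it for x in s)

    if c == p:
        return "conservedStructure"
    if Counter(c) == Counter(p):
        return "differentOrder"
    if subseq(p, c):
        return "extraDomain"
    if subseq(c, p):
        return "lackingDomain"
    if set(c) & set(p):
        return "lackingPlusExtra"
    return "novelDomainStructure"


def quantile_normalize_brute(values: np.ndarray) -> np.ndarray:
    """Rank-mean quantile normalization with average-tie interpolation."""
    from scipy.stats import rankdata

    ref = np.mean(np.sort(values, axis=0), axis=1)
    out = np.empty_like(values, dtype=float)
    grid = np.arange(1, values.shape[0] + 1, dtype=float)
    for j in range(values.shape[1]):
        out[:, j] = np.interp(rankdata(values[:, j]), grid, ref)
    return out
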