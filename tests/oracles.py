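"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: per-base boolean arrays, exhaustive
loops, exact combinatorics via integer arithmetic. These must stay independent
of the code paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd


def per_base_mask(intervals: pd.DataFrame, chrom: str, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for r in intervals.itertuples(index=False):
        if r.chrom == chrom:
            mask[max(0, r.start): min(length, r.end)] = True
    return mask


def brute_merge(intervals: pd.DataFrame, chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Transitive-overlap closure by exhaustive pairwise fixed point.

    Two intervals join a component iff they share >=1 base; bookended
    intervals stay separate.
    """
    rows = []
    for chrom in sorted(chrom_lengths):
        items = [
            [r.start, r.end]
            for r in intervals.itertuples(index=False) if r.chrom == chrom
        ]
        changed = True
        while changed:
            changed = False
            for i in range(len(items)):
                j = i + 1
                while j < len(items):
                    a, b = items[i], items[j]
                    if a[0] < b[1] and b[0] < a[1]:  # >=1 shared base
                        a[0], a[1] = min(a[0], b[0]), max(a[1], b[1])
                        items.pop(j)
                        changed = True
                    else:
                        j += 1
        for s, e in sorted(items):
            rows.append({"chrom": chrom, "start": int(s), "end": int(e)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def brute_overlaps_any(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    out = np.zeros(len(query), dtype=bool)
    for i, q in enumerate(query.itertuples(index=False)):
        for t in targets.itertuples(index=False):
            if q.chrom == t.chrom and q.start < t.end and t.start < q.end:
                out[i] = True
                break
    return out


def brute_count_overlaps(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    counts = np.zeros(len(targets), dtype=int)
    for j, t in enumerate(targets.itertuples(index=False)):
        for q in query.itertuples(index=False):
            if q.chrom == t.chrom and q.start < t.end and t.start < q.end:
                counts[j] += 1
    return counts


def brute_nearest_tss(peak, genes, max_dist=10_000):
    """Exhaustive min over all TSS; tie to smaller gene_id."""
    chrom, start, end = peak
    mid = (start + end) // 2
    cands = sorted(
        (abs(g.tss - mid), g.gene_id) for g in genes if g.chrom == chrom
    )
    if not cands or cands[0][0] >= max_dist:
        return None, None
    return cands[0][1], cands[0][0]


def hypergeom_sf_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) for hypergeometric(N, K, n) by exact summation."""
    total = comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        acc += comb(K, x) * comb(N - K, n - x)
    return Fraction(acc, total)


def brute_scan(sequence: str, matrix: np.ndarray, background: np.ndarray,
               threshold: float) -> list[tuple[int, str]]:
    """Position-by-position log-odds scan on both strands."""
    comp = str.maketrans("ACGT", "TGCA")
    L = matrix.shape[0]
    seq = sequence.upper()

    def score(word: str) -> float:
        s = 0.0
        for j, b in enumerate(word):
            if b == "N":
                continue
            bi = "ACGT".index(b)
            p = matrix[j, bi]
            s += np.log2(p / background[bi]) if p > 0 else -np.inf
        return s

    hits = []
    for pos in range(len(seq) - L + 1):
        w = seq[pos: pos + L]
        if score(w) >= threshold:
            hits.append((pos, "+"))
        if score(w.translate(comp)[::-1]) >= threshold:
            hits.append((pos, "-"))
    return sorted(hits)


def bh_stepup(pvals: list[float]) -> list[float]:
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj
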