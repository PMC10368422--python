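"""Shared interval arithmetic on 0-based half-open intervals.

Interval sets are pandas DataFrames with at least ``chrom``, ``start`` and
``end`` columns. The routines here are the single interval engine behind FRiP,
peak merging and atlas counting; they assume nothing about peak overlap unless
stated, and are exercised against per-base brute-force oracles in the tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INTERVAL_COLS = ["chrom", "start", "end"]


def as_intervals(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in INTERVAL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"interval frame missing columns {missing}")
    return df


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Connected-overlap closure (transitive union) of a set of intervals.

    Returns non-overlapping intervals sorted by (chrom, start). Bookended
    intervals ([0,10) and [10,20)) share no base and are NOT merged.
    """
    as_intervals(df)
    if len(df) == 0:
        return pd.DataFrame(columns=INTERVAL_COLS).astype(
            {"chrom": str, "start": int, "end": int}
        )
    out_chrom: list[str] = []
    out_start: list[int] = []
    out_end: list[int] = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = np.asarray(sub["start"], dtype=np.int64)
        ends = np.asarray(sub["end"], dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s < cur_e:  # ≥1 bp shared under half-open semantics
                cur_e = max(cur_e, e)
            else:
                out_chrom.append(chrom)
                out_start.append(int(cur_s))
                out_end.append(int(cur_e))
                cur_s, cur_e = s, e
        out_chrom.append(chrom)
        out_start.append(int(cur_s))
        out_end.append(int(cur_e))
    return pd.DataFrame({"chrom": out_chrom, "start": out_start, "end": out_end})


def _per_chrom_arrays(merged: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """chrom -> (starts, ends, global row indices) for a merged, sorted frame."""
    out = {}
    for chrom, sub in merged.groupby("chrom", sort=False):
        out[chrom] = (
            np.asarray(sub["start"], dtype=np.int64),
            np.asarray(sub["end"], dtype=np.int64),
            np.asarray(sub.index, dtype=np.int64),
        )
    return out


def overlaps_any(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: does it overlap (≥1 bp) any target interval?

    Targets may overlap each other; they are merged internally first.
    """
    as_intervals(query)
    merged = merge_intervals(targets).reset_index(drop=True)
    lookup = _per_chrom_arrays(merged)
    hit = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(merged) == 0:
        return hit
    for chrom, sub in query.groupby("chrom", sort=False):
        if chrom not in lookup:
            continue
        t_starts, t_ends, _ = lookup[chrom]
        q_starts = np.asarray(sub["start"], dtype=np.int64)
        q_ends = np.asarray(sub["end"], dtype=np.int64)
        # target i overlaps [s,e) iff t_start[i] < e and t_end[i] > s;
        # with sorted non-overlapping targets both bounds are searchsorted.
        hi = np.searchsorted(t_starts, q_ends, side="left")
        lo = np.searchsorted(t_ends, q_starts, side="right")
        hit[np.asarray(sub.index)] = lo < hi
    return hit


def count_overlaps(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Per TARGET interval, the number of query intervals overlapping it ≥1 bp.

    Targets must be non-overlapping and sorted (an atlas); each query interval
    spanning several targets increments every one it touches.
    """
    as_intervals(query)
    as_intervals(targets)
    counts = np.zeros(len(targets), dtype=np.int64)
    if len(query) == 0 or len(targets) == 0:
        return counts
    targets = targets.reset_index(drop=True)
    lookup = _per_chrom_arrays(targets)
    for chrom, sub in query.groupby("chrom", sort=False):
        if chrom not in lookup:
            continue
        t_starts, t_ends, t_idx = lookup[chrom]
        q_starts = np.asarray(sub["start"], dtype=np.int64)
        q_ends = np.asarray(sub["end"], dtype=np.int64)
        hi = np.searchsorted(t_starts, q_ends, side="left")
        lo = np.searchsorted(t_ends, q_starts, side="right")
        ok = lo < hi  # queries overlapping at least one target
        lo, hi = lo[ok], hi[ok]
        # difference-array trick: +1 over [lo, hi) per query, then cumsum
        delta = np.zeros(len(t_starts) + 1, dtype=np.int64)
        np.add.at(delta, lo, 1)
        np.add.at(delta, hi, -1)
        counts[t_idx] += np.cumsum(delta[:-1])
    return counts
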