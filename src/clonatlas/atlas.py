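"""Merged peak atlas and normalized accessibility matrix.

The atlas is the transitive union of all passing samples' peak calls: any two
peaks sharing >=1 bp fall into one atlas peak, closure taken over chains. For
each atlas peak and sample, the raw count is the number of that sample's
fragments overlapping the peak; the per-sample fragment rate (count / total
mapped fragments) is then normalized by the average rate of that peak over all
samples, so every retained peak's normalized row has mean exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._intervals import count_overlaps, merge_intervals

logger = logging.getLogger(__name__)


@dataclass
class PeakAtlas:
    """Atlas peaks (non-overlapping, sorted, stable ids) with count matrices.

    ``normalized`` rows index retained atlas peaks; peaks whose cross-sample
    mean rate is zero are dropped from ``normalized`` (policy "drop").
    """

    peaks: pd.DataFrame           # chrom, start, end, peak_id
    raw_counts: pd.DataFrame      # peak_id x sample_id
    sample_totals: pd.Series      # sample_id -> total fragments
    normalized: pd.DataFrame      # retained peak_id x sample_id


def merge_peaks(peak_sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge per-sample peak calls into atlas intervals with stable ids."""
    if not peak_sets or all(len(p) == 0 for p in peak_sets.values()):
        logger.warning("merge_peaks: no input peaks; atlas is empty")
        return pd.DataFrame(columns=["chrom", "start", "end", "peak_id"])
    stacked = pd.concat(
        [p[["chrom", "start", "end"]] for p in peak_sets.values() if len(p)],
        ignore_index=True,
    )
    merged = merge_intervals(stacked).reset_index(drop=True)
    merged["peak_id"] = [f"peak_{i:06d}" for i in range(len(merged))]
    return merged


def count_matrix(
    atlas: pd.DataFrame,
    fragments: dict[str, pd.DataFrame],
    chrom_names: set[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Raw peak x sample fragment-overlap counts plus per-sample totals.

    Totals count ALL mapped fragments, not only in-atlas ones. A fragment
    spanning the gap between two atlas peaks increments both rows.
    """
    counts = {}
    totals = {}
    for sample_id, frags in fragments.items():
        if chrom_names is not None:
            unknown = set(frags["chrom"].unique()) - chrom_names
            if unknown:
                raise ValueError(
                    f"sample {sample_id}: fragments on unknown chromosome(s) "
                    f"{sorted(unknown)}"
                )
        counts[sample_id] = count_overlaps(frags, atlas)
        totals[sample_id] = int(len(frags))
    raw = pd.DataFrame(counts, index=atlas["peak_id"] if len(atlas) else None)
    return raw, pd.Series(totals, name="total_fragments")


def normalize(
    raw_counts: pd.DataFrame,
    sample_totals: pd.Series,
    zero_row_policy: str = "drop",
) -> pd.DataFrame:
    """Relative accessibility: per-sample rate divided by its all-sample mean.

    normalized[i, j] = (raw[i, j] / total[j]) / mean_j'(raw[i, j'] / total[j'])
    """
    if (sample_totals <= 0).any():
        bad = sample_totals[sample_totals <= 0].index.tolist()
        raise ValueError(f"sample totals must be positive (failed QC upstream): {bad}")
    if zero_row_policy != "drop":
        raise ValueError(f"unknown zero_row_policy {zero_row_policy!r}")
    rates = raw_counts.div(sample_totals.loc[raw_counts.columns], axis=1)
    row_means = rates.mean(axis=1)
    zero = row_means == 0
    if zero.any():
        logger.info("normalize: dropping %d all-zero atlas rows", int(zero.sum()))
    rates = rates.loc[~zero]
    return rates.div(row_means.loc[~zero], axis=0)


def build_atlas(
    peak_sets: dict[str, pd.DataFrame],
    fragments: dict[str, pd.DataFrame],
    chrom_names: set[str] | None = None,
) -> PeakAtlas:
    """One-call construction: merge, count, normalize."""
    if set(peak_sets) != set(fragments):
        raise ValueError("peak_sets and fragments must cover the same samples")
    peaks = merge_peaks(peak_sets)
    raw, totals = count_matrix(peaks, fragments, chrom_names=chrom_names)
    norm = normalize(raw, totals)
    return PeakAtlas(peaks=peaks, raw_counts=raw, sample_totals=totals, normalized=norm)
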