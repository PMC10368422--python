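"""Cross-dataset regulatory comparison.

Two analyses: (1) motif-landscape comparison between this atlas's OCR
clusters and a foreign collection of region-specific OCR sets — shared-motif
counting plus density profiles of the atlas's top motifs around the foreign
peaks; (2) expression-bias analysis of a gene set across a foreign
region x gene expression atlas, normalized per region to the mean over ALL
genes so in-situ intensity differences between regions cancel.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .motifs import MotifPWM, density_profile, share_matrix

logger = logging.getLogger(__name__)


def normalize_atlas(expr: pd.DataFrame) -> pd.DataFrame:
    """Divide each region (column) by its mean over all genes.

    After normalization every region's all-gene mean is exactly 1.
    """
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression atlas has negative values")
    col_means = expr.mean(axis=0)
    zero = col_means[col_means == 0]
    if len(zero):
        raise ValueError(f"region(s) with all-zero expression: {list(zero.index)}")
    return expr.div(col_means, axis=1)


def region_bias(gene_set: set[str], normalized: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-region mean relative expression of a gene set, plus a bias score.

    The bias score is max region mean / median region mean; a set with no
    regional preference scores ~1. Genes absent from the atlas are dropped
    (logged); an empty intersection is an error.
    """
    present = sorted(gene_set & set(normalized.index))
    dropped = len(gene_set) - len(present)
    if not present:
        raise ValueError("gene set has no overlap with the expression atlas")
    if dropped:
        logger.info("region_bias: %d gene(s) not in the atlas dropped", dropped)
    means = normalized.loc[present].mean(axis=0)
    score = float(means.max() / means.median())
    return means, score


def apply_ortholog_map(gene_set: set[str], mapping: pd.DataFrame) -> set[str]:
    """Translate gene ids through a 2-column (own_id, foreign_id) table.

    Rows where several own genes map to one foreign gene are dropped entirely,
    so the mapping used is 1:1.
    """
    own_col, foreign_col = mapping.columns[:2]
    counts = mapping.groupby(foreign_col)[own_col].nunique()
    unique_foreign = set(counts.index[counts == 1])
    usable = mapping[mapping[foreign_col].isin(unique_foreign)]
    return set(usable.loc[usable[own_col].isin(gene_set), foreign_col])


def compare_motif_landscapes(
    own_motif_sets: dict[str, set[str]],
    foreign_motif_sets: dict[str, set[str]],
    own_top_motifs: list[MotifPWM],
    foreign_peaks: dict[str, pd.DataFrame],
    foreign_sequence: dict[str, str],
    window: int = 2000,
    bin_size: int = 20,
) -> tuple[pd.DataFrame, dict[tuple[str, str], pd.Series]]:
    """Shared-motif counts plus per-(motif, foreign region) density profiles."""
    shares = share_matrix(own_motif_sets, foreign_motif_sets)
    profiles: dict[tuple[str, str], pd.Series] = {}
    for region, peaks in foreign_peaks.items():
        if len(peaks) == 0:
            raise ValueError(f"foreign region {region!r} has an empty peak set")
        for m in own_top_motifs:
            profiles[(m.name, region)] = density_profile(
                peaks, m, foreign_sequence, window=window, bin_size=bin_size
            )
    return shares, profiles
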