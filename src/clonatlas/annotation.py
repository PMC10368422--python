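"""Peak-to-gene assignment and genomic-context classification.

Each atlas peak is assigned the gene with the nearest transcription start site
(TSS), measured from the peak midpoint, provided the distance is strictly less
than ``max_dist`` (default 10 kb). Context labels (promoter / exon / intron /
intergenic) are decided at the peak midpoint with precedence
promoter > exon > intron > intergenic; the promoter is a strand-aware window
upstream of the TSS (default 1 kb) plus the TSS base itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .clustering import OCRClusterAssignment

logger = logging.getLogger(__name__)

MAX_TSS_DIST = 10_000
PROMOTER_WINDOW = 1_000
CONTEXTS = ["promoter", "exon", "intron", "intergenic"]


@dataclass
class PeakAnnotation:
    peak_id: str
    target_gene: str | None
    tss_distance: int | None  # unsigned bp from peak midpoint; None if no gene in range
    context: str


def _midpoint(start: int, end: int) -> int:
    return (start + end) // 2


def assign_target(
    peak: tuple[str, int, int],
    genome: GenomeModel,
    max_dist: int = MAX_TSS_DIST,
) -> tuple[str | None, int | None]:
    """Nearest-TSS target for one peak; strict 'distance < max_dist' rule.

    Ties between equidistant TSS are broken toward the lexicographically
    smaller gene_id. Genes on other chromosomes are never considered.
    Returns (gene_id or None, unsigned distance or None).
    """
    chrom, start, end = peak
    mid = _midpoint(start, end)
    best: tuple[int, str] | None = None
    for g in genome.genes_on(chrom):
        d = abs(g.tss - mid)
        cand = (d, g.gene_id)
        if best is None or cand < best:
            best = cand
    if best is None or best[0] >= max_dist:
        return None, None
    return best[1], best[0]


def classify_context(
    peak: tuple[str, int, int],
    genome: GenomeModel,
    promoter_window: int = PROMOTER_WINDOW,
) -> str:
    """Genomic context of the peak midpoint.

    Precedence over all genes on the chromosome: promoter beats exon beats
    intron beats intergenic. Genes without exon structure are treated as a
    single exon spanning the gene body.
    """
    chrom, start, end = peak
    mid = _midpoint(start, end)
    best = "intergenic"
    rank = {c: i for i, c in enumerate(CONTEXTS)}
    for g in genome.genes_on(chrom):
        if g.strand == "+":
            prom_lo, prom_hi = g.tss - promoter_window, g.tss + 1
        else:
            prom_lo, prom_hi = g.tss, g.tss + promoter_window + 1
        label = None
        if prom_lo <= mid < prom_hi:
            label = "promoter"
        elif g.start <= mid < g.end:
            exons = g.exons or ((g.start, g.end),)
            label = "exon" if any(es <= mid < ee for es, ee in exons) else "intron"
        if label is not None and rank[label] < rank[best]:
            best = label
    return best


def annotate_peaks(
    atlas_peaks: pd.DataFrame,
    genome: GenomeModel,
    max_dist: int = MAX_TSS_DIST,
    promoter_window: int = PROMOTER_WINDOW,
) -> list[PeakAnnotation]:
    """Annotate every atlas peak; vectorized nearest-TSS via sorted search.

    Matches assign_target exactly (the per-peak form is kept as the reference
    path and for single peaks).
    """
    # per-chromosome TSS arrays sorted by (position, gene_id) so the
    # lexicographic tie-break falls out of taking the first minimum
    per_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in {g.chrom for g in genome.genes}:
        entries = sorted((g.tss, g.gene_id) for g in genome.genes_on(chrom))
        per_chrom[chrom] = (np.array([t for t, _ in entries], dtype=np.int64),
                            [gid for _, gid in entries])
    out: list[PeakAnnotation] = []
    for row in atlas_peaks.itertuples(index=False):
        chrom, start, end, peak_id = row.chrom, row.start, row.end, row.peak_id
        mid = _midpoint(start, end)
        gene, dist = None, None
        if chrom in per_chrom:
            tss, gids = per_chrom[chrom]
            i = int(np.searchsorted(tss, mid))
            # candidates: nearest on each side, expanded over equal positions
            cand: list[tuple[int, str]] = []
            for j in (i - 1, i):
                if 0 <= j < len(tss):
                    d = abs(int(tss[j]) - mid)
                    k = j
                    while 0 <= k < len(tss) and abs(int(tss[k]) - mid) == d:
                        cand.append((d, gids[k]))
                        k += 1 if j == i else -1
            if cand:
                d, gid = min(cand)
                if d < max_dist:
                    gene, dist = gid, d
        ctx = classify_context((chrom, start, end), genome, promoter_window)
        out.append(PeakAnnotation(peak_id, gene, dist, ctx))
    return out


def annotation_table(annotations: list[PeakAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": [a.peak_id for a in annotations],
            "target_gene": [a.target_gene or "" for a in annotations],
            "tss_distance": [a.tss_distance if a.tss_distance is not None else -1
                             for a in annotations],
            "context": [a.context for a in annotations],
        }
    )


def cluster_context_profile(
    annotations: list[PeakAnnotation],
    assignment: OCRClusterAssignment,
) -> pd.DataFrame:
    """Per OCR cluster, the fraction of peaks in each genomic context.

    Rows sum to 1; an empty cluster yields a zero row (with a warning).
    """
    by_peak = {a.peak_id: a.context for a in annotations}
    rows = {}
    for c in range(1, assignment.k + 1):
        peaks = assignment.peaks_in(c)
        counts = pd.Series(0.0, index=CONTEXTS)
        for p in peaks:
            counts[by_peak[p]] += 1
        if not peaks:
            logger.warning("cluster %d is empty; context profile is all-zero", c)
            rows[c] = counts
        else:
            rows[c] = counts / len(peaks)
    return pd.DataFrame(rows).T.rename_axis("ocr_cluster")
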