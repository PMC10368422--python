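"""Intersection of OCR-cluster target genes with differential expression.

A gene is "actively regulated" in a region when it is both preferentially
expressed there (a significant DE call) and the nearest-TSS target of at
least one peak in that region's specific OCR cluster(s). The report gives the
fraction of a gene universe (the preferential set, optionally restricted to a
category list such as synaptic genes) covered by the cluster targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation import PeakAnnotation
from .clustering import OCRClusterAssignment


@dataclass
class ActiveRegulationReport:
    direction: str                      # "up" or "down"
    clusters: tuple[int, ...]
    universe: frozenset[str]
    targeted: frozenset[str]
    fraction: float | None = field(init=False)  # None when universe is empty

    def __post_init__(self) -> None:
        if not self.targeted <= self.universe:
            raise ValueError("targeted genes must be a subset of the universe")
        self.fraction = (
            len(self.targeted) / len(self.universe) if self.universe else None
        )


def cluster_targets(
    annotations: list[PeakAnnotation],
    assignment: OCRClusterAssignment,
    clusters: set[int],
) -> set[str]:
    """Union of nearest-TSS target genes over the peaks of the given clusters."""
    unknown = clusters - set(range(1, assignment.k + 1))
    if unknown:
        raise ValueError(f"unknown cluster id(s) {sorted(unknown)}")
    wanted = {
        pid for c in clusters for pid in assignment.peaks_in(c)
    }
    return {
        a.target_gene
        for a in annotations
        if a.peak_id in wanted and a.target_gene is not None
    }


def active_regulation(
    preferential: set[str],
    category: set[str] | None,
    targets: set[str],
    direction: str,
    clusters: tuple[int, ...] = (),
) -> ActiveRegulationReport:
    """Fraction of the (optionally category-restricted) preferential genes
    that are cluster targets."""
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    universe = preferential & category if category is not None else set(preferential)
    return ActiveRegulationReport(
        direction=direction,
        clusters=tuple(clusters),
        universe=frozenset(universe),
        targeted=frozenset(universe & targets),
    )
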