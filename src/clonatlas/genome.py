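"""Genome model: chromosomes, gene models with strand-aware TSS, optional sequence.

All coordinates are 0-based half-open (BED convention). The TSS of a gene on the
``+`` strand is its start coordinate; on the ``-`` strand it is ``end - 1`` (the
last base of the interval, i.e. the 5' end of the transcript).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Gene:
    """A gene model. ``exons`` is an optional list of (start, end) intervals;
    when absent the gene body is treated as a single exon."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid gene interval [{self.start}, {self.end})")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GenomeModel:
    """Chromosome sizes, gene models, and (optionally) nucleotide sequence.

    Ground for every interval operation in the pipeline.
    """

    chromosomes: list[tuple[str, int]]
    genes: list[Gene] = field(default_factory=list)
    sequence: dict[str, str] | None = None

    def __post_init__(self) -> None:
        sizes = self.chrom_sizes
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chrom not in sizes:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom!r}")
            if g.end > sizes[g.chrom]:
                raise ValueError(
                    f"gene {g.gene_id} exceeds chromosome {g.chrom} bounds"
                )
        if self.sequence is not None:
            for name, length in self.chromosomes:
                if name in self.sequence and len(self.sequence[name]) != length:
                    raise ValueError(
                        f"sequence length for {name} does not match declared size"
                    )

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]
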