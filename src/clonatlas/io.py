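"""Readers and writers for the pipeline's on-disk formats.

BED6 fragments, narrowPeak peak calls, chrom.sizes, GFF3 gene models (via
gffutils), FASTA (via Biopython), gene x sample count TSVs, and GMT gene-set
files. All interval files are 0-based half-open as in the BED standard.
"""

from __future__ import annotations

import os
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Gene, GenomeModel

NARROWPEAK_COLS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signalValue", "pValue", "qValue", "peak",
]
BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED3+ file; returns at least chrom/start/end."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6_COLS[: df.shape[1]] + list(df.columns[len(BED6_COLS):])
    return df


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in BED6_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = NARROWPEAK_COLS[: df.shape[1]]
    return df


def write_narrowpeak(df: pd.DataFrame, path: str | os.PathLike) -> None:
    out = df.copy()
    for col, default in [
        ("name", "."), ("score", 0), ("strand", "."),
        ("signalValue", 0.0), ("pValue", -1.0), ("qValue", -1.0), ("peak", -1),
    ]:
        if col not in out.columns:
            out[col] = default
    out[NARROWPEAK_COLS].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str | os.PathLike) -> list[tuple[str, int]]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return list(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(chromosomes: Iterable[tuple[str, int]], path) -> None:
    with open(path, "w") as fh:
        for name, size in chromosomes:
            fh.write(f"{name}\t{size}\n")


def write_fasta(sequence: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequence.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genome: GenomeModel, path: str | os.PathLike) -> None:
    """Write gene (+ optional exon) features, converting to 1-based closed GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, size in genome.chromosomes:
            fh.write(f"##sequence-region {name} 1 {size}\n")
        for g in genome.genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tclonatlas\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, (es, ee) in enumerate(g.exons or ()):
                fh.write(
                    f"{g.chrom}\tclonatlas\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}\n"
                )


def read_gff3(path: str | os.PathLike, chromosomes: list[tuple[str, int]] | None = None) -> GenomeModel:
    """Load gene models from GFF3 (gene + exon features) into a GenomeModel.

    If chromosome sizes are not given they are taken from ##sequence-region
    pragmas, falling back to the max feature end per chromosome.
    """
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes: list[Gene] = []
    max_end: dict[str, int] = {}
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = tuple(
            (e.start - 1, e.end) for e in db.children(feat, featuretype="exon", order_by="start")
        )
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            Gene(gene_id=gid, chrom=feat.seqid, strand=feat.strand,
                 start=feat.start - 1, end=feat.end, exons=exons or None)
        )
        max_end[feat.seqid] = max(max_end.get(feat.seqid, 0), feat.end)
    if chromosomes is None:
        chromosomes = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, name, _start, end = line.split()
                    chromosomes.append((name, int(end)))
        if not chromosomes:
            chromosomes = sorted(max_end.items())
    return GenomeModel(chromosomes=chromosomes, genes=genes)


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Gene x sample count matrix TSV; first column = gene ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t")


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """GMT: one term per line — name, description, then member gene ids."""
    terms: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            terms[parts[0]] = [g for g in parts[2:] if g]
    return terms


def write_gmt(terms: dict[str, list[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, members in terms.items():
            fh.write("\t".join([name, name] + list(members)) + "\n")
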