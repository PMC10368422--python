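"""Synthetic cohort generator with known ground truth.

Emulates the data structure of a regional clonal-unit ATAC-seq study: ~65
accepted samples spread over ~10 brain-region labels (pallial and
subpallial), region-specific open-chromatin clusters, one "distinct" region
whose private clusters are closed everywhere else (and which lacks the other
regions' specific clusters), variable sequencing depth including planted
sub-threshold samples, planted cluster-specific motifs, and matched
3-condition RNA-seq counts with planted up/down genes. Every planted
structure is recorded in a TruthRecord that round-trips through JSON, so each
downstream stage can be tested against ground truth without any download.

All intervals are 0-based half-open. Fragments are fixed-length (default
200 bp, echoing the fragment-extension size used when peaks are called on
real data). Fragment placement: with probability ``frip_target`` a fragment
falls entirely inside one of the sample's own (jittered) peaks, otherwise it
is uniform over the genome — so realized FRiP concentrates slightly above
``frip_target`` (background fragments can also land in peaks).
"""

from __future__ import annotations

import json
import logging
import warnings
from bisect import bisect_left, insort
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Gene, GenomeModel
from .motifs import MotifPWM

logger = logging.getLogger(__name__)

FRAGMENT_LENGTH = 200
PEAK_WIDTH = 500
PEAK_MIN_GAP = 400       # keeps jittered neighbours from merging in the atlas
JITTER_SD = 20.0
PEAK_DROP_PROB = 0.05

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class RegionSpec:
    """One region label: how many samples it contributes and its gross
    anatomical class (pallium-like or subpallium-like)."""

    name: str
    n_samples: int
    group: str = "pallium"


@dataclass
class Cohort:
    genome: GenomeModel
    fragments: dict[str, pd.DataFrame]   # sample_id -> BED-like frame
    peaks: dict[str, pd.DataFrame]       # sample_id -> narrowPeak-like frame
    metadata: pd.DataFrame               # sample_id, region, group, total_fragments

    @property
    def sample_ids(self) -> list[str]:
        return list(self.metadata["sample_id"])


@dataclass
class TruthRecord:
    """Ground truth of everything the generator planted."""

    sample_region: dict[str, str] = field(default_factory=dict)
    truth_peaks: list[dict] = field(default_factory=list)  # peak_id/chrom/start/end/cluster
    cluster_region_map: dict[str, list[int]] = field(default_factory=dict)
    distinct_region: str | None = None
    qc_fail_samples: dict[str, str] = field(default_factory=dict)  # sample -> mode
    qc_thresholds: dict[str, float] = field(default_factory=dict)
    frip_target: float | None = None
    de_genes: dict[str, list] = field(default_factory=dict)  # contrast -> [[gene, lfc]]
    motif_plants: dict[str, dict] = field(default_factory=dict)
    term_enrichments: dict[str, list[str]] = field(default_factory=dict)

    def peak_cluster(self) -> dict[str, int]:
        return {p["peak_id"]: p["cluster"] for p in self.truth_peaks}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, length)].tobytes().decode()


def generate_genome(
    n_chrom: int,
    chrom_length: int,
    n_genes: int,
    seed: int,
    gene_length_range: tuple[int, int] = (1_000, 3_000),
    with_sequence: bool = True,
    exon_prob: float = 0.6,
) -> GenomeModel:
    """Random genome: uniform non-overlapping genes, i.i.d. uniform sequence.

    Genes are split as evenly as possible over chromosomes and placed without
    overlap by distributing the leftover space as random gaps; a density at
    which the requested genes cannot fit raises an explicit error. A fraction
    of genes receives a 3-exon structure (exon-intron-exon); the rest are
    single-exon.
    """
    if n_chrom <= 0 or chrom_length <= 0:
        raise ValueError("n_chrom and chrom_length must be positive")
    rng = np.random.default_rng(seed)
    chroms = [(f"chr{i + 1}", int(chrom_length)) for i in range(n_chrom)]
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0)
                 for i in range(n_chrom)]
    genes: list[Gene] = []
    gidx = 0
    for (cname, clen), n_here in zip(chroms, per_chrom):
        if n_here == 0:
            continue
        lengths = rng.integers(gene_length_range[0], gene_length_range[1] + 1, n_here)
        total = int(lengths.sum())
        if total > clen:
            raise ValueError(
                f"cannot place {n_here} genes totalling {total} bp on {cname} "
                f"({clen} bp); reduce n_genes or gene lengths"
            )
        gaps = np.sort(rng.integers(0, clen - total + 1, n_here))
        starts = gaps + np.concatenate([[0], np.cumsum(lengths[:-1])])
        strands = rng.choice(["+", "-"], n_here)
        multi = rng.random(n_here) < exon_prob
        for s, ln, st, mx in zip(starts, lengths, strands, multi):
            s, e = int(s), int(s + ln)
            exons = None
            if mx and ln >= 600:
                cut1 = s + int(ln * 0.25)
                cut2 = s + int(ln * 0.75)
                exons = ((s, cut1), (cut2, e))
            genes.append(
                Gene(gene_id=f"gene_{gidx:05d}", chrom=cname, strand=str(st),
                     start=s, end=e, exons=exons)
            )
            gidx += 1
    sequence = (
        {name: _random_sequence(rng, length) for name, length in chroms}
        if with_sequence else None
    )
    return GenomeModel(chromosomes=chroms, genes=genes, sequence=sequence)


def make_cluster_region_map(
    regions: list[RegionSpec],
    n_clusters: int,
    distinct_region: str,
    n_private: int = 2,
) -> dict[str, list[int]]:
    """Region -> active OCR clusters with the emulated cohort's qualitative structure.

    Clusters 1..n_private are private to the distinct region; the last cluster
    is common to all regions; the remainder are assigned one per non-distinct
    region, then (when clusters outnumber regions) to widening windows of
    adjacent regions so that every non-private cluster has a unique activity
    pattern. The distinct region carries only its private clusters plus the
    common one, so every other region's specific clusters are closed in it
    and vice versa.
    """
    names = [r.name for r in regions]
    if distinct_region not in names:
        raise ValueError(f"distinct_region {distinct_region!r} not among regions")
    if n_clusters < n_private + 2:
        raise ValueError("need at least n_private + 2 clusters")
    private = list(range(1, n_private + 1))
    common = n_clusters
    specific = list(range(n_private + 1, n_clusters))
    others = [n for n in names if n != distinct_region]
    m = len(others)
    cmap: dict[str, list[int]] = {distinct_region: private + [common]}
    for n in others:
        cmap[n] = [common]
    for i, c in enumerate(specific):
        span = i // m + 1
        if span > m:
            raise ValueError("too many clusters for distinct activity patterns")
        for t in range(span):
            cmap[others[(i + t) % m]].append(c)
    return {n: sorted(cs) for n, cs in cmap.items()}


def default_regions(seed_sizes: int = 6) -> list[RegionSpec]:
    """Ten region labels (7 pallial incl. the distinct Dd2-like one, 3
    subpallial), ~6-7 samples each — a study-scale cohort shape."""
    pall = ["Dd2", "Dd1", "Dm", "Dl", "Dc", "Dp", "Dd3"]
    subp = ["Vv", "Vd", "Vs"]
    return [RegionSpec(n, seed_sizes + (1 if i < 3 else 0), "pallium")
            for i, n in enumerate(pall)] + [
        RegionSpec(n, seed_sizes, "subpallium") for n in subp
    ]


def _place_truth_peaks(
    rng: np.random.Generator,
    genome: GenomeModel,
    n_peaks: int,
    peak_width: int,
    tss_anchor_frac: float,
    anchor_max_dist: int = 8_000,
) -> pd.DataFrame:
    """Non-overlapping truth peaks, a fraction anchored near gene TSSs."""
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in genome.chromosomes}
    sizes = genome.chrom_sizes
    chrom_names = [c for c, _ in genome.chromosomes]
    chrom_p = np.array([sizes[c] for c in chrom_names], dtype=float)
    chrom_p /= chrom_p.sum()
    rows = []
    attempts_limit = 200
    for i in range(n_peaks):
        placed = False
        for _ in range(attempts_limit):
            if genome.genes and rng.random() < tss_anchor_frac:
                g = genome.genes[int(rng.integers(len(genome.genes)))]
                chrom = g.chrom
                center = g.tss + int(rng.integers(-anchor_max_dist, anchor_max_dist + 1))
            else:
                chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
                center = int(rng.integers(0, sizes[chrom]))
            s = center - peak_width // 2
            e = s + peak_width
            if s < 0 or e > sizes[chrom]:
                continue
            occ = occupied[chrom]
            j = bisect_left(occ, (s, e))
            if j > 0 and occ[j - 1][1] + PEAK_MIN_GAP > s:
                continue
            if j < len(occ) and e + PEAK_MIN_GAP > occ[j][0]:
                continue
            insort(occ, (s, e))
            rows.append({"peak_id": f"truth_{i:05d}", "chrom": chrom,
                         "start": s, "end": e})
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place truth peak {i} without overlap; genome too "
                f"small for {n_peaks} peaks of width {peak_width}"
            )
    return pd.DataFrame(rows)


def generate_cohort(
    genome: GenomeModel,
    regions: list[RegionSpec],
    n_clusters: int,
    cluster_region_map: dict[str, list[int]] | None,
    distinct_region: str,
    depth_range: tuple[int, int] = (60_000, 120_000),
    n_fail: int = 0,
    frip_target: float = 0.4,
    seed: int = 0,
    peaks_per_cluster: int = 40,
    peak_width: int = PEAK_WIDTH,
    fragment_length: int = FRAGMENT_LENGTH,
    qc_min_fragments: int = 50_000,
    qc_min_frip: float = 0.2,
    tss_anchor_frac: float = 0.5,
) -> tuple[Cohort, TruthRecord]:
    """Generate a full ATAC cohort plus its ground truth.

    Truth peaks are partitioned into ``n_clusters`` OCR clusters; a sample's
    peak calls are the peaks of the clusters active in its region, each
    re-centered by N(0, 20 bp) and dropped with probability 0.05. ``n_fail``
    randomly chosen samples are planted to fail QC, alternating between
    sub-threshold depth and sub-threshold FRiP.
    """
    names = [r.name for r in regions]
    if distinct_region not in names:
        raise ValueError(f"distinct_region {distinct_region!r} not among regions")
    total_samples = sum(r.n_samples for r in regions)
    if n_fail >= total_samples:
        raise ValueError(f"n_fail={n_fail} must be below total samples {total_samples}")
    if cluster_region_map is None:
        cluster_region_map = make_cluster_region_map(regions, n_clusters, distinct_region)
    covered = {c for cs in cluster_region_map.values() for c in cs}
    if covered != set(range(1, n_clusters + 1)):
        raise ValueError(
            f"cluster_region_map must cover clusters 1..{n_clusters}, got {sorted(covered)}"
        )

    rng = np.random.default_rng(seed)
    truth_peaks = _place_truth_peaks(
        rng, genome, n_clusters * peaks_per_cluster, peak_width, tss_anchor_frac
    )
    clusters = np.repeat(np.arange(1, n_clusters + 1), peaks_per_cluster)
    rng.shuffle(clusters)
    truth_peaks["cluster"] = clusters

    sizes = genome.chrom_sizes
    chrom_names = [c for c, _ in genome.chromosomes]
    chrom_p = np.array([sizes[c] for c in chrom_names], dtype=float)
    chrom_p /= chrom_p.sum()

    sample_rows = []
    all_ids = []
    for r in regions:
        for i in range(r.n_samples):
            sid = f"{r.name}_{i + 1:02d}"
            all_ids.append(sid)
            sample_rows.append((sid, r.name, r.group))
    fail_ids = list(rng.choice(all_ids, size=n_fail, replace=False)) if n_fail else []
    fail_mode = {sid: ("depth" if i % 2 == 0 else "frip")
                 for i, sid in enumerate(fail_ids)}

    fragments: dict[str, pd.DataFrame] = {}
    peaks: dict[str, pd.DataFrame] = {}
    meta_rows = []
    for sid, region, group in sample_rows:
        active = truth_peaks[truth_peaks["cluster"].isin(cluster_region_map[region])]
        keep = rng.random(len(active)) >= PEAK_DROP_PROB
        jitter = np.rint(rng.normal(0.0, JITTER_SD, len(active))).astype(int)
        samp = active.loc[keep].copy()
        jit = jitter[keep]
        samp["start"] = samp["start"] + jit
        samp["end"] = samp["end"] + jit
        samp["start"] = samp["start"].clip(lower=0)
        for c in samp["chrom"].unique():
            m = samp["chrom"] == c
            samp.loc[m, "end"] = samp.loc[m, "end"].clip(upper=sizes[c])
        samp = samp.sort_values(["chrom", "start"], ignore_index=True)

        mode = fail_mode.get(sid)
        depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
        sample_frip = frip_target
        if mode == "depth":
            depth = max(1, qc_min_fragments // 2)
        elif mode == "frip":
            sample_frip = qc_min_frip * 0.25
        in_peak = rng.random(depth) < sample_frip
        n_in = int(in_peak.sum())
        frag_chrom = np.empty(depth, dtype=object)
        frag_start = np.empty(depth, dtype=np.int64)
        if n_in and len(samp):
            pick = rng.integers(0, len(samp), n_in)
            ps = samp["start"].to_numpy()[pick]
            pe = samp["end"].to_numpy()[pick]
            span = np.maximum(pe - ps - fragment_length, 1)
            frag_start[in_peak] = ps + (rng.random(n_in) * span).astype(np.int64)
            frag_chrom[in_peak] = samp["chrom"].to_numpy()[pick]
        else:
            in_peak[:] = False
        n_bg = int((~in_peak).sum())
        bg_c = rng.choice(len(chrom_names), size=n_bg, p=chrom_p)
        bg_len = np.array([sizes[chrom_names[i]] for i in bg_c]) - fragment_length
        frag_start[~in_peak] = (rng.random(n_bg) * bg_len).astype(np.int64)
        frag_chrom[~in_peak] = [chrom_names[i] for i in bg_c]
        frags = pd.DataFrame(
            {"chrom": frag_chrom, "start": frag_start,
             "end": frag_start + fragment_length}
        ).sort_values(["chrom", "start"], ignore_index=True)

        fragments[sid] = frags
        peaks[sid] = samp[["chrom", "start", "end"]].assign(
            name=samp["peak_id"].to_numpy()
        )
        meta_rows.append({"sample_id": sid, "region": region, "group": group,
                          "total_fragments": depth})

    cohort = Cohort(
        genome=genome, fragments=fragments, peaks=peaks,
        metadata=pd.DataFrame(meta_rows),
    )
    truth = TruthRecord(
        sample_region={sid: reg for sid, reg, _ in sample_rows},
        truth_peaks=truth_peaks.to_dict(orient="records"),
        cluster_region_map={k: list(map(int, v)) for k, v in cluster_region_map.items()},
        distinct_region=distinct_region,
        qc_fail_samples=fail_mode,
        qc_thresholds={"min_fragments": qc_min_fragments, "min_frip": qc_min_frip},
        frip_target=frip_target,
    )
    return cohort, truth


def generate_expression(
    genome: GenomeModel,
    conditions: tuple[str, str, str] = ("Dd2", "D", "V"),
    n_de_per_contrast: int = 50,
    lfc: float = 2.0,
    dispersion: float = 0.05,
    depth: tuple[float, float] = (0.8, 1.2),
    n_reps: int = 2,
    seed: int = 0,
    de_genes: list[tuple[str, int]] | None = None,
    de_base_mean: float = 500.0,
    base_mean_log_sd: float = 1.0,
    truth: TruthRecord | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Negative-binomial count matrix with planted DE in condition 1 vs 2.

    Counts ~ NB with Var = mu + dispersion * mu^2; planted genes have their
    condition-1 mean multiplied by 2**(+/- lfc) and a baseline of
    ``de_base_mean``; library sizes are drawn uniformly from ``depth``. Pass
    ``de_genes`` as explicit (gene_id, sign) pairs to control which genes are
    planted (e.g. to couple them to OCR-cluster targets); otherwise
    ``n_de_per_contrast`` up and as many down genes are drawn at random.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if min(depth) <= 0:
        raise ValueError("library size factors must be positive")
    if n_reps < 2:
        raise ValueError("need at least 2 replicates per condition")
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genome.genes]
    n_genes = len(gene_ids)
    base = np.exp(rng.normal(np.log(200.0), base_mean_log_sd, n_genes))

    if de_genes is None:
        if lfc == 0 or n_de_per_contrast == 0:
            de_genes = []
        else:
            chosen = rng.choice(n_genes, size=min(2 * n_de_per_contrast, n_genes),
                                replace=False)
            de_genes = [(gene_ids[g], 1 if i < n_de_per_contrast else -1)
                        for i, g in enumerate(chosen)]
    idx = {g: i for i, g in enumerate(gene_ids)}
    for g, _sign in de_genes:
        if g not in idx:
            raise ValueError(f"planted DE gene {g!r} not in genome")
        base[idx[g]] = de_base_mean

    samples = [f"{c}_rep{r + 1}" for c in conditions for r in range(n_reps)]
    sf = rng.uniform(depth[0], depth[1], len(samples))
    mu = np.tile(base[:, None], (1, len(samples))) * sf[None, :]
    c1_cols = [j for j, s in enumerate(samples) if s.startswith(conditions[0] + "_")]
    for g, sign in de_genes:
        mu[idx[g], c1_cols] *= 2.0 ** (sign * lfc)
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    matrix = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                          columns=samples)
    truth = truth or TruthRecord()
    contrast = f"{conditions[0]}_vs_{conditions[1]}"
    truth.de_genes[contrast] = [[g, float(sign * lfc)] for g, sign in de_genes]
    return matrix, truth


def plant_motifs(
    genome: GenomeModel,
    truth_peaks: pd.DataFrame,
    pwm: MotifPWM,
    clusters: set[int],
    prob: float = 0.8,
    offset_sd: float = 0.0,
    seed: int = 0,
    truth: TruthRecord | None = None,
) -> tuple[GenomeModel, TruthRecord]:
    """Write the PWM consensus into selected clusters' peaks.

    Each peak of a target cluster receives, with probability ``prob``, one
    consensus instance at a Gaussian offset (sd ``offset_sd``) around its
    center. Non-target clusters are untouched; a motif that does not fit in a
    peak is skipped with a warning and recorded in the truth.
    """
    if genome.sequence is None:
        raise ValueError("genome has no sequence; regenerate with with_sequence=True")
    motif = pwm.consensus
    rng = np.random.default_rng(seed)
    seqs = {c: bytearray(s, "ascii") for c, s in genome.sequence.items()}
    plants: list[list] = []
    skipped: list[str] = []
    for row in truth_peaks.itertuples(index=False):
        if row.cluster not in clusters:
            continue
        if rng.random() >= prob:
            continue
        width = row.end - row.start
        if len(motif) > width:
            warnings.warn(
                f"motif {pwm.name} ({len(motif)} bp) longer than peak "
                f"{row.peak_id} ({width} bp); skipped"
            )
            skipped.append(row.peak_id)
            continue
        center = (row.start + row.end) // 2
        pos = center - len(motif) // 2 + int(round(rng.normal(0.0, offset_sd)))
        pos = max(row.start, min(pos, row.end - len(motif)))
        seqs[row.chrom][pos : pos + len(motif)] = motif.encode()
        plants.append([row.peak_id, int(pos)])
    mutated = GenomeModel(
        chromosomes=list(genome.chromosomes),
        genes=list(genome.genes),
        sequence={c: bytes(b).decode() for c, b in seqs.items()},
    )
    truth = truth or TruthRecord()
    truth.motif_plants[pwm.name] = {
        "clusters": sorted(int(c) for c in clusters),
        "prob": prob,
        "offset_sd": offset_sd,
        "positions": plants,
        "skipped": skipped,
    }
    return mutated, truth


def select_coupled_de_genes(
    genome: GenomeModel,
    truth: TruthRecord,
    clusters: set[int],
    n_genes: int,
    coupling: float,
    seed: int,
    max_dist: int = 10_000,
) -> list[tuple[str, int]]:
    """Planted up-gene list with a stated coupling to cluster targets.

    A fraction ``coupling`` of the returned genes are nearest-TSS targets of
    truth peaks in the given clusters; the rest are genes no truth peak
    targets at all, so the downstream targeted fraction has expectation
    ``coupling``.
    """
    from .annotation import annotate_peaks

    tp = pd.DataFrame(truth.truth_peaks)
    anns = annotate_peaks(tp[["chrom", "start", "end", "peak_id"]], genome,
                          max_dist=max_dist)
    cluster_of = truth.peak_cluster()
    targeted_by_selected: set[str] = set()
    targeted_any: set[str] = set()
    for a in anns:
        if a.target_gene is None:
            continue
        targeted_any.add(a.target_gene)
        if cluster_of[a.peak_id] in clusters:
            targeted_by_selected.add(a.target_gene)
    untargeted = [g.gene_id for g in genome.genes if g.gene_id not in targeted_any]
    pool_in = sorted(targeted_by_selected)
    n_in = int(round(coupling * n_genes))
    n_out = n_genes - n_in
    if len(pool_in) < n_in or len(untargeted) < n_out:
        raise ValueError(
            f"cannot plant {n_in} coupled + {n_out} uncoupled genes: pools have "
            f"{len(pool_in)} and {len(untargeted)}"
        )
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(pool_in, n_in, replace=False)) + list(
        rng.choice(untargeted, n_out, replace=False)
    )
    return [(g, 1) for g in chosen]


def write_cohort(cohort: Cohort, truth: TruthRecord, outdir) -> None:
    """Write the cohort to disk in the pipeline's input formats.

    fragments/<sample>.bed (BED6), peaks/<sample>.narrowPeak, genome as
    chrom.sizes + GFF3 (+ FASTA when sequence is present), metadata TSV and
    truth JSON.
    """
    from pathlib import Path

    from . import io as cio

    out = Path(outdir)
    (out / "fragments").mkdir(parents=True, exist_ok=True)
    (out / "peaks").mkdir(exist_ok=True)
    cio.write_chrom_sizes(cohort.genome.chromosomes, out / "genome.chrom.sizes")
    cio.write_gff3(cohort.genome, out / "genes.gff3")
    if cohort.genome.sequence is not None:
        cio.write_fasta(cohort.genome.sequence, out / "genome.fa")
    for sid in cohort.sample_ids:
        cio.write_bed(cohort.fragments[sid], out / "fragments" / f"{sid}.bed")
        cio.write_narrowpeak(cohort.peaks[sid], out / "peaks" / f"{sid}.narrowPeak")
    cohort.metadata.to_csv(out / "samples.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")


def generate_gene_sets(
    genome: GenomeModel,
    n_terms: int,
    term_size_range: tuple[int, int],
    seed: int,
    planted_term: str | None = None,
    planted_genes: list[str] | None = None,
    truth: TruthRecord | None = None,
) -> tuple[dict[str, list[str]], TruthRecord]:
    """Random term annotations plus an optional planted (enriched) term."""
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genome.genes]
    terms: dict[str, list[str]] = {}
    for t in range(n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        terms[f"TERM:{t:04d}"] = sorted(
            rng.choice(gene_ids, min(size, len(gene_ids)), replace=False)
        )
    truth = truth or TruthRecord()
    if planted_term is not None:
        if not planted_genes:
            raise ValueError("planted_term requires planted_genes")
        terms[planted_term] = sorted(planted_genes)
        truth.term_enrichments[planted_term] = sorted(planted_genes)
    return terms, truth
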