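"""Pipeline orchestration: one YAML config drives every stage in order.

Stage order: qc -> atlas -> clustering -> annotation -> de -> integration ->
motifs -> ora. Each stage is a pure function of (inputs, config, seed); a
single global seed is fanned out per stage as seed + stage index, and a run
manifest records the seeds and SHA-256 digests of every output so reruns can
be checked for byte-identity. A stage failure halts the run with the stage
name; outputs of completed stages are retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .annotation import annotate_peaks, annotation_table, cluster_context_profile
from .atlas import build_atlas
from .clustering import cluster_peaks, cluster_samples, embed
from .diffexpr import nb_wald, preferential_sets
from .integration import active_regulation, cluster_targets
from .motifs import enrich, read_pwms
from .ora import ora as run_ora
from .qc import compute_frip, qc_filter, qc_table

logger = logging.getLogger(__name__)

STAGES = ["qc", "atlas", "clustering", "annotation", "de", "integration",
          "motifs", "ora"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_cohort_inputs(cohort_dir: Path):
    meta = pd.read_csv(cohort_dir / "samples.tsv", sep="\t")
    fragments = {
        sid: cio.read_bed(cohort_dir / "fragments" / f"{sid}.bed")
        for sid in meta["sample_id"]
    }
    peaks = {
        sid: cio.read_narrowpeak(cohort_dir / "peaks" / f"{sid}.narrowPeak")
        for sid in meta["sample_id"]
    }
    chromosomes = cio.read_chrom_sizes(cohort_dir / "genome.chrom.sizes")
    genome = cio.read_gff3(cohort_dir / "genes.gff3", chromosomes=chromosomes)
    fasta = cohort_dir / "genome.fa"
    if fasta.exists():
        genome.sequence = cio.read_fasta(fasta)
    return meta, fragments, peaks, genome


def run_all(config: dict) -> dict:
    """Execute all configured stages; returns the run manifest."""
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stage_seed = {s: seed + i for i, s in enumerate(STAGES)}
    manifest: dict = {"seed": seed, "stage_seeds": stage_seed, "outputs": {},
                      "stages_run": []}

    def emit(name: str, path: Path):
        manifest["outputs"][name] = _digest(path)

    current = "setup"
    try:
        cohort_dir = Path(config["cohort_dir"])
        meta, fragments, peaks, genome = _load_cohort_inputs(cohort_dir)

        current = "qc"
        qcs = [compute_frip(sid, fragments[sid], peaks[sid])
               for sid in meta["sample_id"]]
        qc_cfg = config.get("qc", {})
        passed, _failed = qc_filter(
            qcs,
            min_fragments=int(qc_cfg.get("min_fragments", 2_000_000)),
            min_frip=float(qc_cfg.get("min_frip", 0.2)),
        )
        table = qc_table(qcs)
        table.to_csv(outdir / "qc.tsv", sep="\t", index=False)
        emit("qc.tsv", outdir / "qc.tsv")
        manifest["stages_run"].append("qc")
        if not passed:
            raise RuntimeError("no passing samples")
        keep = [s.sample_id for s in passed]

        current = "atlas"
        atlas = build_atlas(
            {s: peaks[s] for s in keep}, {s: fragments[s] for s in keep},
            chrom_names=set(genome.chrom_sizes),
        )
        cio.write_bed(atlas.peaks.rename(columns={"peak_id": "name"}),
                      outdir / "atlas.bed")
        atlas.normalized.to_csv(outdir / "normalized.tsv", sep="\t")
        emit("atlas.bed", outdir / "atlas.bed")
        emit("normalized.tsv", outdir / "normalized.tsv")
        manifest["stages_run"].append("atlas")

        current = "clustering"
        cl_cfg = config.get("clustering", {})
        dendro = cluster_samples(atlas.normalized)
        assignment = cluster_peaks(
            atlas.normalized, k=int(cl_cfg.get("k", 15)),
            seed=stage_seed["clustering"],
            n_restarts=int(cl_cfg.get("n_restarts", 10)),
        )
        pd.DataFrame(dendro.linkage_matrix).to_csv(
            outdir / "sample_linkage.tsv", sep="\t", index=False)
        assignment.labels.to_csv(outdir / "peak_clusters.tsv", sep="\t")
        coords = embed(atlas.normalized, method=cl_cfg.get("embedding", "pca"),
                       seed=stage_seed["clustering"])
        coords.to_csv(outdir / "embedding.tsv", sep="\t")
        for f in ["sample_linkage.tsv", "peak_clusters.tsv", "embedding.tsv"]:
            emit(f, outdir / f)
        manifest["stages_run"].append("clustering")

        current = "annotation"
        an_cfg = config.get("annotation", {})
        retained = atlas.peaks[atlas.peaks["peak_id"].isin(atlas.normalized.index)]
        anns = annotate_peaks(
            retained, genome,
            max_dist=int(an_cfg.get("max_dist", 10_000)),
            promoter_window=int(an_cfg.get("promoter_window", 1_000)),
        )
        annotation_table(anns).to_csv(outdir / "annotation.tsv", sep="\t",
                                      index=False)
        cluster_context_profile(anns, assignment).to_csv(
            outdir / "context_profile.tsv", sep="\t")
        emit("annotation.tsv", outdir / "annotation.tsv")
        emit("context_profile.tsv", outdir / "context_profile.tsv")
        manifest["stages_run"].append("annotation")

        de_table = None
        if "de" in config:
            current = "de"
            de_cfg = config["de"]
            counts = cio.read_counts(de_cfg["counts"])
            sheet = pd.read_csv(de_cfg["samples"], sep="\t")
            contrast = de_cfg["contrast"]
            sel = sheet[sheet["condition"].isin(contrast)]
            groups = pd.Series(sel["condition"].to_numpy(),
                               index=sel["sample_id"].to_numpy())
            de_table = nb_wald(counts[groups.index], groups)
            de_table.to_csv(outdir / "de.tsv", sep="\t")
            emit("de.tsv", outdir / "de.tsv")
            manifest["stages_run"].append("de")

        if de_table is not None and "integration" in config:
            current = "integration"
            in_cfg = config["integration"]
            up, down = preferential_sets(de_table)
            pref = up if in_cfg.get("direction", "up") == "up" else down
            targets = cluster_targets(anns, assignment,
                                      set(in_cfg["clusters"]))
            category = None
            if in_cfg.get("category_gmt"):
                gmt = cio.read_gmt(in_cfg["category_gmt"])
                category = set(gmt[in_cfg["category_term"]])
            report = active_regulation(pref, category, targets,
                                       in_cfg.get("direction", "up"),
                                       tuple(in_cfg["clusters"]))
            with open(outdir / "active_regulation.json", "w") as fh:
                json.dump(
                    {"direction": report.direction,
                     "clusters": list(report.clusters),
                     "universe_size": len(report.universe),
                     "targeted_size": len(report.targeted),
                     "fraction": report.fraction,
                     "targeted_genes": sorted(report.targeted)},
                    fh, indent=1)
            emit("active_regulation.json", outdir / "active_regulation.json")
            manifest["stages_run"].append("integration")

        if "motifs" in config and genome.sequence is not None:
            current = "motifs"
            library = read_pwms(config["motifs"]["library"],
                                fmt=config["motifs"].get("format", "jaspar"))
            tables = []
            for c in range(1, assignment.k + 1):
                tgt_ids = set(assignment.peaks_in(c))
                tgt = retained[retained["peak_id"].isin(tgt_ids)]
                bg = retained[~retained["peak_id"].isin(tgt_ids)]
                if len(tgt) == 0 or len(bg) == 0:
                    continue
                tab = enrich(tgt, bg, genome.sequence, library)
                tab.insert(0, "ocr_cluster", c)
                tables.append(tab)
            pd.concat(tables, ignore_index=True).to_csv(
                outdir / "motif_enrichment.tsv", sep="\t", index=False)
            emit("motif_enrichment.tsv", outdir / "motif_enrichment.tsv")
            manifest["stages_run"].append("motifs")

        if "ora" in config and de_table is not None:
            current = "ora"
            terms = cio.read_gmt(config["ora"]["gmt"])
            universe = set(de_table.index[de_table["padj"].notna()])
            up, _ = preferential_sets(de_table)
            res = run_ora(up & universe, universe, terms)
            res.to_csv(outdir / "ora.tsv", sep="\t", index=False)
            emit("ora.tsv", outdir / "ora.tsv")
            manifest["stages_run"].append("ora")
    except Exception as exc:
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise RuntimeError(f"stage {current!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
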