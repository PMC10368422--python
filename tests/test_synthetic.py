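"""Generator contracts: determinism, planted-truth recoverability, NB moments."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from clonatlas.atlas import build_atlas
from clonatlas.motifs import MotifPWM, scan
from clonatlas.synthetic import (
    RegionSpec,
    TruthRecord,
    generate_cohort,
    generate_expression,
    generate_genome,
    make_cluster_region_map,
    plant_motifs,
    select_coupled_de_genes,
)


class TestGenerateGenome:
    def test_zero_genes(self):
        g = generate_genome(1, 10_000, 0, seed=1)
        assert len(g.chromosomes) == 1 and not g.genes

    def test_deterministic_byte_identical(self):
        a = generate_genome(2, 50_000, 20, seed=42)
        b = generate_genome(2, 50_000, 20, seed=42)
        assert a.sequence == b.sequence
        assert a.genes == b.genes

    def test_bounds_and_non_overlap_brute_force(self):
        g = generate_genome(2, 1_000_000, 200, seed=7)
        assert len(g.genes) == 200
        sizes = g.chrom_sizes
        for gene in g.genes:
            assert 0 <= gene.start < gene.end <= sizes[gene.chrom]
            assert gene.tss == (gene.start if gene.strand == "+" else gene.end - 1)
        for chrom in sizes:
            spans = sorted((x.start, x.end) for x in g.genes if x.chrom == chrom)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_infeasible_density_is_error(self):
        with pytest.raises(ValueError, match="reduce n_genes"):
            generate_genome(1, 10_000, 50, seed=1, gene_length_range=(1000, 1000))


class TestGenerateCohort:
    def test_no_failures_when_n_fail_zero(self, demo_cohort):
        genome = generate_genome(1, 400_000, 50, seed=3)
        regions = [RegionSpec("A", 3), RegionSpec("B", 3)]
        _, truth = generate_cohort(genome, regions, 4, None, "A",
                                   n_fail=0, seed=4, peaks_per_cluster=10)
        assert truth.qc_fail_samples == {}

    def test_n_fail_cap(self):
        genome = generate_genome(1, 400_000, 50, seed=3)
        regions = [RegionSpec("A", 2), RegionSpec("B", 2)]
        with pytest.raises(ValueError, match="n_fail"):
            generate_cohort(genome, regions, 4, None, "A", n_fail=4, seed=1)

    def test_identical_cluster_maps_remove_region_structure(self):
        genome = generate_genome(1, 800_000, 50, seed=5)
        regions = [RegionSpec(f"R{i}", 4) for i in range(4)]
        cmap = {r.name: [1, 2, 3] for r in regions}
        cohort, _ = generate_cohort(genome, regions, 3, cmap, "R0",
                                    seed=6, peaks_per_cluster=25)
        atlas = build_atlas(cohort.peaks, cohort.fragments)
        X = atlas.normalized.to_numpy().T
        labels = cohort.metadata["region"]
        assert abs(silhouette_score(X, labels)) < 0.1

    def test_private_cluster_peaks_only_in_distinct_samples(self, demo_cohort):
        """Exhaustive overlap scan: private-cluster truth peaks touch only
        the distinct region's sample peaks."""
        cohort, truth = demo_cohort
        tp = pd.DataFrame(truth.truth_peaks)
        private = tp[tp.cluster.isin([1, 2])]
        region_of = truth.sample_region
        for sid, sample_peaks in cohort.peaks.items():
            overlaps = 0
            for p in private.itertuples(index=False):
                for q in sample_peaks.itertuples(index=False):
                    if q.chrom == p.chrom and q.start < p.end and p.start < q.end:
                        overlaps += 1
            if region_of[sid] != truth.distinct_region:
                assert overlaps == 0
        # and the distinct region's samples do carry them
        distinct = [s for s in cohort.sample_ids
                    if region_of[s] == truth.distinct_region]
        assert any(
            q.start < p.end and p.start < q.end and q.chrom == p.chrom
            for s in distinct
            for p in private.itertuples(index=False)
            for q in cohort.peaks[s].itertuples(index=False)
        )

    def test_cluster_map_distinct_structure(self):
        regions = [RegionSpec(f"R{i}", 2) for i in range(5)]
        cmap = make_cluster_region_map(regions, 8, "R2")
        private = {1, 2}
        for name, clusters in cmap.items():
            if name == "R2":
                assert private <= set(clusters)
            else:
                assert not (private & set(clusters))
        # every non-private cluster has a unique activity pattern
        patterns = {}
        for c in range(3, 9):
            patterns[c] = frozenset(n for n, cs in cmap.items() if c in cs)
        assert len(set(patterns.values())) == len(patterns)

    def test_determinism(self):
        genome = generate_genome(1, 500_000, 40, seed=8)
        regions = [RegionSpec("A", 2), RegionSpec("B", 2)]
        out = []
        for _ in range(2):
            cohort, _ = generate_cohort(genome, regions, 4, None, "A",
                                        seed=9, peaks_per_cluster=10)
            out.append(cohort)
        for s in out[0].sample_ids:
            pd.testing.assert_frame_equal(out[0].fragments[s], out[1].fragments[s])
            pd.testing.assert_frame_equal(out[0].peaks[s], out[1].peaks[s])


class TestGenerateExpression:
    def _genome(self):
        return generate_genome(1, 300_000, 100, seed=13,
                               gene_length_range=(400, 800))

    def test_lfc_zero_plants_nothing(self):
        _, truth = generate_expression(self._genome(), lfc=0.0, seed=14)
        assert truth.de_genes["Dd2_vs_D"] == []

    def test_low_dispersion_mean_ratio_approaches_2_to_lfc(self):
        counts, truth = generate_expression(
            self._genome(), n_de_per_contrast=20, lfc=2.0, dispersion=1e-4,
            depth=(1.0, 1.0), n_reps=10, seed=15, de_base_mean=5_000.0,
        )
        planted = dict(truth.de_genes["Dd2_vs_D"])
        for gene, true_lfc in planted.items():
            a = counts.loc[gene, [c for c in counts if c.startswith("Dd2_")]].mean()
            b = counts.loc[gene, [c for c in counts if c.startswith("D_")]].mean()
            assert a / b == pytest.approx(2.0 ** true_lfc, rel=0.05)

    def test_fixed_seed_identical_matrix(self):
        g = self._genome()
        a, _ = generate_expression(g, seed=16)
        b, _ = generate_expression(g, seed=16)
        pd.testing.assert_frame_equal(a, b)

    def test_parameter_validation(self):
        g = self._genome()
        with pytest.raises(ValueError, match="dispersion"):
            generate_expression(g, dispersion=0.0)
        with pytest.raises(ValueError, match="positive"):
            generate_expression(g, depth=(0.0, 1.0))
        with pytest.raises(ValueError, match="replicates"):
            generate_expression(g, n_reps=1)


class TestPlantMotifs:
    def _setup(self):
        genome = generate_genome(1, 500_000, 60, seed=17)
        regions = [RegionSpec("A", 2), RegionSpec("B", 2)]
        cohort, truth = generate_cohort(genome, regions, 4, None, "A",
                                        seed=18, peaks_per_cluster=15)
        mat = np.zeros((8, 4))
        for i, b in enumerate("ACGGTTAC"):
            mat[i, "ACGT".index(b)] = 1.0
        return genome, truth, MotifPWM("P1", mat)

    def test_prob_zero_leaves_genome_byte_identical(self):
        genome, truth, pwm = self._setup()
        tp = pd.DataFrame(truth.truth_peaks)
        mutated, _ = plant_motifs(genome, tp, pwm, {1}, prob=0.0, seed=19)
        assert mutated.sequence == genome.sequence

    def test_prob_one_offset_zero_plants_every_target_center(self):
        genome, truth, pwm = self._setup()
        tp = pd.DataFrame(truth.truth_peaks)
        mutated, truth = plant_motifs(genome, tp, pwm, {2}, prob=1.0,
                                      offset_sd=0.0, seed=20, truth=truth)
        targets = tp[tp.cluster == 2]
        assert len(truth.motif_plants["P1"]["positions"]) == len(targets)
        for p in targets.itertuples(index=False):
            center = (p.start + p.end) // 2
            window = mutated.sequence[p.chrom][center - 10: center + 10]
            assert pwm.consensus in window  # exhaustive string check

    def test_planted_hits_recoverable_by_scan(self):
        genome, truth, pwm = self._setup()
        tp = pd.DataFrame(truth.truth_peaks)
        mutated, truth = plant_motifs(genome, tp, pwm, {1}, prob=1.0,
                                      offset_sd=5.0, seed=21, truth=truth)
        for peak_id, pos in truth.motif_plants["P1"]["positions"]:
            row = tp[tp.peak_id == peak_id].iloc[0]
            seq = mutated.sequence[row.chrom][row.start: row.end]
            hits = scan(seq, pwm)
            assert (hits.position == pos - row.start).any()


class TestTruthRecord:
    def test_json_round_trip(self, tmp_path, demo_cohort):
        _, truth = demo_cohort
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = TruthRecord.from_json(path)
        assert back == truth


class TestCoupledDeGenes:
    def test_coupling_fraction_exact_in_truth(self):
        genome = generate_genome(2, 1_000_000, 600, seed=23,
                                 gene_length_range=(400, 800))
        regions = [RegionSpec("A", 2), RegionSpec("Dd2", 2)]
        _, truth = generate_cohort(genome, regions, 4, None, "Dd2", seed=24,
                                   peaks_per_cluster=60, tss_anchor_frac=0.9)
        chosen = select_coupled_de_genes(genome, truth, {1, 2}, 40, 0.7, seed=25)
        from clonatlas.annotation import annotate_peaks

        tp = pd.DataFrame(truth.truth_peaks)
        anns = annotate_peaks(tp[["chrom", "start", "end", "peak_id"]], genome)
        cluster_of = truth.peak_cluster()
        targets = {a.target_gene for a in anns
                   if a.target_gene and cluster_of[a.peak_id] in {1, 2}}
        frac = np.mean([g in targets for g, _ in chosen])
        assert frac == pytest.approx(0.7, abs=0.01)
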