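import numpy as np
import pandas as pd
import pytest

from clonatlas.genome import Gene, GenomeModel
from clonatlas.synthetic import RegionSpec, generate_cohort, generate_genome


def random_intervals(rng, n, chrom_lengths, max_len=400):
    """Random interval frame over the given chromosomes."""
    chroms = list(chrom_lengths)
    names = [chroms[i] for i in rng.integers(0, len(chroms), n)]
    starts = np.array([rng.integers(0, chrom_lengths[c]) for c in names])
    lengths = rng.integers(1, max_len + 1, n)
    ends = np.minimum(starts + lengths, [chrom_lengths[c] for c in names])
    return pd.DataFrame({"chrom": names, "start": starts, "end": ends})


@pytest.fixture(scope="session")
def small_genome():
    """2 chromosomes x 200 kb, 60 genes, with sequence."""
    return generate_genome(2, 200_000, 60, seed=101)


@pytest.fixture(scope="session")
def toy_genome():
    """Hand-built genome for exact-coordinate assertions."""
    genes = [
        Gene("gA", "chr1", "+", 1_000, 3_000, exons=((1_000, 1_500), (2_500, 3_000))),
        Gene("gB", "chr1", "-", 10_000, 12_000),
        Gene("gC", "chr2", "+", 5_000, 6_000),
    ]
    return GenomeModel(chromosomes=[("chr1", 50_000), ("chr2", 50_000)], genes=genes)


@pytest.fixture(scope="session")
def demo_cohort():
    """Small multi-region cohort with planted QC failures, reused read-only."""
    genome = generate_genome(2, 1_200_000, 300, seed=11)
    regions = [RegionSpec(f"R{i}", 4) for i in range(5)] + [
        RegionSpec("Dd2", 4)
    ]
    cohort, truth = generate_cohort(
        genome, regions, n_clusters=8, cluster_region_map=None,
        distinct_region="Dd2", n_fail=4, seed=12,
        depth_range=(60_000, 100_000), peaks_per_cluster=30,
    )
    return cohort, truth
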