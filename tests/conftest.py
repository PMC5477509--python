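import numpy as np
import pytest

from feralgen import sim
from feralgen.io import GenotypeMatrix, PopulationMap


def random_genotype_matrix(
    rng,
    n_samples=12,
    n_sites=1000,
    chrom_lengths=(("chr1", 400_000), ("chr2", 300_000)),
    missing_rate=0.08,
):
    """Random biallelic matrix with missing calls, for oracle comparisons."""
    chroms, pos, geno_cols = [], [], []
    total_len = sum(l for _, l in chrom_lengths)
    for chrom, length in chrom_lengths:
        k = max(1, round(n_sites * length / total_len))
        p = np.sort(rng.choice(length, size=k, replace=False))
        chroms.extend([chrom] * k)
        pos.extend(p.tolist())
    n = len(pos)
    freqs = rng.beta(0.5, 0.5, size=n)
    geno = rng.binomial(2, freqs, size=(n_samples, n)).astype(np.int8)
    miss = rng.random((n_samples, n)) < missing_rate
    geno[miss] = -1
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n_samples)],
        chrom=np.array(chroms, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.full(n, "A", dtype=object),
        alt=np.full(n, "G", dtype=object),
        geno=geno,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix(rng):
    return random_genotype_matrix(rng, n_samples=10, n_sites=200)


@pytest.fixture(scope="session")
def preset_runs():
    """Ten selection replicates of the de-domestication preset.

    Shared by the scan-recovery, AFD and heterozygosity acceptance tests;
    each element is (matrix, popmap, truth).
    """
    out = []
    for r in range(10):
        spec, demo, loci = sim.dedomestication_preset()
        out.append(
            sim.simulate_dedomestication(spec, demo, loci, 40, 40, seed=100 + r)
        )
    return out


@pytest.fixture(scope="session")
def neutral_control_runs():
    """Matched neutral controls (same genome and demography, no selection)."""
    out = []
    for r in range(10):
        spec, demo, loci = sim.dedomestication_preset(with_selection=False)
        out.append(
            sim.simulate_dedomestication(spec, demo, loci, 40, 40, seed=100 + r)
        )
    return out
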