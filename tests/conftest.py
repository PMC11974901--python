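import numpy as np
import pytest

from scancestry.genotype import GenotypeMatrix, ReferencePanel, SnpRecord
from scancestry.simulate import SimScenario, make_scenario


def make_snps(n, chrom="1", start=1000, step=1000, alleles=("A", "G")):
    return [
        SnpRecord(f"{chrom}:{start + j * step}:{alleles[0]}:{alleles[1]}",
                  chrom, start + j * step, alleles[0], alleles[1])
        for j in range(n)
    ]


def matrix_from(dosages, sample_prefix="S", snps=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    if snps is None:
        snps = make_snps(dosages.shape[1])
    ids = [f"{sample_prefix}{i}" for i in range(dosages.shape[0])]
    return GenotypeMatrix(ids, snps, dosages)


@pytest.fixture(scope="session")
def small_panel():
    """3 groups x 2 populations x 10 samples, 300 SNPs: quick but structured."""
    scenario = SimScenario(
        n_groups=3, populations_per_group=2, samples_per_population=10,
        n_snps=300, seed=42,
    )
    panel, _, _ = make_scenario(scenario)
    return panel


@pytest.fixture(scope="session")
def two_cluster_panel():
    """Two well-separated groups for PCA separation checks."""
    scenario = SimScenario(
        n_groups=2, populations_per_group=2, samples_per_population=15,
        n_snps=400, seed=7,
    )
    panel, _, _ = make_scenario(scenario)
    return panel
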