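import numpy as np
import pytest

from mitovar import syndata, sitefilter


@pytest.fixture(scope="session")
def small_cfg() -> syndata.SimConfig:
    """A compact clean cohort (no heteroplasmy) for recovery tests."""
    return syndata.SimConfig(
        genome_length=6000,
        n_accessions=12,
        n_clades=3,
        snps_per_clade=20,
        private_snp_rate=0.5,
        plastid_regions=((500, 900),),
        numt_regions=((3000, 3400),),
        heteroplasmy_rate=0.0,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    reference, haplotypes, truth = syndata.simulate_clades(small_cfg)
    tables = syndata.make_site_tables(haplotypes, small_cfg, reference)
    return reference, haplotypes, truth, tables


@pytest.fixture(scope="session")
def small_snp_matrix(small_cohort):
    _, _, _, tables = small_cohort
    cm = sitefilter.build_consensus_matrix(tables)
    return sitefilter.extract_snp_sites(cm)


def random_snp_matrix(
    rng: np.random.Generator, n_acc: int = 6, n_sites: int = 12
) -> sitefilter.SnpMatrix:
    """Random polymorphic matrix (every column has >= 2 distinct bases)."""
    while True:
        bases = rng.integers(0, 4, size=(n_acc, n_sites)).astype(np.int8)
        poly = (bases != bases[0]).any(axis=0)
        if poly.all():
            break
    positions = np.sort(
        rng.choice(np.arange(1, n_sites * 50), size=n_sites, replace=False)
    )
    ids = [f"S{i:02d}" for i in range(n_acc)]
    return sitefilter.SnpMatrix(ids, positions, bases)
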