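import numpy as np
import pytest

from strainps.genotype_io import MISSING, GenotypeMatrix, PhenotypeDataset


def make_matrix(calls, pos=None, chrom="chr1", names=None):
    """Build a GenotypeMatrix from a 2-d array of {0,1,MISSING} calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 100
    if names is None:
        names = [f"s{i + 1}" for i in range(n)]
    alleles = np.empty((m, 2), dtype=object)
    alleles[:, 0] = "A"
    alleles[:, 1] = "T"
    chroms = np.full(m, chrom, dtype=object) if isinstance(chrom, str) else chrom
    return GenotypeMatrix(names, chroms, pos, alleles, calls)


def random_matrix(rng, n, m, missing_rate=0.0):
    calls = rng.integers(0, 2, (n, m)).astype(np.int8)
    if missing_rate:
        calls[rng.random((n, m)) < missing_rate] = MISSING
    return make_matrix(calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_panel():
    """10 strains x 8 SNPs splitting 5/5 identically at every site."""
    col = np.array([0] * 5 + [1] * 5, dtype=np.int8)
    return make_matrix(np.tile(col[:, None], (1, 8)))


@pytest.fixture
def retinal_instance():
    """A 29-strain binary-phenotype instance: 8 affected strains share one
    haplotype over a planted block, 21 unaffected share the other."""
    import strainps as sp

    cfg = sp.SimulationConfig(
        n_groups=1,
        strains_per_group=(29,),
        n_snps=60,
        fst=0.0,
        seed=26721,
    )
    gm, truth = sp.simulate_structured_panel(cfg)
    carriers = set(gm.strain_names[:8])
    gm, truth = sp.plant_causal_block(gm, truth, carriers, 6)
    affected = np.array([1.0 if s in carriers else 0.0 for s in gm.strain_names])
    ds = PhenotypeDataset(
        dataset_id="retinal-degeneration",
        sex="both",
        categorical=True,
        strains=gm.strain_names,
        mean=affected,
        sd=np.zeros(29),
        n_animals=np.full(29, 8),
    )
    return gm, truth, ds, carriers
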