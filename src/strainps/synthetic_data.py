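"""Synthetic inbred-strain panels with controlled population structure.

The generator emulates the study system: a panel of 10-49 fully homozygous
strains drawn from up to four diverged sub-populations, with an optional
planted causative haplotype block and an MPD-style phenotype dataset (strain
means, SDs, animal counts, replicates) of controlled genetic effect size.

Divergence follows the Balding-Nichols model: each site has an ancestral
allele frequency p drawn uniformly from ``ancestral_maf_range``; each
sub-population's frequency is Beta-distributed with mean p and variance
``fst * p * (1 - p)``; each strain contributes one Bernoulli allele from its
sub-population frequency (homozygous by construction).

Defaults encode the study conditions: four sub-populations of sizes
7/14/23/5 (the 49-strain panel composition), fst 0.3, ancestral minor-allele
frequencies uniform on (0.05, 0.5), 8 replicate animals per strain with unit
within-strain SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .genotype_io import GenotypeMatrix, PhenotypeDataset


@dataclass
class SimulationConfig:
    """Free parameters of the panel/phenotype generator."""

    n_groups: int = 4
    strains_per_group: tuple[int, ...] = (7, 14, 23, 5)
    n_snps: int = 5000
    fst: float = 0.3
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    planted_block: tuple[str, int, int, frozenset] | None = None
    target_eta2: float = 0.0
    replicates_per_strain: int = 8
    within_strain_sd: float = 1.0
    seed: int = 0
    chrom: str = "chr1"
    snp_spacing_bp: int = 1000

    def __post_init__(self) -> None:
        self.strains_per_group = tuple(int(x) for x in self.strains_per_group)
        if not 1 <= self.n_groups <= 4:
            raise ParameterError("n_groups must be in 1..4")
        if len(self.strains_per_group) != self.n_groups:
            raise ParameterError("strains_per_group must list n_groups sizes")
        if sum(self.strains_per_group) < 2:
            raise ParameterError("need at least 2 strains in total")
        if not 0.0 <= self.fst < 1.0:
            raise ParameterError("fst must lie in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ParameterError("ancestral_maf_range must sit within (0, 0.5]")
        if not 0.0 <= self.target_eta2 < 1.0:
            raise ParameterError("target_eta2 must lie in [0, 1)")
        if self.replicates_per_strain < 1:
            raise ParameterError("replicates_per_strain must be >= 1")
        if self.within_strain_sd < 0:
            raise ParameterError("within_strain_sd must be >= 0")
        if self.n_snps < 1:
            raise ParameterError("n_snps must be >= 1")

    @property
    def n_strains(self) -> int:
        return sum(self.strains_per_group)


@dataclass
class SimulationTruth:
    """Ground truth carried alongside a simulated panel."""

    group_labels: np.ndarray  # (n,) int, 1-based sub-population labels
    planted_interval: tuple[str, int, int] | None = None  # chrom, start/end idx
    carriers: frozenset = field(default_factory=frozenset)
    group_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.group_labels = np.asarray(self.group_labels, dtype=int)
        if self.planted_interval is not None and not self.carriers:
            raise ParameterError("a planted block needs a nonempty carrier set")


def _strain_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def simulate_structured_panel(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Draw a homozygous strain panel under the Balding-Nichols model.

    Deterministic given ``config.seed``.  If ``config.planted_block`` is set,
    the block is planted (see :func:`plant_causal_block`) before returning.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_strains, config.n_snps
    labels = np.repeat(
        np.arange(1, config.n_groups + 1), config.strains_per_group
    )
    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    if config.fst == 0.0:
        p_group = np.tile(p_anc, (config.n_groups, 1))
    else:
        # Beta with mean p and variance fst*p*(1-p)
        c = (1.0 - config.fst) / config.fst
        p_group = rng.beta(p_anc * c, (1.0 - p_anc) * c, size=(config.n_groups, m))
    calls = (
        rng.random((n, m)) < p_group[labels - 1]
    ).astype(np.int8)
    pos = np.arange(1, m + 1, dtype=np.int64) * config.snp_spacing_bp
    alleles = np.empty((m, 2), dtype=object)
    alleles[:, 0] = "A"
    alleles[:, 1] = "T"
    gm = GenotypeMatrix(
        _strain_names(n),
        np.full(m, config.chrom, dtype=object),
        pos,
        alleles,
        calls,
    )
    truth = SimulationTruth(group_labels=labels)
    if config.planted_block is not None:
        _, start, count, carriers = config.planted_block
        gm, truth = plant_causal_block(gm, truth, set(carriers), count, start)
    return gm, truth


def plant_causal_block(
    genotypes: GenotypeMatrix,
    truth: SimulationTruth,
    carriers: set[str],
    snp_count: int,
    start_index: int | None = None,
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Overwrite ``snp_count`` consecutive sites with a two-haplotype pattern.

    Carrier strains receive the all-alternate string, non-carriers the
    all-reference string, so the interval partitions the panel into exactly
    the carrier / non-carrier groups.
    """
    if snp_count < 4:
        raise ParameterError("a planted block needs at least 4 SNPs")
    carriers = frozenset(carriers)
    names = set(genotypes.strain_names)
    if not carriers or not carriers < names:
        raise ParameterError(
            "carriers must be a nonempty proper subset of the panel strains"
        )
    if start_index is None:
        start_index = (genotypes.n_sites - snp_count) // 2
    end_index = start_index + snp_count - 1
    if start_index < 0 or end_index >= genotypes.n_sites:
        raise ParameterError("planted interval falls outside the panel")
    chrom = genotypes.chrom[start_index]
    if genotypes.chrom[end_index] != chrom:
        raise ParameterError("planted interval crosses a chromosome boundary")
    calls = genotypes.calls.copy()
    is_carrier = np.array(
        [s in carriers for s in genotypes.strain_names], dtype=np.int8
    )
    calls[:, start_index : end_index + 1] = is_carrier[:, None]
    gm = GenotypeMatrix(
        genotypes.strain_names,
        genotypes.chrom,
        genotypes.pos_bp,
        genotypes.alleles,
        calls,
    )
    new_truth = replace(
        truth,
        planted_interval=(str(chrom), int(start_index), int(end_index)),
        carriers=carriers,
    )
    return gm, new_truth


def simulate_phenotype(
    truth: SimulationTruth,
    config: SimulationConfig,
    strain_names: list[str] | None = None,
    dataset_id: str = "synthetic",
) -> PhenotypeDataset:
    """Simulate an MPD-style dataset with a chosen genetic effect size.

    Carrier and non-carrier strain means are offset by delta solving the
    variance decomposition eta2 = sigmaB^2 / (sigmaB^2 + sigmaW^2), where
    sigmaW^2 = within_strain_sd^2 / replicates is the sampling variance of an
    observed strain mean and sigmaB^2 = f(1-f) delta^2 with f the carrier
    fraction.  Replicate animal values add Gaussian within-strain noise.
    Deterministic given ``config.seed``.
    """
    n = len(truth.group_labels)
    if strain_names is None:
        strain_names = _strain_names(n)
    if len(strain_names) != n:
        raise ParameterError("strain_names length does not match the truth")
    if config.target_eta2 > 0 and truth.planted_interval is None:
        raise ParameterError("target_eta2 > 0 requires a planted block")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    is_carrier = np.array([s in truth.carriers for s in strain_names])
    t = config.target_eta2
    sigma_w2 = config.within_strain_sd**2 / config.replicates_per_strain
    if t > 0:
        f = is_carrier.mean()
        if sigma_w2 == 0.0:
            delta = 1.0  # noise-free: any offset gives perfect separation
        else:
            delta = np.sqrt(t / (1.0 - t) * sigma_w2 / (f * (1.0 - f)))
    else:
        delta = 0.0
    true_means = delta * is_carrier.astype(float)
    reps = rng.normal(
        true_means[:, None],
        config.within_strain_sd,
        size=(n, config.replicates_per_strain),
    )
    if config.within_strain_sd == 0.0:
        reps = np.tile(true_means[:, None], (1, config.replicates_per_strain))
    mean = reps.mean(axis=1)
    sd = reps.std(axis=1, ddof=1) if reps.shape[1] > 1 else np.zeros(n)
    return PhenotypeDataset(
        dataset_id=dataset_id,
        sex="both",
        categorical=False,
        strains=list(strain_names),
        mean=mean,
        sd=sd,
        n_animals=np.full(n, config.replicates_per_strain),
        replicates={s: reps[i] for i, s in enumerate(strain_names)},
    )
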