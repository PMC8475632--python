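"""Block-phenotype association scoring, effect size, power and dataset QC.

Association uses one value per strain (the strain mean): a one-way ANOVA of
strain means across the haplotype groups of a block.  The genetic effect size
is eta^2 = SSB/SST.  Power calculations use the noncentral F distribution
with noncentrality lambda = n * eta2 / (1 - eta2).

A dataset passes quality control when every strain mean comes from more than
5 animals and the inter- versus intra-strain one-way ANOVA (on replicates, or
reconstructed from per-strain mean/SD/count summaries) gives p < 1e-10; in
bulk mode categorical datasets are additionally rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateGroupingError, ParameterError, ValidationError
from .genotype_io import PhenotypeDataset
from .haplotype_blocks import UNASSIGNED, HaplotypeBlock

QC_MIN_ANIMALS = 5  # strict: every strain must have n_animals > 5
QC_ANOVA_P = 1e-10
HBCGM_P_CUTOFF = 0.01


@dataclass
class BlockAssociationResult:
    """One-way ANOVA of strain means across a block's haplotype groups."""

    block: HaplotypeBlock | None
    F_statistic: float
    p_hbcgm: float
    eta2: float
    groups_used: int
    strains_used: int
    ssb: float
    sst: float
    unbounded_F: bool = False  # perfect separation: zero within-group variance

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_hbcgm <= 1.0:
            raise ValidationError("p-value outside [0, 1]")
        if self.p_hbcgm == 0.0 and not self.unbounded_F:
            raise ValidationError("p = 0 is only valid under perfect separation")


@dataclass
class PowerSpec:
    """Inputs of a one-way ANOVA power calculation."""

    alpha: float
    eta2: float
    n: int
    k: int

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must lie in (0, 1)")
        if not 0.0 <= self.eta2 < 1.0:
            raise ParameterError("eta2 must lie in [0, 1)")
        if self.k < 2:
            raise ParameterError("need at least 2 groups")
        if self.n <= self.k:
            raise ParameterError("need n > k")

    @property
    def lam(self) -> float:
        """Noncentrality lambda = n * eta2 / (1 - eta2)."""
        return self.n * self.eta2 / (1.0 - self.eta2)

    @property
    def f_crit(self) -> float:
        """(1 - alpha) quantile of the central F(k-1, n-k)."""
        return float(stats.f.isf(self.alpha, self.k - 1, self.n - self.k))


@dataclass
class QCDecision:
    accepted: bool
    reasons: list[str] = field(default_factory=list)
    anova_p: float | None = None


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def _strain_anova_from_summaries(ds: PhenotypeDataset) -> float:
    """Inter- vs intra-strain one-way ANOVA p from (mean, SD, n) summaries."""
    n = ds.n_animals.astype(float)
    total_n = n.sum()
    grand = float(np.sum(n * ds.mean) / total_n)
    ssb = float(np.sum(n * (ds.mean - grand) ** 2))
    ssw = float(np.sum((n - 1) * ds.sd**2))
    k = ds.n_strains
    df1, df2 = k - 1, int(total_n) - k
    if df2 <= 0:
        raise ValidationError("no residual degrees of freedom for QC ANOVA")
    if ssw == 0.0:
        return 0.0 if ssb > 0 else 1.0
    f = (ssb / df1) / (ssw / df2)
    return float(stats.f.sf(f, df1, df2))


def qc_dataset(ds: PhenotypeDataset, bulk: bool = True) -> QCDecision:
    """Accept or reject a dataset per the selection rules.

    Rejection reasons are machine-readable codes: ``too_few_animals``,
    ``anova_not_significant``, ``categorical``.
    """
    if ds.n_strains < 2:
        raise ValidationError("QC ANOVA undefined for a single strain")
    reasons = []
    if np.any(ds.n_animals <= QC_MIN_ANIMALS):
        reasons.append("too_few_animals")
    if ds.replicates is not None:
        groups = [np.asarray(ds.replicates[s], dtype=float) for s in ds.strains]
        if all(len(g) > 1 for g in groups):
            if all(np.ptp(g) == 0 for g in groups):
                means = [g[0] for g in groups]
                p = 0.0 if np.ptp(means) > 0 else 1.0
            else:
                p = float(stats.f_oneway(*groups).pvalue)
        else:
            p = _strain_anova_from_summaries(ds)
    else:
        p = _strain_anova_from_summaries(ds)
    if not p < QC_ANOVA_P:
        reasons.append("anova_not_significant")
    if bulk and ds.categorical:
        reasons.append("categorical")
    return QCDecision(accepted=not reasons, reasons=reasons, anova_p=p)


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------

def one_way_anova(values: np.ndarray, labels: np.ndarray) -> dict:
    """Sums of squares, F and p for a one-way layout (one value per unit).

    Perfect separation (zero within-group variance, unequal group means)
    returns p = 0 with an infinite F, flagged; a constant response returns
    F = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    k, n = len(groups), len(values)
    if k < 2:
        raise DegenerateGroupingError("fewer than 2 groups with data")
    if n <= k:
        raise DegenerateGroupingError("no residual degrees of freedom")
    grand = values.mean()
    ssb = 0.0
    ssw = 0.0
    for g in groups:
        v = values[labels == g]
        ssb += len(v) * (v.mean() - grand) ** 2
        ssw += float(np.sum((v - v.mean()) ** 2))
    sst = float(np.sum((values - grand) ** 2))
    rel_tol = 1e-12 * max(sst, 1.0)
    if sst <= rel_tol:
        return dict(F=0.0, p=1.0, ssb=0.0, sst=sst, k=k, n=n, unbounded=False)
    if ssw <= rel_tol:
        return dict(
            F=np.inf, p=0.0, ssb=ssb, sst=sst, k=k, n=n, unbounded=True
        )
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return dict(F=float(f), p=p, ssb=ssb, sst=sst, k=k, n=n, unbounded=False)


def block_anova(
    block: HaplotypeBlock, dataset: PhenotypeDataset
) -> BlockAssociationResult:
    """Score a block against a phenotype: one-way ANOVA of strain means.

    Strains without a haplotype assignment or without phenotype data are
    dropped; groups are reduced to those retaining at least one strain.
    Categorical phenotypes (integer-coded) run through the same F machinery.
    """
    values, labels = [], []
    for strain, value in zip(dataset.strains, dataset.mean):
        if strain not in block.strain_names:
            continue
        lab = block.strain_groups[block.strain_names.index(strain)]
        if lab == UNASSIGNED:
            continue
        values.append(value)
        labels.append(lab)
    if not values:
        raise DegenerateGroupingError("no phenotyped strain is assigned")
    res = one_way_anova(np.array(values), np.array(labels))
    eta2 = res["ssb"] / res["sst"] if res["sst"] > 0 else 0.0
    return BlockAssociationResult(
        block=block,
        F_statistic=res["F"],
        p_hbcgm=res["p"],
        eta2=float(eta2),
        groups_used=res["k"],
        strains_used=res["n"],
        ssb=res["ssb"],
        sst=res["sst"],
        unbounded_F=res["unbounded"],
    )


def effect_size(result: BlockAssociationResult) -> float:
    """Genetic effect size eta^2 = SSB/SST of an association result."""
    if result.sst <= 0:
        raise ValidationError("effect size undefined when SST = 0")
    return float(result.ssb / result.sst)


def anova_power(spec: PowerSpec) -> float:
    """Power of the one-way ANOVA F test at effect size eta^2.

    Upper-tail probability of the noncentral F(k-1, n-k, lambda) beyond the
    central critical value.  At eta2 = 0 the noncentral law reduces to the
    central F, so the power equals alpha exactly; that limit is evaluated
    through the central distribution for numerical exactness.
    """
    df1, df2 = spec.k - 1, spec.n - spec.k
    if spec.lam == 0.0:
        return float(stats.f.sf(spec.f_crit, df1, df2))
    return float(stats.ncf.sf(spec.f_crit, df1, df2, spec.lam))


def select_correlated(
    results: list[BlockAssociationResult],
    cutoff: float = HBCGM_P_CUTOFF,
    gene_labels: list[str | None] | None = None,
) -> list[BlockAssociationResult]:
    """Keep results with p strictly below ``cutoff``.

    When gene labels are supplied (parallel to ``results``), only the
    smallest-p block per gene is retained; unlabelled blocks are kept
    individually.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ParameterError("cutoff must lie in (0, 1]")
    if gene_labels is not None and len(gene_labels) != len(results):
        raise ValidationError("gene_labels must parallel results")
    kept = [
        (i, r) for i, r in enumerate(results) if r.p_hbcgm < cutoff
    ]
    if gene_labels is None:
        return [r for _, r in kept]
    best: dict[str, tuple[int, BlockAssociationResult]] = {}
    out = []
    for i, r in kept:
        g = gene_labels[i]
        if g is None:
            out.append((i, r))
        elif g not in best or r.p_hbcgm < best[g][1].p_hbcgm:
            best[g] = (i, r)
    out.extend(best.values())
    out.sort(key=lambda t: t[0])
    return [r for _, r in out]
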