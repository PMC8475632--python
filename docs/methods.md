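# Methods

## The inverted population-structure test

For a panel of n fully inbred (homozygous) strains, let y be the n×p matrix
of strain scores on the first p principal components of a genome-wide
relationship matrix. Instead of entering structure as a covariate of the
trait model, `strainps` treats y as the response:

    y = μ + Xβ + e

where X encodes a haplotype block's strain grouping (or a variant's allele
indicator) as a single categorical factor, μ is the grand mean and e the
residual. A one-factor MANOVA asks whether the grouping predicts genome-wide
relatedness. The test statistic is Pillai's trace V = tr(H(H+E)⁻¹) by
default (H and E the between- and within-group SSCP matrices), with the
standard F approximation; Wilks' Λ with Rao's F approximation is selectable.
Pillai was chosen as the default because it is the most robust of the
classical MANOVA statistics when group counts are small and unbalanced,
which is the norm at n ≤ 33 strains; for two groups it reduces to
Hotelling's T², where the F transform is exact under normality. Both
statistics are computed in-package and are cross-checked against an
independent MANOVA implementation in the test suite.

When the residual degrees of freedom fall below p (possible at n as low as
10 with p = 4), the parametric approximation is not trusted: the test falls
back to a label-permutation null of the Pillai statistic (10 000 permutations
by default) and flags the result `method="permutation"`.

p-values for a dataset's family of correlated blocks are adjusted by the
Benjamini–Hochberg step-up rule, p_adj(i) = min_{j≥i} min(1, p(j)·m/j) in
sorted order. The bare p·m/i formula without the cumulative minimum can be
non-monotone; the step-up rule is the procedure the FDR guarantee attaches
to. A block is PS⁺ iff p_adj < q (default q = 0.05); the boundary
p_adj = q is PS⁻ (the no-association null is not rejected there). The family
is per dataset by default; a cross-dataset mode is available.

### PC response: construction and size

PCs are eigenvectors of either the GRM (per-site standardized allele codes,
z = (x−p̄)/√(p̄(1−p̄)), averaged over co-observed sites per strain pair, no
minor-allele-frequency filter) or the IBS similarity matrix (fraction of
co-observed matching calls). Both matrices are Gower double-centered before
eigendecomposition. For a complete-data GRM this is a no-op (standardized
codes sum to zero across strains); for the IBS matrix it removes the
constant mean-similarity direction, whose raw leading eigenvector is
essentially the all-ones vector and would otherwise occupy a response
dimension while carrying no between-strain contrast. Scores are scaled by
√eigenvalue by default so scatter plots of PCs reproduce the matrix
geometry; an unscaled mode exists, and the MANOVA p-value is invariant to
any full-rank linear transformation of the response, including this scaling
(the test suite asserts this).

The response size p defaults to 4, the scree-elbow choice appropriate for a
49-strain diversity panel. `choose_n_pcs` implements the variance-share
alternative — retain every PC explaining more than 5 % of the relationship
variance (at least 2) — which adapts p to the panel actually analyzed: on a
simulated panel with g exchangeable sub-populations the structured subspace
has g−1 dimensions and the rule selects accordingly. This matters for
GRM/IBS agreement: the two matrices weight sites differently, so eigenvector
directions inside the *degenerate noise subspace* are essentially arbitrary
and uncorrelated between them, while the structured directions coincide.
With p sized to the structure, PS p-values from GRM- and IBS-derived PCs are
nearly identical (rank correlation ≈ 1 in the concordance test); a fixed
p = 4 on a 4-group panel includes one noise dimension and the agreement,
while still strong, is looser.

### Tracy–Widom assessment

Whether a leading eigenvalue exceeds its no-structure expectation is tested
Patterson-style: the remaining spectrum is renormalized, an effective marker
count is estimated by moment matching from the eigenvalue spread (capped at
the true marker count), and the centered, scaled leading eigenvalue is
referred to the Tracy–Widom β = 1 law. The TW distribution itself is
evaluated through Chiani's shifted-gamma approximation
(TW₁ ≈ Γ(k=46.446, θ=0.18605) − 9.84801), whose CDF error (~10⁻⁴) is far
below the 0.05 decision threshold; this replaces the more common tabulated
quantile interpolation because it is smooth and needs no embedded table.
The test is applied iteratively to successive eigenvalues.

## Haplotype blocks

A block is a maximal run of ≥ 4 consecutive filtered SNPs over which the
strains with complete calls occupy 2–5 distinct allele strings. Maximality
is realized per (start, budget H): the interval is emitted only when
extending one SNP right or left would push the distinct-string count above
H or run off the chromosome; budgets 2–5 are pooled. Blocks may overlap. A
block nested in a larger emitted block with the identical strain partition
is removed, so a SNP only extends a block if it adds a haplotype.
Equivalence with exhaustive enumeration over all intervals and budgets is
asserted on random small panels (with and without missing data).

Strains with a missing call inside a block are unassigned rather than
imputed, and unassigned strains are ignored when counting distinct strings —
otherwise missingness would inflate the haplotype count. Variant filtering
ahead of block construction keeps sites that are polymorphic among the
phenotyped strains and have at least 8 unambiguous calls.

## Trait association, effect size, power, QC

Association uses one value per strain (the strain mean); replicates enter
only dataset QC. The block ANOVA returns F, p, η² = SSB/SST. Perfect
separation (zero within-group variance, unequal means) returns p exactly 0
with an explicit unbounded-F flag, keeping downstream sorting well-defined —
this is the regime of a fully penetrant causative block matched by a binary
phenotype. A constant phenotype returns F = 0, p = 1.

Power of the one-way ANOVA at effect size η² uses the noncentral
F(k−1, n−k, λ) with λ = n·η²/(1−η²) beyond the central critical value
F_{1−α}. The upper tail is used: only the upper tail satisfies
power(η²=0) = α and grows with λ (a lower-tail reading of the same
quantities is the type-II error). At λ = 0 the noncentral law reduces to the
central F analytically, and that limit is evaluated through the central
distribution so the identity power = α holds to machine precision. λ is
used as stated for unequal group sizes as well, although its derivation
assumes equal sizes; at the panel sizes involved the distinction is below
the resolution of any decision made with it.

Dataset QC accepts a dataset iff every strain mean comes from more than 5
animals and the inter- vs intra-strain one-way ANOVA (replicate-level when
available, otherwise reconstructed from mean/SD/count summaries) gives
p < 10⁻¹⁰; in bulk mode categorical datasets are also rejected. Note the
screen's noncentrality is n·η²/(1−η²) regardless of replicate count, so a
synthetic dataset whose heritability comes from a single planted locus needs
η² ≈ 0.85–0.9 to pass — real panel datasets clear it through many-locus
strain differences.

## The synthetic-data generator

The generator emulates the study system, not any particular dataset: a panel
of homozygous strains from up to 4 sub-populations under the
Balding–Nichols model (ancestral frequency per site uniform on
(0.05, 0.5]; per-group frequency Beta with mean p and variance
F_ST·p(1−p); one Bernoulli allele per strain). Defaults encode the panel
composition the package targets — group sizes 7/14/23/5 (49 strains),
F_ST = 0.3, 5 000 markers desk-scale, 8 replicate animals per strain with
unit within-strain SD. Strains are exchangeable within groups: no pedigree,
no within-group kinship gradients, no recombination maps. Planted causative
blocks overwrite a run of sites with a two-haplotype carrier/non-carrier
pattern. Phenotypes offset carrier strain means by δ solving
η² = σ_B²/(σ_B²+σ_W²) with σ_B² = f(1−f)δ² (f the carrier fraction) and
σ_W² = within-SD²/replicates (the sampling variance of an observed strain
mean). The realized η̂² then carries the usual small-sample upward bias,
≈ (λ+k−1)/(λ+n−1); at target 0.6 with n = 30 this is about +0.02, well
inside the recovery tolerance the tests assert.

What passing tests on these panels do **not** show: behavior under
hierarchical or admixed relatedness, under genotyping error, or at real
marker density. One finite-marker artifact is handled explicitly: a planted
block's own sites sit in the relationship matrix and, being in perfect LD
with the carrier contrast, add an eigenvalue boost of roughly
(block SNPs × n)/M along it. At M in the low thousands this can rotate a
low-variance PC toward the carrier direction and make a
structure-orthogonal causative block look PS-associated; at real density
(tens of millions of markers) the fraction is nil. End-to-end planted-block
tests therefore simulate 20 000 markers, where the boost is under 1 % of a
noise eigenvalue.

## Pipeline and summaries

`run_pipeline` executes QC → variant filter → block construction → block
ANOVA → correlated-block selection (p < 0.01, strict) → GRM (or IBS) → PCA
(p = 4 default) → PS MANOVA → BH within the dataset family → PS⁺/PS⁻ →
summary, deterministically given the run seed (permutation-fallback seeds
are derived per block from it). Per-dataset summaries report total
correlated blocks, PS⁻/PS⁺ counts and the percent-PS⁻ bin; bins are
[0, 25), [25, 50), [50, 75), [75, 100] — an exact 50 % falls in the third
bin. `summarize_vs_strain_count` aggregates summaries by panel size with
box-plot statistics (quartiles, median) of the percent distributions.

## Numerical choices and degenerate inputs

- Within-group variance ≤ 10⁻¹² × max(SST, 1) is treated as perfect
  separation; SST below the same tolerance as a constant response.
- Eigenvalues below 10⁻¹⁰ of the maximum are dropped before the TW
  normalization; negative (centered-IBS) eigenvalues are clipped to zero for
  score scaling but retained in variance fractions.
- Haplotype labels are numbered by first occurrence in strain order, so the
  labels are deterministic and the induced partition is invariant to strain
  reordering.
- BH uses a stable mergesort throughout, making ties reproducible.
- LD pruning slides half-window steps and removes the later-positioned site
  of a violating pair; a brute-force within-window post-check is asserted in
  tests.
- Multi-allelic VCF records are reduced to the primary alternate; calls
  carrying a secondary alternate become missing and are counted in the read
  warning summary, as are heterozygous and half-missing genotypes.

## Known limitations

- The generator's exchangeable-group model cannot express the nested
  relatedness of real strain families (e.g. closely related classical
  sub-populations vs highly diverged wild-derived strains); a single F_ST
  compresses that hierarchy to one knob.
- The parametric MANOVA p is an approximation when the response is made of
  eigenvector scores (fixed column norms, exact orthogonality): measured
  against permutation nulls it is accurate to a few hundredths and slightly
  conservative in the tail used for classification.
- No linear-mixed-model trait correction, no model-based (admixture-style)
  clustering, no phylogeny-based structure methods, and no liftover or
  variant calling: inputs are assumed to be clean homozygous calls.
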