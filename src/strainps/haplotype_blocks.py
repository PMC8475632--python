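"""Maximal haplotype-block construction for homozygous strain panels.

A haplotype block is a run of at least 4 consecutive SNPs over which the
strains with complete calls fall into between 2 and 5 distinct allele strings
(haplotypes).  Blocks are built "maximally": for a haplotype budget H in
{2..5}, an interval is emitted only when extending it one site to the right
or to the left would push the number of distinct strings above H (or run off
the chromosome).  Blocks may overlap; a block nested inside a larger emitted
block that induces the identical strain partition is removed, so extra SNPs
enter a block only when they add haplotypes.

Strains with one or more missing calls inside an interval are unassigned
there and are ignored when counting distinct strings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import StrainPSError, ValidationError
from .genotype_io import MISSING, GenotypeMatrix

MIN_SNPS = 4
MAX_HAPLOTYPES = 5
MIN_UNAMBIGUOUS_CALLS = 8

UNASSIGNED = 0  # strain-group label for strains with missing calls in a block


@dataclass
class HaplotypeBlock:
    """A genomic interval partitioning strains into 2-5 haplotype groups.

    ``strain_groups`` holds one label per strain in panel order: 1..H by
    first occurrence, or ``UNASSIGNED`` (0) for strains with a missing call
    inside the block.  Intervals are 1-based and closed (``bp_range``);
    ``snp_index_range`` indexes columns of the source matrix, also inclusive.
    """

    chrom: str
    snp_index_range: tuple[int, int]
    bp_range: tuple[int, int]
    n_snps: int
    n_haplotypes: int
    strain_groups: np.ndarray
    haplotype_strings: tuple[str, ...]
    strain_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.strain_groups = np.asarray(self.strain_groups, dtype=int)
        if self.n_snps < MIN_SNPS:
            raise ValidationError("a block needs at least 4 SNPs")
        if not 2 <= self.n_haplotypes <= MAX_HAPLOTYPES:
            raise ValidationError("haplotype count must lie in 2..5")
        if len(self.haplotype_strings) != self.n_haplotypes:
            raise ValidationError("haplotype_strings length mismatch")
        labels = set(self.strain_groups) - {UNASSIGNED}
        if labels != set(range(1, self.n_haplotypes + 1)):
            raise ValidationError("strain group labels must cover 1..H")

    def partition_key(self) -> tuple:
        """Canonical form of the induced strain partition (first-occurrence
        relabelling; unassigned strains keep a distinct marker)."""
        return _canonical_labels(self.strain_groups)

    def groups_for(self, strain_subset: list[str]) -> np.ndarray:
        idx = [self.strain_names.index(s) for s in strain_subset]
        return self.strain_groups[idx]


def _canonical_labels(labels: np.ndarray) -> tuple:
    out, mapping, nxt = [], {}, 1
    for lab in labels:
        if lab == UNASSIGNED:
            out.append(-1)
            continue
        if lab not in mapping:
            mapping[lab] = nxt
            nxt += 1
        out.append(mapping[lab])
    return tuple(out)


# ---------------------------------------------------------------------------
# variant filtering
# ---------------------------------------------------------------------------

def filter_variants(
    genotypes: GenotypeMatrix,
    trait_strains: list[str],
    min_calls: int = MIN_UNAMBIGUOUS_CALLS,
) -> GenotypeMatrix:
    """Keep sites usable for mapping on the phenotyped strains.

    A site is retained iff, restricted to ``trait_strains``, it is polymorphic
    among the called strains and at least ``min_calls`` strains have
    unambiguous (non-missing) calls.  Returns the column-filtered matrix
    restricted to ``trait_strains``.
    """
    if len(trait_strains) < 2:
        raise ValidationError("need at least 2 trait strains")
    sub = genotypes.subset_strains(list(trait_strains))
    calls = sub.calls
    called = calls != MISSING
    n_called = called.sum(axis=0)
    n_alt = ((calls == 1) & called).sum(axis=0)
    polymorphic = (n_alt > 0) & (n_alt < n_called)
    keep = polymorphic & (n_called >= min_calls)
    return sub.subset_sites(keep)


# ---------------------------------------------------------------------------
# block construction
# ---------------------------------------------------------------------------

def _distinct_over(calls: np.ndarray, s: int, e: int) -> int:
    """Distinct complete allele strings over columns [s, e] (direct)."""
    window = calls[:, s : e + 1]
    assigned = ~(window == MISSING).any(axis=1)
    sub = window[assigned]
    if sub.shape[0] == 0:
        return 0
    return np.unique(sub, axis=0).shape[0]


def build_blocks(genotypes: GenotypeMatrix) -> list[HaplotypeBlock]:
    """Construct all maximal haplotype blocks of a (filtered) matrix.

    Output is deterministic, ordered by (chromosome, start, end, H), with
    nested blocks carrying an identical strain partition removed.
    """
    blocks: list[HaplotypeBlock] = []
    if genotypes.n_sites == 0:
        return blocks
    calls = genotypes.calls
    chrom_arr = genotypes.chrom
    # contiguous runs of equal chromosome (positions already sorted per chrom)
    boundaries = [0]
    for j in range(1, genotypes.n_sites):
        if chrom_arr[j] != chrom_arr[j - 1]:
            boundaries.append(j)
    boundaries.append(genotypes.n_sites)
    seen: dict[tuple, HaplotypeBlock] = {}
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        _build_chromosome(genotypes, calls, b0, b1, seen)
    blocks = _remove_nested(list(seen.values()))
    blocks.sort(key=lambda b: (str(b.chrom), b.snp_index_range, b.n_haplotypes))
    return blocks


def _build_chromosome(
    gm: GenotypeMatrix,
    calls: np.ndarray,
    lo: int,
    hi: int,
    seen: dict,
) -> None:
    n = calls.shape[0]
    # per-strain indices of missing calls inside [lo, hi), for the stop rule
    missing_ahead = [
        np.flatnonzero(calls[i, lo:hi] == MISSING) + lo for i in range(n)
    ]
    for s in range(lo, hi):
        assigned = np.ones(n, dtype=bool)
        codes = np.zeros(n, dtype=np.int64)
        for e in range(s, hi):
            col = calls[:, e]
            assigned = assigned & (col != MISSING)
            if assigned.any():
                pairs = codes[assigned] * 3 + col[assigned]
                uniq, inv = np.unique(pairs, return_inverse=True)
                codes = codes.copy()
                codes[assigned] = inv
                d = uniq.shape[0]
            else:
                d = 0
            if e - s + 1 >= MIN_SNPS and 2 <= d <= MAX_HAPLOTYPES:
                # the block is emitted iff the smallest admissible budget
                # H = d is both right- and left-maximal; larger budgets are
                # strictly harder to satisfy on both sides
                d_next = (
                    _distinct_next(calls, s, e, hi, assigned, codes)
                    if e + 1 < hi
                    else None
                )
                right_max = d_next is None or d_next > d
                left_max = s == lo or _distinct_over(calls, s - 1, e) > d
                if right_max and left_max:
                    _emit(gm, s, e, assigned, codes, d, seen)
            if (d > MAX_HAPLOTYPES or d == 0) and not _any_missing_ahead(
                missing_ahead, assigned, e, hi
            ):
                break


def _distinct_next(
    calls: np.ndarray,
    s: int,
    e: int,
    hi: int,
    assigned: np.ndarray,
    codes: np.ndarray,
) -> int:
    col = calls[:, e + 1]
    nxt = assigned & (col != MISSING)
    if not nxt.any():
        return 0
    return np.unique(codes[nxt] * 3 + col[nxt]).shape[0]


def _any_missing_ahead(
    missing_ahead: list[np.ndarray], assigned: np.ndarray, e: int, hi: int
) -> bool:
    for i in np.flatnonzero(assigned):
        arr = missing_ahead[i]
        if arr.size and arr[-1] > e:
            return True
    return False


def _emit(
    gm: GenotypeMatrix,
    s: int,
    e: int,
    assigned: np.ndarray,
    codes: np.ndarray,
    d: int,
    seen: dict,
) -> None:
    key = (str(gm.chrom[s]), s, e)
    if key in seen:
        return
    groups = np.zeros(gm.n_strains, dtype=int)
    mapping: dict[int, int] = {}
    strings: list[str] = []
    for i in np.flatnonzero(assigned):
        c = codes[i]
        if c not in mapping:
            mapping[c] = len(mapping) + 1
            strings.append("".join(str(int(x)) for x in gm.calls[i, s : e + 1]))
        groups[i] = mapping[c]
    seen[key] = HaplotypeBlock(
        chrom=str(gm.chrom[s]),
        snp_index_range=(s, e),
        bp_range=(int(gm.pos_bp[s]), int(gm.pos_bp[e])),
        n_snps=e - s + 1,
        n_haplotypes=d,
        strain_groups=groups,
        haplotype_strings=tuple(strings),
        strain_names=tuple(gm.strain_names),
    )


def _remove_nested(blocks: list[HaplotypeBlock]) -> list[HaplotypeBlock]:
    """Drop blocks strictly contained in a larger block with the identical
    strain partition."""
    by_partition: dict[tuple, list[HaplotypeBlock]] = {}
    for b in blocks:
        by_partition.setdefault((b.chrom, b.partition_key()), []).append(b)
    keep: list[HaplotypeBlock] = []
    for group in by_partition.values():
        for b in group:
            s, e = b.snp_index_range
            nested = any(
                (a.snp_index_range != b.snp_index_range)
                and a.snp_index_range[0] <= s
                and a.snp_index_range[1] >= e
                for a in group
            )
            if not nested:
                keep.append(b)
    return keep


# ---------------------------------------------------------------------------
# haplotype assignment
# ---------------------------------------------------------------------------

def assign_haplotypes(
    block: HaplotypeBlock, genotypes: GenotypeMatrix
) -> np.ndarray:
    """Label each strain with its haplotype group over ``block``.

    Strains whose allele string over the block matches the h-th haplotype
    string get label h (numbered by first occurrence in strain order); strains
    with any missing call are ``UNASSIGNED``.  A complete string matching no
    recorded haplotype indicates the block does not belong to this matrix.
    """
    s, e = block.snp_index_range
    if e >= genotypes.n_sites:
        raise ValidationError("block indices exceed the genotype matrix")
    window = genotypes.calls[:, s : e + 1]
    labels = np.zeros(genotypes.n_strains, dtype=int)
    lookup = {h: i + 1 for i, h in enumerate(block.haplotype_strings)}
    for i in range(genotypes.n_strains):
        row = window[i]
        if (row == MISSING).any():
            continue
        string = "".join(str(int(x)) for x in row)
        if string not in lookup:
            raise StrainPSError(
                f"strain {genotypes.strain_names[i]} carries haplotype "
                f"{string} not recorded in the block"
            )
        labels[i] = lookup[string]
    return labels
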