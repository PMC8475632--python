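"""End-to-end orchestration: QC -> blocks -> trait ANOVA -> PS test -> summary.

For each phenotype dataset the pipeline (i) applies dataset QC, (ii) filters
variants to those informative for the phenotyped strains, (iii) constructs
maximal haplotype blocks, (iv) scores block-trait association and keeps the
correlated blocks (p < 0.01), (v) computes the GRM (or IBS) and its first
p = 4 principal components, (vi) runs the PS MANOVA on each correlated block,
(vii) Benjamini-Hochberg adjusts within the dataset's block family and calls
PS+/PS-, and (viii) summarizes the PS composition.  All stages are
deterministic given the run seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateGroupingError, StrainPSError
from .genotype_io import GenotypeMatrix, PhenotypeDataset, empty_block_table
from .haplotype_blocks import (
    MIN_UNAMBIGUOUS_CALLS,
    build_blocks,
    filter_variants,
)
from .population_structure import (
    DEFAULT_N_PCS,
    compute_grm,
    compute_ibs,
    pca,
)
from .ps_association import FDR_Q, make_ps_results, ps_manova_test
from .trait_association import (
    HBCGM_P_CUTOFF,
    block_anova,
    qc_dataset,
    select_correlated,
)

logger = logging.getLogger("strainps")

#: Fig-2-style bins of the percent of PS- blocks; 50 falls in the third bin
PS_MINUS_BINS = ((0.0, 25.0, "0-24"), (25.0, 50.0, "25-49"),
                 (50.0, 75.0, "50-74"), (75.0, 100.0, "75-100"))


def percent_bin(percent: float) -> str:
    for lo, hi, label in PS_MINUS_BINS:
        if lo <= percent < hi:
            return label
    if percent == 100.0:
        return "75-100"
    raise ValueError(f"percent {percent} outside [0, 100]")


@dataclass
class RunConfig:
    """Declarative parameters of an end-to-end run (all thresholds visible)."""

    hbcgm_cutoff: float = HBCGM_P_CUTOFF
    fdr_q: float = FDR_Q
    n_pcs: int = DEFAULT_N_PCS
    pc_source: str = "GRM"  # {"GRM", "IBS"}
    statistic: str = "pillai"
    apply_qc: bool = True
    min_calls: int = MIN_UNAMBIGUOUS_CALLS
    seed: int = 0
    gene_labels: pd.DataFrame | None = None  # BED intervals for labelling


@dataclass
class DatasetSummary:
    """PS composition of one dataset's correlated blocks."""

    dataset_id: str
    n_strains: int
    total_blocks: int
    ps_minus: int
    ps_plus: int
    percent_ps_minus: float | None
    bin: str | None
    status: str = "ok"
    dropped_strains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.total_blocks:
            assert self.ps_minus + self.ps_plus == self.total_blocks
            expect = 100.0 * self.ps_minus / self.total_blocks
            assert abs(self.percent_ps_minus - expect) < 1e-9

    def to_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "n_strains": self.n_strains,
            "total_blocks": self.total_blocks,
            "ps_minus": self.ps_minus,
            "ps_plus": self.ps_plus,
            "percent_ps_minus": self.percent_ps_minus,
            "bin": self.bin,
            "status": self.status,
            "dropped_strains": list(self.dropped_strains),
        }


def _gene_for_block(block, bed: pd.DataFrame | None) -> str | None:
    if bed is None:
        return None
    lo, hi = block.bp_range
    hit = bed[
        (bed["chrom"] == block.chrom)
        & (bed["start_bp"] <= hi)
        & (bed["end_bp"] >= lo)
    ]
    return None if hit.empty else str(hit.iloc[0]["name"])


def run_pipeline(
    genotypes: GenotypeMatrix,
    datasets: list[PhenotypeDataset] | PhenotypeDataset,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, list[DatasetSummary]]:
    """Run the full analysis; returns (block table, per-dataset summaries)."""
    if isinstance(datasets, PhenotypeDataset):
        datasets = [datasets]
    config = config or RunConfig()
    tables, summaries = [], []
    for ds_i, ds in enumerate(datasets):
        try:
            table, summary = _run_dataset(genotypes, ds, config, ds_i)
        except StrainPSError as e:
            raise type(e)(f"dataset {ds.dataset_id}: {e}") from e
        tables.append(table)
        summaries.append(summary)
    table = (
        pd.concat(tables, ignore_index=True) if tables else empty_block_table()
    )
    return table, summaries


def _run_dataset(
    genotypes: GenotypeMatrix,
    ds: PhenotypeDataset,
    config: RunConfig,
    ds_index: int,
):
    if config.apply_qc:
        decision = qc_dataset(ds)
        if not decision.accepted:
            logger.info("dataset %s rejected: %s", ds.dataset_id, decision.reasons)
            return empty_block_table(), DatasetSummary(
                dataset_id=ds.dataset_id,
                n_strains=ds.n_strains,
                total_blocks=0,
                ps_minus=0,
                ps_plus=0,
                percent_ps_minus=None,
                bin=None,
                status="rejected:" + ",".join(decision.reasons),
            )
    genotyped = set(genotypes.strain_names)
    trait_strains = [s for s in ds.strains if s in genotyped]
    dropped = tuple(s for s in ds.strains if s not in genotyped)
    if dropped:
        logger.info(
            "dataset %s: dropping %d unmeasurable strains %s",
            ds.dataset_id, len(dropped), dropped,
        )
    filtered = filter_variants(genotypes, trait_strains, config.min_calls)
    logger.info(
        "dataset %s: %d/%d sites pass variant filters",
        ds.dataset_id, filtered.n_sites, genotypes.n_sites,
    )
    blocks = build_blocks(filtered)
    results = []
    for b in blocks:
        try:
            results.append(block_anova(b, ds))
        except DegenerateGroupingError:
            continue
    gene_labels = (
        [_gene_for_block(r.block, config.gene_labels) for r in results]
        if config.gene_labels is not None
        else None
    )
    correlated = select_correlated(results, config.hbcgm_cutoff, gene_labels)
    logger.info(
        "dataset %s: %d blocks, %d scored, %d correlated (p < %g)",
        ds.dataset_id, len(blocks), len(results), len(correlated),
        config.hbcgm_cutoff,
    )
    matrix = (
        compute_grm(filtered) if config.pc_source == "GRM" else compute_ibs(filtered)
    )
    n = len(trait_strains)
    coords = pca(matrix, p=min(config.n_pcs, n - 1))
    ps_rows = []
    if correlated:
        p_raws, methods = [], []
        for i, r in enumerate(correlated):
            fit = ps_manova_test(
                r.block.strain_groups,
                coords,
                statistic=config.statistic,
                seed=_stable_seed(config.seed, ds_index, i),
            )
            p_raws.append(fit.p_value)
            methods.append(fit.method)
        ps_results = make_ps_results(
            correlated, p_raws, q=config.fdr_q, pc_source=config.pc_source
        )
        for res, meth in zip(ps_results, methods):
            res.method = meth
        ps_rows = ps_results
    table = _to_table(ds, correlated, ps_rows, gene_labels, config)
    n_minus = sum(1 for r in ps_rows if r.classification == "PS-")
    n_plus = len(ps_rows) - n_minus
    total = len(ps_rows)
    percent = 100.0 * n_minus / total if total else None
    summary = DatasetSummary(
        dataset_id=ds.dataset_id,
        n_strains=n,
        total_blocks=total,
        ps_minus=n_minus,
        ps_plus=n_plus,
        percent_ps_minus=percent,
        bin=percent_bin(percent) if total else None,
        dropped_strains=dropped,
    )
    return table, summary


def _stable_seed(seed: int, ds_index: int, block_index: int) -> int:
    return int(
        np.random.SeedSequence([seed, ds_index, block_index]).generate_state(1)[0]
        % (2**31)
    )


def _to_table(ds, correlated, ps_rows, gene_labels, config) -> pd.DataFrame:
    rows = []
    ps_by_target = {id(r.target): r for r in ps_rows}
    for i, r in enumerate(correlated):
        b = r.block
        ps = ps_by_target.get(id(r))
        rows.append(
            {
                "dataset_id": ds.dataset_id,
                "chrom": b.chrom,
                "start_bp": b.bp_range[0],
                "end_bp": b.bp_range[1],
                "n_snps": b.n_snps,
                "n_haplotypes": b.n_haplotypes,
                "strain_groups": ",".join(
                    f"{s}:{g}" for s, g in zip(b.strain_names, b.strain_groups)
                ),
                "F_stat": r.F_statistic,
                "p_hbcgm": r.p_hbcgm,
                "eta2": r.eta2,
                "ps_p": ps.p_raw if ps else np.nan,
                "ps_p_adj": ps.p_adj if ps else np.nan,
                "ps_class": ps.classification if ps else "",
                "ps_method": ps.method if ps else "",
                "pc_source": config.pc_source,
                "gene": (gene_labels[i] or "") if gene_labels else "",
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["p_hbcgm", "chrom", "start_bp"], kind="mergesort"
        ).reset_index(drop=True)
    return df


def summarize_vs_strain_count(summaries: list[DatasetSummary]) -> pd.DataFrame:
    """Aggregate dataset summaries by strain count.

    Per strain count: mean numbers of total/PS-/PS+ blocks and the quartiles
    and median of the percent PS- and PS+ distributions (box-plot summaries).
    """
    if not summaries:
        raise ValueError("need at least one summary")
    rows = [
        s for s in summaries if s.status == "ok" and s.total_blocks > 0
    ]
    records = []
    for n in sorted({s.n_strains for s in rows}):
        grp = [s for s in rows if s.n_strains == n]
        pm = np.array([s.percent_ps_minus for s in grp])
        records.append(
            {
                "n_strains": n,
                "n_datasets": len(grp),
                "mean_total_blocks": float(np.mean([s.total_blocks for s in grp])),
                "mean_ps_minus": float(np.mean([s.ps_minus for s in grp])),
                "mean_ps_plus": float(np.mean([s.ps_plus for s in grp])),
                "pct_ps_minus_q25": float(np.percentile(pm, 25)),
                "pct_ps_minus_median": float(np.median(pm)),
                "pct_ps_minus_q75": float(np.percentile(pm, 75)),
                "pct_ps_plus_q25": float(np.percentile(100 - pm, 25)),
                "pct_ps_plus_median": float(np.median(100 - pm)),
                "pct_ps_plus_q75": float(np.percentile(100 - pm, 75)),
            }
        )
    return pd.DataFrame(records)
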