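"""Input/output layer: genotypes, phenotypes, block tables, BED intervals.

The internal genotype representation is haploid: inbred strains are fully
homozygous, so each strain carries a single allele code per site, one of
``0`` (reference), ``1`` (alternate) or ``MISSING``.  Heterozygous or
half-missing diploid VCF genotypes are mapped to missing and counted in a
warning summary rather than rejected.  Multi-allelic VCF records are reduced
to the primary alternate allele; calls carrying a secondary alternate become
missing (counted separately in the warning summary).

Coordinate conventions: variant positions and block intervals are 1-based and
closed on both ends, matching VCF POS.  BED input (0-based, half-open) is
converted on read.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

MISSING: int = -1

#: stable column order for block-table output
BLOCK_TABLE_COLUMNS = [
    "chrom",
    "start_bp",
    "end_bp",
    "n_snps",
    "n_haplotypes",
    "strain_groups",
    "F_stat",
    "p_hbcgm",
    "eta2",
    "ps_p",
    "ps_p_adj",
    "ps_class",
    "ps_method",
    "pc_source",
    "gene",
]

_FLOAT_COLS = ("F_stat", "p_hbcgm", "eta2", "ps_p", "ps_p_adj")


@dataclass
class GenotypeMatrix:
    """Homozygous allele calls for ``n`` strains at ``M`` ordered variants.

    ``calls`` is an ``n x M`` int8 array over {0, 1, MISSING}.  Positions are
    strictly increasing within each chromosome.
    """

    strain_names: list[str]
    chrom: np.ndarray  # (M,) str
    pos_bp: np.ndarray  # (M,) int64, 1-based
    alleles: np.ndarray  # (M, 2) str: ref, alt
    calls: np.ndarray  # (n, M) int8

    def __post_init__(self) -> None:
        self.strain_names = list(self.strain_names)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n, m = self.calls.shape
        if n < 2:
            raise ValidationError("a genotype matrix needs at least 2 strains")
        if m < 1:
            raise ValidationError("a genotype matrix needs at least 1 variant")
        if len(self.strain_names) != n:
            raise ValidationError("strain_names length does not match calls")
        if len(set(self.strain_names)) != n:
            raise ValidationError("duplicate strain names")
        if not (self.chrom.shape == self.pos_bp.shape == (m,)):
            raise ValidationError("per-variant arrays must have length M")
        if self.alleles.shape != (m, 2):
            raise ValidationError("alleles must be (M, 2)")
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise ValidationError("calls must be 0, 1 or missing")
        for c in pd.unique(self.chrom):
            pos = self.pos_bp[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(
                    f"positions not strictly increasing on {c}"
                )

    # -- convenience ------------------------------------------------------
    @property
    def n_strains(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def strain_index(self, names: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.strain_names)}
        try:
            return np.array([lookup[s] for s in names], dtype=int)
        except KeyError as e:
            raise ValidationError(f"unknown strain {e.args[0]!r}") from None

    def subset_strains(self, names: list[str]) -> "GenotypeMatrix":
        idx = self.strain_index(names)
        return GenotypeMatrix(
            [self.strain_names[i] for i in idx],
            self.chrom,
            self.pos_bp,
            self.alleles,
            self.calls[idx],
        )

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        if keep.size == 0:
            # empty matrix: represented with zero columns, bypass validation
            out = GenotypeMatrix.__new__(GenotypeMatrix)
            out.strain_names = list(self.strain_names)
            out.chrom = self.chrom[:0]
            out.pos_bp = self.pos_bp[:0]
            out.alleles = self.alleles[:0]
            out.calls = self.calls[:, :0]
            return out
        return GenotypeMatrix(
            self.strain_names,
            self.chrom[keep],
            self.pos_bp[keep],
            self.alleles[keep],
            self.calls[:, keep],
        )


@dataclass
class ReadWarnings:
    """Counts of calls masked while reading genotypes."""

    heterozygous: int = 0
    half_missing: int = 0
    secondary_alt: int = 0

    @property
    def total(self) -> int:
        return self.heterozygous + self.half_missing + self.secondary_alt


@dataclass
class PhenotypeDataset:
    """MPD-style per-strain phenotype summaries.

    One record per strain: mean response, standard deviation and number of
    animals measured; replicate-level values are optional.  Categorical
    datasets carry integer-coded class labels in ``mean``.
    """

    dataset_id: str
    sex: str  # {"F", "M", "both"}
    categorical: bool
    strains: list[str]
    mean: np.ndarray
    sd: np.ndarray
    n_animals: np.ndarray
    replicates: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.strains = list(self.strains)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n_animals = np.asarray(self.n_animals, dtype=int)
        if len(set(self.strains)) != len(self.strains):
            raise ValidationError("duplicate strain names in phenotype dataset")
        k = len(self.strains)
        if not (self.mean.shape == self.sd.shape == self.n_animals.shape == (k,)):
            raise ValidationError("per-strain arrays must share one length")
        if k == 0:
            raise ValidationError("phenotype dataset has no strains")
        if np.any(self.n_animals < 1):
            raise ValidationError("n_animals must be >= 1")
        if np.any(self.sd < 0):
            raise ValidationError("sd must be >= 0")
        if self.categorical and not np.allclose(self.mean, np.round(self.mean)):
            raise ValidationError("categorical values must be integer-coded")

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def value_for(self, strain: str) -> float:
        return float(self.mean[self.strains.index(strain)])


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(
    path: str, format: str = "auto"
) -> tuple[GenotypeMatrix, ReadWarnings]:
    """Read strain genotypes from VCF or the tabular format.

    Returns the validated matrix together with a summary of calls that were
    masked to missing (heterozygous, half-missing, secondary-alternate).
    """
    if format == "auto":
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "table"
    if format == "vcf":
        return _read_vcf(path)
    if format == "table":
        return _read_table(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: str) -> tuple[GenotypeMatrix, ReadWarnings]:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
        samples = list(vcf.samples)
    except Exception as e:  # htslib raises bare Exceptions
        raise FormatError(f"cannot parse VCF {path}: {e}") from e
    if len(set(samples)) != len(samples):
        raise ValidationError("duplicate strain in VCF header")
    warn = ReadWarnings()
    chroms, poss, alleles, cols = [], [], [], []
    for lineno, rec in enumerate(vcf, start=1):
        col = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            a = gt[:-1]  # final element is the phased flag
            observed = [x for x in a if x >= 0]
            if not observed or len(observed) < len(a):
                if observed:
                    warn.half_missing += 1
                continue
            if len(set(observed)) > 1:
                warn.heterozygous += 1
                continue
            allele = observed[0]
            if allele > 1:
                warn.secondary_alt += 1
                continue
            col[i] = allele
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        alt = rec.ALT[0] if rec.ALT else "."
        if len(rec.ALT) > 1:
            warnings.warn(
                f"multi-allelic site {rec.CHROM}:{rec.POS}: keeping primary "
                f"alternate {alt!r}",
                stacklevel=2,
            )
        alleles.append((rec.REF, alt))
        cols.append(col)
    if not cols:
        raise FormatError(f"VCF {path} contains no variant records")
    gm = GenotypeMatrix(
        samples,
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(alleles, dtype=object),
        np.column_stack(cols),
    )
    return gm, warn


_TABLE_FIXED = ["chrom", "pos", "ref", "alt"]


def _read_table(path: str) -> tuple[GenotypeMatrix, ReadWarnings]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    raw_strains = [c for c in header if c not in _TABLE_FIXED]
    if len(set(raw_strains)) != len(raw_strains):
        raise ValidationError("duplicate strain column")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as e:
        raise FormatError(f"cannot parse genotype table {path}: {e}") from e
    missing_cols = [c for c in _TABLE_FIXED if c not in df.columns]
    if missing_cols:
        raise FormatError(
            f"genotype table {path} lacks columns {missing_cols}", line=1
        )
    strains = [c for c in df.columns if c not in _TABLE_FIXED]
    calls = np.full((len(strains), len(df)), MISSING, dtype=np.int8)
    for j, s in enumerate(strains):
        vals = df[s].to_numpy()
        for i, v in enumerate(vals):
            if v in ("0", "1"):
                calls[j, i] = int(v)
            elif v in (".", "NA", "", None) or pd.isna(v):
                continue
            else:
                raise FormatError(
                    f"invalid call {v!r} for strain {s}", line=i + 2
                )
    gm = GenotypeMatrix(
        strains,
        df["chrom"].to_numpy(dtype=object),
        df["pos"].astype(np.int64).to_numpy(),
        np.array(list(zip(df["ref"], df["alt"])), dtype=object),
        calls,
    )
    return gm, ReadWarnings()


def write_genotypes(gm: GenotypeMatrix, path: str, format: str = "auto") -> str:
    """Write a GenotypeMatrix as VCF (homozygous diploid GTs) or as a table."""
    if format == "auto":
        format = "vcf" if str(path).endswith(".vcf") else "table"
    if format == "vcf":
        _write_vcf(gm, path)
    elif format == "table":
        _write_table(gm, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    return str(path)


_GT_CODE = {0: "0/0", 1: "1/1", MISSING: "./."}


def _write_vcf(gm: GenotypeMatrix, path: str) -> None:
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=strainps\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    for c in pd.unique(gm.chrom):
        last = int(gm.pos_bp[gm.chrom == c].max())
        buf.write(f"##contig=<ID={c},length={last + 1}>\n")
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.strain_names)
        + "\n"
    )
    for j in range(gm.n_sites):
        ref, alt = gm.alleles[j]
        gts = "\t".join(_GT_CODE[int(x)] for x in gm.calls[:, j])
        buf.write(
            f"{gm.chrom[j]}\t{gm.pos_bp[j]}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def _write_table(gm: GenotypeMatrix, path: str) -> None:
    code = {0: "0", 1: "1", MISSING: "."}
    df = pd.DataFrame(
        {
            "chrom": gm.chrom,
            "pos": gm.pos_bp,
            "ref": [a for a, _ in gm.alleles],
            "alt": [b for _, b in gm.alleles],
        }
    )
    for i, s in enumerate(gm.strain_names):
        df[s] = [code[int(x)] for x in gm.calls[i]]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

_PHENO_REQUIRED = ["strain", "mean", "sd", "nindiv"]


def read_phenotypes(path: str) -> PhenotypeDataset:
    """Read a tab-separated phenotype table.

    Required columns: ``strain``, ``mean``, ``sd``, ``nindiv``.  Optional
    replicate columns are named ``rep1`` .. ``repK`` (NA-padded).  Dataset
    metadata may be given in leading comment lines of the form
    ``#key=value`` for keys ``dataset_id``, ``sex`` and ``categorical``.
    """
    meta = {"dataset_id": str(path), "sex": "both", "categorical": "false"}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            if "=" in line:
                k, v = line[1:].strip().split("=", 1)
                meta[k.strip()] = v.strip()
        else:  # file exhausted (empty or comments only)
            raise ValidationError(f"phenotype file {path} has no data rows")
    df = pd.read_csv(path, sep="\t", skiprows=header_lines)
    if df.empty:
        raise ValidationError(f"phenotype file {path} has no data rows")
    missing_cols = [c for c in _PHENO_REQUIRED if c not in df.columns]
    if missing_cols:
        raise ValidationError(
            f"phenotype file {path} lacks required columns {missing_cols}"
        )
    for col in ("mean", "sd"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValidationError(f"column {col!r} is not numeric in {path}")
    rep_cols = sorted(
        (c for c in df.columns if c.startswith("rep") and c[3:].isdigit()),
        key=lambda c: int(c[3:]),
    )
    replicates = None
    if rep_cols:
        replicates = {}
        for _, row in df.iterrows():
            vals = row[rep_cols].to_numpy(dtype=float)
            replicates[row["strain"]] = vals[~np.isnan(vals)]
    return PhenotypeDataset(
        dataset_id=meta["dataset_id"],
        sex=meta["sex"],
        categorical=meta["categorical"].lower() in ("1", "true", "yes"),
        strains=df["strain"].astype(str).tolist(),
        mean=df["mean"].to_numpy(dtype=float),
        sd=df["sd"].to_numpy(dtype=float),
        n_animals=df["nindiv"].to_numpy(dtype=int),
        replicates=replicates,
    )


def write_phenotypes(ds: PhenotypeDataset, path: str) -> str:
    """Inverse of :func:`read_phenotypes`."""
    df = pd.DataFrame(
        {
            "strain": ds.strains,
            "mean": ds.mean,
            "sd": ds.sd,
            "nindiv": ds.n_animals,
        }
    )
    if ds.replicates is not None:
        width = max(len(v) for v in ds.replicates.values())
        for r in range(width):
            df[f"rep{r + 1}"] = [
                ds.replicates[s][r] if r < len(ds.replicates[s]) else np.nan
                for s in ds.strains
            ]
    with open(path, "w") as fh:
        fh.write(f"#dataset_id={ds.dataset_id}\n")
        fh.write(f"#sex={ds.sex}\n")
        fh.write(f"#categorical={str(ds.categorical).lower()}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")
    return str(path)


# ---------------------------------------------------------------------------
# block tables
# ---------------------------------------------------------------------------

def empty_block_table() -> pd.DataFrame:
    return pd.DataFrame(columns=BLOCK_TABLE_COLUMNS)


def write_results(table: pd.DataFrame, path: str) -> str:
    """Write a block table as TSV with a stable column order.

    Floating-point association statistics are written in full-precision
    scientific notation (15 significant digits) so a write/read round trip is
    lossless well past 12 significant digits.
    """
    out = table.copy()
    for col in BLOCK_TABLE_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    extra = [c for c in out.columns if c not in BLOCK_TABLE_COLUMNS]
    out = out[extra + BLOCK_TABLE_COLUMNS]
    for col in _FLOAT_COLS:
        out[col] = [
            "" if pd.isna(v) else f"{float(v):.15e}" for v in out[col]
        ]
    out.to_csv(path, sep="\t", index=False)
    return str(path)


def read_results(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in _FLOAT_COLS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str) -> pd.DataFrame:
    """Read a BED3+ file into 1-based closed intervals (chrom, start_bp,
    end_bp, name)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"BED file {path} needs at least 3 columns", line=1)
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start_bp": df[1].astype(np.int64) + 1,
            "end_bp": df[2].astype(np.int64),
            "name": df[3].astype(str) if df.shape[1] > 3 else "",
        }
    )
    if (out["start_bp"] > out["end_bp"]).any():
        raise ValidationError(f"BED file {path} has an empty/negative interval")
    return out
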