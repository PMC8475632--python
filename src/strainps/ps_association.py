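"""The population-structure association test.

Instead of treating population structure (PS) as a covariate to correct the
trait test, PS is the response: the strain coordinates on the first p
principal components of a genome-wide relationship matrix form an n x p
multivariate response y, modelled as

    y = mu + X beta + e

where X is the haplotype-group indicator of a block (or a variant's allele
indicator).  A one-factor MANOVA then asks whether the block's strain
grouping predicts genome-wide relatedness.  Blocks whose grouping is
significantly associated with PS after Benjamini-Hochberg adjustment
(p_adj < q, default q = 0.05) are PS+; the rest are PS-.

Pillai's trace is the default statistic (most robust at the small strain
numbers typical of these panels); Wilks' lambda is selectable.  When the
residual degrees of freedom fall below p the parametric F approximation is
unreliable and the test falls back to a label-permutation null, flagged in
the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateGroupingError,
    ParameterError,
    RareVariantError,
    ValidationError,
)
from .haplotype_blocks import UNASSIGNED
from .population_structure import PCACoordinates

FDR_Q = 0.05
MIN_CARRIER_STRAINS = 3  # rare variants in < 3 strains are untestable
DEFAULT_PERMUTATIONS = 10_000


@dataclass
class ManovaFit:
    """A fitted one-factor multivariate linear model on PC scores."""

    grand_mean: np.ndarray  # (p,)
    effects: np.ndarray  # (k-1, p) deviation contrasts
    residuals: np.ndarray  # (n, p)
    statistic: str  # {"pillai", "wilks"}
    statistic_value: float
    approx_F: float | None
    df1: float | None
    df2: float | None
    p_value: float
    method: str  # {"parametric", "permutation"}
    n_groups: int
    n_strains: int
    n_permutations: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p-value outside [0, 1]")


@dataclass
class PSTestResult:
    """A block's (or variant's) PS test after FDR adjustment."""

    target: object
    p_raw: float
    rank: int
    m: int
    p_adj: float
    classification: str  # {"PS+", "PS-"}
    q: float
    method: str = "parametric"
    pc_source: str = "GRM"

    def __post_init__(self) -> None:
        if self.p_adj < self.p_raw - 1e-15 or self.p_adj > 1.0 + 1e-15:
            raise ValidationError("p_adj must satisfy p_raw <= p_adj <= 1")


# ---------------------------------------------------------------------------
# one-way MANOVA (authored here; statsmodels serves only as a test oracle)
# ---------------------------------------------------------------------------

def _sscp(y: np.ndarray, labels: np.ndarray):
    """Between (H) and within (E) SSCP matrices of a one-way layout."""
    grand = y.mean(axis=0)
    groups = np.unique(labels)
    p = y.shape[1]
    h = np.zeros((p, p))
    e = np.zeros((p, p))
    means = {}
    for g in groups:
        sub = y[labels == g]
        mg = sub.mean(axis=0)
        means[g] = mg
        d = (mg - grand)[:, None]
        h += len(sub) * (d @ d.T)
        r = sub - mg
        e += r.T @ r
    return h, e, grand, means, groups


def _pillai(h: np.ndarray, e: np.ndarray) -> float:
    t = h + e
    return float(np.trace(np.linalg.solve(t, h)))


def _wilks(h: np.ndarray, e: np.ndarray) -> float:
    sign_e, logdet_e = np.linalg.slogdet(e)
    sign_t, logdet_t = np.linalg.slogdet(h + e)
    if sign_e <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError("singular SSCP matrix")
    return float(np.exp(logdet_e - logdet_t))


def _parametric_p(
    stat: float, statistic: str, n: int, k: int, p: int
) -> tuple[float, float, float, float]:
    """F approximation (F, df1, df2, p) for Pillai or Wilks."""
    from scipy import stats as sps

    q = k - 1
    s = min(p, q)
    if statistic == "pillai":
        m = (abs(p - q) - 1) / 2.0
        n2 = (n - k - p - 1) / 2.0
        df1 = s * (2 * m + s + 1)
        df2 = s * (2 * n2 + s + 1)
        if df2 <= 0 or stat >= s:
            return np.inf, df1, df2, 0.0
        f = (df2 / df1) * stat / (s - stat)
    else:  # wilks, Rao's approximation
        df1 = p * q
        if p**2 + q**2 - 5 > 0:
            t = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5))
        else:
            t = 1.0
        w = n - 1 - (p + q + 1) / 2.0
        df2 = w * t - (p * q - 2) / 2.0
        if df2 <= 0:
            return np.inf, df1, df2, 0.0
        lam_t = stat ** (1.0 / t)
        if lam_t == 0:
            return np.inf, df1, df2, 0.0
        f = (1.0 - lam_t) / lam_t * df2 / df1
    return float(f), float(df1), float(df2), float(sps.f.sf(f, df1, df2))


def manova_statistic(
    y: np.ndarray, labels: np.ndarray, statistic: str = "pillai"
) -> float:
    h, e, *_ = _sscp(y, labels)
    return _pillai(h, e) if statistic == "pillai" else _wilks(h, e)


def ps_manova_test(
    grouping: np.ndarray,
    coords: PCACoordinates,
    statistic: str = "pillai",
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> ManovaFit:
    """Test a strain grouping against the PC-score response.

    ``grouping`` is one label per strain in ``coords`` order; strains labelled
    ``UNASSIGNED`` (0) are dropped.  Falls back to a label-permutation null
    (flagged ``method="permutation"``) when the residual degrees of freedom
    are below p.
    """
    if statistic not in ("pillai", "wilks"):
        raise ParameterError("statistic must be 'pillai' or 'wilks'")
    labels = np.asarray(grouping)
    if len(labels) != len(coords.strain_names):
        raise ValidationError("grouping length does not match coordinates")
    keep = labels != UNASSIGNED
    labels = labels[keep]
    y = coords.scores[keep]
    n, p = y.shape
    if p == 0:
        raise ParameterError("coords carry no principal components")
    groups = np.unique(labels)
    k = len(groups)
    if k < 2:
        raise DegenerateGroupingError("grouping has a single level")
    h, e, grand, means, _ = _sscp(y, labels)
    stat = _pillai(h, e) if statistic == "pillai" else None
    use_permutation = (n - k) < p
    if statistic == "wilks" and not use_permutation:
        try:
            stat = _wilks(h, e)
        except np.linalg.LinAlgError:
            use_permutation = True
    if use_permutation:
        # Pillai remains defined whenever H+E is invertible; permutation
        # calibrates it without the F approximation
        stat = _pillai(h, e)
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            hp, ep, *_ = _sscp(y, perm)
            if _pillai(hp, ep) >= stat - 1e-12:
                count += 1
        p_value = (1 + count) / (1 + n_permutations)
        f = df1 = df2 = None
        method = "permutation"
        statistic = "pillai"
    else:
        f, df1, df2, p_value = _parametric_p(stat, statistic, n, k, p)
        method = "parametric"
    unweighted = np.mean([means[g] for g in groups], axis=0)
    effects = np.array([means[g] - unweighted for g in groups[:-1]])
    fitted = np.vstack([means[g] for g in labels])
    return ManovaFit(
        grand_mean=grand,
        effects=effects,
        residuals=y - fitted,
        statistic=statistic,
        statistic_value=float(stat),
        approx_F=f,
        df1=df1,
        df2=df2,
        p_value=float(p_value),
        method=method,
        n_groups=k,
        n_strains=n,
        n_permutations=n_permutations if method == "permutation" else None,
    )


def variant_ps_test(
    allele_indicator: np.ndarray,
    coords: PCACoordinates,
    statistic: str = "pillai",
    **kwargs,
) -> ManovaFit:
    """PS test for a single variant: the factor is the allele indicator.

    Variants whose minor allele is carried by fewer than 3 strains are
    rejected (untestable against structure).
    """
    x = np.asarray(allele_indicator)
    if not np.isin(x, (0, 1)).all():
        raise ValidationError("allele indicator must be 0/1")
    minor = int(min(x.sum(), len(x) - x.sum()))
    if minor == 0:
        raise DegenerateGroupingError("monomorphic allele indicator")
    if minor < MIN_CARRIER_STRAINS:
        raise RareVariantError(
            f"minor allele present in {minor} strains (< {MIN_CARRIER_STRAINS})"
        )
    return ps_manova_test(x + 1, coords, statistic=statistic, **kwargs)


# ---------------------------------------------------------------------------
# FDR adjustment and classification
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    p_adj(i) = min over j >= i (sorted order) of min(1, p(j) * m / j).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p_values must be a nonempty 1-d sequence")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


def make_ps_results(
    targets: list,
    p_raw,
    q: float = FDR_Q,
    method: str = "parametric",
    pc_source: str = "GRM",
) -> list[PSTestResult]:
    """Adjust a family of raw PS p-values and classify each target."""
    p = np.asarray(p_raw, dtype=float)
    if len(targets) != p.size:
        raise ValidationError("targets must parallel p_raw")
    adj = bh_adjust(p)
    ranks = np.empty(p.size, dtype=int)
    ranks[np.argsort(p, kind="mergesort")] = np.arange(1, p.size + 1)
    return [
        PSTestResult(
            target=t,
            p_raw=float(pi),
            rank=int(r),
            m=p.size,
            p_adj=float(a),
            classification="PS+" if a < q else "PS-",
            q=q,
            method=method,
            pc_source=pc_source,
        )
        for t, pi, r, a in zip(targets, p, ranks, adj)
    ]


def classify_ps(results: list[PSTestResult], q: float = FDR_Q) -> list[PSTestResult]:
    """(Re)classify results at FDR level q: PS+ iff p_adj < q.

    The boundary p_adj = q is PS- (the null of no structure association is
    not rejected there)."""
    for r in results:
        r.classification = "PS+" if r.p_adj < q else "PS-"
        r.q = q
    return results
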