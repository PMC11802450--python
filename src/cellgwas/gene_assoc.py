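"""LD-aware gene-level association from GWAS summary statistics.

Per gene: SNPs within a strand-aware window (35 kb upstream to 10 kb
downstream by default) are collected, their p-values probit-transformed
to z-statistics, and the gene statistic is the sum of squared z's. Under
the null this statistic is a mixture sum(lambda_j * chi2_1) with weights
equal to the eigenvalues of the member-SNP LD correlation matrix; the
survival probability is evaluated by Imhof-type numeric inversion with a
Kuonen saddlepoint fallback in the far tail. The module also builds the
sparse gene-gene correlation induced by shared/adjacent LD, which the
regression stage uses as its error-covariance model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.optimize import brentq

DEFAULT_WINDOW_UP = 35_000
DEFAULT_WINDOW_DOWN = 10_000
PVALUE_FLOOR = 1e-300
#: eigenvalues below this fraction of the largest are pruned
EIGEN_PRUNE_REL = 1e-4
#: gene pairs farther apart than this never correlate
CORRELATION_RADIUS = 5_000_000


@dataclass
class GeneModel:
    """Per-gene SNP membership and LD eigenstructure."""

    gene: str
    chrom: object
    w_start: int
    w_end: int
    snp_indices: np.ndarray
    snp_ids: list[str] = field(default_factory=list)
    lambdas: np.ndarray | None = None  # retained eigenvalues, descending
    n_pruned: int = 0
    trace: float = 0.0  # sum of ALL clipped eigenvalues (= retained SNP count)
    sum_sq: float = 0.0  # sum over SNP pairs of r_ij^2 (null variance / 2)

    @property
    def n_snps(self) -> int:
        return int(len(self.snp_indices))


class GeneCorrelation:
    """Gene-gene correlation of gene statistics induced by LD; PSD."""

    def __init__(self, genes: list[str], matrix: np.ndarray):
        self.genes = list(genes)
        self.matrix = np.asarray(matrix, dtype=float)
        if self.matrix.shape != (len(self.genes), len(self.genes)):
            raise ValueError("correlation matrix shape mismatch")

    def subset(self, genes) -> "GeneCorrelation":
        idx = pd.Index(self.genes).get_indexer(genes)
        if (idx < 0).any():
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise KeyError(f"genes absent from correlation: {missing[:5]}")
        return GeneCorrelation(list(genes), self.matrix[np.ix_(idx, idx)])

    def to_triplets(self) -> pd.DataFrame:
        i, j = np.nonzero(np.triu(self.matrix, k=1))
        return pd.DataFrame(
            {
                "GENE1": [self.genes[a] for a in i],
                "GENE2": [self.genes[b] for b in j],
                "R": self.matrix[i, j],
            }
        )


def annotate_snps_to_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    window_up: int = DEFAULT_WINDOW_UP,
    window_down: int = DEFAULT_WINDOW_DOWN,
) -> list[GeneModel]:
    """Assign SNPs to strand-aware gene windows (1-based, inclusive bounds).

    For a '+' gene [s, e] the window is [s - window_up, e + window_down];
    for '-' it is [s - window_down, e + window_up]; clipped at 1. A SNP may
    belong to several genes. Genes with zero SNPs are dropped with a warning.
    """
    snp_chrom_set = set(str(c) for c in snps["chrom"].unique())
    bad = sorted(set(str(c) for c in genes["chrom"].unique()) - snp_chrom_set)
    if bad:
        raise ValueError(f"chromosome naming mismatch between inputs: {bad}")

    by_chrom = {
        str(c): sub.sort_values("pos").reset_index() for c, sub in snps.groupby("chrom")
    }
    models: list[GeneModel] = []
    dropped = []
    for row in genes.itertuples(index=False):
        strand = getattr(row, "strand", "+") or "+"
        if strand == "-":
            w_lo, w_hi = row.start - window_down, row.end + window_up
        else:
            w_lo, w_hi = row.start - window_up, row.end + window_down
        w_lo = max(int(w_lo), 1)
        w_hi = int(w_hi)
        sub = by_chrom[str(row.chrom)]
        pos = sub["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, w_lo, side="left"), np.searchsorted(pos, w_hi, side="right")
        if hi <= lo:
            dropped.append(row.gene)
            continue
        models.append(
            GeneModel(
                gene=row.gene,
                chrom=row.chrom,
                w_start=w_lo,
                w_end=w_hi,
                snp_indices=sub["index"].to_numpy()[lo:hi],
                snp_ids=list(sub["snp"].to_numpy()[lo:hi]),
            )
        )
    if dropped:
        warnings.warn(f"{len(dropped)} genes had no SNPs in their window and were dropped")
    return models


def snp_z_from_p(p):
    """Probit transform z = Phi^{-1}(1 - p) of SNP p-values.

    p is clamped to [1e-300, 1 - 1e-16] so the transform is finite at both
    boundaries; values outside (0, 1] are rejected.
    """
    arr = np.atleast_1d(np.asarray(p, dtype=float))
    if ((arr <= 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    clamped = np.clip(arr, PVALUE_FLOOR, 1.0 - 1e-16)
    z = stats.norm.isf(clamped)
    return z if np.ndim(p) else float(z[0])


def gene_statistic(z) -> float:
    """Sum of squared SNP z-statistics."""
    arr = np.asarray(z, dtype=float)
    if arr.size == 0:
        raise ValueError("gene statistic requires at least one SNP")
    return float(np.sum(arr**2))


def ld_eigenvalues(
    genotypes: np.ndarray, prune_rel: float = EIGEN_PRUNE_REL
) -> tuple[np.ndarray, int, float]:
    """Eigenvalues of the member-SNP Pearson correlation matrix.

    Zero-variance SNPs are removed (with a warning) before decomposition.
    Returns (retained eigenvalues descending, number pruned, full trace);
    eigenvalues below ``prune_rel * lambda_max`` are pruned, negatives are
    clipped to zero, and the full trace equals the retained SNP count.
    """
    X = np.asarray(genotypes, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    variances = X.var(axis=0)
    if (variances == 0).any():
        warnings.warn(f"{int((variances == 0).sum())} zero-variance SNPs removed")
        X = X[:, variances > 0]
    if X.shape[1] == 0:
        raise ValueError("no SNPs with nonzero variance")
    if X.shape[1] == 1:
        return np.array([1.0]), 0, 1.0
    R = np.corrcoef(X, rowvar=False)
    lam = np.linalg.eigvalsh(R)[::-1]
    lam = np.clip(lam, 0.0, None)
    trace = float(lam.sum())
    keep = lam >= prune_rel * lam[0]
    return lam[keep], int((~keep).sum()), trace


def _imhof_sf(T: float, lam: np.ndarray, epsabs: float = 1e-12) -> tuple[float, float]:
    """Pr(sum lambda_j chi2_1 > T) by Imhof's inversion integral."""
    import math

    half_T = 0.5 * T
    arctan = np.arctan
    log1p = np.log1p

    def integrand(u):
        lu = lam * u
        theta = 0.5 * arctan(lu).sum() - half_T * u
        rho = math.exp(0.25 * log1p(lu * lu).sum())
        return math.sin(theta) / (u * rho)

    val, err = integrate.quad(integrand, 0.0, np.inf, epsabs=epsabs, limit=500)
    return 0.5 + val / np.pi, err


def _saddlepoint_sf(T: float, lam: np.ndarray) -> float:
    """Kuonen saddlepoint (Lugannani-Rice) tail for the weighted chi-square."""
    lam_max = lam.max()
    mean = lam.sum()
    if abs(T - mean) < 1e-12 * max(mean, 1.0):
        return 0.5

    def kprime(z):
        return np.sum(lam / (1.0 - 2.0 * z * lam))

    hi = 0.5 / lam_max
    zhat = brentq(lambda z: kprime(z) - T, -1e4, hi - 1e-12 * hi, maxiter=200)
    K = -0.5 * np.sum(np.log1p(-2.0 * zhat * lam))
    Kpp = np.sum(2.0 * lam**2 / (1.0 - 2.0 * zhat * lam) ** 2)
    w = np.sign(zhat) * np.sqrt(max(2.0 * (zhat * T - K), 0.0))
    v = zhat * np.sqrt(Kpp)
    if w == 0.0 or v == 0.0:
        return 0.5
    return float(stats.norm.sf(w + np.log(v / w) / w))


def mixture_pvalue(T: float, lam, flag: dict | None = None) -> float:
    """Survival probability of sum_j lambda_j chi2_1 at T.

    Uses the exact chi-square survival function when all weights are equal,
    Imhof numeric inversion otherwise, and a saddlepoint approximation in
    the far tail (or on non-convergence, recorded in ``flag``). The result
    is floored at 1e-300 so the probit transform stays finite.
    """
    if T < 0:
        raise ValueError("gene statistic must be nonnegative")
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0 or lam.sum() <= 0:
        raise ValueError("at least one positive eigenvalue is required")
    if T == 0:
        return 1.0
    if np.ptp(lam) <= 1e-12 * lam[0]:
        p = float(stats.chi2.sf(T / lam[0], df=lam.size))
        return max(p, PVALUE_FLOOR)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        p, err = _imhof_sf(T, lam)
    if p < 1e-8 or err > max(abs(p) * 1e-3, 1e-11) or not np.isfinite(p):
        if flag is not None:
            flag["saddlepoint"] = True
        p = _saddlepoint_sf(T, lam)
    return float(np.clip(p, PVALUE_FLOOR, 1.0))


def gene_gene_correlation(
    models: list[GeneModel],
    panel: np.ndarray,
    radius: int = CORRELATION_RADIUS,
) -> GeneCorrelation:
    """Null correlation between gene statistics from cross-gene LD.

    For genes g, h whose windows lie within ``radius`` bp on one chromosome,
    corr(T_g, T_h) = sum_{i in g, j in h} r_ij^2 / sqrt(S_g * S_h) with
    S_g = sum_{i, i' in g} r_{i i'}^2 (the null variance of T_g up to a
    factor 2). The matrix is ridge-repaired to positive semidefiniteness
    and rescaled to unit diagonal if the repair was needed.
    """
    n = len(models)
    M = np.eye(n)
    Xs = panel.astype(float)
    mu = Xs.mean(axis=0)
    sd = Xs.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Xs - mu) / sd  # standardized columns: cross-corr = Z_g' Z_h / n_hap

    def self_sum(m: GeneModel) -> float:
        if m.sum_sq > 0:
            return m.sum_sq
        C = Z[:, m.snp_indices].T @ Z[:, m.snp_indices] / Z.shape[0]
        m.sum_sq = float(np.sum(C**2))
        return m.sum_sq

    order = sorted(range(n), key=lambda i: (str(models[i].chrom), models[i].w_start))
    for a in range(n):
        i = order[a]
        mi = models[i]
        for b in range(a + 1, n):
            j = order[b]
            mj = models[j]
            if str(mj.chrom) != str(mi.chrom):
                break
            gap = mj.w_start - mi.w_end
            if gap > radius:
                break
            C = Z[:, mi.snp_indices].T @ Z[:, mj.snp_indices] / Z.shape[0]
            r = float(np.sum(C**2) / np.sqrt(self_sum(mi) * self_sum(mj)))
            M[i, j] = M[j, i] = min(r, 1.0)

    w_min = float(np.linalg.eigvalsh(M)[0])
    if w_min < -1e-10:
        delta = abs(w_min) + 1e-8
        M = M + delta * np.eye(n)
        d = np.sqrt(np.diag(M))
        M = M / np.outer(d, d)
    return GeneCorrelation([m.gene for m in models], M)


def run_gene_analysis(
    gwas: pd.DataFrame,
    genes: pd.DataFrame,
    panel: np.ndarray,
    snps: pd.DataFrame,
    window_up: int = DEFAULT_WINDOW_UP,
    window_down: int = DEFAULT_WINDOW_DOWN,
) -> tuple[pd.DataFrame, GeneCorrelation, list[GeneModel]]:
    """Full gene analysis: statistics, mixture p-values, covariates, LD.

    Returns a per-gene table (GENE, NSNPS, STAT, P, ZSTAT plus covariates:
    NSNPS and DENSITY = effective tests / SNPs, INV_MAC, MEAN_N and natural
    logs of each), the gene-gene correlation, and the fitted gene models.
    GWAS SNPs absent from the panel are rejected; genes with no SNPs are
    dropped with a warning.
    """
    unmapped = set(gwas["SNP"]) - set(snps["snp"])
    if unmapped:
        raise ValueError(f"GWAS SNPs missing from the panel: {sorted(unmapped)[:5]}")
    merged = snps.merge(gwas, left_on="snp", right_on="SNP", how="left")
    usable = merged["P"].notna().to_numpy()
    z_all = np.full(len(merged), np.nan)
    z_all[usable] = snp_z_from_p(merged.loc[usable, "P"].to_numpy())
    n_all = merged["N"].to_numpy(dtype=float)
    mac = merged["mac"].to_numpy(dtype=float) if "mac" in merged else panel.sum(axis=0)

    models = annotate_snps_to_genes(snps, genes, window_up, window_down)
    rows = []
    kept_models = []
    for m in models:
        idx = m.snp_indices[usable[m.snp_indices]]
        if idx.size == 0:
            continue
        m.snp_indices = idx
        z = z_all[idx]
        lam, n_pruned, trace = ld_eigenvalues(panel[:, idx])
        m.lambdas, m.n_pruned, m.trace = lam, n_pruned, trace
        T = gene_statistic(z)
        flag: dict = {}
        p_g = mixture_pvalue(T, lam, flag)
        nsnps = idx.size
        density = lam.size / nsnps
        inv_mac = 1.0 / float(np.mean(mac[idx]))
        mean_n = float(np.nanmean(n_all[idx]))
        rows.append(
            {
                "GENE": m.gene,
                "CHR": m.chrom,
                "START": m.w_start,
                "STOP": m.w_end,
                "NSNPS": nsnps,
                "STAT": T,
                "P": p_g,
                "ZSTAT": float(stats.norm.isf(np.clip(p_g, PVALUE_FLOOR, 1 - 1e-16))),
                "DENSITY": density,
                "INV_MAC": inv_mac,
                "MEAN_N": mean_n,
                "LOG_NSNPS": float(np.log(nsnps)),
                "LOG_DENSITY": float(np.log(density)),
                "LOG_INV_MAC": float(np.log(inv_mac)),
                "LOG_MEAN_N": float(np.log(mean_n)),
                "SADDLEPOINT": bool(flag.get("saddlepoint", False)),
            }
        )
        kept_models.append(m)
    if not rows:
        raise ValueError("no genes with usable SNPs")
    stats_df = pd.DataFrame(rows)
    corr = gene_gene_correlation(kept_models, panel)
    return stats_df, corr, kept_models


COVARIATE_COLUMNS = [
    "NSNPS",
    "DENSITY",
    "INV_MAC",
    "MEAN_N",
    "LOG_NSNPS",
    "LOG_DENSITY",
    "LOG_INV_MAC",
    "LOG_MEAN_N",
]
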