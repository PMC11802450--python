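"""Gene-property regression of gene z-scores on cell-type specificity.

For each cell type c the model is

    Z = b0 + P_c b1 + C b2 + eps,    eps ~ N(0, sigma^2 R)

with Z the probit gene z-scores (truncated at mean - 3 sd / mean + 6 sd),
P_c the cell type's specificity column (truncated at mean +/- 5 sd), C the
gene-level covariates and R the LD-induced gene-gene correlation. The fit
whitens by the Cholesky factor of R and tests b1 one-sidedly (H1: b1 > 0);
cell types are flagged at the Bonferroni threshold alpha / C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .gene_assoc import COVARIATE_COLUMNS, GeneCorrelation, PVALUE_FLOOR

Z_TRUNC_LOWER_SD = 3.0  # clamp below mean - 3 sd
Z_TRUNC_UPPER_SD = 6.0  # clamp above mean + 6 sd
SPEC_TRUNC_SD = 5.0  # symmetric clamp at mean +/- 5 sd


class CollinearityError(ValueError):
    """Raised when the design matrix is rank-deficient."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"design is rank-deficient; collinear column: {column}")


@dataclass
class CellTypeAssociation:
    celltype: object
    beta1: float
    se: float
    t: float
    p_one_sided: float
    df: int
    bonferroni_significant: bool = False


def truncate_gene_z(z) -> np.ndarray:
    """Asymmetric clamp of gene z-scores at mean - 3 sd / mean + 6 sd.

    Mean and sd are computed once on the raw vector (no iteration), so the
    operation is idempotent.
    """
    arr = np.asarray(z, dtype=float).copy()
    if arr.size < 2:
        raise ValueError("at least two genes are required")
    sd = float(np.std(arr, ddof=1))
    if sd == 0:
        warnings.warn("zero variance; z-scores returned unchanged")
        return arr
    mu = float(np.mean(arr))
    return np.clip(arr, mu - Z_TRUNC_LOWER_SD * sd, mu + Z_TRUNC_UPPER_SD * sd)


def truncate_specificity(s) -> np.ndarray:
    """Symmetric clamp of a specificity column at mean +/- 5 sd."""
    arr = np.asarray(s, dtype=float).copy()
    if arr.size < 2:
        raise ValueError("at least two genes are required")
    sd = float(np.std(arr, ddof=1))
    if sd == 0:
        warnings.warn("zero variance; specificity returned unchanged")
        return arr
    mu = float(np.mean(arr))
    return np.clip(arr, mu - SPEC_TRUNC_SD * sd, mu + SPEC_TRUNC_SD * sd)


@dataclass
class RegressionDesign:
    """One cell type's GLS problem, after truncation and gene intersection."""

    genes: list
    Z: np.ndarray
    spec: np.ndarray
    covariates: np.ndarray  # (G, k); may have zero columns
    corr: np.ndarray  # (G, G) gene-gene correlation
    celltype: object = None

    def __post_init__(self) -> None:
        G = len(self.genes)
        if not (self.Z.shape == (G,) and self.spec.shape == (G,)):
            raise ValueError("column lengths disagree")
        if self.covariates.shape[0] != G or self.corr.shape != (G, G):
            raise ValueError("covariate/correlation shapes disagree")
        if np.isnan(self.Z).any() or np.isnan(self.spec).any() or np.isnan(self.covariates).any():
            raise ValueError("missing values in the design")


def drop_constant_columns(C: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Remove zero-variance covariates (they are collinear with the intercept)."""
    C = np.asarray(C, dtype=float)
    if C.size == 0:
        return C.reshape(len(C), 0), []
    keep = C.std(axis=0) > 0
    return C[:, keep], [n for n, k in zip(names, keep) if k]


def drop_dependent_columns(
    C: np.ndarray, names: list[str], rtol: float = 1e-8
) -> tuple[np.ndarray, list[str]]:
    """Remove covariates linearly dependent on the intercept or earlier columns.

    Discrete covariates can make their log versions exactly collinear (a log
    of a two-valued column is an affine function of it), so redundant columns
    are dropped greedily, earliest first, before any fit.
    """
    G = C.shape[0]
    basis = [np.ones(G) / np.sqrt(G)]
    kept_idx: list[int] = []
    for j in range(C.shape[1]):
        v = C[:, j].astype(float)
        scale = np.linalg.norm(v)
        for b in basis:
            v = v - (b @ v) * b
        if np.linalg.norm(v) > rtol * max(scale, 1.0):
            basis.append(v / np.linalg.norm(v))
            kept_idx.append(j)
    return C[:, kept_idx], [names[j] for j in kept_idx]


def _whitener(R: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of R, with a tiny ridge if needed."""
    try:
        return linalg.cholesky(R, lower=True)
    except linalg.LinAlgError:
        w_min = np.linalg.eigvalsh(R)[0]
        return linalg.cholesky(R + (abs(min(w_min, 0.0)) + 1e-10) * np.eye(len(R)), lower=True)


def gls_fit(design: RegressionDesign) -> CellTypeAssociation:
    """Whitened least squares; one-sided t-test of the specificity slope."""
    G = len(design.genes)
    X = np.column_stack([np.ones(G), design.spec, design.covariates])
    ncol = X.shape[1]
    L = _whitener(design.corr)
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, design.Z, lower=True)

    rank = np.linalg.matrix_rank(Xw)
    if rank < ncol:
        names = ["intercept", "specificity"] + [f"covariate_{i}" for i in range(ncol - 2)]
        for j in range(ncol - 1, -1, -1):
            others = np.delete(Xw, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                raise CollinearityError(names[j])
        raise CollinearityError("unknown")

    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    df = G - ncol  # G - (k + 2): intercept + specificity + k covariates
    if df <= 0:
        raise ValueError("not enough genes for the requested covariates")
    sigma2 = float(resid @ resid) / df
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = float(np.sqrt(max(sigma2 * XtX_inv[1, 1], 0.0)))
    b1 = float(beta[1])
    if se == 0.0:
        t = np.inf if b1 > 0 else (-np.inf if b1 < 0 else 0.0)
        p = PVALUE_FLOOR if b1 > 0 else 1.0
    else:
        t = b1 / se
        p = float(np.clip(stats.t.sf(t, df), PVALUE_FLOOR, 1.0))
    return CellTypeAssociation(design.celltype, b1, se, t, p, df)


class ScanEngine:
    """Shared precomputation for scanning many cell types over one Z.

    Whitens once, residualizes each whitened specificity column against the
    whitened base design (intercept + covariates), and obtains each cell
    type's slope test from the residualized regression, which is
    algebraically identical to the full GLS fit.
    """

    def __init__(
        self,
        gene_stats: pd.DataFrame,
        spec: pd.DataFrame,
        corr: GeneCorrelation,
        covariate_columns: list[str] | None = None,
    ):
        if covariate_columns is None:
            covariate_columns = [c for c in COVARIATE_COLUMNS if c in gene_stats.columns]
        common = [g for g in gene_stats["GENE"] if g in set(spec.index)]
        if not common:
            raise ValueError("no genes shared between GWAS-side and expression-side tables")
        gs = gene_stats.set_index("GENE").loc[common]
        self.genes = common
        self.celltypes = list(spec.columns)
        self.Z = truncate_gene_z(gs["ZSTAT"].to_numpy())
        C_raw = gs[covariate_columns].to_numpy(dtype=float)
        C0, names0 = drop_constant_columns(C_raw, covariate_columns)
        self.covariates, self.covariate_names = drop_dependent_columns(C0, names0)
        self.R = corr.subset(common).matrix
        self.L = _whitener(self.R)
        S = np.column_stack([truncate_specificity(spec[c].to_numpy()) for c in spec.columns])
        self.spec_truncated = S
        self.Sw = linalg.solve_triangular(self.L, S, lower=True)
        G = len(common)
        base = np.column_stack([np.ones(G), self.covariates])
        self.base_w = linalg.solve_triangular(self.L, base, lower=True)
        self.Q, _ = np.linalg.qr(self.base_w)
        self.S_resid = self.Sw - self.Q @ (self.Q.T @ self.Sw)
        self.df = G - (self.covariates.shape[1] + 2)
        if self.df <= 0:
            raise ValueError("not enough genes for the covariate set")

    def scan(self, Z: np.ndarray | None = None, alpha: float = 0.05) -> pd.DataFrame:
        """One-sided slope test for every cell type against Z (default: own Z)."""
        Z = self.Z if Z is None else np.asarray(Z, dtype=float)
        zw = linalg.solve_triangular(self.L, Z, lower=True)
        z_resid = zw - self.Q @ (self.Q.T @ zw)
        ss = np.einsum("ij,ij->j", self.S_resid, self.S_resid)
        if (ss <= 1e-12 * len(Z)).any():
            bad = self.celltypes[int(np.argmin(ss))]
            raise CollinearityError(f"specificity[{bad}]")
        beta = (self.S_resid.T @ z_resid) / ss
        rss = float(z_resid @ z_resid) - beta**2 * ss
        sigma2 = np.maximum(rss, 0.0) / self.df
        se = np.sqrt(sigma2 / ss)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, np.where(beta > 0, np.inf, 0.0))
        p = np.clip(stats.t.sf(t, self.df), PVALUE_FLOOR, 1.0)
        thresh = alpha / len(self.celltypes)
        return pd.DataFrame(
            {
                "CELLTYPE": self.celltypes,
                "BETA": beta,
                "SE": se,
                "T": t,
                "P_ONESIDED": p,
                "BONF_SIG": p < thresh,
            }
        )


def run_celltype_scan(
    gene_stats: pd.DataFrame,
    spec: pd.DataFrame,
    corr: GeneCorrelation,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One GLS slope test per cell type; Bonferroni flags at alpha / C."""
    return ScanEngine(gene_stats, spec, corr).scan(alpha=alpha)
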