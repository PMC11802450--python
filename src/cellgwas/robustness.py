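"""Calibration and sensitivity machinery around the cell-type scan.

Contains the gene-label permutation null (type-I error control of the
gene-property regression), the effective sample size of a case-control
GWAS, the cell-count vs significance correlation, export of
specifically-expressed-gene (SEG) genome annotations (top-decile
specificity genes with 100-kb flanks) and a power-curve harness that
reruns the full synthetic pipeline over a grid of GWAS sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .regression import ScanEngine
from .gene_assoc import GeneCorrelation


@dataclass
class PermutationSummary:
    n_permutations: int
    n_celltypes: int
    alpha: float
    n_tests_total: int
    n_significant_at_alpha: int
    n_significant_at_bonferroni: int
    expected_at_alpha: float
    expected_at_bonferroni: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_tests_total != self.n_permutations * self.n_celltypes:
            raise ValueError("test count must equal n_permutations * n_celltypes")


def expected_significant(n_perm: int, n_celltypes: int, alpha: float) -> float:
    """Analytic chance expectation: n_perm * C * alpha."""
    return n_perm * n_celltypes * alpha


def permutation_null(
    gene_stats: pd.DataFrame,
    spec: pd.DataFrame,
    corr: GeneCorrelation,
    n_perm: int,
    seed: int = 0,
    alpha: float = 0.05,
) -> PermutationSummary:
    """Gene-label permutation null for the cell-type scan.

    Each iteration shuffles the gene labels of the gene-statistic table —
    breaking the gene-specificity link while preserving both marginals —
    and reruns the full scan (one shuffle shared by all cell types). The
    statistic's covariates and LD correlation travel with it, so the
    shuffle is applied to the specificity rows, which is the same
    permutation seen from the other side.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    engine = ScanEngine(gene_stats, spec, corr)
    rng = np.random.default_rng(seed)
    C = len(engine.celltypes)
    bonf = alpha / C
    n_alpha = 0
    n_bonf = 0
    from scipy.linalg import solve_triangular

    zw = solve_triangular(engine.L, engine.Z, lower=True)
    z_resid = zw - engine.Q @ (engine.Q.T @ zw)
    for _ in range(n_perm):
        perm = rng.permutation(len(engine.genes))
        S_perm = engine.spec_truncated[perm]
        Sw = solve_triangular(engine.L, S_perm, lower=True)
        S_resid = Sw - engine.Q @ (engine.Q.T @ Sw)
        ss = np.einsum("ij,ij->j", S_resid, S_resid)
        beta = (S_resid.T @ z_resid) / ss
        rss = float(z_resid @ z_resid) - beta**2 * ss
        se = np.sqrt(np.maximum(rss, 0.0) / engine.df / ss)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, np.inf)
        p = stats.t.sf(t, engine.df)
        n_alpha += int((p < alpha).sum())
        n_bonf += int((p < bonf).sum())
    return PermutationSummary(
        n_permutations=n_perm,
        n_celltypes=C,
        alpha=alpha,
        n_tests_total=n_perm * C,
        n_significant_at_alpha=n_alpha,
        n_significant_at_bonferroni=n_bonf,
        expected_at_alpha=expected_significant(n_perm, C, alpha),
        expected_at_bonferroni=expected_significant(n_perm, C, alpha / C),
        seed=seed,
    )


def effective_n(cases: float, controls: float) -> float:
    """Effective GWAS size of a case-control design: 4/((1/cases)+(1/controls))."""
    if cases <= 0 or controls <= 0:
        raise ValueError("cases and controls must be positive")
    return 4.0 / (1.0 / cases + 1.0 / controls)


def significance_vs_cellcount(
    scan: pd.DataFrame, cells_per_cluster: pd.Series
) -> tuple[float, float]:
    """Pearson r between -log10(P) and cell count, with its two-sided p."""
    counts = np.asarray([cells_per_cluster[c] for c in scan["CELLTYPE"]], dtype=float)
    neglogp = -np.log10(scan["P_ONESIDED"].to_numpy())
    if np.std(counts) == 0 or np.std(neglogp) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(neglogp, counts)
    return float(r), float(p)


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def export_seg_annotations(
    spec: pd.DataFrame,
    gene_coords: pd.DataFrame,
    top_fraction: float = 0.10,
    window: int = 100_000,
) -> dict:
    """Genome annotations from specifically expressed genes, per cell type.

    Selects the ceil(top_fraction * G) most specific genes (ties broken by
    gene id ascending), surrounds each with ``window`` bp flanks (clipped
    at position 1), and merges overlapping intervals. Intervals are
    1-based inclusive; the BED writer converts on output.
    """
    coords = gene_coords.set_index("gene") if "gene" in gene_coords.columns else gene_coords
    missing = [g for g in spec.index if g not in coords.index]
    if missing:
        raise KeyError(f"coordinates missing for genes: {missing[:5]}")
    k = math.ceil(top_fraction * len(spec))
    out = {}
    for c in spec.columns:
        ranking = sorted(zip(-spec[c].to_numpy(), spec.index))
        top = [g for _, g in ranking[:k]]
        per_chrom: dict = {}
        for g in top:
            row = coords.loc[g]
            per_chrom.setdefault(row["chrom"], []).append(
                (max(int(row["start"]) - window, 1), int(row["end"]) + window)
            )
        rows = []
        for chrom in sorted(per_chrom, key=str):
            for s, e in _merge_intervals(per_chrom[chrom]):
                rows.append({"chrom": chrom, "start": s, "end": e})
        out[c] = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return out


def power_curve_harness(
    base_config,
    gwas_n_grid,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rerun the full synthetic pipeline over a grid of GWAS sample sizes.

    Ground truth (causal clusters and genes) is held fixed; the per-gene
    noncentrality scales with gwas_n, so detected-cell-type counts are
    non-decreasing in expectation.
    """
    from .pipeline import run_synthetic

    if len(gwas_n_grid) < 2:
        raise ValueError("at least two sample sizes are required")
    rows = []
    for n in gwas_n_grid:
        cfg = replace(base_config, gwas_n=int(n))
        res = run_synthetic(cfg, alpha=alpha)
        rows.append(
            {
                "gwas_n": int(n),
                "n_significant_celltypes": int(res["scan"]["BONF_SIG"].sum()),
                "n_selected_independent": len(res["selection"].selected),
            }
        )
    return pd.DataFrame(rows)
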