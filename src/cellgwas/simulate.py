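"""Synthetic data with planted ground truth.

Generates the three inputs the pipeline consumes — an LD reference panel,
a cluster-labelled single-cell count matrix, and GWAS summary statistics —
with a known causal structure: designated "causal" clusters over-express a
set of causal genes, and SNPs falling in the windows of those genes carry
non-zero association signal. Everything is a pure function of
(config, seed), so downstream stages can be tested end-to-end without any
external downloads.

Model sketch
------------
* Genotypes: per-chromosome blocks of SNPs; within a block, haplotype
  alleles are generated from a Gaussian copula with equicorrelated latent
  variables, thresholded at the allele frequency. The latent correlation
  is calibrated (per block) so the *realized* allele-level LD matches the
  requested ``within_block_r`` despite dichotomization attenuation.
* Expression: clusters sit at the leaves of a binary tree; a child's
  log-mean profile is its parent's plus independent Gaussian noise scaled
  by ``1 - cluster_tree_correlation``. Counts are negative binomial
  (dispersion 0.5) with lognormal library-size factors (sigma = 0.3).
  Causal genes have their mean multiplied by ``enrichment_effect`` in
  causal clusters.
* GWAS: per-block SNP z-scores are multivariate normal with covariance
  equal to the empirical block LD; SNPs inside causal-gene windows get a
  mean shift sized so each causal gene's chi-square noncentrality equals
  ``gwas_effect_scale * gwas_n / 100,000``. P-values are two-sided normal
  tails, so with zero effect they are exactly Uniform(0, 1).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.optimize import brentq

# Window convention shared with the gene association stage (bp).
WINDOW_UP = 35_000
WINDOW_DOWN = 10_000

#: GWAS size at which ``gwas_effect_scale`` equals the per-gene noncentrality.
GWAS_REFERENCE_N = 100_000

GENE_LENGTH = 10_000
GENE_GAP = 50_000  # genes laid end-to-end with 50-kb gaps
_GENE_PERIOD = GENE_LENGTH + GENE_GAP
_GENE_OFFSET = 40_000  # leaves room for the 35-kb upstream window


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the defaults used throughout."""

    n_haplotypes: int = 1_000
    n_chromosomes: int = 5
    n_blocks_per_chrom: int = 100
    snps_per_block: int = 10
    within_block_r: float = 0.5
    n_genes: int = 500
    n_clusters: int = 20
    causal_clusters: tuple[int, ...] = (0,)
    n_causal_genes: int = 50
    enrichment_effect: float = 10.0
    gwas_effect_scale: float = 30.0
    gwas_n: int = 100_000
    cells_per_cluster: int = 50
    cluster_tree_correlation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_haplotypes": self.n_haplotypes,
            "n_chromosomes": self.n_chromosomes,
            "n_blocks_per_chrom": self.n_blocks_per_chrom,
            "snps_per_block": self.snps_per_block,
            "n_genes": self.n_genes,
            "n_clusters": self.n_clusters,
            "gwas_n": self.gwas_n,
            "cells_per_cluster": self.cells_per_cluster,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if not 0.0 <= self.within_block_r < 1.0:
            raise ValueError("within_block_r must lie in [0, 1)")
        if not 0.0 <= self.cluster_tree_correlation < 1.0:
            raise ValueError("cluster_tree_correlation must lie in [0, 1)")
        if self.enrichment_effect < 1.0:
            raise ValueError("enrichment_effect must be >= 1")
        if self.gwas_effect_scale < 0.0:
            raise ValueError("gwas_effect_scale must be >= 0")
        bad = [c for c in self.causal_clusters if not 0 <= c < self.n_clusters]
        if bad:
            raise ValueError(f"causal_clusters out of range: {bad}")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, named random stream derived from the root seed."""
        key = zlib.crc32(stream.encode()) % 2**31  # stable across processes
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class GroundTruth:
    """Planted causal structure: which clusters, which genes, how strong."""

    causal_clusters: tuple[int, ...]
    causal_genes: dict[int, list[str]]
    noncentrality: dict[str, float]

    def __post_init__(self) -> None:
        for c in self.causal_clusters:
            if not self.causal_genes.get(c):
                raise ValueError(f"causal cluster {c} has no causal genes")

    @property
    def all_causal_genes(self) -> list[str]:
        out: list[str] = []
        for c in self.causal_clusters:
            out.extend(self.causal_genes[c])
        return out

    def to_json(self, path) -> None:
        payload = {
            "causal_clusters": list(self.causal_clusters),
            "causal_genes": {str(k): v for k, v in self.causal_genes.items()},
            "noncentrality": self.noncentrality,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def gene_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Synthetic gene annotation: protein-coding genes laid end-to-end.

    Genes are distributed as evenly as possible over chromosomes; on each
    chromosome they occupy 10-kb intervals separated by 50-kb gaps
    (1-based inclusive coordinates, all on the '+' strand).
    """
    chroms = np.arange(config.n_genes) % config.n_chromosomes + 1
    idx_on_chrom = np.arange(config.n_genes) // config.n_chromosomes
    start = _GENE_OFFSET + idx_on_chrom * _GENE_PERIOD + 1
    return pd.DataFrame(
        {
            "gene": [f"G{i:05d}" for i in range(config.n_genes)],
            "symbol": [f"SYM{i:05d}" for i in range(config.n_genes)],
            "chrom": chroms,
            "start": start,
            "end": start + GENE_LENGTH - 1,
            "strand": "+",
            "biotype": "protein_coding",
        }
    )


def make_ground_truth(config: SimulationConfig, genes: pd.DataFrame | None = None) -> GroundTruth:
    """Draw disjoint causal-gene sets for each causal cluster."""
    if genes is None:
        genes = gene_annotation(config)
    rng = config.rng("truth")
    pool = list(genes["gene"])
    causal: dict[int, list[str]] = {}
    nc = config.gwas_effect_scale * config.gwas_n / GWAS_REFERENCE_N
    noncentrality: dict[str, float] = {}
    for c in config.causal_clusters:
        n = min(config.n_causal_genes, len(pool))
        if n == 0:
            raise ValueError("not enough genes left to assign causal sets")
        chosen = sorted(rng.choice(len(pool), size=n, replace=False))
        picked = [pool[i] for i in chosen]
        for i in sorted(chosen, reverse=True):
            pool.pop(i)
        causal[c] = picked
        for g in picked:
            noncentrality[g] = nc
    return GroundTruth(tuple(config.causal_clusters), causal, noncentrality)


@lru_cache(maxsize=4096)
def _calibrated_latent_r(target_r: float, maf: float) -> float:
    """Latent Gaussian correlation giving allele-level correlation target_r.

    Alleles are 1 when the latent normal exceeds t = Phi^{-1}(1 - maf);
    thresholding attenuates correlation, so we solve the bivariate-normal
    orthant equation for the latent value that undoes the attenuation.
    """
    if target_r <= 0.0:
        return 0.0
    t = stats.norm.isf(maf)

    def realized(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [-t, -t], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        return (p11 - maf**2) / (maf * (1.0 - maf))

    lo, hi = target_r, 1.0 - 1e-9
    if realized(hi) <= target_r:  # unattainable corner; use near-comonotone
        return hi
    return brentq(lambda r: realized(r) - target_r, lo, hi, xtol=1e-6)


def simulate_reference_panel(
    config: SimulationConfig,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Generate the LD reference panel.

    Returns
    -------
    panel : (n_haplotypes, n_snps) uint8 array of alleles in {0, 1}
    snps : DataFrame with columns snp, chrom, pos, block, maf, mac;
        positions strictly increasing within each chromosome.
    """
    rng = config.rng("panel")
    n_hap = config.n_haplotypes
    per_chrom = np.bincount(
        np.arange(config.n_genes) % config.n_chromosomes, minlength=config.n_chromosomes
    )
    cols = []
    rows = []
    block_id = 0
    for chrom in range(1, config.n_chromosomes + 1):
        n_genes_here = max(int(per_chrom[chrom - 1]), 1)
        span = n_genes_here * _GENE_PERIOD + _GENE_OFFSET
        block_span = span / config.n_blocks_per_chrom
        for b in range(config.n_blocks_per_chrom):
            k = config.snps_per_block
            maf = float(rng.uniform(0.05, 0.5))
            latent_r = _calibrated_latent_r(round(config.within_block_r, 6), round(maf, 3))
            # equicorrelated latent normals via a shared factor
            shared = rng.standard_normal((n_hap, 1))
            own = rng.standard_normal((n_hap, k))
            z = np.sqrt(latent_r) * shared + np.sqrt(1.0 - latent_r) * own
            alleles = (z > stats.norm.isf(maf)).astype(np.uint8)
            cols.append(alleles)
            pos0 = b * block_span
            pos = np.round(pos0 + (np.arange(k) + 0.5) * block_span / k).astype(np.int64)
            pos = np.maximum.accumulate(pos + np.arange(k) * 0)  # monotone within block
            # guarantee strict increase even after rounding collisions
            for i in range(1, k):
                if pos[i] <= pos[i - 1]:
                    pos[i] = pos[i - 1] + 1
            rows.append(
                pd.DataFrame(
                    {
                        "snp": [f"rs{chrom}_{b}_{i}" for i in range(k)],
                        "chrom": chrom,
                        "pos": pos + 1,
                        "block": block_id,
                        "maf": maf,
                    }
                )
            )
            block_id += 1
    panel = np.concatenate(cols, axis=1)
    snps = pd.concat(rows, ignore_index=True)
    counts = panel.sum(axis=0).astype(np.int64)
    snps["mac"] = np.minimum(counts, n_hap - counts)
    return panel, snps


def _cluster_log_means(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Binary-tree hierarchy of cluster log-mean profiles, (genes, clusters).

    Leaves are assigned cluster ids in tree order, so numerically adjacent
    clusters are siblings and share correlated profiles — the structure the
    conditional analysis must disentangle.
    """
    g = config.n_genes
    root = rng.normal(0.0, 1.0, size=g)
    branch_sd = 1.0 - config.cluster_tree_correlation
    profiles = [root]
    while len(profiles) < config.n_clusters:
        nxt = []
        for p in profiles:
            nxt.append(p + rng.normal(0.0, branch_sd, size=g))
            nxt.append(p + rng.normal(0.0, branch_sd, size=g))
        profiles = nxt
    return np.column_stack(profiles[: config.n_clusters])


def simulate_expression(
    config: SimulationConfig,
    truth: GroundTruth,
    genes: pd.DataFrame | None = None,
    cells_per_cluster: int | None = None,
) -> tuple[sparse.csr_matrix, np.ndarray, pd.DataFrame]:
    """Cluster-labelled sparse count matrix (genes x cells).

    Returns (counts, labels, genes); ``labels[i]`` is the cluster of cell i.
    """
    if config.n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    n_cells = cells_per_cluster if cells_per_cluster is not None else config.cells_per_cluster
    if n_cells < 1:
        raise ValueError("cells_per_cluster must be >= 1 for every cluster")
    if genes is None:
        genes = gene_annotation(config)
    rng = config.rng("expression")
    logmu = _cluster_log_means(config, rng)
    gene_index = pd.Index(genes["gene"])
    for c in truth.causal_clusters:
        idx = gene_index.get_indexer(truth.causal_genes[c])
        if (idx < 0).any():
            raise ValueError("ground-truth causal gene absent from annotation")
        logmu[idx, c] += np.log(config.enrichment_effect)
    mu = np.exp(logmu)

    dispersion = 0.5  # NB: var = m + dispersion * m^2
    shape = 1.0 / dispersion
    blocks = []
    labels = []
    for c in range(config.n_clusters):
        lib = rng.lognormal(mean=0.0, sigma=0.3, size=n_cells)
        m = mu[:, [c]] * lib[np.newaxis, :]  # genes x cells
        lam = rng.gamma(shape, m * dispersion)
        counts = rng.poisson(lam)
        blocks.append(sparse.csr_matrix(counts))
        labels.extend([c] * n_cells)
    return sparse.hstack(blocks, format="csr"), np.asarray(labels), genes


def simulate_gwas(
    config: SimulationConfig,
    truth: GroundTruth,
    panel: np.ndarray,
    snps: pd.DataFrame,
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """GWAS summary statistics with signal planted in causal-gene windows.

    SNP z-scores within each LD block are multivariate normal with the
    block's empirical allele correlation; the mean is zero except for SNPs
    inside a causal gene's window, where squared means sum to the gene's
    noncentrality. P is the two-sided normal tail.
    """
    if panel.shape[1] != len(snps):
        raise ValueError("panel and SNP table disagree on the number of SNPs")
    if genes is None:
        genes = gene_annotation(config)
    rng = config.rng("gwas")

    delta = np.zeros(len(snps), dtype=float)
    pos = snps["pos"].to_numpy()
    chrom = snps["chrom"].to_numpy()
    gene_rows = genes.set_index("gene")
    for g, nc in truth.noncentrality.items():
        row = gene_rows.loc[g]
        w_lo = max(int(row["start"]) - WINDOW_UP, 1)
        w_hi = int(row["end"]) + WINDOW_DOWN
        members = np.flatnonzero((chrom == row["chrom"]) & (pos >= w_lo) & (pos <= w_hi))
        if members.size == 0:
            continue
        delta[members] += np.sqrt(nc / members.size)

    z = np.empty(len(snps), dtype=float)
    for _, block in snps.groupby("block", sort=True):
        idx = block.index.to_numpy()
        X = panel[:, idx].astype(float)
        if len(idx) == 1:
            R = np.ones((1, 1))
        else:
            R = np.corrcoef(X, rowvar=False)
            R = np.nan_to_num(R, nan=0.0)
            np.fill_diagonal(R, 1.0)
        # nearest-PSD guard for empirical noise
        w, V = np.linalg.eigh(R)
        L = V * np.sqrt(np.clip(w, 0.0, None))
        z[idx] = delta[idx] + L @ rng.standard_normal(len(idx))

    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    return pd.DataFrame(
        {
            "SNP": snps["snp"].to_numpy(),
            "CHR": snps["chrom"].to_numpy(),
            "BP": snps["pos"].to_numpy(),
            "P": p,
            "N": config.gwas_n,
        }
    )


def simulate_all(config: SimulationConfig, truth: GroundTruth | None = None) -> dict:
    """Generate the full input bundle for one synthetic study.

    A custom ``truth`` (e.g. the same causal genes shared by two sibling
    clusters) overrides the default disjoint causal-gene assignment.
    """
    genes = gene_annotation(config)
    if truth is None:
        truth = make_ground_truth(config, genes)
    panel, snps = simulate_reference_panel(config)
    counts, labels, _ = simulate_expression(config, truth, genes)
    gwas = simulate_gwas(config, truth, panel, snps, genes)
    return {
        "config": config,
        "genes": genes,
        "truth": truth,
        "panel": panel,
        "snps": snps,
        "counts": counts,
        "labels": labels,
        "gwas": gwas,
    }


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["causal_clusters"] = list(d["causal_clusters"])
    return d
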