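import dataclasses

import numpy as np
import pytest

from cellgwas import SimulationConfig, run_synthetic
from cellgwas.simulate import gene_annotation


TINY = SimulationConfig(
    n_haplotypes=300,
    n_chromosomes=2,
    n_blocks_per_chrom=20,
    snps_per_block=5,
    n_genes=60,
    n_clusters=4,
    n_causal_genes=10,
    cells_per_cluster=20,
    seed=5,
)


@pytest.fixture(scope="session")
def tiny_config():
    return TINY


@pytest.fixture(scope="session")
def null_run():
    """Full pipeline on data with zero planted effects (20 clusters, 500 genes)."""
    cfg = SimulationConfig(gwas_effect_scale=0.0, enrichment_effect=1.0, seed=11)
    return run_synthetic(cfg, run_selection=False)


@pytest.fixture(scope="session")
def planted_run():
    """Full pipeline with the default single planted causal cluster."""
    return run_synthetic(SimulationConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def exact_correlation_sample(R: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n observations whose *sample* correlation equals R exactly.

    Orthonormalizes centered Gaussian columns and mixes them with the
    Cholesky factor of R, so empirical-correlation-based oracles see R
    without Monte-Carlo noise.
    """
    k = R.shape[0]
    X = rng.standard_normal((n, k))
    X -= X.mean(axis=0)
    Q, _ = np.linalg.qr(X)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(k))
    return Q @ L.T


def variant_config(base: SimulationConfig, **kw) -> SimulationConfig:
    return dataclasses.replace(base, **kw)


@pytest.fixture(scope="session")
def tiny_genes():
    return gene_annotation(TINY)
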