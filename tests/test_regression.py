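"""Truncation rules and the GLS gene-property regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cellgwas import (
    CollinearityError,
    GeneCorrelation,
    RegressionDesign,
    ScanEngine,
    gls_fit,
    run_celltype_scan,
    truncate_gene_z,
    truncate_specificity,
)


def brute_force_gls(Z, X, R):
    """Explicit-inverse GLS oracle: beta, SE(beta), one-sided P for column 1."""
    Ri = np.linalg.inv(R)
    XtRiX = X.T @ Ri @ X
    beta = np.linalg.solve(XtRiX, X.T @ Ri @ Z)
    resid = Z - X @ beta
    df = len(Z) - X.shape[1]
    sigma2 = float(resid @ Ri @ resid) / df
    cov = sigma2 * np.linalg.inv(XtRiX)
    se = float(np.sqrt(cov[1, 1]))
    t = beta[1] / se
    return float(beta[1]), se, float(stats.t.sf(t, df))


def make_design(Z, spec, C=None, R=None, genes=None):
    G = len(Z)
    C = np.empty((G, 0)) if C is None else np.asarray(C, dtype=float)
    R = np.eye(G) if R is None else R
    genes = genes or [f"g{i}" for i in range(G)]
    return RegressionDesign(genes, np.asarray(Z, float), np.asarray(spec, float), C, R)


def random_correlation(G, rng):
    A = rng.standard_normal((G, G + 5))
    S = A @ A.T / (G + 5)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


class TestTruncation:
    def test_gene_z_within_bounds_unchanged(self):
        v = np.array([0.0, 0.0, 0.0, 0.0, 100.0])
        # mean 20, sd 44.72: 100 < 20 + 6 * 44.72, so nothing clamps
        assert np.array_equal(truncate_gene_z(v), v)

    def test_gene_z_outlier_clamped_asymmetrically(self):
        # a single outlier in a short vector can never exceed mean + 6 sd
        # (max standardized value is (n-1)/sqrt(n)); use n = 100
        v = np.concatenate([np.zeros(99), [1_000.0]])
        out = truncate_gene_z(v)
        assert out[-1] == pytest.approx(v.mean() + 6 * v.std(ddof=1))  # 610
        low = -v
        assert truncate_gene_z(low)[-1] == pytest.approx(
            low.mean() - 3 * low.std(ddof=1)
        )

    def test_specificity_symmetric_clamp(self, rng):
        v = np.concatenate([rng.normal(0, 1, 500), [50.0]])
        out = truncate_specificity(v)
        assert out[-1] == pytest.approx(v.mean() + 5 * v.std(ddof=1))

    def test_zero_variance_warns_and_passes_through(self):
        with pytest.warns(UserWarning):
            out = truncate_gene_z(np.ones(5))
        assert np.array_equal(out, np.ones(5))

    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=40))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_truncations_are_idempotent(self, values):
        v = np.asarray(values)
        for fn in (truncate_gene_z, truncate_specificity):
            once = fn(v)
            assert np.allclose(fn(once), once, rtol=0, atol=1e-9)


class TestGlsFit:
    def test_identity_correlation_matches_ols(self, rng):
        Z = rng.standard_normal(10)
        s = rng.standard_normal(10)
        fit = gls_fit(make_design(Z, s))
        X = np.column_stack([np.ones(10), s])
        b_ols = np.linalg.solve(X.T @ X, X.T @ Z)
        assert fit.beta1 == pytest.approx(b_ols[1], abs=1e-8)

    @pytest.mark.parametrize("G,k", [(20, 0), (50, 3)])
    def test_matches_explicit_inverse_oracle(self, G, k, rng):
        R = random_correlation(G, rng)
        Z = rng.standard_normal(G)
        s = rng.standard_normal(G)
        C = rng.standard_normal((G, k))
        fit = gls_fit(make_design(Z, s, C, R))
        X = np.column_stack([np.ones(G), s, C])
        b, se, p = brute_force_gls(Z, X, R)
        assert fit.beta1 == pytest.approx(b, abs=1e-8)
        assert fit.se == pytest.approx(se, abs=1e-8)
        assert fit.p_one_sided == pytest.approx(p, abs=1e-8)

    def test_exact_linear_relation_saturates(self, rng):
        s = rng.standard_normal(12)
        fit = gls_fit(make_design(2.0 * s + 1.0, s))
        assert fit.beta1 == pytest.approx(2.0, abs=1e-10)
        assert fit.p_one_sided <= 1e-12

    def test_collinear_specificity_identified(self, rng):
        s = rng.standard_normal(15)
        with pytest.raises(CollinearityError, match="specificity|covariate"):
            gls_fit(make_design(rng.standard_normal(15), s, C=s[:, None]))

    def test_scale_equivariance(self, rng):
        Z = rng.standard_normal(30)
        s = rng.standard_normal(30)
        R = random_correlation(30, rng)
        a = gls_fit(make_design(Z, s, R=R))
        b = gls_fit(make_design(Z, 7.0 * s, R=R))
        assert b.beta1 == pytest.approx(a.beta1 / 7.0, rel=1e-9)
        assert b.t == pytest.approx(a.t, rel=1e-9)
        assert b.p_one_sided == pytest.approx(a.p_one_sided, rel=1e-9)


def toy_scan_inputs(G, C, rng, signal_col=None):
    genes = [f"g{i}" for i in range(G)]
    spec = pd.DataFrame(
        rng.dirichlet(np.ones(C), size=G), index=pd.Index(genes, name="gene")
    )
    Z = rng.standard_normal(G)
    if signal_col is not None:
        Z = Z + 8.0 * spec[signal_col].to_numpy()
    gene_stats = pd.DataFrame({"GENE": genes, "ZSTAT": Z})
    corr = GeneCorrelation(genes, np.eye(G))
    return gene_stats, spec, corr


class TestCellTypeScan:
    def test_scan_agrees_with_single_fits(self, rng):
        gene_stats, spec, corr = toy_scan_inputs(80, 5, rng, signal_col=2)
        scan = run_celltype_scan(gene_stats, spec, corr)
        engine = ScanEngine(gene_stats, spec, corr)
        for _, row in scan.iterrows():
            design = RegressionDesign(
                engine.genes,
                engine.Z,
                engine.spec_truncated[:, engine.celltypes.index(row["CELLTYPE"])],
                engine.covariates,
                engine.R,
                celltype=row["CELLTYPE"],
            )
            fit = gls_fit(design)
            assert row["BETA"] == pytest.approx(fit.beta1, abs=1e-8)
            assert row["P_ONESIDED"] == pytest.approx(fit.p_one_sided, abs=1e-8)

    def test_signal_column_is_top_hit_and_flagged(self, rng):
        gene_stats, spec, corr = toy_scan_inputs(300, 8, rng, signal_col=3)
        scan = run_celltype_scan(gene_stats, spec, corr)
        best = scan.sort_values("P_ONESIDED").iloc[0]
        assert best["CELLTYPE"] == 3
        assert best["BONF_SIG"]
        assert (scan["P_ONESIDED"] < 0.05 / 8).equals(scan["BONF_SIG"])

    def test_independent_specificity_gives_null_pvalues(self, rng):
        """Specificity columns independent of Z yield calibrated one-sided P."""
        G, C, n_rep = 120, 3, 150
        genes = [f"g{i}" for i in range(G)]
        corr = GeneCorrelation(genes, np.eye(G))
        spec = pd.DataFrame(
            rng.uniform(size=(G, C)), index=pd.Index(genes, name="gene")
        )
        hits = 0
        for _ in range(n_rep):
            Z = rng.standard_normal(G)
            scan = ScanEngine(
                pd.DataFrame({"GENE": genes, "ZSTAT": Z}), spec, corr
            ).scan()
            hits += int((scan["P_ONESIDED"] < 0.05).sum())
        n_tests = n_rep * C
        rate = hits / n_tests
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_tests)

    def test_empty_gene_intersection_rejected(self, rng):
        gene_stats, spec, corr = toy_scan_inputs(10, 2, rng)
        other = spec.copy()
        other.index = [f"x{i}" for i in range(10)]
        with pytest.raises(ValueError, match="no genes shared"):
            run_celltype_scan(gene_stats, other, corr)
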