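"""MANOVA engine: SSCP oracles, Pillai trace, F mapping, per-SNP contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drmanova.data import (
    MISSING,
    AnalysisDataset,
    CovariateMatrix,
    GenotypeDataset,
    PhenotypeMatrix,
    SampleInfo,
    SNPInfo,
)
from drmanova.manova import (
    DegenerateDesignError,
    DesignSpec,
    SSCPPair,
    build_design,
    fit_sscp,
    pillai_f_approx,
    pillai_trace,
    run_gwas,
)
from drmanova.manova import test_snp as manova_test_snp


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def test_genotypic_design_indicator_columns():
    Xf, Xr, dfh = build_design(np.array([0, 1, 2, 1]), None, DesignSpec())
    assert dfh == 2
    assert np.array_equal(Xf[:, 1], [0, 1, 0, 1])
    assert np.array_equal(Xf[:, 2], [0, 0, 1, 0])
    assert Xr.shape[1] == 1


def test_two_class_genotype_collapses_to_single_indicator():
    Xf, _, dfh = build_design(np.array([0, 1, 0, 1]), None, DesignSpec())
    assert dfh == 1
    assert Xf.shape[1] == 2
    assert np.array_equal(Xf[:, 1], [0, 1, 0, 1])


def test_additive_design_uses_counts():
    Xf, _, dfh = build_design(np.array([0, 1, 2]), None, DesignSpec("additive"))
    assert dfh == 1
    assert np.array_equal(Xf[:, 1], [0, 1, 2])


def test_monomorphic_counts_raise():
    with pytest.raises(DegenerateDesignError, match="monomorphic"):
        build_design(np.zeros(10, dtype=int), None, DesignSpec())


# ---------------------------------------------------------------------------
# SSCP fitting vs explicit hat-matrix oracle
# ---------------------------------------------------------------------------


def _hat(X):
    return X @ np.linalg.pinv(X)


@pytest.mark.parametrize("seed", range(5))
def test_fit_sscp_matches_hat_matrix_oracle(seed):
    rng = np.random.default_rng(seed)
    n, p = 12, 2
    g = rng.integers(0, 3, n)
    g[:3] = [0, 1, 2]  # guarantee 3 classes
    cov = rng.normal(size=(n, 1))
    Y = rng.normal(size=(n, p))
    Xf, Xr, _ = build_design(g, cov, DesignSpec())
    sscp = fit_sscp(Y, Xf, Xr)
    I = np.eye(n)
    E_o = Y.T @ (I - _hat(Xf)) @ Y
    H_o = Y.T @ (_hat(Xf) - _hat(Xr)) @ Y
    np.testing.assert_allclose(sscp.E, E_o, atol=1e-10)
    np.testing.assert_allclose(sscp.H, H_o, atol=1e-10)
    assert sscp.df_err == n - np.linalg.matrix_rank(Xf)


def test_perfect_fit_gives_zero_error_sscp(rng):
    n = 20
    g = rng.integers(0, 3, n)
    g[:3] = [0, 1, 2]
    Xf, Xr, _ = build_design(g, None, DesignSpec())
    B = rng.normal(size=(Xf.shape[1], 2))
    Y = Xf @ B  # exactly linear in the design
    sscp = fit_sscp(Y, Xf, Xr)
    np.testing.assert_allclose(sscp.E, 0, atol=1e-12)


def test_identical_designs_give_zero_hypothesis_sscp(rng):
    X = np.column_stack([np.ones(15), rng.normal(size=15)])
    Y = rng.normal(size=(15, 3))
    sscp = fit_sscp(Y, X, X)
    np.testing.assert_allclose(sscp.H, 0, atol=1e-10)
    assert sscp.df_hyp == 0


# ---------------------------------------------------------------------------
# Pillai trace and its F approximation
# ---------------------------------------------------------------------------


def test_pillai_trace_hand_values():
    one = SSCPPair(H=np.array([[3.0]]), E=np.array([[1.0]]), df_hyp=1, df_err=10)
    assert pillai_trace(one) == pytest.approx(0.75)
    zero = SSCPPair(H=np.zeros((2, 2)), E=np.eye(2), df_hyp=2, df_err=10)
    assert pillai_trace(zero) == pytest.approx(0.0)
    # E ~ 0 with invertible H: every eigenvalue 1, V = p = 2
    sep = SSCPPair(H=np.eye(2), E=np.eye(2) * 1e-14, df_hyp=2, df_err=10)
    assert pillai_trace(sep) == pytest.approx(2.0, abs=1e-10)


def test_pillai_f_edge_cases():
    F, df1, df2, p = pillai_f_approx(0.0, 3, 2, 100)
    assert F == 0 and p == 1.0
    F, _, _, p = pillai_f_approx(1.0, 2, 1, 100)  # V at its bound s=1
    assert np.isinf(F) and p == np.nextafter(0.0, 1.0)


@pytest.mark.parametrize("seed", range(8))
def test_univariate_reduction_equals_ancova(seed):
    """p=1 Pillai pipeline reproduces the classical ANCOVA F test exactly."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    rng = np.random.default_rng(100 + seed)
    n = 30 + seed
    g = rng.integers(0, 3, n)
    g[:3] = [0, 1, 2]
    x = rng.normal(size=n)
    y = 0.4 * g + 0.3 * x + rng.normal(size=n)
    Xf, Xr, _ = build_design(g, x[:, None], DesignSpec())
    sscp = fit_sscp(y[:, None], Xf, Xr)
    V = pillai_trace(sscp)
    F, df1, df2, p = pillai_f_approx(V, 1, sscp.df_hyp, sscp.df_err)
    tab = anova_lm(
        smf.ols("y ~ x + C(g)", pd.DataFrame({"y": y, "g": g, "x": x})).fit(), typ=2
    )
    assert F == pytest.approx(tab.loc["C(g)", "F"], abs=1e-10)
    assert df1 == tab.loc["C(g)", "df"]
    assert df2 == tab.loc["Residual", "df"]
    assert p == pytest.approx(tab.loc["C(g)", "PR(>F)"], abs=1e-10)


@given(st.integers(0, 500))
def test_trace_bounded_by_s(seed):
    rng = np.random.default_rng(seed)
    n, p = 25, 3
    g = rng.integers(0, 3, n)
    if np.unique(g).size < 2:
        g[0] = (g[1] + 1) % 3
    Y = rng.normal(size=(n, p))
    Xf, Xr, dfh = build_design(g, None, DesignSpec())
    sscp = fit_sscp(Y, Xf, Xr)
    V = pillai_trace(sscp)
    assert 0.0 <= V <= min(p, sscp.df_hyp) + 1e-12


def test_affine_invariance_of_test(rng):
    """Shifting one response column or rescaling all leaves V and p unchanged."""
    n = 60
    g = rng.integers(0, 3, n)
    g[:3] = [0, 1, 2]
    Y = rng.normal(size=(n, 4))

    def run(Ym):
        Xf, Xr, _ = build_design(g, None, DesignSpec())
        sscp = fit_sscp(Ym, Xf, Xr)
        V = pillai_trace(sscp)
        return V, pillai_f_approx(V, 4, sscp.df_hyp, sscp.df_err)[3]

    V0, p0 = run(Y)
    shifted = Y.copy()
    shifted[:, 2] += 7.3
    V1, p1 = run(shifted)
    V2, p2 = run(2.5 * Y)
    assert V1 == pytest.approx(V0, abs=1e-10) and p1 == pytest.approx(p0, abs=1e-10)
    assert V2 == pytest.approx(V0, abs=1e-10) and p2 == pytest.approx(p0, abs=1e-10)


def test_permutation_and_asymptotic_pvalues_agree():
    """Genotype-label permutation p-value tracks the F-approximation p-value."""
    from drmanova.simulate import signal_config, simulate

    rng = np.random.default_rng(77)
    ds = simulate(signal_config(effect_size=0.0), rng=rng)
    g, Y = ds.genotype_counts, ds.Y

    def pillai_V(gv):
        Xf, Xr, _ = build_design(gv, None, DesignSpec())
        return pillai_trace(fit_sscp(Y, Xf, Xr))

    Xf, Xr, _ = build_design(g, None, DesignSpec())
    sscp = fit_sscp(Y, Xf, Xr)
    V_obs = pillai_trace(sscp)
    p_asym = pillai_f_approx(V_obs, sscp.p, sscp.df_hyp, sscp.df_err)[3]
    n_perm = 4000
    exceed = 0
    for _ in range(n_perm):
        exceed += pillai_V(rng.permutation(g)) >= V_obs
    p_perm = (1 + exceed) / (1 + n_perm)
    assert abs(p_perm - p_asym) < 0.02


# ---------------------------------------------------------------------------
# per-SNP streaming
# ---------------------------------------------------------------------------


def _toy_dataset(rng, n=40, m=5, missing_snp=None, monomorphic_snp=None):
    counts = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    counts[:3, :] = np.array([[0], [1], [2]]) @ np.ones((1, m), dtype=np.int8)
    if missing_snp is not None:
        counts[rng.random(n) < 0.1, missing_snp] = MISSING
    if monomorphic_snp is not None:
        counts[:, monomorphic_snp] = 0
    samples = [SampleInfo("F", f"I{i}") for i in range(n)]
    snps = [SNPInfo("1", f"rs{j}", 0.0, j + 1, "A", "C", "A", 0.3) for j in range(m)]
    geno = GenotypeDataset(samples=samples, snps=snps, counts=counts)
    pheno = PhenotypeMatrix(
        samples=samples, doses=np.arange(1.0, 4.0), values=rng.normal(size=(n, 3))
    )
    return AnalysisDataset(genotype=geno, phenotype=pheno)


def test_monomorphic_snp_yields_skipped_result(rng):
    ds = _toy_dataset(rng, monomorphic_snp=2)
    res = manova_test_snp(ds, 2)
    assert res.note == "monomorphic"
    assert not res.tested


def test_missing_genotypes_reduce_n_used(rng):
    ds = _toy_dataset(rng, missing_snp=1)
    res = manova_test_snp(ds, 1)
    n_missing = int((ds.genotype.counts[:, 1] == MISSING).sum())
    assert res.n_used == ds.n_samples - n_missing
    assert res.tested


def test_run_gwas_matches_test_snp_exactly(rng):
    ds = _toy_dataset(rng, m=8, missing_snp=3, monomorphic_snp=6)
    results = run_gwas(ds)
    assert len(results) == 8
    for j, r in enumerate(results):
        single = manova_test_snp(ds, j)
        assert r.p_value == single.p_value or (np.isnan(r.p_value) and np.isnan(single.p_value))
        assert r.statistic == single.statistic or np.isnan(r.statistic)
        assert r.note == single.note


def test_strong_signal_detected():
    from drmanova.simulate import signal_config, simulate

    rng = np.random.default_rng(5)
    ds = simulate(signal_config(effect_size=1.0), rng=rng)
    Xf, Xr, _ = build_design(ds.genotype_counts, None, DesignSpec())
    sscp = fit_sscp(ds.Y, Xf, Xr)
    V = pillai_trace(sscp)
    p = pillai_f_approx(V, sscp.p, sscp.df_hyp, sscp.df_err)[3]
    assert p < 1e-6


def test_null_gwas_rejection_rate_calibrated(rng):
    """Fraction of p < 0.05 over many null SNPs is binomially consistent."""
    n, m = 150, 800
    counts = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    samples = [SampleInfo("F", f"I{i}") for i in range(n)]
    snps = [SNPInfo("1", f"rs{j}", 0.0, j + 1, "A", "C", "A", 0.5) for j in range(m)]
    geno = GenotypeDataset(samples=samples, snps=snps, counts=counts)
    pheno = PhenotypeMatrix(
        samples=samples, doses=np.arange(1.0, 5.0), values=rng.normal(size=(n, 4))
    )
    results = run_gwas(AnalysisDataset(genotype=geno, phenotype=pheno))
    pvals = np.array([r.p_value for r in results if r.tested])
    rate = np.mean(pvals < 0.05)
    assert abs(rate - 0.05) < 4 * np.sqrt(0.05 * 0.95 / pvals.size)
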