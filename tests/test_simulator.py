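"""Generating model: HWE draws, effect scaling, covariances, moments."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drmanova.hill import fit_hill
from drmanova.simulate import (
    CovarianceSpec,
    ErrorFamily,
    HillPopulationConfig,
    MeanProfileSet,
    SimulationConfig,
    build_covariance,
    effect_means,
    hill_population,
    sample_genotypes,
    signal_config,
    simulate,
    summary_driven_means,
    synthetic_signal,
)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def test_hwe_class_frequencies_at_half_maf():
    g = sample_genotypes(10_000, 0.5, seed=1)
    counts = np.bincount(g, minlength=3)
    for k, p in enumerate([0.25, 0.5, 0.25]):
        se = np.sqrt(p * (1 - p) * 10_000)
        assert abs(counts[k] - p * 10_000) < 4 * se


def test_rare_allele_limit_mostly_homozygous():
    g = sample_genotypes(2000, 1e-6, seed=2)
    assert np.all(g == 0)


def test_genotype_determinism_and_validation():
    assert np.array_equal(sample_genotypes(50, 0.3, seed=7), sample_genotypes(50, 0.3, seed=7))
    with pytest.raises(ValueError):
        sample_genotypes(10, 0.7, seed=0)
    with pytest.raises(ValueError):
        sample_genotypes(10, 0.0, seed=0)


# ---------------------------------------------------------------------------
# effect-size scaling of means
# ---------------------------------------------------------------------------


def test_effect_means_null_and_full():
    means = MeanProfileSet(
        doses=[1.0, 2.0], mu0=[0.0, 0.0], mu1=[2.0, 4.0], mu2=[3.0, 5.0]
    )
    m0, m1, m2 = effect_means(means, 0.0)
    assert np.array_equal(m1, m0) and np.array_equal(m2, m0)
    _, m1, m2 = effect_means(means, 1.0)
    np.testing.assert_allclose(m1, [2.0, 4.0])
    np.testing.assert_allclose(m2, [3.0, 5.0])
    _, m1, _ = effect_means(means, 0.5)
    np.testing.assert_allclose(m1, [1.0, 2.0])


@given(st.floats(0, 1), st.integers(0, 50))
def test_group_separation_linear_in_effect_size(es, seed):
    rng = np.random.default_rng(seed)
    means = MeanProfileSet(
        doses=np.arange(1.0, 5.0),
        mu0=rng.normal(size=4),
        mu1=rng.normal(size=4),
        mu2=rng.normal(size=4),
    )
    m0, _, m2 = effect_means(means, es)
    lhs = np.linalg.norm(m2 - m0)
    rhs = es * np.linalg.norm(means.mu2 - means.mu0)
    assert lhs == pytest.approx(rhs, abs=1e-10)


# ---------------------------------------------------------------------------
# covariance constructors
# ---------------------------------------------------------------------------


def test_autoregressive_matrix_values():
    got = build_covariance(CovarianceSpec("autoregressive", 0.5, 1.0), 3)
    np.testing.assert_allclose(got, [[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]])


def test_compound_symmetric_matrix_values():
    got = build_covariance(CovarianceSpec("compound_symmetric", 0.75, 2.0), 6)
    off = got[~np.eye(6, dtype=bool)]
    np.testing.assert_allclose(off, 0.75 * 4.0)
    np.testing.assert_allclose(np.diag(got), 4.0)


def test_independent_is_diagonal():
    got = build_covariance(CovarianceSpec("independent", 0.0, [1.0, 2.0, 3.0]), 3)
    np.testing.assert_allclose(got, np.diag([1.0, 4.0, 9.0]))


def test_invalid_cs_rho_rejected():
    with pytest.raises(ValueError, match="rho"):
        build_covariance(CovarianceSpec("compound_symmetric", -0.5, 1.0), 6)


@given(
    st.sampled_from(["compound_symmetric", "autoregressive", "independent"]),
    st.floats(-0.15, 0.95),
    st.integers(2, 8),
)
def test_covariances_positive_definite_in_valid_range(family, rho, d):
    sigma = build_covariance(CovarianceSpec(family, rho, 1.0), d)
    assert np.linalg.eigvalsh(sigma).min() > 0


# ---------------------------------------------------------------------------
# simulate(): determinism and moments
# ---------------------------------------------------------------------------


def test_simulate_deterministic_given_seed():
    cfg = signal_config(effect_size=0.7, n=40, seed=123)
    a, b = simulate(cfg), simulate(cfg)
    assert np.array_equal(a.Y, b.Y)
    assert np.array_equal(a.genotype_counts, b.genotype_counts)


def test_gamma_error_moments():
    means, _ = synthetic_signal()
    cfg = SimulationConfig(
        means=means,
        errors=ErrorFamily(kind="gamma_centered", gamma_shape=8.0, gamma_scale=0.125),
        effect_size=0.0,
        n=20_000,
    )
    ds = simulate(cfg, rng=np.random.default_rng(3))
    eps = ds.Y - means.mu0  # ES=0: all share mu0
    n_draws = eps.size
    target_var = 8.0 * 0.125**2
    assert abs(eps.mean()) < 4 * np.sqrt(target_var / n_draws)
    assert abs(eps.var() - target_var) < 4 * target_var * np.sqrt(2.0 / n_draws)


def test_replicates_share_individual_genotype():
    cfg = signal_config(effect_size=0.0, n=30)
    cfg = SimulationConfig(
        means=cfg.means, covariance=cfg.covariance, effect_size=0.0, n=30,
        replicates_per_individual=3,
    )
    ds = simulate(cfg, rng=np.random.default_rng(1))
    assert ds.Y.shape == (90, 6)
    assert np.array_equal(ds.individual, np.repeat(np.arange(30), 3))


# ---------------------------------------------------------------------------
# synthetic signal
# ---------------------------------------------------------------------------


def test_signal_null_at_zero_strength():
    means, _ = synthetic_signal(strength=0.0)
    np.testing.assert_allclose(means.mu1, means.mu0)
    np.testing.assert_allclose(means.mu2, means.mu0)


def test_signal_curves_monotone_decreasing_and_ordered():
    means, cov = synthetic_signal()
    for mu in (means.mu0, means.mu1, means.mu2):
        assert np.all(np.diff(mu) < 0)
    # separation grows with allele count (resistance ordering) at mid doses
    assert np.all(means.mu2[1:5] > means.mu0[1:5])
    corr = cov.matrix / np.sqrt(np.outer(np.diag(cov.matrix), np.diag(cov.matrix)))
    off = corr[~np.eye(6, dtype=bool)]
    assert off.min() > 0.4 and off.max() <= 0.9 + 1e-12


# ---------------------------------------------------------------------------
# hill-population (Laplace) alternatives
# ---------------------------------------------------------------------------


def test_hill_population_zero_shift_zero_noise_identical_within_genotype():
    cfg = HillPopulationConfig(
        sd_min=0.0, sd_max=0.0, sd_log_ic50=0.0, sd_slope=0.0,
        shift_per_allele=0.0, laplace_scale=1e-12, n=60,
    )
    ds = hill_population(cfg, es=1.0, seed=3)
    np.testing.assert_allclose(ds.Y, np.broadcast_to(ds.Y[0], ds.Y.shape), atol=1e-9)


def test_hill_population_laplace_kurtosis():
    cfg = HillPopulationConfig(
        sd_min=0.0, sd_max=0.0, sd_log_ic50=0.0, sd_slope=0.0,
        shift_per_allele=0.0, laplace_scale=0.25, n=20_000, doses=np.arange(1.0, 6.0),
    )
    ds = hill_population(cfg, es=0.0, seed=4)
    eps = ds.Y - ds.Y.mean(axis=0)
    z = eps.ravel()
    kurt = np.mean(z**4) / np.mean(z**2) ** 2 - 3.0
    assert kurt == pytest.approx(3.0, abs=0.25)  # Laplace excess kurtosis


def test_hill_population_ic50_shift_moves_only_ic50():
    cfg = HillPopulationConfig(
        sd_min=0.0, sd_max=0.0, sd_log_ic50=0.0, sd_slope=0.0,
        shifted_param="ic50", shift_per_allele=0.2, laplace_scale=1e-12, n=300,
    )
    ds = hill_population(cfg, es=1.0, seed=5)
    for g in range(3):
        rows = ds.Y[ds.genotype_counts == g]
        fit = fit_hill(cfg.doses, rows[0])
        assert np.log10(fit.ic50) == pytest.approx(np.log10(cfg.base_ic50) + 0.2 * g, abs=1e-3)
        assert fit.min_asymptote == pytest.approx(cfg.base_min, abs=1e-3)


# ---------------------------------------------------------------------------
# summary-driven 12-dose means
# ---------------------------------------------------------------------------


def test_summary_driven_zero_shift_identical():
    m = summary_driven_means("IC50", shift=0.0)
    np.testing.assert_allclose(m.mu1, m.mu0)
    np.testing.assert_allclose(m.mu2, m.mu0)


def test_summary_driven_ic50_changes_only_ic50():
    m = summary_driven_means("IC50")
    fits = [fit_hill(m.doses, mu) for mu in (m.mu0, m.mu1, m.mu2)]
    ic50s = [f.ic50 for f in fits]
    assert ic50s[0] < ic50s[1] < ic50s[2]
    for f in fits:
        assert f.min_asymptote == pytest.approx(fits[0].min_asymptote, abs=1e-3)
        assert f.max_asymptote == pytest.approx(fits[0].max_asymptote, abs=1e-3)


def test_summary_driven_auc_offsets_match_design():
    shift = 0.02
    m = summary_driven_means("AUC", shift=shift)
    from drmanova.summaries import auc_empirical

    a0 = auc_empirical(m.doses, m.mu0)
    span = m.doses[-1] - m.doses[0]
    assert auc_empirical(m.doses, m.mu1) - a0 == pytest.approx(shift * span, abs=1e-10)
    assert auc_empirical(m.doses, m.mu2) - a0 == pytest.approx(2 * shift * span, abs=1e-10)
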