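"""Generative models for genotypes and multivariate dose-response phenotypes.

The core generating model draws, for individual j with genotype i (number of
minor alleles) and replicate k,

    Y_ijk = mu~_i + eps,        mu~_i = mu_0 + ES * (mu_i - mu_0),

where ES in [0, 1] scales the genotype mean-difference vectors (ES = 0 is
the null; ES = 1 reproduces the full configured between-genotype
differences). Errors are multivariate gaussian with a configurable
covariance (empirical, compound-symmetric, autoregressive or independent),
or independent centred-gamma / Laplace components for robustness studies.
Genotypes are drawn under Hardy-Weinberg equilibrium at a configured MAF.

``synthetic_signal`` builds a realistic stand-in for an empirically derived
cytotoxicity signal: three monotone sigmoid mean curves over six
concentrations whose separation grows with minor-allele count, plus a
covariance with strong positive correlations decaying with dose distance.
It is a synthetic emulation, not a digitisation of any real assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from scipy.special import expit

from .hill import LN10, hill_curve


@dataclass
class MeanProfileSet:
    """Mean response vectors for genotypes carrying 0, 1 and 2 minor alleles."""

    doses: np.ndarray
    mu0: np.ndarray
    mu1: np.ndarray
    mu2: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.mu0 = np.asarray(self.mu0, dtype=float)
        self.mu1 = np.asarray(self.mu1, dtype=float)
        self.mu2 = np.asarray(self.mu2, dtype=float)
        d = self.doses.size
        if not (self.mu0.size == self.mu1.size == self.mu2.size == d):
            raise ValueError("mean vectors and dose grid must share one length")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")

    @property
    def n_doses(self) -> int:
        return self.doses.size


@dataclass
class CovarianceSpec:
    """Error covariance recipe: a correlation family scaled by per-dose SDs.

    families:
      - ``empirical``: explicit d x d covariance in ``matrix``
      - ``compound_symmetric``: constant correlation rho, valid for
        rho in (-1/(d-1), 1)
      - ``autoregressive``: correlation rho**|i-j|, rho in (-1, 1)
      - ``independent``: identity correlation
    """

    family: str = "independent"
    rho: float = 0.0
    scale: float | np.ndarray = 1.0
    matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family not in ("empirical", "compound_symmetric", "autoregressive", "independent"):
            raise ValueError(f"unknown covariance family {self.family!r}")


@dataclass
class ErrorFamily:
    """Error distribution for the response vectors.

    ``gaussian`` uses the configured covariance; ``gamma_centered`` and
    ``laplace`` draw components independently across doses. The default
    Laplace scale 0.25 gives variance 2 * 0.25**2 = 0.125, matching the
    default centred gamma (shape 8, scale 0.125, variance 8 * 0.125**2).
    """

    kind: str = "gaussian"
    gamma_shape: float = 8.0
    gamma_scale: float = 0.125
    laplace_scale: float = 0.25

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "gamma_centered", "laplace"):
            raise ValueError(f"unknown error family {self.kind!r}")


@dataclass
class SimulationConfig:
    """Full recipe for one generating model."""

    means: MeanProfileSet
    covariance: CovarianceSpec = field(default_factory=CovarianceSpec)
    errors: ErrorFamily = field(default_factory=ErrorFamily)
    effect_size: float = 1.0
    n: int = 500
    maf: float = 0.5
    replicates_per_individual: int = 1
    seed: int = 0
    n_snps: int = 1  # extra null SNPs when writing on-disk fixtures

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect size must be non-negative")
        if not (0 < self.maf <= 0.5):
            raise ValueError("MAF must lie in (0, 0.5]")
        if self.replicates_per_individual < 1:
            raise ValueError("need at least one replicate per individual")
        if self.n < 1 or self.n_snps < 1:
            raise ValueError("n and n_snps must be positive")

    def with_effect_size(self, es: float) -> "SimulationConfig":
        return replace(self, effect_size=es)


@dataclass
class SimulatedDataset:
    """One simulated cohort: genotypes plus (n * k) x d responses."""

    genotype_counts: np.ndarray  # (n,) in {0, 1, 2}
    Y: np.ndarray  # (n * k, d)
    individual: np.ndarray  # (n * k,) row -> individual index
    truth: SimulationConfig

    @property
    def doses(self) -> np.ndarray:
        return self.truth.means.doses


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_genotypes(n: int, maf: float, seed) -> np.ndarray:
    """Draw n genotypes (minor-allele counts) under Hardy-Weinberg equilibrium."""
    if not (0 < maf <= 0.5):
        raise ValueError("MAF must lie in (0, 0.5]")
    rng = _as_rng(seed)
    probs = ((1 - maf) ** 2, 2 * maf * (1 - maf), maf**2)
    return rng.choice(3, size=n, p=probs).astype(np.int8)


def effect_means(means: MeanProfileSet, es: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale the genotype mean differences by the effect size.

    Returns (mu~0, mu~1, mu~2) with mu~0 = mu0 and
    mu~i = mu0 + es * (mu_i - mu0).
    """
    if es < 0:
        raise ValueError("effect size must be non-negative")
    mu0 = means.mu0
    return mu0.copy(), mu0 + es * (means.mu1 - mu0), mu0 + es * (means.mu2 - mu0)


def build_covariance(spec: CovarianceSpec, d: int) -> np.ndarray:
    """Materialise the d x d covariance and verify positive definiteness."""
    if spec.family == "empirical":
        if spec.matrix is None:
            raise ValueError("empirical covariance requires an explicit matrix")
        sigma = np.asarray(spec.matrix, dtype=float)
        if sigma.shape != (d, d):
            raise ValueError(f"empirical covariance must be {d}x{d}")
        if not np.allclose(sigma, sigma.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
    else:
        if spec.family == "compound_symmetric":
            if not (-1.0 / (d - 1) < spec.rho < 1.0):
                raise ValueError(
                    f"compound-symmetric rho must lie in (-1/(d-1), 1) = "
                    f"({-1.0 / (d - 1):.4f}, 1) for d={d}"
                )
            corr = np.full((d, d), spec.rho)
            np.fill_diagonal(corr, 1.0)
        elif spec.family == "autoregressive":
            if not (-1.0 < spec.rho < 1.0):
                raise ValueError("autoregressive rho must lie in (-1, 1)")
            idx = np.arange(d)
            corr = spec.rho ** np.abs(idx[:, None] - idx[None, :])
        else:  # independent
            corr = np.eye(d)
        sd = np.broadcast_to(np.asarray(spec.scale, dtype=float), (d,))
        sigma = corr * sd[:, None] * sd[None, :]
    eigmin = float(np.linalg.eigvalsh(sigma).min())
    if eigmin <= 0:
        raise ValueError(f"covariance is not positive definite (min eigenvalue {eigmin:.3e})")
    return sigma


def simulate(config: SimulationConfig, rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Draw one dataset under the configured generating model.

    Deterministic given ``config.seed`` when no generator is passed.
    """
    rng = _as_rng(config.seed) if rng is None else rng
    d = config.means.n_doses
    n, k = config.n, config.replicates_per_individual
    g = sample_genotypes(n, config.maf, rng)
    mus = np.stack(effect_means(config.means, config.effect_size))  # (3, d)
    mean_rows = np.repeat(mus[g], k, axis=0)  # (n*k, d)

    kind = config.errors.kind
    if kind == "gaussian":
        sigma = build_covariance(config.covariance, d)
        L = np.linalg.cholesky(sigma)
        eps = rng.standard_normal((n * k, d)) @ L.T
    elif kind == "gamma_centered":
        shape, scale = config.errors.gamma_shape, config.errors.gamma_scale
        eps = rng.gamma(shape, scale, size=(n * k, d)) - shape * scale
    else:  # laplace
        eps = rng.laplace(0.0, config.errors.laplace_scale, size=(n * k, d))

    return SimulatedDataset(
        genotype_counts=g,
        Y=mean_rows + eps,
        individual=np.repeat(np.arange(n), k),
        truth=config,
    )


# ---------------------------------------------------------------------------
# synthetic correlated signal (stand-in for an empirically estimated signal)
# ---------------------------------------------------------------------------

#: per-dose error SDs of the synthetic signal (largest where the curve is steep)
_SIGNAL_SDS = np.array([0.14, 0.19, 0.23, 0.24, 0.21, 0.17])
_SIGNAL_CORR_DECAY = 0.9  # adjacent-dose correlation; decays with distance


def synthetic_signal(
    d: int = 6, strength: float = 1.0, seed: int | None = None
) -> tuple[MeanProfileSet, CovarianceSpec]:
    """Construct a synthetic correlated dose-response association signal.

    Three monotone-decreasing sigmoid mean curves over ``d`` equally spaced
    concentrations; each copy of the minor allele shifts the curve toward
    resistance with a change of shape, not just of level: log10-IC50 up by
    ``0.08 * strength``, transition steepness up by ``0.35 * strength`` and
    lower plateau up by ``0.02 * strength`` per allele. The shape component
    matters: resistance signals that alter the curve's form are where a
    joint multivariate test has the most to gain over per-curve summaries.
    The covariance mimics empirically estimated assay error: correlations
    decay from ~0.9 (adjacent doses) toward ~0.6 (extreme doses) with
    per-dose SDs peaking mid-curve. Entirely synthetic — a stand-in
    emulation, not derived from any real assay.

    ``seed`` optionally jitters the SDs by a few percent to emulate
    re-estimated variances; the default (None) is the canonical model.
    """
    if strength < 0:
        raise ValueError("strength must be non-negative")
    doses = np.arange(1.0, d + 1.0)
    base_ic50 = 10 ** (np.log10(doses[0]) + 0.52 * (np.log10(doses[-1]) - np.log10(doses[0])))
    mus = []
    for g in range(3):
        mus.append(
            hill_curve(
                doses,
                min_asymptote=0.15 + 0.02 * strength * g,
                max_asymptote=1.0,
                ic50=base_ic50 * 10 ** (0.08 * strength * g),
                slope=1.6 + 0.35 * strength * g,
            )
        )
    means = MeanProfileSet(doses=doses, mu0=mus[0], mu1=mus[1], mu2=mus[2])

    idx = np.arange(d)
    corr = _SIGNAL_CORR_DECAY ** np.abs(idx[:, None] - idx[None, :])
    if d <= _SIGNAL_SDS.size:
        sds = _SIGNAL_SDS[:d].copy()
    else:
        sds = np.interp(np.linspace(0, 1, d), np.linspace(0, 1, _SIGNAL_SDS.size), _SIGNAL_SDS)
    if seed is not None:
        rng = np.random.default_rng(seed)
        sds = sds * np.exp(rng.normal(0.0, 0.05, size=d))
    sigma = corr * sds[:, None] * sds[None, :]
    return means, CovarianceSpec(family="empirical", matrix=sigma)


def signal_config(
    effect_size: float = 1.0,
    n: int = 500,
    maf: float = 0.5,
    d: int = 6,
    strength: float = 1.0,
    seed: int = 0,
    errors: ErrorFamily | None = None,
    covariance: CovarianceSpec | None = None,
) -> SimulationConfig:
    """Convenience: a SimulationConfig built on the synthetic signal."""
    means, cov = synthetic_signal(d=d, strength=strength)
    return SimulationConfig(
        means=means,
        covariance=cov if covariance is None else covariance,
        errors=errors if errors is not None else ErrorFamily(),
        effect_size=effect_size,
        n=n,
        maf=maf,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# hill-parameter population alternatives (Laplace-noise curve simulations)
# ---------------------------------------------------------------------------


@dataclass
class HillPopulationConfig:
    """Population of random 4PL curves with one genotype-shifted parameter.

    Each individual's curve parameters are drawn around their genotype's
    means: ``shifted_param`` moves by ``shift_per_allele`` per minor allele
    (log10 scale for IC50), the other parameters are shared. Responses are
    the 4PL curve at the dose grid plus i.i.d. Laplace noise.
    """

    doses: np.ndarray = field(default_factory=lambda: np.arange(1.0, 7.0))
    n: int = 500
    maf: float = 0.5
    base_min: float = 0.1
    base_max: float = 1.0
    base_ic50: float = 3.0
    base_slope: float = 1.5
    sd_min: float = 0.02
    sd_max: float = 0.02
    sd_log_ic50: float = 0.05
    sd_slope: float = 0.1
    shifted_param: str = "ic50"  # one of min, max, ic50, slope
    shift_per_allele: float = 0.1
    laplace_scale: float = 0.25

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        if self.shifted_param not in ("min", "max", "ic50", "slope"):
            raise ValueError(f"unknown shifted parameter {self.shifted_param!r}")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive")


def hill_population(
    config: HillPopulationConfig, es: float = 1.0, seed=0
) -> SimulatedDataset:
    """Simulate a cohort of random hill curves with Laplace errors.

    The genotype effect (``shift_per_allele``) is scaled by ``es`` so the
    same config serves both null (es=0) and alternative draws.
    """
    rng = _as_rng(seed)
    n, d = config.n, config.doses.size
    g = sample_genotypes(n, config.maf, rng)
    shift = es * config.shift_per_allele * g

    mn = rng.normal(config.base_min, config.sd_min, size=n)
    mx = rng.normal(config.base_max, config.sd_max, size=n)
    log_ic50 = rng.normal(np.log10(config.base_ic50), config.sd_log_ic50, size=n)
    slope = rng.normal(config.base_slope, config.sd_slope, size=n)
    if config.shifted_param == "min":
        mn = mn + shift
    elif config.shifted_param == "max":
        mx = mx + shift
    elif config.shifted_param == "ic50":
        log_ic50 = log_ic50 + shift  # log10-concentration shift
    else:
        slope = slope + shift

    x = np.log10(config.doses)
    f = expit(-LN10 * slope[:, None] * (x[None, :] - log_ic50[:, None]))
    Y = mn[:, None] + (mx - mn)[:, None] * f
    Y = Y + rng.laplace(0.0, config.laplace_scale, size=(n, d))

    placeholder_means = MeanProfileSet(
        doses=config.doses,
        mu0=hill_curve(config.doses, config.base_min, config.base_max, config.base_ic50, config.base_slope),
        mu1=np.zeros(d),
        mu2=np.zeros(d),
    )
    truth = SimulationConfig(
        means=placeholder_means,
        errors=ErrorFamily(kind="laplace", laplace_scale=config.laplace_scale),
        effect_size=es,
        n=n,
        maf=config.maf,
    )
    return SimulatedDataset(
        genotype_counts=g, Y=Y, individual=np.arange(n), truth=truth
    )


# ---------------------------------------------------------------------------
# summary-driven mean configurations (12-dose non-ideal alternatives)
# ---------------------------------------------------------------------------

#: base 4PL for the contrived 12-dose alternatives: both plateaus are well
#: sampled and the transition is steep, so every hill parameter is cleanly
#: identifiable from a single curve
_SUMMARY_BASE = {"min": 0.1, "max": 1.0, "ic50": 2.5, "slope": 4.0}


def summary_driven_means(
    summary: str, d: int = 12, shift: float | None = None
) -> MeanProfileSet:
    """Mean curves whose between-genotype difference is one univariate summary.

    ``summary`` is one of ``AUC``, ``Min``, ``IC50`` or ``Slope``. The three
    genotype mean curves derive from one base 4PL curve over ``d`` equally
    spaced doses; only the named summary differs across genotypes:

      - AUC: uniform vertical offset of ``shift`` per minor allele,
      - Min / IC50 / Slope: the corresponding hill parameter shifted by
        ``genotype count x shift`` (IC50 in concentration units).

    Default shifts give moderate per-allele separations relative to typical
    assay noise; they are parameters, not estimates of any real assay.
    """
    key = summary.lower().replace("_emp", "").replace("auc_emp", "auc")
    if key not in ("auc", "min", "ic50", "slope"):
        raise ValueError(f"unknown summary {summary!r}")
    defaults = {"auc": 0.02, "min": 0.03, "ic50": 0.035, "slope": 0.15}
    if shift is None:
        shift = defaults[key]
    doses = np.arange(1.0, d + 1.0)
    base = dict(_SUMMARY_BASE)
    curves = []
    for g in range(3):
        p = dict(base)
        if key == "min":
            p["min"] = base["min"] + g * shift
        elif key == "ic50":
            p["ic50"] = base["ic50"] + g * shift
        elif key == "slope":
            p["slope"] = base["slope"] + g * shift
        mu = hill_curve(doses, p["min"], p["max"], p["ic50"], p["slope"])
        if key == "auc":
            mu = mu + g * shift
        curves.append(mu)
    return MeanProfileSet(doses=doses, mu0=curves[0], mu1=curves[1], mu2=curves[2])
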