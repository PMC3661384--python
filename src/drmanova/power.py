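"""Method-comparison experiments: resampling p-values, power, type-I error,
Friedman cross-method tests and QQ calibration diagnostics.

The experimental design mirrors a standard simulation-based method
comparison: for each effect size, many datasets are simulated and *all*
methods are evaluated on the same dataset (paired design). A separate
stream of null datasets (effect size 0, disjoint seed stream) provides a
per-method null reference distribution; empirical p-values are the add-one
proportion of null statistics at least as extreme as the observed one,

    p = (1 + #{null >= stat}) / (1 + N_null),

so that p > 0 always and ties count toward the null (conservative).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import PhenotypeMatrix, SampleInfo
from .hill import fit_hill_curves
from .manova import DesignSpec, build_design, fit_sscp, pillai_f_approx, pillai_trace
from .simulate import SimulatedDataset, SimulationConfig, simulate
from .summaries import SummaryVector, anova_pooled_test, anova_summary_test, summarize

logger = logging.getLogger(__name__)

METHODS = ("MANOVA", "IC50", "Slope", "AUC_Emp", "ANOVA_pooled")

_NULL_STREAM = 0x9E3779B9  # seed-stream tag for null draws (disjoint from alternatives)


@dataclass
class NullReference:
    """Sorted null statistics for one method plus a config fingerprint."""

    method: str
    statistics: np.ndarray
    config_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.statistics = np.sort(np.asarray(self.statistics, dtype=float))
        if self.statistics.size < 1000:
            raise ValueError("null reference needs at least 1,000 statistics")

    @property
    def n_null(self) -> int:
        return self.statistics.size


def config_fingerprint(config: SimulationConfig) -> str:
    """Hash of the generating model with the effect size forced to zero."""
    null_cfg = config.with_effect_size(0.0)
    payload = {
        "doses": null_cfg.means.doses.tolist(),
        "mu0": null_cfg.means.mu0.tolist(),
        "mu1": null_cfg.means.mu1.tolist(),
        "mu2": null_cfg.means.mu2.tolist(),
        "cov_family": null_cfg.covariance.family,
        "rho": null_cfg.covariance.rho,
        "scale": np.asarray(null_cfg.covariance.scale, float).tolist(),
        "matrix": None
        if null_cfg.covariance.matrix is None
        else np.asarray(null_cfg.covariance.matrix, float).tolist(),
        "errors": (null_cfg.errors.kind, null_cfg.errors.gamma_shape,
                   null_cfg.errors.gamma_scale, null_cfg.errors.laplace_scale),
        "n": null_cfg.n,
        "maf": null_cfg.maf,
        "k": null_cfg.replicates_per_individual,
    }
    return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def empirical_pvalues(
    alt_stats: np.ndarray, null_ref: NullReference, fingerprint: str | None = None
) -> np.ndarray:
    """Add-one resampling p-values against a null reference.

    Statistics must be oriented so larger = more extreme. When both
    ``fingerprint`` (of the alternative generating model, effect size
    aside) and the reference's fingerprint are set, they must agree.
    """
    alt_stats = np.asarray(alt_stats, dtype=float)
    if fingerprint and null_ref.config_fingerprint and fingerprint != null_ref.config_fingerprint:
        raise ValueError("alternative and null statistics come from different generating models")
    nulls = null_ref.statistics  # sorted ascending
    n_ge = nulls.size - np.searchsorted(nulls, alt_stats, side="left")
    return (1.0 + n_ge) / (1.0 + nulls.size)


def estimate_power(pvals: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """Rejection proportion at ``alpha`` with its binomial standard error."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("no p-values supplied")
    power = float(np.mean(pvals <= alpha))
    return power, float(np.sqrt(power * (1.0 - power) / pvals.size))


# ---------------------------------------------------------------------------
# per-dataset method evaluation
# ---------------------------------------------------------------------------


@dataclass
class MethodOutcome:
    statistic: float  # F-scale (or trace-scale), larger = more extreme
    p_asymptotic: float


def evaluate_methods(dataset: SimulatedDataset, methods=METHODS) -> dict[str, MethodOutcome]:
    """Compute each method's test statistic and asymptotic p on one dataset.

    The IC50 and Slope methods share a single 4PL fit per individual.
    Degenerate outcomes (e.g. a monomorphic genotype draw) yield NaNs.
    """
    g = dataset.genotype_counts
    pheno = PhenotypeMatrix(
        samples=_sample_stubs(dataset.Y.shape[0]), doses=dataset.doses, values=dataset.Y
    )
    out: dict[str, MethodOutcome] = {}

    hill_methods = [m for m in methods if m in ("IC50", "Slope")]
    summaries = {}
    if hill_methods:
        fits = fit_hill_curves(dataset.doses, dataset.Y)
        for method in hill_methods:
            values = np.full(len(fits), np.nan)
            failed = set()
            for i, fit in enumerate(fits):
                if not fit.converged:
                    failed.add(i)
                elif method == "IC50":
                    values[i] = np.log10(fit.ic50)
                else:
                    values[i] = fit.slope
            summaries[method] = SummaryVector(method=method, values=values, failed=failed)

    for method in methods:
        if method == "MANOVA":
            try:
                X_full, X_reduced, _ = build_design(g, None, DesignSpec())
                sscp = fit_sscp(dataset.Y, X_full, X_reduced)
                V = pillai_trace(sscp)
                F, _, _, p = pillai_f_approx(V, sscp.p, sscp.df_hyp, sscp.df_err)
                out[method] = MethodOutcome(statistic=F, p_asymptotic=p)
            except Exception:  # degenerate draw
                out[method] = MethodOutcome(np.nan, np.nan)
        elif method in ("IC50", "Slope"):
            res = anova_summary_test(summaries[method], g)
            out[method] = MethodOutcome(statistic=res.F, p_asymptotic=res.p_value)
        elif method == "AUC_Emp":
            res = anova_summary_test(summarize(pheno, "AUC_Emp"), g)
            out[method] = MethodOutcome(statistic=res.F, p_asymptotic=res.p_value)
        elif method == "ANOVA_pooled":
            res = anova_pooled_test(pheno, g)
            out[method] = MethodOutcome(statistic=res.F, p_asymptotic=res.p_value)
        else:
            raise ValueError(f"unknown method {method!r}")
    return out


_STUB_CACHE: dict[int, list] = {}


def _sample_stubs(n: int) -> list[SampleInfo]:
    if n not in _STUB_CACHE:
        _STUB_CACHE[n] = [SampleInfo("F0", f"I{i}") for i in range(n)]
    return _STUB_CACHE[n]


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


@dataclass
class PowerTable:
    """method x effect-size grid of rejection proportions."""

    table: pd.DataFrame  # columns: method, effect_size, power, mc_stderr, n_reps

    def power(self, method: str, effect_size: float) -> float:
        t = self.table
        row = t[(t.method == method) & (np.isclose(t.effect_size, effect_size))]
        return float(row.power.iloc[0])


@dataclass
class PowerExperimentResult:
    power_table: PowerTable
    pvalue_matrices: dict[float, pd.DataFrame]  # effect size -> reps x methods
    null_references: dict[str, NullReference]
    statistic_matrices: dict[float, pd.DataFrame] = field(default_factory=dict)


def run_power_experiment(
    make_dataset,
    methods=METHODS,
    effect_sizes=(0.0, 0.25, 0.5, 0.75, 1.0),
    n_alt: int = 2500,
    n_null: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    fingerprint: str = "",
    max_failure_rate: float = 0.2,
) -> PowerExperimentResult:
    """Paired-design power comparison with a shared resampling null.

    ``make_dataset(es, rng)`` must return a :class:`SimulatedDataset` for
    effect size ``es``. One null reference per method is built from an
    effect-size-0 stream with a seed offset disjoint from the alternative
    streams; within a replicate every method sees the same dataset.
    Deterministic given ``seed``. Aborts if any method fails (NaN statistic)
    on more than ``max_failure_rate`` of replicates.
    """
    methods = tuple(methods)
    null_rng = np.random.default_rng(np.random.SeedSequence([seed, _NULL_STREAM]))
    null_stats = {m: np.empty(n_null) for m in methods}
    for r in range(n_null):
        ds = make_dataset(0.0, null_rng)
        outcome = evaluate_methods(ds, methods)
        for m in methods:
            null_stats[m][r] = outcome[m].statistic
    null_refs = {}
    for m in methods:
        stats_m = null_stats[m]
        bad = np.isnan(stats_m).mean()
        if bad > max_failure_rate:
            raise RuntimeError(f"method {m} failed on {bad:.0%} of null replicates")
        null_refs[m] = NullReference(
            method=m, statistics=stats_m[~np.isnan(stats_m)], config_fingerprint=fingerprint
        )

    rows = []
    pmats: dict[float, pd.DataFrame] = {}
    smats: dict[float, pd.DataFrame] = {}
    for es in effect_sizes:
        alt_rng = np.random.default_rng(np.random.SeedSequence([seed, 1, int(round(es * 1_000_000))]))
        stats_mat = np.empty((n_alt, len(methods)))
        for r in range(n_alt):
            ds = make_dataset(es, alt_rng)
            outcome = evaluate_methods(ds, methods)
            for c, m in enumerate(methods):
                stats_mat[r, c] = outcome[m].statistic
        pmat = np.empty_like(stats_mat)
        for c, m in enumerate(methods):
            col = stats_mat[:, c]
            if np.isnan(col).mean() > max_failure_rate:
                raise RuntimeError(f"method {m} failed on too many replicates at ES={es}")
            pcol = np.full(col.size, np.nan)
            ok = ~np.isnan(col)
            pcol[ok] = empirical_pvalues(col[ok], null_refs[m])
            pmat[:, c] = pcol
            power, se = estimate_power(pcol[ok], alpha)
            rows.append(
                {"method": m, "effect_size": es, "power": power, "mc_stderr": se, "n_reps": int(ok.sum())}
            )
        pmats[es] = pd.DataFrame(pmat, columns=list(methods))
        smats[es] = pd.DataFrame(stats_mat, columns=list(methods))

    return PowerExperimentResult(
        power_table=PowerTable(pd.DataFrame(rows)),
        pvalue_matrices=pmats,
        null_references=null_refs,
        statistic_matrices=smats,
    )


def friedman_compare(pmatrix: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Friedman rank test across methods (columns) over replicates (rows).

    Average ranks for ties, with the standard tie correction. Returns
    (chi-square statistic, df, upper-tail p). Rows containing NaN are
    dropped; all-constant data gives statistic 0 and p = 1.
    """
    X = np.asarray(pmatrix, dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    n, k = X.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 methods and 2 replicates")
    ranks = stats.rankdata(X, axis=1)
    rbar = ranks.mean(axis=0)
    chi = 12.0 * n / (k * (k + 1)) * float(((rbar - (k + 1) / 2.0) ** 2).sum())
    # tie correction: C = 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_sum = 0.0
    for row in X:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts**3 - counts).sum())
    C = 1.0 - tie_sum / (n * k * (k * k - 1))
    if C <= 0:
        return 0.0, k - 1, 1.0
    chi /= C
    return chi, k - 1, float(stats.chi2.sf(chi, k - 1))


def type1_error(
    method: str,
    null_config: SimulationConfig,
    n_reps: int = 10_000,
    alpha: float = 0.05,
    mode: str = "asymptotic",
    seed: int = 0,
    n_null: int = 2000,
) -> float:
    """Empirical rejection rate under the null (effect size must be 0)."""
    if null_config.effect_size != 0:
        raise ValueError("type-I error requires a null config (effect size 0)")
    if mode not in ("asymptotic", "resampling"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    stats_vec = np.empty(n_reps)
    pvals = np.empty(n_reps)
    for r in range(n_reps):
        ds = simulate(null_config, rng=rng)
        outcome = evaluate_methods(ds, (method,))[method]
        stats_vec[r] = outcome.statistic
        pvals[r] = outcome.p_asymptotic
    if mode == "asymptotic":
        return float(np.nanmean(pvals <= alpha))
    null_rng = np.random.default_rng(np.random.SeedSequence([seed, _NULL_STREAM]))
    ref_stats = np.empty(n_null)
    for r in range(n_null):
        ds = simulate(null_config, rng=null_rng)
        ref_stats[r] = evaluate_methods(ds, (method,))[method].statistic
    ref = NullReference(method=method, statistics=ref_stats[~np.isnan(ref_stats)])
    emp = empirical_pvalues(stats_vec[~np.isnan(stats_vec)], ref)
    return float(np.mean(emp <= alpha))


def null_statistics(
    config: SimulationConfig, method: str = "MANOVA", n_reps: int = 2000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate null statistics and asymptotic p-values for one method."""
    if config.effect_size != 0:
        raise ValueError("null statistics require effect size 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    stats_vec = np.empty(n_reps)
    pvals = np.empty(n_reps)
    for r in range(n_reps):
        ds = simulate(config, rng=rng)
        outcome = evaluate_methods(ds, (method,))[method]
        stats_vec[r] = outcome.statistic
        pvals[r] = outcome.p_asymptotic
    return stats_vec, pvals


def qq_data(
    null_stats: np.ndarray, reference: str, params: tuple = ()
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """QQ pairs and KS test of null statistics against a reference law.

    ``reference`` is ``"F"`` (params = (df1, df2)) or ``"uniform"``.
    Returns (theoretical quantiles, sorted observed, KS statistic, KS p).
    Theoretical quantiles use plotting positions (i - 0.5) / N.
    """
    null_stats = np.sort(np.asarray(null_stats, dtype=float))
    N = null_stats.size
    if N < 100:
        raise ValueError("need at least 100 statistics for a QQ diagnostic")
    probs = (np.arange(1, N + 1) - 0.5) / N
    if reference == "F":
        dist = stats.f(*params)
    elif reference == "uniform":
        dist = stats.uniform()
    else:
        raise ValueError(f"unknown reference {reference!r}")
    theoretical = dist.ppf(probs)
    ks = stats.kstest(null_stats, dist.cdf)
    return theoretical, null_stats, float(ks.statistic), float(ks.pvalue)
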