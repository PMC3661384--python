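"""Per-SNP multivariate linear model testing via Pillai's trace.

For each SNP a multivariate linear model is fitted to the n x p response
matrix Y under a full design (intercept + covariates + genotype terms) and
a reduced design (intercept + covariates). With E the residual SSCP under
the full model and H the extra SSCP explained by genotype,

    V = trace(H (H + E)^{-1})

is Pillai's trace, mapped to an F statistic through the standard
(s, m, n*) approximation (exact when s = min(p, df_hyp) = 1):

    s  = min(p, h),  m = (|p - h| - 1) / 2,  n* = (df_err - p - 1) / 2
    F  = (2n* + s + 1) / (2m + s + 1) * (V / s) / (1 - V / s)
    df1 = s (2m + s + 1),  df2 = s (2n* + s + 1)

The genotype enters either as a 3-level factor ("genotypic", two indicator
columns for 1 and 2 minor alleles, 2 hypothesis df) or as the allele count
("additive", 1 df). When only two genotype classes are observed the
genotypic model collapses to a single indicator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .data import MISSING, AnalysisDataset, AssociationResult, CovariateMatrix, SNPInfo

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-8  # relative pivot tolerance for collinearity pruning

#: note attached when a p-value underflows and is floored at the smallest
#: positive double
BOUNDARY_NOTE = "p-value floored at smallest positive double"


class DegenerateDesignError(ValueError):
    """Raised when a SNP cannot support the requested genotype design."""


@dataclass
class DesignSpec:
    """How the genotype enters the model."""

    genetic_model: str = "genotypic"  # or "additive"

    def __post_init__(self) -> None:
        if self.genetic_model not in ("genotypic", "additive"):
            raise ValueError(f"unknown genetic model {self.genetic_model!r}")


@dataclass
class SSCPPair:
    """Hypothesis/error sum-of-squares-and-cross-products matrices.

    ``y_scale`` records the total sum of squares of the responses so that
    degenerate fits (H + E numerically zero because the reduced model
    already fits perfectly) can be told apart from genuine effects.
    """

    H: np.ndarray
    E: np.ndarray
    df_hyp: int
    df_err: int
    y_scale: float = float("nan")

    @property
    def p(self) -> int:
        return self.H.shape[0]


def _prune_collinear(X: np.ndarray, tol: float = _RANK_TOL) -> np.ndarray:
    """Drop collinear columns via QR with pivoting (deterministic)."""
    if X.shape[1] == 0:
        return X
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] == 0:
        return X[:, :0]
    rank = int((diag > tol * diag[0]).sum())
    keep = np.sort(piv[:rank])
    if rank < X.shape[1]:
        logger.debug("dropped %d collinear design column(s)", X.shape[1] - rank)
    return X[:, keep]


def genotype_design_columns(counts: np.ndarray, genetic_model: str) -> tuple[np.ndarray, int]:
    """Genotype columns of the full design and their nominal df.

    Genotypic: indicators for 1 and 2 minor alleles (collapses to a single
    indicator when only two classes are observed). Additive: the count.
    """
    counts = np.asarray(counts)
    classes = np.unique(counts)
    if classes.size < 2:
        raise DegenerateDesignError("monomorphic genotype: fewer than 2 classes observed")
    if genetic_model == "additive":
        return counts.astype(float)[:, None], 1
    if classes.size == 2:
        return (counts == classes[1]).astype(float)[:, None], 1
    cols = np.column_stack([(counts == 1).astype(float), (counts == 2).astype(float)])
    return cols, 2


def build_design(
    counts: np.ndarray,
    covariates: CovariateMatrix | np.ndarray | None,
    spec: DesignSpec,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Assemble (X_full, X_reduced, df_hyp) for one SNP.

    X_reduced = intercept + covariates (collinear columns pruned);
    X_full additionally carries the genotype columns.
    """
    counts = np.asarray(counts)
    n = counts.size
    blocks = [np.ones((n, 1))]
    if covariates is not None:
        cov = covariates.data if isinstance(covariates, CovariateMatrix) else np.asarray(covariates, float)
        if cov.shape[0] != n:
            raise ValueError("covariate rows do not match genotype length")
        if cov.shape[1]:
            blocks.append(cov)
    X_reduced = np.column_stack(blocks)
    if X_reduced.shape[1] > 1:
        kept = _prune_collinear(X_reduced[:, 1:])
        X_reduced = np.column_stack([X_reduced[:, :1], kept])
    geno_cols, df_hyp = genotype_design_columns(counts, spec.genetic_model)
    X_full = np.column_stack([X_reduced, geno_cols])
    return X_full, X_reduced, df_hyp


def _residual_sscp(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual SSCP of Y on span(X) plus rank(X), via economy QR."""
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = diag.max() if diag.size else 0.0
    rank = int((diag > _RANK_TOL * scale).sum()) if scale > 0 else 0
    if rank < X.shape[1]:
        # re-orthogonalise on the independent columns only
        Q, _, piv = sla.qr(X, mode="economic", pivoting=True)
        Q = Q[:, :rank]
    resid = Y - Q[:, :rank] @ (Q[:, :rank].T @ Y)
    sscp = resid.T @ resid
    return 0.5 * (sscp + sscp.T), rank


def fit_sscp(Y: np.ndarray, X_full: np.ndarray, X_reduced: np.ndarray) -> SSCPPair:
    """Hypothesis and error SSCP matrices for the nested model pair.

    E is the residual SSCP under the full design, H the drop in residual
    SSCP from reduced to full; df_err = n - rank(X_full) and
    df_hyp = rank(X_full) - rank(X_reduced).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim != 2 or Y.shape[0] != X_full.shape[0]:
        raise ValueError("response and design row counts differ")
    n = Y.shape[0]
    E, rank_full = _residual_sscp(Y, X_full)
    Er, rank_red = _residual_sscp(Y, X_reduced)
    if n <= rank_full:
        raise DegenerateDesignError(f"n={n} does not exceed rank(X_full)={rank_full}")
    H = Er - E
    H = 0.5 * (H + H.T)
    return SSCPPair(
        H=H,
        E=E,
        df_hyp=rank_full - rank_red,
        df_err=n - rank_full,
        y_scale=float((Y * Y).sum()),
    )


def pillai_trace(sscp: SSCPPair) -> float:
    """Pillai's trace V = tr(H (H+E)^-1), clamped to [0, s].

    Computed from the symmetric generalized eigenproblem H v = theta (H+E) v
    so the result is numerically symmetric in the responses.
    """
    s = min(sscp.p, sscp.df_hyp)
    if s == 0:
        return 0.0
    HpE = sscp.H + sscp.E
    # reduced model already fits perfectly: nothing left for genotype
    if np.isfinite(sscp.y_scale) and np.trace(HpE) <= 1e-12 * max(sscp.y_scale, 1e-300):
        return 0.0
    try:
        theta = sla.eigh(sscp.H, HpE, eigvals_only=True)
    except (np.linalg.LinAlgError, sla.LinAlgError, ValueError) as exc:
        raise DegenerateDesignError(f"singular H + E matrix: {exc}") from exc
    return float(np.clip(theta.sum(), 0.0, s))


def pillai_f_approx(
    V: float, p: int, df_hyp: int, df_err: int
) -> tuple[float, float, float, float]:
    """Map Pillai's trace to (F, df1, df2, p_value).

    Standard (s, m, n*) F approximation; exact for s = 1. A trace at its
    upper bound s (perfect separation) yields F = inf and a p-value floored
    at the smallest positive double (p-values are never exactly 0).
    """
    if df_err < p:
        raise DegenerateDesignError(f"df_err={df_err} < p={p}: error SSCP is singular")
    s = min(p, df_hyp)
    if s == 0:
        return 0.0, 0.0, float(df_err), 1.0
    m = (abs(p - df_hyp) - 1) / 2.0
    n_star = (df_err - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n_star + s + 1)
    ratio = V / s
    if ratio >= 1.0 - 1e-14:
        return float("inf"), df1, df2, float(np.nextafter(0.0, 1.0))
    if ratio <= 0.0:
        return 0.0, df1, df2, 1.0
    F = (df2 / df1) * ratio / (1.0 - ratio)
    p_value = float(stats.f.sf(F, df1, df2))
    if p_value <= 0.0:
        p_value = float(np.nextafter(0.0, 1.0))
    return float(F), df1, df2, p_value


class _ReducedModelCache:
    """Reduced-design quantities shared across SNPs.

    The reduced design (intercept + covariates) is SNP-invariant, so its
    residual SSCP is computed once and reused for every SNP with complete
    genotypes; SNPs with missing calls fall back to a per-SNP subset fit.
    """

    def __init__(self, Y: np.ndarray, covariates: CovariateMatrix | None, spec: DesignSpec):
        self.Y = np.asarray(Y, dtype=float)
        self.covariates = covariates
        self.spec = spec
        n = self.Y.shape[0]
        blocks = [np.ones((n, 1))]
        if covariates is not None and covariates.data.shape[1]:
            blocks.append(covariates.data)
        X_reduced = np.column_stack(blocks)
        if X_reduced.shape[1] > 1:
            X_reduced = np.column_stack([X_reduced[:, :1], _prune_collinear(X_reduced[:, 1:])])
        self.X_reduced = X_reduced
        self._Er, self._rank_red = _residual_sscp(self.Y, X_reduced)
        self._y_scale = float((self.Y * self.Y).sum())

    def test(self, counts: np.ndarray, snp: SNPInfo) -> AssociationResult:
        mask = counts != MISSING
        n_used = int(mask.sum())
        complete = bool(mask.all())
        sub_counts = counts[mask]
        sub_Y = self.Y if complete else self.Y[mask]
        try:
            if complete:
                geno_cols, _ = genotype_design_columns(sub_counts, self.spec.genetic_model)
                X_full = np.column_stack([self.X_reduced, geno_cols])
                E, rank_full = _residual_sscp(sub_Y, X_full)
                if n_used <= rank_full:
                    raise DegenerateDesignError(
                        f"n={n_used} does not exceed rank(X_full)={rank_full}"
                    )
                H = self._Er - E
                sscp = SSCPPair(
                    H=0.5 * (H + H.T),
                    E=E,
                    df_hyp=rank_full - self._rank_red,
                    df_err=n_used - rank_full,
                    y_scale=self._y_scale,
                )
            else:
                sub_cov = None if self.covariates is None else self.covariates.data[mask]
                X_full, X_reduced, _ = build_design(sub_counts, sub_cov, self.spec)
                sscp = fit_sscp(sub_Y, X_full, X_reduced)
            V = pillai_trace(sscp)
            F, df1, df2, p = pillai_f_approx(V, sscp.p, sscp.df_hyp, sscp.df_err)
        except DegenerateDesignError as exc:
            note = "monomorphic" if "monomorphic" in str(exc) else f"degenerate: {exc}"
            return AssociationResult(snp=snp, n_used=n_used, note=note)
        note = BOUNDARY_NOTE if p <= np.nextafter(0.0, 1.0) else ""
        return AssociationResult(
            snp=snp, n_used=n_used, statistic=V, F=F, df1=df1, df2=df2, p_value=p, note=note
        )


def test_snp(dataset: AnalysisDataset, snp_index: int, spec: DesignSpec | None = None) -> AssociationResult:
    """MANOVA test of one SNP (complete-case over that SNP's genotypes)."""
    spec = spec or DesignSpec()
    cache = _ReducedModelCache(dataset.phenotype.values, dataset.covariates, spec)
    counts = dataset.genotype.counts[:, snp_index]
    return cache.test(counts, dataset.genotype.snps[snp_index])


def run_gwas(
    dataset: AnalysisDataset,
    spec: DesignSpec | None = None,
    progress_every: int = 10_000,
) -> list[AssociationResult]:
    """Test every SNP in .bim order; memory stays bounded in the SNP count."""
    spec = spec or DesignSpec()
    cache = _ReducedModelCache(dataset.phenotype.values, dataset.covariates, spec)
    results: list[AssociationResult] = []
    m = dataset.genotype.n_snps
    for j in range(m):
        results.append(cache.test(dataset.genotype.counts[:, j], dataset.genotype.snps[j]))
        if progress_every and (j + 1) % progress_every == 0:
            logger.info("tested %d / %d SNPs", j + 1, m)
    return results
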