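"""Univariate comparison methods for dose-response association testing.

Each method collapses an individual's d-dose response vector to a scalar
and tests that scalar against genotype with a linear-model F test
(genotypic coding, optional covariates):

- ``IC50``: log10 of the fitted 4PL half-maximal concentration,
- ``Slope``: the fitted 4PL slope parameter,
- ``AUC_Emp``: empirical area under the curve (trapezoid rule on the dose
  grid as given; log10-dose spacing available via a flag).

``anova_pooled_test`` instead stacks all n x d observations as a single
univariate response with dose as a nominal factor, deliberately ignoring
the within-individual correlation. Its asymptotic p-values are miscalibrated
whenever responses are correlated; it exists for method comparison through
resampling, matching how such pooled ANOVAs have been used historically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import AssociationResult, CovariateMatrix, PhenotypeMatrix, SNPInfo
from .hill import fit_hill_curves
from .manova import (
    BOUNDARY_NOTE,
    DegenerateDesignError,
    DesignSpec,
    build_design,
    fit_sscp,
    pillai_f_approx,
    pillai_trace,
)

logger = logging.getLogger(__name__)

SUMMARY_METHODS = ("IC50", "Slope", "AUC_Emp")


@dataclass
class SummaryVector:
    """Per-individual scalar summaries plus indices of failed fits."""

    method: str
    values: np.ndarray  # (n,) float; NaN at failed indices
    failed: set[int] = field(default_factory=set)

    @property
    def ok_mask(self) -> np.ndarray:
        mask = np.ones(self.values.size, dtype=bool)
        if self.failed:
            mask[sorted(self.failed)] = False
        return mask


def auc_empirical(doses: np.ndarray, responses: np.ndarray, log_dose: bool = False) -> float:
    """Trapezoid-rule area under one response curve over the dose grid.

    ``log_dose=True`` integrates over log10(dose) spacing instead of the
    raw concentrations.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.size < 2:
        raise ValueError("need at least 2 doses for an AUC")
    if np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be strictly increasing")
    grid = np.log10(doses) if log_dose else doses
    return float(np.trapezoid(responses, grid))


def summarize(phenotype: PhenotypeMatrix, method: str, log_dose: bool = False) -> SummaryVector:
    """Collapse each individual's curve to one scalar under ``method``.

    Hill-fit failures (flat or degenerate curves) are recorded in
    ``failed`` and excluded from downstream tests; AUC never fails.
    """
    if method not in SUMMARY_METHODS:
        raise ValueError(f"unknown summary method {method!r}; choose from {SUMMARY_METHODS}")
    Y = phenotype.values
    n = Y.shape[0]
    if method == "AUC_Emp":
        grid = np.log10(phenotype.doses) if log_dose else phenotype.doses
        values = np.trapezoid(Y, grid, axis=1)
        return SummaryVector(method=method, values=np.asarray(values, float))

    fits = fit_hill_curves(phenotype.doses, Y)
    values = np.full(n, np.nan)
    failed = set()
    for i, fit in enumerate(fits):
        if not fit.converged:
            failed.add(i)
        elif method == "IC50":
            values[i] = np.log10(fit.ic50)
        else:
            values[i] = fit.slope
    if failed:
        logger.info("%s summary: %d/%d hill fits failed and were excluded", method, len(failed), n)
    return SummaryVector(method=method, values=values, failed=failed)


def _univariate_f_result(
    y: np.ndarray,
    genotype_counts: np.ndarray,
    covariates: np.ndarray | CovariateMatrix | None,
    snp: SNPInfo | None,
    n_reported: int | None = None,
) -> AssociationResult:
    """F test of the genotype factor on a univariate response.

    Runs the p=1 multivariate pipeline, so the result is exactly the
    classical ANCOVA F (the trace-to-F map is exact at s=1).
    """
    snp = snp or SNPInfo("0", "summary", 0.0, 0, "A", "B")
    spec = DesignSpec(genetic_model="genotypic")
    try:
        X_full, X_reduced, _ = build_design(genotype_counts, covariates, spec)
        sscp = fit_sscp(y[:, None], X_full, X_reduced)
        V = pillai_trace(sscp)
        F, df1, df2, p = pillai_f_approx(V, 1, sscp.df_hyp, sscp.df_err)
    except DegenerateDesignError as exc:
        note = "monomorphic" if "monomorphic" in str(exc) else f"degenerate: {exc}"
        return AssociationResult(snp=snp, n_used=int(y.size), note=note)
    note = BOUNDARY_NOTE if p <= np.nextafter(0.0, 1.0) else ""
    return AssociationResult(
        snp=snp,
        n_used=int(y.size if n_reported is None else n_reported),
        statistic=F,
        F=F,
        df1=df1,
        df2=df2,
        p_value=p,
        note=note,
    )


def anova_summary_test(
    summary: SummaryVector,
    genotype_counts: np.ndarray,
    covariates: CovariateMatrix | np.ndarray | None = None,
    snp: SNPInfo | None = None,
) -> AssociationResult:
    """Genotype F test on a per-individual summary (failed fits excluded)."""
    genotype_counts = np.asarray(genotype_counts)
    mask = summary.ok_mask
    y = summary.values[mask]
    g = genotype_counts[mask]
    cov = None
    if covariates is not None:
        data = covariates.data if isinstance(covariates, CovariateMatrix) else np.asarray(covariates, float)
        cov = data[mask]
    return _univariate_f_result(y, g, cov, snp)


def anova_pooled_test(
    phenotype: PhenotypeMatrix,
    genotype_counts: np.ndarray,
    covariates: CovariateMatrix | np.ndarray | None = None,
    snp: SNPInfo | None = None,
) -> AssociationResult:
    """Pooled-observation ANOVA: all n x d responses stacked as univariate.

    Dose enters as a nominal factor, genotype with genotypic coding;
    within-individual correlation is ignored by construction. With d = 1
    this reduces exactly to :func:`anova_summary_test` on the single
    response column.
    """
    genotype_counts = np.asarray(genotype_counts)
    Y = phenotype.values
    n, d = Y.shape
    if genotype_counts.size != n:
        raise ValueError("genotype vector length does not match phenotype rows")
    y = Y.reshape(-1)  # individual-major stacking
    g = np.repeat(genotype_counts, d)
    blocks = []
    if d > 1:
        dose_idx = np.tile(np.arange(d), n)
        dose_dummies = np.column_stack([(dose_idx == t).astype(float) for t in range(1, d)])
        blocks.append(dose_dummies)
    if covariates is not None:
        data = covariates.data if isinstance(covariates, CovariateMatrix) else np.asarray(covariates, float)
        blocks.append(np.repeat(data, d, axis=0))
    cov = np.column_stack(blocks) if blocks else None
    return _univariate_f_result(y, g, cov, snp, n_reported=n)
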