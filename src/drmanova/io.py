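"""Delimited-table I/O, sample alignment, results output and test fixtures.

Phenotype and covariate tables are whitespace/tab-delimited with a header
whose first two columns are FID and IID. Phenotype columns must all parse
as numbers ("NA" marks a missing value); covariate columns are inferred as
numeric when every value parses, otherwise nominal and dummy-expanded with
the first observed level as the reference.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    MISSING,
    AnalysisDataset,
    AssociationResult,
    CovariateMatrix,
    GenotypeDataset,
    PhenotypeMatrix,
    SampleInfo,
    SNPInfo,
)
from .plink import minor_allele_from_a1_counts, write_plink
from .simulate import SimulationConfig, sample_genotypes, simulate

logger = logging.getLogger(__name__)

_NA_STRINGS = {"NA", "NaN", "nan", ""}


def _read_keyed_frame(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need FID, IID and at least one data column")
    first_two = [c.upper() for c in df.columns[:2]]
    if first_two != ["FID", "IID"]:
        raise ValueError(f"{path}: first two header columns must be FID and IID, got {list(df.columns[:2])}")
    df.columns = ["FID", "IID", *df.columns[2:]]
    dup = df.duplicated(subset=["FID", "IID"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(f"{path}: duplicate (FID, IID) pair at data row {row + 1}")
    return df


def _numeric_column(series: pd.Series) -> np.ndarray | None:
    """Parse a string column to float (NA-aware); None if any cell fails."""
    values = np.full(len(series), np.nan)
    for i, cell in enumerate(series):
        if cell in _NA_STRINGS:
            continue
        try:
            values[i] = float(cell)
        except ValueError:
            return None
    return values


def read_table(path: str | os.PathLike, kind: str, doses: np.ndarray | None = None):
    """Read a phenotype or covariate table keyed by (FID, IID).

    ``kind`` is ``"phenotype"`` or ``"covariate"``. For phenotypes, ``doses``
    supplies the concentration grid (default: 1..d equally spaced). Nominal
    covariates are dummy-expanded (reference = first observed level) and
    constant expanded columns are dropped.
    """
    if kind not in ("phenotype", "covariate"):
        raise ValueError(f"kind must be 'phenotype' or 'covariate', got {kind!r}")
    df = _read_keyed_frame(path)
    samples = [SampleInfo(fid=f, iid=i) for f, i in zip(df["FID"], df["IID"])]
    data_cols = list(df.columns[2:])

    if kind == "phenotype":
        columns = []
        for col in data_cols:
            values = _numeric_column(df[col])
            if values is None:
                bad = next(
                    i for i, c in enumerate(df[col]) if c not in _NA_STRINGS and not _is_float(c)
                )
                raise ValueError(
                    f"{path}: non-numeric phenotype value {df[col].iloc[bad]!r} "
                    f"in column {col!r}, data row {bad + 1}"
                )
            columns.append(values)
        values = np.column_stack(columns)
        d = values.shape[1]
        grid = np.arange(1.0, d + 1.0) if doses is None else np.asarray(doses, float)
        return PhenotypeMatrix(samples=samples, doses=grid, values=values)

    names: list[str] = []
    blocks: list[np.ndarray] = []
    for col in data_cols:
        numeric = _numeric_column(df[col])
        if numeric is not None:
            names.append(col)
            blocks.append(numeric)
            continue
        levels = list(dict.fromkeys(df[col]))  # first-observed order
        reference = levels[0]
        for level in levels[1:]:
            names.append(f"{col}={level}")
            blocks.append((df[col] == level).to_numpy(dtype=float))
        logger.info("covariate %r dummy-coded with reference level %r", col, reference)
    data = np.column_stack(blocks) if blocks else np.empty((len(samples), 0))
    keep = [i for i in range(data.shape[1]) if np.nanstd(data[:, i]) > 0]
    if len(keep) < data.shape[1]:
        dropped = [names[i] for i in range(data.shape[1]) if i not in keep]
        logger.info("dropped constant covariate column(s): %s", ", ".join(dropped))
    return CovariateMatrix(
        samples=samples, names=[names[i] for i in keep], data=data[:, keep]
    )


def _is_float(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def align(
    genotype: GenotypeDataset,
    phenotype: PhenotypeMatrix,
    covariates: CovariateMatrix | None = None,
) -> AnalysisDataset:
    """Restrict all sources to their shared samples, in genotype order.

    Individuals missing any phenotype value are dropped (MANOVA needs the
    complete response vector); likewise rows with missing covariates. Every
    dropped sample lands in exactly one reason bucket of ``drop_counts``.
    """
    pheno_idx = {s.key: i for i, s in enumerate(phenotype.samples)}
    cov_idx = {s.key: i for i, s in enumerate(covariates.samples)} if covariates is not None else None

    keep_rows: list[int] = []
    pheno_rows: list[int] = []
    cov_rows: list[int] = []
    drops = {"not_shared": 0, "missing_phenotype": 0, "missing_covariate": 0}
    for gi, sample in enumerate(genotype.samples):
        pi = pheno_idx.get(sample.key)
        ci = cov_idx.get(sample.key) if cov_idx is not None else -1
        if pi is None or ci is None:
            drops["not_shared"] += 1
            continue
        if np.isnan(phenotype.values[pi]).any():
            drops["missing_phenotype"] += 1
            continue
        if covariates is not None and np.isnan(covariates.data[ci]).any():
            drops["missing_covariate"] += 1
            continue
        keep_rows.append(gi)
        pheno_rows.append(pi)
        cov_rows.append(ci)

    if not keep_rows:
        raise ValueError("no samples shared across genotype/phenotype/covariate sources")
    for reason, count in drops.items():
        if count:
            logger.info("alignment dropped %d sample(s): %s", count, reason)

    samples = [genotype.samples[i] for i in keep_rows]
    aligned_geno = GenotypeDataset(
        samples=samples, snps=genotype.snps, counts=genotype.counts[keep_rows]
    )
    aligned_pheno = PhenotypeMatrix(
        samples=samples, doses=phenotype.doses, values=phenotype.values[pheno_rows]
    )
    aligned_cov = None
    if covariates is not None:
        aligned_cov = CovariateMatrix(
            samples=samples, names=covariates.names, data=covariates.data[cov_rows]
        )
    return AnalysisDataset(
        genotype=aligned_geno,
        phenotype=aligned_pheno,
        covariates=aligned_cov,
        drop_counts=drops,
    )


_RESULT_HEADER = ["CHR", "SNP", "BP", "A1", "A2", "N", "STAT", "F", "DF1", "DF2", "P", "NOTE"]


def write_results(results: list[AssociationResult], path: str | os.PathLike) -> None:
    """Write per-SNP results as a tab-delimited table (one row per SNP).

    Skipped SNPs appear with NA statistics and their reason in NOTE;
    p-values are printed in scientific notation with 6 significant digits
    so that extreme values are never rendered as 0.
    """
    if not results:
        raise ValueError("no results to write")

    def fmt(value: float, pval: bool = False) -> str:
        if not np.isfinite(value):
            return "inf" if value == np.inf else "NA"
        return f"{value:.6e}" if pval else f"{value:.6g}"

    with open(path, "w") as fh:
        fh.write("\t".join(_RESULT_HEADER) + "\n")
        for r in results:
            snp = r.snp
            a1 = snp.minor_allele or snp.allele1
            a2 = snp.allele2 if a1 == snp.allele1 else snp.allele1
            fh.write(
                "\t".join(
                    [
                        snp.chromosome,
                        snp.snp_id,
                        str(snp.position),
                        a1,
                        a2,
                        str(r.n_used),
                        fmt(r.statistic),
                        fmt(r.F),
                        fmt(r.df1),
                        fmt(r.df2),
                        fmt(r.p_value, pval=True),
                        r.note or ".",
                    ]
                )
                + "\n"
            )


def write_fixture(config: SimulationConfig, seed: int, prefix: str | os.PathLike) -> SimulatedFiles:
    """Generate an on-disk PLINK trio + phenotype/covariate tables.

    The first SNP is causal under the configured generating model (effect
    size included); the remaining ``config.n_snps - 1`` SNPs are independent
    null draws at the same MAF. Deterministic given ``seed``. Requires
    ``replicates_per_individual == 1`` (one table row per individual).
    """
    if config.replicates_per_individual != 1:
        raise ValueError("on-disk fixtures support a single replicate per individual")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sim = simulate(config, rng=rng)
    n, m, d = config.n, config.n_snps, config.means.n_doses

    raw = np.empty((n, m), dtype=np.int8)
    raw[:, 0] = sim.genotype_counts
    for j in range(1, m):
        if config.maf >= 1e-12:
            raw[:, j] = sample_genotypes(n, config.maf, rng)
        else:
            raw[:, j] = 0

    samples = [SampleInfo(fid=f"F{i + 1:04d}", iid=f"I{i + 1:04d}") for i in range(n)]
    snps = []
    counts = np.empty_like(raw)
    for j in range(m):
        # raw column = dosage of allele "B" (allele1); orient to the minor allele
        snp = SNPInfo(
            chromosome="1",
            snp_id=f"snp{j + 1}",
            genetic_distance=0.0,
            position=(j + 1) * 5000,
            allele1="B",
            allele2="A",
        )
        minor, maf = minor_allele_from_a1_counts(raw[:, j], snp)
        snp.minor_allele = minor
        snp.maf = maf
        counts[:, j] = raw[:, j] if minor == snp.allele1 else (2 - raw[:, j])
        snps.append(snp)
    write_plink(prefix, samples, snps, counts)

    with open(f"{prefix}.pheno.txt", "w") as fh:
        fh.write("FID IID " + " ".join(f"C{t + 1}" for t in range(d)) + "\n")
        for i, s in enumerate(samples):
            row = " ".join(f"{v:.10g}" for v in sim.Y[i])
            fh.write(f"{s.fid} {s.iid} {row}\n")

    growth = rng.normal(1.0, 0.15, size=n)
    batch = rng.choice(["L1", "L2", "L3"], size=n)
    with open(f"{prefix}.covar.txt", "w") as fh:
        fh.write("FID IID growth batch\n")
        for i, s in enumerate(samples):
            fh.write(f"{s.fid} {s.iid} {growth[i]:.10g} {batch[i]}\n")

    return SimulatedFiles(
        bed=prefix.with_suffix(".bed"),
        bim=prefix.with_suffix(".bim"),
        fam=prefix.with_suffix(".fam"),
        pheno=Path(f"{prefix}.pheno.txt"),
        covar=Path(f"{prefix}.covar.txt"),
        causal_counts=raw[:, 0].copy(),
        counts=counts.copy(),
    )


class SimulatedFiles:
    """Paths (and in-memory truth) produced by :func:`write_fixture`."""

    def __init__(self, bed, bim, fam, pheno, covar, causal_counts, counts):
        self.bed = bed
        self.bim = bim
        self.fam = fam
        self.pheno = pheno
        self.covar = covar
        self.causal_counts = causal_counts
        self.counts = counts
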