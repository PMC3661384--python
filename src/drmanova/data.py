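"""Core in-memory containers shared across the package.

Genotypes are stored as minor-allele dosage (0/1/2) in a dense int8 matrix
with ``MISSING`` (-1) marking no-calls; phenotypes are an n x d matrix of
responses (one column per drug concentration); covariates are kept as an
already dummy-expanded numeric design block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for a missing genotype call in int8 count matrices.
MISSING: int = -1


@dataclass(frozen=True)
class SampleInfo:
    """A (family id, individual id) pair, the PLINK .fam sample key."""

    fid: str
    iid: str

    @property
    def key(self) -> tuple[str, str]:
        return (self.fid, self.iid)


@dataclass
class SNPInfo:
    """Per-SNP metadata following the PLINK .bim convention.

    ``minor_allele`` and ``maf`` are derived from observed calls (frequency
    among non-missing genotypes); an exact 50/50 tie resolves to ``allele1``.
    """

    chromosome: str
    snp_id: str
    genetic_distance: float
    position: int
    allele1: str
    allele2: str
    minor_allele: str = ""
    maf: float = float("nan")

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative base-pair position for {self.snp_id}")
        if self.minor_allele and self.minor_allele not in (self.allele1, self.allele2):
            raise ValueError(
                f"minor allele {self.minor_allele!r} of {self.snp_id} is neither "
                f"{self.allele1!r} nor {self.allele2!r}"
            )


@dataclass
class GenotypeDataset:
    """Minor-allele count matrix (individuals x SNPs) plus metadata."""

    samples: list[SampleInfo]
    snps: list[SNPInfo]
    counts: np.ndarray  # (n, m) int8; entries in {0, 1, 2, MISSING}

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int8)
        n, m = self.counts.shape
        if n != len(self.samples) or m != len(self.snps):
            raise ValueError(
                f"count matrix is {n}x{m} but metadata lists "
                f"{len(self.samples)} samples and {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.counts, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype counts must be 0, 1, 2 or missing")
        keys = [s.key for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (FID, IID) pairs in genotype samples")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]


@dataclass
class PhenotypeMatrix:
    """n x d response matrix: viabilities at d ascending drug concentrations."""

    samples: list[SampleInfo]
    doses: np.ndarray  # (d,) strictly increasing
    values: np.ndarray  # (n, d) float; NaN = missing

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("phenotype values must be a 2-d matrix")
        if self.doses.size != self.values.shape[1]:
            raise ValueError("dose grid length must equal the number of response columns")
        if self.doses.size < 1:
            raise ValueError("need at least one response column")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if len(self.samples) != self.values.shape[0]:
            raise ValueError("one phenotype row per sample required")

    @property
    def n_doses(self) -> int:
        return self.doses.size


@dataclass
class CovariateMatrix:
    """Dummy-expanded numeric covariate block.

    Nominal input columns are expanded to indicator columns against a
    reference level (the first observed level); constant expanded columns
    are dropped at construction time by :func:`drmanova.io.read_table`.
    """

    samples: list[SampleInfo]
    names: list[str]
    data: np.ndarray  # (n, q) float; NaN = missing

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("covariate data must be a 2-d matrix")
        if self.data.shape != (len(self.samples), len(self.names)):
            raise ValueError("covariate matrix shape does not match metadata")


@dataclass
class AnalysisDataset:
    """Genotype + phenotype (+ covariates) aligned to a shared sample order."""

    genotype: GenotypeDataset
    phenotype: PhenotypeMatrix
    covariates: CovariateMatrix | None = None
    drop_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [s.key for s in self.genotype.samples]
        if [s.key for s in self.phenotype.samples] != keys:
            raise ValueError("genotype and phenotype sample orders differ")
        if self.covariates is not None and [s.key for s in self.covariates.samples] != keys:
            raise ValueError("covariate sample order differs from genotype order")
        if not keys:
            raise ValueError("aligned dataset is empty")

    @property
    def n_samples(self) -> int:
        return self.genotype.n_samples


@dataclass
class AssociationResult:
    """Outcome of one per-SNP association test.

    ``statistic`` is Pillai's trace V for the multivariate test and the
    F statistic for univariate summary tests. Skipped SNPs carry NaN fields
    and a human-readable ``note`` (e.g. "monomorphic").
    """

    snp: SNPInfo
    n_used: int
    statistic: float = float("nan")
    F: float = float("nan")
    df1: float = float("nan")
    df2: float = float("nan")
    p_value: float = float("nan")
    note: str = ""

    @property
    def tested(self) -> bool:
        return np.isfinite(self.p_value)
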