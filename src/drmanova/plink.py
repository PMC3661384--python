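"""PLINK 1 binary genotype I/O (.bed/.bim/.fam).

Only the SNP-major v1.00 layout is supported: a 3-byte header
(``0x6C 0x1B`` magic followed by mode ``0x01``) and then, per SNP,
``ceil(n/4)`` bytes holding one two-bit code per sample (LSB first):

====  ==========================
code  meaning
====  ==========================
00    homozygous for allele1
01    missing call
10    heterozygous
11    homozygous for allele2
====  ==========================

On read, genotypes are re-oriented to minor-allele dosage per SNP. The
minor allele is determined from the observed allele frequency among
non-missing calls; an exact 50/50 tie resolves to allele1 so that the
orientation is deterministic.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .data import MISSING, GenotypeDataset, SampleInfo, SNPInfo

MAGIC = b"\x6c\x1b"
MODE_SNP_MAJOR = b"\x01"

# two-bit code -> allele1 dosage (MISSING for code 01)
_CODE_TO_A1_COUNT = np.array([2, MISSING, 1, 0], dtype=np.int8)


class PlinkFormatError(ValueError):
    """Malformed .bed/.bim/.fam content."""


def read_fam(path: str | os.PathLike) -> list[SampleInfo]:
    samples: list[SampleInfo] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise PlinkFormatError(f"{path}:{lineno}: expected at least FID IID")
            samples.append(SampleInfo(fid=parts[0], iid=parts[1]))
    keys = [s.key for s in samples]
    if len(set(keys)) != len(keys):
        raise PlinkFormatError(f"{path}: duplicate (FID, IID) pairs")
    return samples


def read_bim(path: str | os.PathLike) -> list[SNPInfo]:
    snps: list[SNPInfo] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise PlinkFormatError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            chrom, snp_id, cm, bp, a1, a2 = parts
            snps.append(
                SNPInfo(
                    chromosome=chrom,
                    snp_id=snp_id,
                    genetic_distance=float(cm),
                    position=int(bp),
                    allele1=a1,
                    allele2=a2,
                )
            )
    return snps


def minor_allele_from_a1_counts(a1_counts: np.ndarray, snp: SNPInfo) -> tuple[str, float]:
    """Determine (minor allele, MAF) from allele1 dosages of one SNP.

    Ties at frequency exactly 0.5 resolve toward allele1. All-missing SNPs
    get ``minor_allele = allele1`` and ``maf = nan``.
    """
    called = a1_counts[a1_counts != MISSING]
    if called.size == 0:
        return snp.allele1, float("nan")
    freq_a1 = float(called.mean()) / 2.0
    if freq_a1 <= 0.5:
        return snp.allele1, freq_a1
    return snp.allele2, 1.0 - freq_a1


def read_plink(prefix: str | os.PathLike) -> GenotypeDataset:
    """Read a ``prefix.bed``/``.bim``/``.fam`` trio into a GenotypeDataset.

    Counts in the result are minor-allele dosages; missing calls are
    ``MISSING``. Raises :class:`PlinkFormatError` on a wrong magic/mode byte
    or when the .bed payload size disagrees with the .bim/.fam line counts.
    """
    prefix = Path(prefix)
    samples = read_fam(prefix.with_suffix(".fam"))
    snps = read_bim(prefix.with_suffix(".bim"))
    n, m = len(samples), len(snps)

    bed = prefix.with_suffix(".bed").read_bytes()
    if bed[:2] != MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes {bed[:2]!r}")
    if bed[2:3] != MODE_SNP_MAJOR:
        raise PlinkFormatError(
            f"{prefix}.bed: unsupported mode byte {bed[2:3]!r} (need SNP-major 0x01)"
        )
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(bed, dtype=np.uint8, offset=3)
    if payload.size != m * bytes_per_snp:
        raise PlinkFormatError(
            f"{prefix}.bed: payload of {payload.size} bytes does not match "
            f"{m} SNPs x {bytes_per_snp} bytes/SNP from .bim/.fam"
        )

    if m == 0 or n == 0:
        counts = np.zeros((n, m), dtype=np.int8)
        return GenotypeDataset(samples=samples, snps=snps, counts=counts)

    bits = np.unpackbits(payload.reshape(m, bytes_per_snp), axis=1, bitorder="little")
    codes = (bits[:, 0::2] + 2 * bits[:, 1::2])[:, :n]  # (m, n)
    a1_counts = _CODE_TO_A1_COUNT[codes]

    counts = np.empty((n, m), dtype=np.int8)
    for j, snp in enumerate(snps):
        col = a1_counts[j]
        minor, maf = minor_allele_from_a1_counts(col, snp)
        snp.minor_allele = minor
        snp.maf = maf
        if minor == snp.allele1:
            out = col.copy()
        else:
            out = np.where(col == MISSING, MISSING, 2 - col).astype(np.int8)
        counts[:, j] = out
    return GenotypeDataset(samples=samples, snps=snps, counts=counts)


def write_plink(
    prefix: str | os.PathLike,
    samples: list[SampleInfo],
    snps: list[SNPInfo],
    counts: np.ndarray,
) -> None:
    """Write a GenotypeDataset's pieces as a ``.bed``/``.bim``/``.fam`` trio.

    ``counts`` must be minor-allele dosages consistent with each SNP's
    ``minor_allele`` field (callers should orient with
    :func:`minor_allele_from_a1_counts` first so a read round-trips).
    """
    prefix = Path(prefix)
    counts = np.asarray(counts, dtype=np.int8)
    n, m = counts.shape
    if n != len(samples) or m != len(snps):
        raise ValueError("count matrix shape does not match sample/SNP metadata")

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in samples:
            fh.write(f"{s.fid} {s.iid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for snp in snps:
            fh.write(
                f"{snp.chromosome}\t{snp.snp_id}\t{snp.genetic_distance:g}\t"
                f"{snp.position}\t{snp.allele1}\t{snp.allele2}\n"
            )

    bytes_per_snp = (n + 3) // 4
    padded = 4 * bytes_per_snp
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(MAGIC + MODE_SNP_MAJOR)
        if m == 0 or n == 0:
            return
        # map minor-allele dosage -> two-bit code, per SNP orientation
        codes = np.empty((m, padded), dtype=np.uint8)
        codes[:] = 1  # pad positions encode "missing"; ignored on read
        for j, snp in enumerate(snps):
            minor = snp.minor_allele or snp.allele1
            col = counts[:, j]
            if minor == snp.allele1:
                lut = {2: 0, 1: 2, 0: 3, MISSING: 1}
            else:
                lut = {0: 0, 1: 2, 2: 3, MISSING: 1}
            mapped = np.empty(n, dtype=np.uint8)
            for value, code in lut.items():
                mapped[col == value] = code
            codes[j, :n] = mapped
        bits = np.zeros((m, padded * 2), dtype=np.uint8)
        bits[:, 0::2] = codes & 1
        bits[:, 1::2] = codes >> 1
        fh.write(np.packbits(bits, axis=1, bitorder="little").tobytes())
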