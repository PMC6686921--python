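"""Minimal PLINK 1.9 bed/bim/fam reader and writer.

Only the SNP-major layout (the only layout PLINK 1.9 writes) is supported.
Genotypes are exchanged as counts of the bim A1 allele with -1 for missing;
2-bit codes: 00 = homozygous A1, 01 = missing, 10 = heterozygous,
11 = homozygous A2.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

MAGIC = bytes((0x6C, 0x1B, 0x01))
MISSING = np.int8(-1)

# 2-bit code -> A1 allele count
_DECODE = np.array([2, -1, 1, 0], dtype=np.int8)
# A1 count (index -1 wraps to missing) -> 2-bit code
_ENCODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Corrupt or unsupported PLINK fileset."""


def read_bim(path) -> pd.DataFrame:
    bim = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    return bim


def read_fam(path) -> pd.DataFrame:
    fam = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    return fam


def read_plink(prefix) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Read a bed/bim/fam triplet.

    Returns ``(variants, samples, genotypes)`` where ``genotypes`` is an
    int8 array of shape (n_samples, n_variants) counting the bim A1 allele,
    -1 for missing. No imputation is ever performed.
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(ext).exists():
            raise FileNotFoundError(f"missing PLINK file {prefix.with_suffix(ext)}")
    variants = read_bim(prefix.with_suffix(".bim"))
    samples = read_fam(prefix.with_suffix(".fam"))
    if len(samples) == 0:
        raise PlinkFormatError(f"empty .fam file: no subjects in {prefix}")
    n, s = len(samples), len(variants)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:3].tobytes() != MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes (not a PLINK 1.9 SNP-major bed)")
    body = raw[3:]
    bytes_per_snp = (n + 3) // 4
    if body.size != bytes_per_snp * s:
        raise PlinkFormatError(
            f"{bed_path}: size {body.size} does not match "
            f"{s} variants x {len(samples)} samples ({bytes_per_snp * s} bytes expected)"
        )
    body = body.reshape(s, bytes_per_snp)
    # unpack 4 two-bit codes per byte, sample-within-byte order is LSB first
    codes = np.stack([(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(s, bytes_per_snp * 4)[:, :n]
    genotypes = _DECODE[codes].T.copy()  # (n, s)
    return variants, samples, genotypes


def write_plink(
    prefix,
    subject_ids,
    variants: pd.DataFrame,
    genotypes: np.ndarray,
) -> None:
    """Write a bed/bim/fam triplet.

    ``variants`` needs columns chrom, snp_id, pos, a1, a2 (cm optional);
    ``genotypes`` is (n_subjects, n_variants) of A1 counts with -1 missing.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    g = np.asarray(genotypes, dtype=np.int8)
    n, s = g.shape
    if len(subject_ids) != n or len(variants) != s:
        raise ValueError("genotype matrix shape does not match subjects/variants")
    if not np.isin(g, [-1, 0, 1, 2]).all():
        raise ValueError("genotypes must be in {-1, 0, 1, 2}")

    bim = pd.DataFrame(
        {
            "chrom": variants["chrom"].to_numpy(),
            "snp_id": variants["snp_id"].to_numpy(),
            "cm": variants["cm"].to_numpy() if "cm" in variants else np.zeros(s, dtype=int),
            "pos": variants["pos"].to_numpy(),
            "a1": variants["a1"].to_numpy(),
            "a2": variants["a2"].to_numpy(),
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": subject_ids,
            "iid": subject_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "phenotype": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    # code lookup indexed by genotype value (-1 handled via index 3)
    lut = np.empty(4, dtype=np.uint8)
    for count, code in _ENCODE.items():
        lut[count] = code  # -1 wraps to index 3
    codes = lut[g.T]  # (s, n)
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((s, pad), dtype=np.uint8)], axis=1
        )
    codes = codes.reshape(s, -1, 4)
    packed = (
        codes[:, :, 0]
        | (codes[:, :, 1] << 2)
        | (codes[:, :, 2] << 4)
        | (codes[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(MAGIC)
        fh.write(packed.tobytes())
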