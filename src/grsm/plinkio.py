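"""PLINK 1 binary (bed/bim/fam) reading and writing.

Implements the SNP-major layout: three magic bytes ``0x6C 0x1B 0x01`` followed
by ceil(n_samples/4) bytes per SNP.  Within a byte, samples are packed
low-bits-first with the 2-bit codes

    00 = homozygous A1   (dosage 2 — A1 is written as the minor allele here)
    01 = missing
    10 = heterozygous    (dosage 1)
    11 = homozygous A2   (dosage 0)

Round-trip write→read is the identity, including missingness.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix

MAGIC = bytes((0x6C, 0x1B, 0x01))

# dosage (0,1,2,missing) -> 2-bit code and back
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


class PlinkFormatError(ValueError):
    pass


def write_plink(G: GenotypeMatrix, prefix: str | os.PathLike,
                sex: np.ndarray | None = None) -> None:
    """Write ``prefix``.bed/.bim/.fam (SNP-major bed).

    ``sex`` is an optional per-sample female indicator (1 = female) used for
    the fam sex column (PLINK codes 1 = male, 2 = female, 0 = unknown).
    """
    prefix = os.fspath(prefix)
    n, m = G.n_samples, G.n_snps

    # ---- bed ----
    lut = np.zeros(256, dtype=np.uint8)
    for dos, code in _DOSAGE_TO_CODE.items():
        lut[dos & 0xFF] = code      # MISSING (-1) lands on index 255
    codes = lut[G.genotypes.T.astype(np.uint8)]  # (m, n) 2-bit codes
    n_pad = (-n) % 4
    if n_pad:
        pad = np.full((m, n_pad), 0b00, dtype=np.uint8)  # padding bits are zero
        codes = np.concatenate([codes, pad], axis=1)
    codes = codes.reshape(m, -1, 4)
    packed = (codes[:, :, 0] | (codes[:, :, 1] << 2)
              | (codes[:, :, 2] << 4) | (codes[:, :, 3] << 6)).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(MAGIC)
        fh.write(packed.tobytes())

    # ---- bim ----
    bim = pd.DataFrame({
        "chrom": G.snps["chrom"].to_numpy(),
        "snp": G.snps.index.to_numpy(),
        "cm": 0,
        "pos": G.snps["pos"].to_numpy(),
        "a1": G.snps["a1"].to_numpy(),
        "a2": G.snps["a2"].to_numpy(),
    })
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)

    # ---- fam ----
    if sex is None:
        sex_code = np.zeros(n, dtype=int)
    else:
        sex_code = np.where(np.asarray(sex) == 1, 2, 1)
    fam = pd.DataFrame({
        "fid": G.sample_ids, "iid": G.sample_ids,
        "pid": 0, "mid": 0, "sex": sex_code, "pheno": -9,
    })
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


def read_plink(prefix: str | os.PathLike) -> GenotypeMatrix:
    """Read ``prefix``.bed/.bim/.fam into a :class:`GenotypeMatrix`."""
    prefix = os.fspath(prefix)
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"snp": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix + ".fam", sep=r"\s+", header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"], dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    bytes_per_snp = (n + 3) // 4

    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != MAGIC:
            raise PlinkFormatError(
                f"{prefix}.bed: bad magic bytes {magic!r} at offset 0 "
                f"(expected {MAGIC!r})"
            )
        raw = fh.read()
    expected = m * bytes_per_snp
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{prefix}.bed: truncated genotype block at offset {3 + len(raw)} "
            f"(got {len(raw)} bytes, expected {expected})"
        )

    packed = np.frombuffer(raw, dtype=np.uint8).reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    codes[:, 0::4] = packed & 0b11
    codes[:, 1::4] = (packed >> 2) & 0b11
    codes[:, 2::4] = (packed >> 4) & 0b11
    codes[:, 3::4] = (packed >> 6) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # (n, m)

    snps = pd.DataFrame(
        {"chrom": bim["chrom"].to_numpy(), "pos": bim["pos"].to_numpy(),
         "a1": bim["a1"].to_numpy(), "a2": bim["a2"].to_numpy()},
        index=pd.Index(bim["snp"], name="snp_id"),
    )
    return GenotypeMatrix(dosages, snps, fam["iid"].to_numpy())
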