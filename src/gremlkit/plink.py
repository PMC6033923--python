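"""PLINK-1 binary (.bed/.bim/.fam) reader and writer.

The .bed payload is SNP-major: one variant per row of ``ceil(n_samples/4)``
bytes, two bits per genotype, samples packed LSB-first.  Two-bit codes (for
the A1 allele listed in .bim):

====  =======================
code  meaning
====  =======================
0b00  homozygous A1 (dosage 2)
0b01  missing
0b10  heterozygous (dosage 1)
0b11  homozygous A2 (dosage 0)
====  =======================
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import MISSING, GenotypeDataset, VariantRecord

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# two-bit code -> dosage of A1
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
# dosage of A1 (with MISSING mapped to index 3) -> two-bit code
_DOSAGE_TO_CODE = {0: 0b11, 1: 0b10, 2: 0b00, MISSING: 0b01}


def _ext(prefix: Path, ext: str) -> Path:
    # Path.with_suffix would mangle prefixes containing dots
    return prefix.parent / f"{prefix.name}.{ext}"


class PlinkFormatError(ValueError):
    """Malformed PLINK binary input (bad magic bytes or mode)."""


class PlinkLengthError(ValueError):
    """.bed byte count inconsistent with .bim/.fam dimensions."""


def read_plink(prefix: str | Path) -> GenotypeDataset:
    """Read a .bed/.bim/.fam trio into a :class:`GenotypeDataset`."""
    prefix = Path(prefix)
    if _ext(prefix, "bim").stat().st_size == 0:
        bim = pd.DataFrame(columns=["chrom", "id", "cm", "pos", "a1", "a2"])
    else:
        bim = pd.read_csv(
            _ext(prefix, "bim"),
        sep=r"\s+",
        header=None,
            names=["chrom", "id", "cm", "pos", "a1", "a2"],
            dtype={"chrom": str, "id": str, "a1": str, "a2": str},
        )
    fam = pd.read_csv(
        _ext(prefix, "fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    variants = [
        VariantRecord(r.id, r.chrom, int(r.pos), r.a1, r.a2)
        for r in bim.itertuples()
    ]
    m, n = len(variants), len(fam)

    raw = _ext(prefix, "bed").read_bytes()
    if raw[:3] != _MAGIC:
        raise PlinkFormatError(
            f"{prefix}.bed: bad magic/mode bytes {raw[:3].hex()} "
            f"(expected {_MAGIC.hex()}, SNP-major PLINK-1)"
        )
    bytes_per_variant = math.ceil(n / 4) if n else 0
    expected = 3 + bytes_per_variant * m
    if len(raw) != expected:
        raise PlinkLengthError(
            f"{prefix}.bed: {len(raw)} bytes, expected {expected} "
            f"for {m} variants x {n} samples"
        )

    calls = np.empty((m, n), dtype=np.int8)
    if m and n:
        payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_variant)
        # unpack two-bit fields, sample index increasing from the LSB
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        codes = (payload[:, :, None] >> shifts[None, None, :]) & 0b11
        calls = _CODE_TO_DOSAGE[codes.reshape(m, -1)[:, :n]]
    return GenotypeDataset(variants=variants, samples=fam, calls=calls)


def write_plink(dataset: GenotypeDataset, prefix: str | Path) -> None:
    """Write ``dataset`` as a PLINK-1 trio; inverse of :func:`read_plink`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    m, n = dataset.n_variants, dataset.n_samples

    with open(_ext(prefix, "bim"), "w") as fh:
        for v in dataset.variants:
            fh.write(f"{v.chromosome}\t{v.id}\t0\t{v.position}\t{v.allele1}\t{v.allele2}\n")

    fam = dataset.samples
    with open(_ext(prefix, "fam"), "w") as fh:
        for _, r in fam.iterrows():
            sex = int(r["sex"]) if "sex" in fam.columns and pd.notna(r["sex"]) else 0
            phe = r["phenotype"] if "phenotype" in fam.columns and pd.notna(r.get("phenotype")) else -9
            father = r.get("father", 0) if pd.notna(r.get("father", 0)) else 0
            mother = r.get("mother", 0) if pd.notna(r.get("mother", 0)) else 0
            fh.write(f"{r['fid']}\t{r['iid']}\t{father}\t{mother}\t{sex}\t{phe}\n")

    bytes_per_variant = math.ceil(n / 4) if n else 0
    codes = np.empty((m, n), dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[dataset.calls == dosage] = code
    padded = np.zeros((m, bytes_per_variant * 4), dtype=np.uint8)
    if n:
        padded[:, :n] = codes
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (padded.reshape(m, bytes_per_variant, 4) << shifts[None, None, :]).sum(
        axis=2, dtype=np.uint8
    )
    with open(_ext(prefix, "bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())
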