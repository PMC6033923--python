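"""Core in-memory containers for genotype data.

Genotypes are hard calls stored as counts of ``allele1`` (the A1 column of a
PLINK .bim file) in ``{0, 1, 2}``, with :data:`MISSING` as the sentinel for a
missing call.  Coordinates are 1-based base-pair positions, as in .bim.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.  Distinct from any valid dosage;
#: every downstream operation must branch on it.
MISSING: int = -9

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Strand-ambiguous allele pairs (palindromic SNPs).
AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})


@dataclass(frozen=True)
class VariantRecord:
    """A single biallelic SNP."""

    id: str
    chromosome: str
    position: int
    allele1: str
    allele2: str
    frequency_allele1: float | None = None

    def __post_init__(self) -> None:
        if self.allele1 == self.allele2:
            raise ValueError(f"{self.id}: allele1 == allele2 ({self.allele1})")
        if self.position < 1:
            raise ValueError(f"{self.id}: position must be >= 1, got {self.position}")

    @property
    def is_ambiguous(self) -> bool:
        return (self.allele1, self.allele2) in AMBIGUOUS_PAIRS


@dataclass
class GenotypeDataset:
    """Variant-by-sample matrix of allele1 counts with metadata.

    Parameters
    ----------
    variants
        Ordered variant records; ids must be unique.
    samples
        DataFrame with at least columns ``fid``, ``iid`` (plus optional
        ``sex``, ``cohort``, ``phenotype``).  The working sample id is
        ``fid_iid``.
    calls
        int8 array of shape (n_variants, n_samples); entries in {0, 1, 2}
        or :data:`MISSING`.
    haplotypes
        Optional (2, n_variants, n_samples) 0/1 array retained by the
        simulator so related individuals can be constructed by haplotype
        transmission.  Never serialized.
    """

    variants: list[VariantRecord]
    samples: pd.DataFrame
    calls: np.ndarray
    haplotypes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        ids = self.variant_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids")
        sids = self.sample_ids
        if len(set(sids)) != len(sids):
            raise ValueError("duplicate sample ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0,1,2} or the missing sentinel")

    # -- basic views ------------------------------------------------------

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    @property
    def sample_ids(self) -> list[str]:
        return [f"{f}_{i}" for f, i in zip(self.samples["fid"], self.samples["iid"])]

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def allele1_frequency(self) -> np.ndarray:
        """In-sample frequency of allele1 from non-missing calls (nan if none)."""
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=1)
        counts = np.where(obs, self.calls, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, counts / (2.0 * n_obs), np.nan)

    def call_rate_variants(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=1)

    def call_rate_samples(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=0)

    # -- subsetting -------------------------------------------------------

    def subset_variants(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        hap = self.haplotypes[:, keep, :] if self.haplotypes is not None else None
        return GenotypeDataset(
            variants=[self.variants[i] for i in keep],
            samples=self.samples.reset_index(drop=True),
            calls=self.calls[keep, :],
            haplotypes=hap,
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        hap = self.haplotypes[:, :, keep] if self.haplotypes is not None else None
        return GenotypeDataset(
            variants=list(self.variants),
            samples=self.samples.iloc[keep].reset_index(drop=True),
            calls=self.calls[:, keep],
            haplotypes=hap,
        )

    def subset_samples_by_id(self, ids: list[str]) -> "GenotypeDataset":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        return self.subset_samples(np.array([index[s] for s in ids], dtype=int))

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            variants=list(self.variants),
            samples=self.samples.copy(),
            calls=self.calls.copy(),
            haplotypes=None if self.haplotypes is None else self.haplotypes.copy(),
        )

    def __eq__(self, other: object) -> bool:
        # allele frequency is derived metadata not carried by .bim, so it is
        # excluded from identity (round-trip through PLINK files must hold)
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        strip = [replace(v, frequency_allele1=None) for v in self.variants]
        ostrip = [replace(v, frequency_allele1=None) for v in other.variants]
        return (
            strip == ostrip
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.calls, other.calls)
        )
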