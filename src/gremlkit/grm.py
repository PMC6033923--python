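"""Genomic relationship matrix (GRM) construction and ancestry PCs.

The estimator is the standard allele-frequency-standardized form

    G_jk = (1/m_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

summed over variants ``i`` non-missing in both individuals, with ``m_jk``
the per-pair count of such variants.  With genotypes in Hardy–Weinberg
proportions the diagonal averages 1 and off-diagonals are ~N(0, 1/m) for
unrelated pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datasets import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class GRMatrix:
    """Symmetric relatedness matrix with per-pair variant counts."""

    values: np.ndarray          # (n, n) float
    n_snps_used: np.ndarray     # (n, n) int
    sample_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("GRM not symmetric")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def submatrix(self, ids: list[str]) -> "GRMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([index[s] for s in ids], dtype=int)
        return GRMatrix(
            values=self.values[np.ix_(idx, idx)].copy(),
            n_snps_used=self.n_snps_used[np.ix_(idx, idx)].copy(),
            sample_ids=list(ids),
        )

    def cross_block(self, a_ids: list[str], b_ids: list[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        ia = np.array([index[s] for s in a_ids], dtype=int)
        ib = np.array([index[s] for s in b_ids], dtype=int)
        return self.values[np.ix_(ia, ib)].copy()

    # -- serialization: GCTA-style text (lower triangle, ids, counts) ------

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        with open(f"{prefix}.grm.id", "w") as fh:
            for s in self.sample_ids:
                fid, _, iid = s.partition("_")
                fh.write(f"{fid}\t{iid or s}\n")
        with open(f"{prefix}.grm.txt", "w") as fh:
            for j in range(self.n):
                for k in range(j + 1):
                    fh.write(
                        f"{j + 1}\t{k + 1}\t{self.n_snps_used[j, k]}\t"
                        f"{self.values[j, k]:.10g}\n"
                    )

    @classmethod
    def load(cls, prefix: str | Path) -> "GRMatrix":
        prefix = Path(prefix)
        ids = []
        with open(f"{prefix}.grm.id") as fh:
            for line in fh:
                fid, iid = line.split()
                ids.append(f"{fid}_{iid}")
        n = len(ids)
        values = np.zeros((n, n))
        counts = np.zeros((n, n), dtype=int)
        with open(f"{prefix}.grm.txt") as fh:
            for line in fh:
                j, k, m, v = line.split()
                j, k = int(j) - 1, int(k) - 1
                values[j, k] = values[k, j] = float(v)
                counts[j, k] = counts[k, j] = int(m)
        return cls(values=values, n_snps_used=counts, sample_ids=ids)


def compute_grm(
    d: GenotypeDataset, frequencies: np.ndarray | None = None
) -> GRMatrix:
    """Build the GRM from hard-call genotypes.

    Allele frequencies are estimated in-sample from non-missing calls unless
    ``frequencies`` is supplied (used when two cohorts must share a single
    scaling, e.g. a combined-cohort GRM built against merged frequencies).
    Monomorphic variants carry no information and are skipped with a warning;
    missing genotypes are handled by pairwise-complete variant counts rather
    than imputation, which keeps the diagonal unbiased.
    """
    calls = d.calls
    p = d.allele1_frequency() if frequencies is None else np.asarray(frequencies, float)
    if p.shape != (d.n_variants,):
        raise ValueError("one frequency per variant required")

    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic variants")
    if (~poly).sum():
        logger.warning("%d monomorphic variants skipped in GRM", int((~poly).sum()))
    calls = calls[poly]
    p = p[poly]

    obs = calls != MISSING
    if not obs.any(axis=0).all():
        raise ValueError("sample with zero usable genotypes")
    scale = 1.0 / np.sqrt(2.0 * p * (1.0 - p))
    w = np.where(obs, (calls - 2.0 * p[:, None]) * scale[:, None], 0.0)
    numer = w.T @ w
    m_jk = obs.astype(np.float64).T @ obs.astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(m_jk > 0, numer / m_jk, 0.0)
    values = (values + values.T) / 2.0  # enforce exact symmetry
    return GRMatrix(
        values=values,
        n_snps_used=m_jk.astype(int),
        sample_ids=d.sample_ids,
    )


@dataclass
class PrincipalComponents:
    """Top-k eigenpairs of the (double-centered) GRM."""

    scores: np.ndarray       # (n, k), eigenvector * sqrt(eigenvalue)
    eigenvalues: np.ndarray  # (k,), non-increasing


def grm_pca(g: GRMatrix, k: int) -> PrincipalComponents:
    """Ancestry principal components from the GRM.

    The GRM is double-centered first (ancestry PCs conventionally derive
    from centered relatedness); scores are eigenvectors scaled by the square
    root of their eigenvalue, with the sign fixed so the largest-magnitude
    loading is positive.
    """
    n = g.n
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    centered = g.values - g.values.mean(axis=0) - g.values.mean(axis=1)[:, None] \
        + g.values.mean()
    centered = (centered + centered.T) / 2.0
    eigval, eigvec = np.linalg.eigh(centered)
    order = np.argsort(eigval)[::-1][:k]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    for j in range(k):
        lead = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[lead, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    scores = eigvec * np.sqrt(np.maximum(eigval, 0.0))
    return PrincipalComponents(scores=scores, eigenvalues=eigval)
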