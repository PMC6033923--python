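"""Genotype and sample quality control.

Implements the standard GWAS filtering battery: per-variant call rate, minor
allele frequency and Hardy–Weinberg equilibrium (exact test), per-sample call
rate, ancestry-outlier removal on principal components, and relatedness
pruning on the genomic relationship matrix (within and across cohorts).

Threshold direction follows the usual "exclude if < x" convention, so a
variant sitting exactly on a boundary is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datasets import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QcThresholds:
    """Filtering thresholds; defaults mirror a stringent case-control QC.

    ``hwe_p_min`` is the single-stratum threshold used for quantitative
    cohorts; for case-control data HWE is tested separately in controls
    (``hwe_p_min_controls``) and cases (``hwe_p_min_cases``), the case
    threshold being much more lenient because ascertainment itself distorts
    case genotype proportions.
    """

    variant_call_rate_min: float = 0.95
    maf_min: float = 0.01
    hwe_p_min: float = 1e-7
    hwe_p_min_controls: float = 1e-6
    hwe_p_min_cases: float = 1e-10
    sample_call_rate_min: float = 0.98
    relatedness_max: float = 0.05
    ancestry_sd_limit: float = 6.0

    def __post_init__(self) -> None:
        for name in ("variant_call_rate_min", "maf_min", "sample_call_rate_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.relatedness_max <= 0:
            raise ValueError("relatedness_max must be > 0")


@dataclass
class QcReport:
    """Ordered log of applied filters and per-criterion removal counts."""

    steps: list[dict] = field(default_factory=list)

    def add(self, step: str, removed: int, removed_ids: list[str], detail: str = "") -> None:
        self.steps.append(
            {"step": step, "removed": removed, "removed_ids": list(removed_ids),
             "detail": detail}
        )

    @property
    def total_removed(self) -> int:
        return sum(s["removed"] for s in self.steps)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"step": s["step"], "removed": s["removed"], "detail": s["detail"]}
             for s in self.steps]
        )


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

def _het_distribution(n_total: int, n_rare: int) -> np.ndarray:
    """Exact distribution of the heterozygote count.

    Probability of each heterozygote count consistent with ``n_rare`` copies
    of the rarer allele among ``n_total`` diploids, under random union of
    gametes.  Returned as a vector indexed by het count; entries with the
    wrong parity are zero.  Computed by the Wigginton recurrence from the
    distribution mode outward, then normalized.
    """
    probs = np.zeros(n_rare + 1)
    # mode of the het distribution, parity-corrected
    mid = int(round(n_rare * (2 * n_total - n_rare) / (2.0 * n_total)))
    if mid % 2 != n_rare % 2:
        mid += 1
    if mid > n_rare:
        mid -= 2
    probs[mid] = 1.0
    # downward: P(h-2)/P(h) = h(h-1) / (4 (hom_r+1)(hom_c+1))
    for h in range(mid, 1, -2):
        hom_r = (n_rare - h) // 2
        hom_c = n_total - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
    # upward: P(h+2)/P(h) = 4 hom_r hom_c / ((h+2)(h+1))
    for h in range(mid, n_rare - 1, 2):
        hom_r = (n_rare - h) // 2
        hom_c = n_total - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
    return probs / probs.sum()


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy–Weinberg p-value (Wigginton-style).

    Sums the probabilities of all heterozygote configurations no more likely
    than the observed one.  Symmetric under allele relabeling.  A monomorphic
    variant carries no information and returns 1 by convention.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n_total = n_hom1 + n_het + n_hom2
    if n_total == 0:
        raise ValueError("no genotyped individuals")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n_rare == 0 or n_rare == 2 * n_total:
        logger.debug("monomorphic variant: HWE p = 1 by convention")
        return 1.0
    probs = _het_distribution(n_total, n_rare)
    # tolerant tie comparison so exactly-tied configurations computed by a
    # different route are still counted together
    thresh = probs[n_het] * (1.0 + 1e-9)
    return float(min(1.0, probs[probs <= thresh].sum()))


def hwe_test_variants(d: GenotypeDataset, mask: np.ndarray | None = None) -> np.ndarray:
    """HWE exact p per variant, over the samples selected by ``mask``."""
    calls = d.calls if mask is None else d.calls[:, mask]
    p = np.empty(d.n_variants)
    for i in range(d.n_variants):
        row = calls[i]
        obs = row[row != MISSING]
        if obs.size == 0:
            p[i] = 1.0
            continue
        n2 = int((obs == 0).sum())
        n_het = int((obs == 1).sum())
        n1 = int((obs == 2).sum())
        p[i] = hwe_exact_test(n1, n_het, n2)
    return p


# ---------------------------------------------------------------------------
# Variant and sample filters
# ---------------------------------------------------------------------------

def filter_variants(
    d: GenotypeDataset,
    t: QcThresholds,
    case_status: np.ndarray | None = None,
) -> tuple[GenotypeDataset, QcReport]:
    """Apply the variant filters in order: call rate, MAF, HWE.

    ``case_status`` (0/1 per sample) switches HWE to the stratified
    case-control mode; otherwise the single-stratum threshold applies.
    Variants are excluded when strictly below a threshold, so boundary
    values survive.
    """
    if d.n_variants == 0:
        raise ValueError("empty dataset")
    report = QcReport()
    keep = np.ones(d.n_variants, dtype=bool)
    ids = np.array(d.variant_ids)

    cr = d.call_rate_variants()
    drop = keep & (cr < t.variant_call_rate_min)
    report.add("call_rate", int(drop.sum()), list(ids[drop]),
               f"call rate < {t.variant_call_rate_min}")
    keep &= ~drop

    freq = d.allele1_frequency()
    maf = np.minimum(freq, 1.0 - freq)
    drop = keep & (np.nan_to_num(maf, nan=0.0) < t.maf_min)
    report.add("maf", int(drop.sum()), list(ids[drop]), f"MAF < {t.maf_min}")
    keep &= ~drop

    if case_status is None:
        hwe_p = hwe_test_variants(d)
        drop = keep & (hwe_p < t.hwe_p_min)
        report.add("hwe", int(drop.sum()), list(ids[drop]), f"HWE p < {t.hwe_p_min}")
    else:
        case_status = np.asarray(case_status)
        p_ctrl = hwe_test_variants(d, case_status == 0)
        p_case = hwe_test_variants(d, case_status == 1)
        drop = keep & ((p_ctrl < t.hwe_p_min_controls) | (p_case < t.hwe_p_min_cases))
        report.add("hwe", int(drop.sum()), list(ids[drop]),
                   f"HWE p < {t.hwe_p_min_controls} (controls) or "
                   f"< {t.hwe_p_min_cases} (cases)")
    keep &= ~drop

    if not keep.any():
        logger.warning("no variants survive QC")
    return d.subset_variants(keep), report


def filter_variants_by_metric(
    d: GenotypeDataset, values: np.ndarray, min_value: float, name: str = "metric"
) -> tuple[GenotypeDataset, QcReport]:
    """Pass-through filter on a supplied per-variant quality column.

    Covers externally computed metrics (e.g. imputation INFO) that this
    package does not recompute: a variant is excluded when its value is
    strictly below ``min_value``.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (d.n_variants,):
        raise ValueError("one value per variant required")
    keep = ~(values < min_value)
    report = QcReport()
    ids = np.array(d.variant_ids)
    report.add(name, int((~keep).sum()), list(ids[~keep]), f"{name} < {min_value}")
    return d.subset_variants(keep), report


def filter_samples_by_call_rate(
    d: GenotypeDataset, min_rate: float
) -> tuple[GenotypeDataset, QcReport]:
    """Remove samples whose genotype call rate is strictly below ``min_rate``."""
    cr = d.call_rate_samples()
    keep = ~(cr < min_rate)
    report = QcReport()
    ids = np.array(d.sample_ids)
    report.add("sample_call_rate", int((~keep).sum()), list(ids[~keep]),
               f"sample call rate < {min_rate}")
    return d.subset_samples(keep), report


def ancestry_filter(
    pcs: np.ndarray,
    reference_mean: np.ndarray,
    reference_sd: np.ndarray,
    limit: float,
    sample_ids: list[str] | None = None,
) -> list:
    """Keep samples within ``limit`` reference SDs of the reference mean.

    Only the first two principal components are tested (the conventional
    ancestry-cluster criterion); the boundary is inclusive.
    """
    pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
    mean = np.asarray(reference_mean, dtype=float)
    sd = np.asarray(reference_sd, dtype=float)
    if pcs.shape[1] < 2:
        raise ValueError("need at least two principal components")
    if limit <= 0:
        raise ValueError("limit must be > 0")
    if np.any(sd[:2] == 0):
        raise ValueError("reference SD of zero on a tested component")
    dev = np.abs(pcs[:, :2] - mean[:2]) / sd[:2]
    keep = np.all(dev <= limit, axis=1)
    idx = np.flatnonzero(keep)
    if sample_ids is None:
        return list(idx)
    return [sample_ids[i] for i in idx]


def prune_related(grm, threshold: float, seed: int = 0) -> list[str]:
    """Greedy relatedness pruning of a genomic relationship matrix.

    Repeatedly removes the individual with the most partners above
    ``threshold``, breaking ties with a seeded uniform draw (pairs above the
    cut-off have one member "randomly removed").  Greedy degree-first removal
    approximately minimizes the number excluded.  The result is verified:
    no surviving off-diagonal exceeds the threshold.
    """
    values = np.array(grm.values, dtype=float, copy=True)
    ids = list(grm.sample_ids)
    n = values.shape[0]
    np.fill_diagonal(values, -np.inf)
    adj = values > threshold
    rng = np.random.default_rng(seed)
    alive = np.ones(n, dtype=bool)
    degree = adj.sum(axis=1).astype(float)
    while True:
        active = alive & (degree > 0)
        if not active.any():
            break
        maxdeg = degree[active].max()
        candidates = np.flatnonzero(alive & (degree == maxdeg))
        victim = int(rng.choice(candidates))
        alive[victim] = False
        degree[adj[victim] & alive] -= 1
        degree[victim] = 0
    kept = np.flatnonzero(alive)
    sub = grm.values[np.ix_(kept, kept)].copy()
    np.fill_diagonal(sub, 0.0)
    assert sub.size == 0 or sub.max() <= threshold, "pruning left a related pair"
    return [ids[i] for i in kept]


def cross_cohort_prune(
    grm_cross: np.ndarray, threshold: float, b_ids: list[str] | None = None
) -> list:
    """Drop cohort-B samples related above ``threshold`` to any cohort-A sample.

    ``grm_cross`` is the A-by-B block of a joint GRM; cohort A is left
    untouched by design (its composition anchors the analysis).
    """
    block = np.atleast_2d(np.asarray(grm_cross, dtype=float))
    keep = np.flatnonzero(~(block > threshold).any(axis=0))
    if b_ids is None:
        return list(keep)
    return [b_ids[i] for i in keep]
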