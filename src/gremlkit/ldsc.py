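"""LD scores and LD score regression (univariate h² and cross-trait rg).

For variant j the LD score is the sum of bias-adjusted squared correlations
with every variant within a physical window (self included):

    l_j = sum_k r2_adj(j,k),    r2_adj = r2 - (1 - r2) / (n - 2)

Univariate LDSC regresses per-variant association chi-square on
(n/m) * l_j; the slope estimates h² and the intercept (1 under no
confounding) absorbs population stratification.  Cross-trait LDSC regresses
z1_j * z2_j on sqrt(n1 n2)/m * l_j; the slope estimates the genetic
covariance and the intercept absorbs sample overlap.  When cohorts are
known to be disjoint the intercepts can be constrained (1 and 0
respectively), trading robustness for precision.  Standard errors come from
a delete-a-block jackknife over contiguous variant blocks.

Regression weights are 1/max(l_j, 1) — a deliberate simplification of the
full heteroskedasticity weighting, adequate for recovery-style validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_KB = 1000
DEFAULT_N_BLOCKS = 200


def compute_ld_scores(
    d: GenotypeDataset, window_kb: int = DEFAULT_WINDOW_KB
) -> pd.DataFrame:
    """Bias-adjusted LD scores from genotype data.

    Variants must be sorted by (chromosome, position); the window is
    ``window_kb`` kilobases either side.  Pairs with missing genotypes are
    handled pairwise-complete.  Returns a frame with columns
    (chromosome, id, position, l2) — the common ldscore file layout.
    """
    if window_kb <= 0:
        raise ValueError("window must be positive")
    chrom = np.array([v.chromosome for v in d.variants])
    pos = np.array([v.position for v in d.variants], dtype=float)
    for c in np.unique(chrom):
        pc = pos[chrom == c]
        if np.any(np.diff(pc) < 0):
            raise ValueError(f"variants on chromosome {c} not position-sorted")

    calls = np.where(d.calls == MISSING, np.nan, d.calls.astype(float))
    n = d.n_samples
    l2 = np.empty(d.n_variants)
    window_bp = window_kb * 1000.0
    complete = not np.isnan(calls).any()
    if complete:
        # fast path: standardize once, r via one matrix product per variant
        mu = calls.mean(axis=1, keepdims=True)
        sd = calls.std(axis=1, keepdims=True)
        mono = (sd == 0).ravel()
        sd[sd == 0] = 1.0
        zs = (calls - mu) / sd
        zs[mono] = np.nan  # monomorphic: correlation undefined, excluded
        for j in range(d.n_variants):
            in_win = (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= window_bp)
            idx = np.flatnonzero(in_win)
            r = zs[idx] @ zs[j] / n
            r2 = r * r
            if n > 2:
                r2 = r2 - (1.0 - r2) / (n - 2.0)
            valid = np.isfinite(r2)
            l2[j] = r2[valid].sum()
    else:
        for j in range(d.n_variants):
            in_win = (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= window_bp)
            idx = np.flatnonzero(in_win)
            xj = calls[j]
            total = 0.0
            for k in idx:
                r2 = _pairwise_r2(xj, calls[k])
                if np.isnan(r2):
                    continue
                n_eff = np.sum(~np.isnan(xj) & ~np.isnan(calls[k]))
                if n_eff > 2:
                    r2 = r2 - (1.0 - r2) / (n_eff - 2.0)
                total += r2
            l2[j] = total
    return pd.DataFrame(
        {"chromosome": chrom, "id": d.variant_ids, "position": pos.astype(int),
         "l2": l2}
    )


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        return np.nan
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy)
    return float(r * r)


def write_ld_scores(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def read_ld_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+")


@dataclass
class LdscFit:
    """Slope-derived quantity (h² or genetic covariance) from LDSC."""

    estimate: float                # h2 or genetic covariance
    se: float                      # block-jackknife SE
    intercept: float               # estimated, or the constrained value
    intercept_se: float | None     # None when constrained
    intercept_constrained: bool
    n_blocks: int


@dataclass
class LdscRg:
    """Cross-trait LDSC genetic correlation with jackknife SE."""

    rg: float
    se: float
    gcov: LdscFit
    h2_1: LdscFit
    h2_2: LdscFit


def _weighted_fit(
    yv: np.ndarray, xv: np.ndarray, w: np.ndarray, free_intercept: bool,
    offset: float,
) -> tuple[float, float]:
    """Weighted LS of (yv - offset) on xv; returns (slope, intercept)."""
    yy = yv - offset
    if free_intercept:
        Xd = np.column_stack([xv, np.ones_like(xv)])
        wX = Xd * w[:, None]
        coef = np.linalg.solve(Xd.T @ wX, wX.T @ yy)
        return float(coef[0]), float(coef[1]) + offset
    slope = float((w * xv * yy).sum() / (w * xv * xv).sum())
    return slope, offset


def _jackknife(values: np.ndarray) -> float:
    b = len(values)
    mean = values.mean()
    return float(np.sqrt((b - 1.0) / b * np.sum((values - mean) ** 2)))


def _block_bounds(m: int, n_blocks: int) -> list[np.ndarray]:
    n_blocks = max(2, min(n_blocks, m // 2))
    return np.array_split(np.arange(m), n_blocks)


def ldsc_h2(
    stats_df: pd.DataFrame,
    ld: pd.DataFrame,
    n: float,
    m: int | None = None,
    intercept: str = "free",
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> LdscFit:
    """Univariate LD score regression: chi2_j on (n/m) l_j.

    ``intercept`` is ``"free"`` or ``"constrained"`` (fixed at 1, the
    no-confounding value).  The slope estimates SNP-heritability.
    """
    merged = stats_df.merge(ld[["id", "l2"]], on="id")
    if m is None:
        m = len(merged)
    if m == 0 or len(merged) == 0:
        raise ValueError("no variants to regress")
    chi2 = merged["chi_square"].to_numpy(dtype=float)
    if np.isnan(chi2).any():
        chi2 = np.where(
            np.isnan(chi2),
            (merged["beta"] / merged["se"]).to_numpy(dtype=float) ** 2,
            chi2,
        )
    x = (n / m) * merged["l2"].to_numpy(dtype=float)
    w = 1.0 / np.maximum(merged["l2"].to_numpy(dtype=float), 1.0)
    free = intercept == "free"

    slope, icept = _weighted_fit(chi2, x, w, free, offset=1.0)
    blocks = _block_bounds(len(x), n_blocks)
    keep_masks = [np.ones(len(x), dtype=bool) for _ in blocks]
    deletes = np.empty((len(blocks), 2))
    for bi, idx in enumerate(blocks):
        mask = keep_masks[bi]
        mask[idx] = False
        s, ic = _weighted_fit(chi2[mask], x[mask], w[mask], free, offset=1.0)
        deletes[bi] = (s, ic)
    se = _jackknife(deletes[:, 0])
    icept_se = _jackknife(deletes[:, 1]) if free else None
    return LdscFit(
        estimate=slope, se=se, intercept=icept, intercept_se=icept_se,
        intercept_constrained=not free, n_blocks=len(blocks),
    )


def ldsc_rg(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    ld: pd.DataFrame,
    n1: float,
    n2: float,
    intercept: str = "free",
    univariate_intercept: str = "constrained",
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> LdscRg:
    """Cross-trait LD score regression on a shared (aligned) variant panel.

    Regresses z1_j z2_j on sqrt(n1 n2)/m * l_j.  ``intercept`` governs the
    cross-trait regression: ``"free"`` estimates the sample-overlap term,
    ``"constrained"`` fixes it at 0 (valid only for disjoint cohorts).  The
    univariate denominators are a separate choice (``univariate_intercept``,
    constrained to 1 by default; set ``"free"`` when confounding is
    suspected).  rg and its SE come from a joint delete-a-block jackknife
    over all three regressions, so the SE accounts for the correlated
    numerator and denominators.
    """
    merged = stats1.merge(stats2, on="id", suffixes=("_1", "_2")).merge(
        ld[["id", "l2"]], on="id"
    )
    m = len(merged)
    if m == 0:
        raise ValueError("no shared variants")
    z1 = (merged["beta_1"] / merged["se_1"]).to_numpy(dtype=float)
    z2 = (merged["beta_2"] / merged["se_2"]).to_numpy(dtype=float)
    l2 = merged["l2"].to_numpy(dtype=float)
    w = 1.0 / np.maximum(l2, 1.0)
    free = intercept == "free"
    uni_free = univariate_intercept == "free"

    x_cross = np.sqrt(n1 * n2) / m * l2
    x_1 = (n1 / m) * l2
    x_2 = (n2 / m) * l2
    zz = z1 * z2
    chi1, chi2_ = z1**2, z2**2

    def estimate(mask: np.ndarray) -> tuple[float, float, float, float, float]:
        gcov, ic = _weighted_fit(zz[mask], x_cross[mask], w[mask], free, offset=0.0)
        h1, _ = _weighted_fit(chi1[mask], x_1[mask], w[mask], uni_free, offset=1.0)
        h2, _ = _weighted_fit(chi2_[mask], x_2[mask], w[mask], uni_free, offset=1.0)
        denom = h1 * h2
        rg = gcov / np.sqrt(denom) if denom > 0 else np.nan
        return gcov, ic, h1, h2, rg

    full = np.ones(m, dtype=bool)
    gcov, icept, h1, h2, rg = estimate(full)
    if not (h1 > 0 and h2 > 0):
        raise ValueError(
            f"non-positive LDSC heritability (h2_1={h1:.3g}, h2_2={h2:.3g}); "
            "rg undefined"
        )

    blocks = _block_bounds(m, n_blocks)
    deletes = np.empty((len(blocks), 5))
    for bi, idx in enumerate(blocks):
        mask = full.copy()
        mask[idx] = False
        deletes[bi] = estimate(mask)
    ok = np.isfinite(deletes[:, 4])
    if ok.sum() < 2:
        raise ValueError("jackknife failed: denominators non-positive")
    rg_se = _jackknife(deletes[ok, 4])
    gcov_se = _jackknife(deletes[:, 0])
    icept_se = _jackknife(deletes[:, 1]) if free else None
    h1_se = _jackknife(deletes[:, 2])
    h2_se = _jackknife(deletes[:, 3])

    return LdscRg(
        rg=float(rg),
        se=rg_se,
        gcov=LdscFit(gcov, gcov_se, icept if free else 0.0, icept_se,
                     not free, len(blocks)),
        h2_1=LdscFit(h1, h1_se, np.nan, None, not free, len(blocks)),
        h2_2=LdscFit(h2, h2_se, np.nan, None, not free, len(blocks)),
    )
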