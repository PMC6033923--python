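"""Per-SNP association testing and weighted-allele profile scores.

The profile score (PRS-score) is the classic weighted allele-count sum: per
target individual, sum over scorable SNPs of the training-cohort effect size
times the dosage of the effect allele.  No p-value thresholding or LD
clumping is applied — every QC-surviving SNP contributes, matching the
dense-polygenic scoring strategy the downstream mixed-model analyses assume.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlleleAlignment
from .datasets import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


def gwas_linear(d: GenotypeDataset, y_adjusted: np.ndarray) -> pd.DataFrame:
    """Simple linear regression of an adjusted phenotype on each variant.

    ``y_adjusted`` should already be residualized on covariates (see
    :func:`gremlkit.greml.residualize`); each variant is tested with its own
    intercept, excluding samples missing that variant's call.  Returns the
    canonical summary-statistics frame (id, alleles, beta, se, p, n,
    chi_square); monomorphic variants get NaN effects and are flagged.
    """
    y = np.asarray(y_adjusted, dtype=float)
    if len(y) != d.n_samples:
        raise ValueError("phenotype length != sample count")
    calls = d.calls.astype(float)
    obs = d.calls != MISSING

    x = np.where(obs, calls, 0.0)
    n_i = obs.sum(axis=1).astype(float)
    sum_x = x.sum(axis=1)
    sum_x2 = (x * x).sum(axis=1)
    sum_y = (obs * y).sum(axis=1)
    sum_y2 = (obs * y**2).sum(axis=1)
    sum_xy = (x * y).sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        sxx = sum_x2 - sum_x**2 / n_i
        sxy = sum_xy - sum_x * sum_y / n_i
        syy = sum_y2 - sum_y**2 / n_i
        beta = sxy / sxx
        rss = syy - beta * sxy
        df = n_i - 2
        sigma2 = np.where(df > 0, rss / df, np.nan)
        se = np.sqrt(sigma2 / sxx)
    degenerate = (sxx <= 0) | (n_i < 3)
    if degenerate.any():
        logger.warning("%d variant(s) with zero dosage variance flagged",
                       int(degenerate.sum()))
    beta = np.where(degenerate, np.nan, beta)
    se = np.where(degenerate, np.nan, se)

    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), np.maximum(df, 1))
    # a perfect fit has se=0: report p=0 rather than NaN
    perfect = (~degenerate) & (se == 0)
    p = np.where(perfect, 0.0, p)
    # constant phenotype: no association by definition
    const_y = syy <= 0
    p = np.where(const_y & ~degenerate, 1.0, p)
    beta = np.where(const_y & ~degenerate, 0.0, beta)

    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(se > 0, (beta / se) ** 2, np.nan)
    return pd.DataFrame(
        {
            "id": d.variant_ids,
            "allele1": [v.allele1 for v in d.variants],
            "allele2": [v.allele2 for v in d.variants],
            "beta": beta,
            "se": se,
            "p": p,
            "n": n_i.astype(int),
            "chi_square": chi2,
        }
    )


def profile_score(
    target: GenotypeDataset,
    stats_df: pd.DataFrame,
    alignment: AlleleAlignment | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Weighted allele-count profile score per target individual.

    ``alignment`` maps the summary-statistic effect allele onto the target
    panel's allele1 (swap-classified variants score ``2 - dosage``); without
    it, variant ids are matched directly and effect alleles are assumed
    already oriented.  A missing genotype contributes the variant's mean
    dosage times its weight, keeping scores comparable across samples with
    unequal call rates.

    Returns a frame with raw score, standardized score (z-scored within the
    cohort; the conventional unit for downstream regression), number of SNPs
    scored and per-sample count of mean-imputed genotypes.
    """
    weights = dict(zip(stats_df["id"], stats_df["beta"]))
    t_index = {v.id: i for i, v in enumerate(target.variants)}

    rows, betas, flip = [], [], []
    for vid, beta in weights.items():
        if vid not in t_index or not np.isfinite(beta):
            continue
        if alignment is not None:
            action = alignment.actions.get(vid)
            if action is None or action.drops:
                continue
            flip.append(action.swaps)
        else:
            flip.append(False)
        rows.append(t_index[vid])
        betas.append(beta)
    if not rows:
        raise ValueError("no scorable variants shared between panel and weights")

    calls = target.calls[rows, :].astype(float)
    obs = target.calls[rows, :] != MISSING
    betas = np.asarray(betas, dtype=float)
    flip = np.asarray(flip, dtype=bool)
    calls = np.where(obs, np.where(flip[:, None], 2.0 - calls, calls), np.nan)

    mean_dosage = np.nanmean(np.where(obs, calls, np.nan), axis=1)
    mean_dosage = np.nan_to_num(mean_dosage, nan=0.0)
    filled = np.where(obs, calls, mean_dosage[:, None])
    score = betas @ filled
    n_imputed = (~obs).sum(axis=0)

    out = pd.DataFrame(
        {
            "sample_id": target.sample_ids,
            "score": score,
            "n_snps_scored": len(rows),
            "n_mean_imputed": n_imputed,
        }
    )
    if standardize:
        sd = score.std(ddof=0)
        if sd == 0:
            logger.warning("constant profile score; standardized score set to 0")
            out["score_std"] = 0.0
        else:
            out["score_std"] = (score - score.mean()) / sd
    return out
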