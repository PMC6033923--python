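"""Synthetic cohorts with the statistical structure the analyses assume.

Two cohorts are emulated at configurable scale:

* a case-control cohort for a binary disease under the liability-threshold
  model, with cases oversampled relative to the population prevalence, and
* an independent quantitative cohort of women measured for age at first
  birth (AFB), in which the genetic architecture *differs* between women
  who have their first child young versus old.

The heterogeneity device: three correlated effect-size vectors (disease
liability, younger-AFB architecture, older-AFB architecture) are drawn per
causal variant from a trivariate normal whose correlation matrix holds the
target genetic correlations.  Each woman is assigned to a stratum by a
latent propensity that is only weakly genetic, then her AFB is generated
from that stratum's own architecture — so stratum-specific effects, not
selection, drive the between-stratum genetic correlation below 1.
Truncation selection is a separate switch for robustness experiments.

Genotypes are drawn from a latent-Gaussian haplotype model: within blocks
of ``ld_block_size`` adjacent variants the latent variables follow an
AR(rho) process, giving realistic short-range LD; blocks are independent.
All operations are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import GenotypeDataset, VariantRecord
from .greml import PhenotypeBlock

logger = logging.getLogger(__name__)

#: base-pair spacing between simulated variants
_BP_SPACING = 5000

TRAITS = ("liability", "younger", "older")


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario parameters; defaults encode the default study conditions.

    Heritabilities are on the liability scale for the binary trait and the
    within-stratum phenotypic scale for AFB; genetic correlations follow the
    reciprocal pattern (negative with younger AFB, positive with older, and
    well below 1 between strata).
    """

    n_case: int = 1500
    n_control: int = 1500
    n_target: int = 5000
    m: int = 5000
    m_causal: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 20
    ld_rho: float = 0.7
    prevalence: float = 0.01
    h2_liability: float = 0.30
    h2_afb_younger: float = 0.10
    h2_afb_older: float = 0.03
    rg_liability_younger: float = -0.16
    rg_liability_older: float = 0.14
    rg_younger_older: float = 0.47
    afb_mean: float = 26.0
    afb_sd: float = 4.0
    cutpoint: float = 26.0
    younger_fraction: float = 0.55
    propensity_genetic_weight: float = 0.1
    truncation: tuple[float, float] | None = None
    relatedness_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("h2_liability", "h2_afb_younger", "h2_afb_older"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("rg_liability_younger", "rg_liability_older", "rg_younger_older"):
            v = getattr(self, name)
            if not -1 <= v <= 1:
                raise ValueError(f"{name} must be in [-1,1], got {v}")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0,1)")
        if self.m_causal > self.m:
            raise ValueError(f"m_causal ({self.m_causal}) exceeds m ({self.m})")
        R = self.rg_matrix()
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError(f"genetic correlation targets are not PSD:\n{R}")

    def rg_matrix(self) -> np.ndarray:
        r12, r13, r23 = (self.rg_liability_younger, self.rg_liability_older,
                         self.rg_younger_older)
        return np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])

    def h2_vector(self) -> np.ndarray:
        return np.array([self.h2_liability, self.h2_afb_younger, self.h2_afb_older])


@dataclass
class SimulatedTruth:
    """Ground truth retained for recovery tests."""

    causal_ids: list[str]
    effects: dict[str, np.ndarray]        # standardized-genotype scale, len m
    genetic_values: dict[str, np.ndarray]  # per retained sample, per trait
    frequencies: np.ndarray
    extra: dict = field(default_factory=dict)

    def realized_rg(self, t1: str, t2: str) -> float:
        b1, b2 = self.effects[t1], self.effects[t2]
        return float(b1 @ b2 / np.sqrt((b1 @ b1) * (b2 @ b2)))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def draw_frequencies(m: int, maf_range: tuple[float, float], seed: int) -> np.ndarray:
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"invalid maf_range {maf_range}")
    return np.random.default_rng(seed).uniform(lo, hi, size=m)


def _draw_haplotypes(
    rng: np.random.Generator,
    n_hap: int,
    frequencies: np.ndarray,
    ld_block_size: int,
    rho: float,
) -> np.ndarray:
    """(m, n_hap) 0/1 haplotypes; AR(rho) latent Gaussians within blocks."""
    m = len(frequencies)
    z = np.empty((m, n_hap))
    eps = rng.standard_normal((m, n_hap))
    block = max(1, ld_block_size)
    carry = np.sqrt(1.0 - rho**2)
    for i in range(m):
        if i % block == 0:
            z[i] = eps[i]
        else:
            z[i] = rho * z[i - 1] + carry * eps[i]
    thresh = stats.norm.ppf(frequencies)
    return (z < thresh[:, None]).astype(np.int8)


def simulate_genotypes(
    n: int,
    m: int | None = None,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block_size: int = 20,
    rho: float = 0.7,
    seed: int = 0,
    frequencies: np.ndarray | None = None,
    sample_prefix: str = "sim",
    store_haplotypes: bool = False,
) -> GenotypeDataset:
    """Simulate diploid genotypes for ``n`` individuals.

    Supply ``frequencies`` to draw additional cohorts from the same
    population panel (otherwise they are drawn uniform on ``maf_range``
    from the same seed, so the panel itself is reproducible).  Dosage is
    the count of allele1; variants are A/G with ids ``rs0..rs{m-1}`` at
    5 kb spacing on one chromosome.
    """
    if frequencies is None:
        if m is None:
            raise ValueError("either m or frequencies required")
        frequencies = draw_frequencies(m, maf_range, seed=seed * 2 + 1)
    frequencies = np.asarray(frequencies, dtype=float)
    m = len(frequencies)
    if m < 1:
        raise ValueError("need at least one variant")

    rng = np.random.default_rng(seed)
    h1 = _draw_haplotypes(rng, n, frequencies, ld_block_size, rho)
    h2 = _draw_haplotypes(rng, n, frequencies, ld_block_size, rho)
    calls = (h1 + h2).astype(np.int8)

    variants = [
        VariantRecord(
            id=f"rs{i}", chromosome="1", position=(i + 1) * _BP_SPACING,
            allele1="A", allele2="G", frequency_allele1=float(frequencies[i]),
        )
        for i in range(m)
    ]
    samples = pd.DataFrame(
        {
            "fid": [sample_prefix] * n,
            "iid": [f"{sample_prefix}{j}" for j in range(n)],
            "sex": np.zeros(n, dtype=int),
            "phenotype": [-9] * n,
        }
    )
    hap = np.stack([h1, h2]) if store_haplotypes else None
    return GenotypeDataset(variants=variants, samples=samples, calls=calls,
                           haplotypes=hap)


# ---------------------------------------------------------------------------
# Effects
# ---------------------------------------------------------------------------

def simulate_effects(
    config: SimulationConfig, seed: int | None = None
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Draw trivariate causal effects on the standardized-genotype scale.

    Returns (causal variant indices, {trait: length-m effect vector}).
    Per causal variant the three effects are jointly normal with covariance
    diag(sqrt(h2)) R diag(sqrt(h2)) / m_causal, so the expected genetic
    variance of each trait matches its h² target and the expected pairwise
    effect correlations match the rg targets.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sd = np.sqrt(config.h2_vector())
    C = np.outer(sd, sd) * config.rg_matrix() / config.m_causal
    causal = np.sort(rng.choice(config.m, size=config.m_causal, replace=False))
    # svd handles the singular cases (|rg| = 1 targets, zero-h2 traits)
    draws = rng.multivariate_normal(np.zeros(3), C, size=config.m_causal,
                                    method="svd")
    effects = {}
    for t, trait in enumerate(TRAITS):
        b = np.zeros(config.m)
        b[causal] = draws[:, t]
        effects[trait] = b
    return causal, effects


def genetic_values(
    d: GenotypeDataset, effects: dict[str, np.ndarray], frequencies: np.ndarray
) -> dict[str, np.ndarray]:
    """True genetic value per sample: effects on standardized genotypes."""
    p = np.asarray(frequencies, dtype=float)
    w = (d.calls - 2.0 * p[:, None]) / np.sqrt(2.0 * p * (1.0 - p))[:, None]
    return {t: b @ w for t, b in effects.items()}


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def simulate_case_control(
    config: SimulationConfig,
    effects: dict[str, np.ndarray],
    frequencies: np.ndarray,
    seed: int = 0,
    max_draw_factor: int = 6,
    batch_size: int = 4000,
) -> tuple[GenotypeDataset, PhenotypeBlock, SimulatedTruth]:
    """Ascertain a case-control cohort under the liability-threshold model.

    Population individuals are drawn in batches; liability is the genetic
    value plus a normal residual, and an individual is a case when liability
    exceeds Phi^-1(1 - K).  Sampling continues until the case and control
    quotas are filled (cases oversampled relative to K); exceeding
    ``max_draw_factor`` times the expected number of required draws raises.
    """
    K = config.prevalence
    threshold = stats.norm.isf(K)
    resid_sd = np.sqrt(max(1.0 - config.h2_liability, 0.0))
    need_cases, need_controls = config.n_case, config.n_control
    expected = need_cases / K + need_controls / (1 - K)
    max_draws = int(max_draw_factor * expected) + batch_size

    rng = np.random.default_rng(seed)
    kept_calls, kept_hap, kept_g, kept_y = [], [], [], []
    kept_other = {t: [] for t in TRAITS}
    drawn = 0
    b_liab = effects["liability"]
    scale = 1.0 / np.sqrt(2.0 * frequencies * (1.0 - frequencies))
    while need_cases > 0 or need_controls > 0:
        if drawn >= max_draws:
            raise RuntimeError(
                f"case/control quota unreachable within {max_draws} draws "
                f"(still need {need_cases} cases, {need_controls} controls)"
            )
        sub_seed = int(rng.integers(2**31 - 1))
        batch = simulate_genotypes(
            batch_size, frequencies=frequencies,
            ld_block_size=config.ld_block_size, rho=config.ld_rho,
            seed=sub_seed, store_haplotypes=True,
        )
        drawn += batch_size
        w = (batch.calls - 2.0 * frequencies[:, None]) * scale[:, None]
        g = b_liab @ w
        liab = g + resid_sd * rng.standard_normal(batch_size)
        is_case = liab > threshold
        take_case = np.flatnonzero(is_case)[:need_cases]
        take_ctrl = np.flatnonzero(~is_case)[:need_controls]
        take = np.concatenate([take_case, take_ctrl])
        if take.size:
            kept_calls.append(batch.calls[:, take])
            kept_hap.append(batch.haplotypes[:, :, take])
            kept_y.append(is_case[take].astype(float))
            for t in TRAITS:
                kept_other[t].append((effects[t] @ w)[take])
        need_cases -= take_case.size
        need_controls -= take_ctrl.size

    calls = np.concatenate(kept_calls, axis=1)
    hap = np.concatenate(kept_hap, axis=2)
    y = np.concatenate(kept_y)
    order = np.argsort(-y, kind="stable")  # cases first, stable within group
    calls, hap, y = calls[:, order], hap[:, :, order], y[order]
    g_all = {t: np.concatenate(kept_other[t])[order] for t in TRAITS}

    n = len(y)
    samples = pd.DataFrame(
        {"fid": ["cc"] * n, "iid": [f"cc{j}" for j in range(n)],
         "sex": np.zeros(n, dtype=int), "phenotype": (y + 1).astype(int)}
    )
    template = simulate_genotypes(1, frequencies=frequencies, seed=0)
    dataset = GenotypeDataset(variants=list(template.variants), samples=samples,
                              calls=calls, haplotypes=hap)
    block = PhenotypeBlock(trait="disease", sample_ids=dataset.sample_ids, y=y)
    truth = SimulatedTruth(
        causal_ids=[f"rs{i}" for i in np.flatnonzero(effects["liability"])],
        effects=effects,
        genetic_values=g_all,
        frequencies=frequencies,
        extra={"case_status": y.copy(), "prevalence": K},
    )
    return dataset, block, truth


def simulate_afb_cohort(
    config: SimulationConfig,
    effects: dict[str, np.ndarray],
    frequencies: np.ndarray,
    seed: int = 0,
) -> tuple[GenotypeDataset, pd.DataFrame, SimulatedTruth]:
    """Simulate the quantitative AFB cohort with stratum-specific architecture.

    Stage (i): a latent propensity — weakly genetic via
    ``propensity_genetic_weight`` on the averaged stratum genetic values —
    assigns each woman below/above the cut-point, hitting
    ``younger_fraction`` on average.  Stage (ii): within-stratum AFB is
    stratum mean plus that stratum's genetic value plus a residual scaled so
    the stratum h² matches its target; stratum means sit at
    ``afb_mean -/+ afb_sd`` with within-stratum SD ``afb_sd / 2``, keeping
    cross-over past the cut-point rare.  Optional truncation discards women
    whose AFB falls outside the configured interval.

    Returns the genotypes, a phenotype table (sample_id, afb, stratum) and
    the simulation truth.
    """
    if not (config.afb_mean - 2 * config.afb_sd < config.cutpoint
            < config.afb_mean + 2 * config.afb_sd):
        raise ValueError("cutpoint implausibly far from the AFB distribution")
    rng = np.random.default_rng(seed)
    d = simulate_genotypes(
        config.n_target, frequencies=frequencies,
        ld_block_size=config.ld_block_size, rho=config.ld_rho,
        seed=int(rng.integers(2**31 - 1)), sample_prefix="ukb",
        store_haplotypes=True,
    )
    g = genetic_values(d, effects, frequencies)

    w_g = config.propensity_genetic_weight
    g_avg = g["younger"] + g["older"]
    sd_avg = g_avg.std() or 1.0
    propensity = w_g * g_avg / sd_avg + np.sqrt(1 - w_g**2) * \
        rng.standard_normal(config.n_target)
    younger = propensity < stats.norm.ppf(config.younger_fraction)
    if younger.all() or not younger.any():
        raise ValueError("degenerate stratum assignment (empty stratum)")

    afb = np.empty(config.n_target)
    strata = np.where(younger, "younger", "older")
    sigma_within = config.afb_sd / 2.0
    for stratum, sel, sign in (("younger", younger, -1), ("older", ~younger, +1)):
        h2 = config.h2_afb_younger if stratum == "younger" else config.h2_afb_older
        gs = g[stratum][sel]
        resid = np.sqrt(max(1.0 - h2, 0.0)) * rng.standard_normal(sel.sum())
        score = gs + resid          # unit variance in expectation, h2 genetic
        mu = config.afb_mean + sign * config.afb_sd
        afb[sel] = mu + sigma_within * score

    table = pd.DataFrame(
        {"sample_id": d.sample_ids, "afb": afb, "stratum": strata}
    )
    truth = SimulatedTruth(
        causal_ids=[f"rs{i}" for i in np.flatnonzero(effects["younger"])],
        effects=effects,
        genetic_values=g,
        frequencies=frequencies,
        extra={"stratum": strata.copy(), "sigma_within": sigma_within},
    )
    if config.truncation is not None:
        lo, hi = config.truncation
        keep = (afb >= lo) & (afb <= hi)
        if not keep.any():
            raise ValueError("truncation interval removes every sample")
        d = d.subset_samples(keep)
        table = table.loc[keep].reset_index(drop=True)
        truth.genetic_values = {t: v[keep] for t, v in truth.genetic_values.items()}
        truth.extra["stratum"] = strata[keep]
        truth.extra["truncated"] = int((~keep).sum())
    return d, table, truth


def inject_relatedness(
    a: GenotypeDataset, b: GenotypeDataset, n_pairs: int, seed: int = 0
) -> tuple[GenotypeDataset, GenotypeDataset]:
    """Turn ``n_pairs`` cross-cohort pairs into parent-offspring relatives.

    The i-th selected b-sample becomes a child of the i-th selected
    a-sample: one haplotype transmitted whole from the parent, the other a
    population haplotype (borrowed from another b-sample).  Requires both
    datasets to carry haplotypes (as produced by the simulator).
    """
    if n_pairs == 0:
        return a, b
    if a.haplotypes is None or b.haplotypes is None:
        raise ValueError("both datasets must carry haplotypes")
    if n_pairs > min(a.n_samples, b.n_samples):
        raise ValueError("n_pairs exceeds cohort size")
    rng = np.random.default_rng(seed)
    a_idx = rng.choice(a.n_samples, size=n_pairs, replace=False)
    b_idx = rng.choice(b.n_samples, size=n_pairs, replace=False)
    b_new = b.copy()
    others = np.setdiff1d(np.arange(b.n_samples), b_idx)
    for pi, (ia, ib) in enumerate(zip(a_idx, b_idx)):
        transmitted = a.haplotypes[rng.integers(2), :, ia]
        donor = others[rng.integers(len(others))] if len(others) else ib
        population = b.haplotypes[rng.integers(2), :, donor]
        b_new.haplotypes[0, :, ib] = transmitted
        b_new.haplotypes[1, :, ib] = population
        b_new.calls[:, ib] = (transmitted + population).astype(np.int8)
    return a, b_new
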