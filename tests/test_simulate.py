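"""Synthetic-cohort generator: reproducibility, moments, ascertainment."""

from __future__ import annotations

import numpy as np
import pytest

from gremlkit.grm import compute_grm
from gremlkit.prs import gwas_linear
from gremlkit.qc import cross_cohort_prune
from gremlkit.simulate import (SimulationConfig, draw_frequencies,
                               genetic_values, inject_relatedness,
                               simulate_afb_cohort, simulate_case_control,
                               simulate_effects, simulate_genotypes)


def small_config(**kw):
    defaults = dict(n_case=60, n_control=60, n_target=150, m=120, m_causal=60,
                    prevalence=0.1, seed=5)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_fixed_seed_is_bit_reproducible():
    a = simulate_genotypes(40, m=80, seed=9)
    b = simulate_genotypes(40, m=80, seed=9)
    assert a == b
    cfg = small_config()
    freq = draw_frequencies(cfg.m, cfg.maf_range, 1)
    _, e1 = simulate_effects(cfg, seed=3)
    _, e2 = simulate_effects(cfg, seed=3)
    for t in e1:
        np.testing.assert_array_equal(e1[t], e2[t])
    d1, b1, _ = simulate_case_control(cfg, e1, freq, seed=7)
    d2, b2, _ = simulate_case_control(cfg, e1, freq, seed=7)
    assert d1 == d2
    np.testing.assert_array_equal(b1.y, b2.y)


def test_maf_half_gives_mean_dosage_one():
    d = simulate_genotypes(800, m=60, maf_range=(0.5, 0.5), seed=2)
    # binomial(2, 0.5) mean 1; wide band because within-block LD correlates draws
    assert d.calls.mean() == pytest.approx(1.0, abs=0.03)


def test_block_ld_structure():
    d = simulate_genotypes(1500, m=60, ld_block_size=10, rho=0.8, seed=3)
    calls = d.calls.astype(float)
    within = np.corrcoef(calls[0], calls[1])[0, 1] ** 2
    across = np.corrcoef(calls[9], calls[10])[0, 1] ** 2  # block boundary
    assert within > 0.2
    assert across < 0.05


def test_invalid_maf_range_rejected():
    with pytest.raises(ValueError):
        simulate_genotypes(10, m=5, maf_range=(0.0, 0.5), seed=0)


def test_effects_proportional_when_rg_one():
    cfg = small_config(rg_liability_younger=1.0, rg_liability_older=1.0,
                       rg_younger_older=1.0, h2_liability=0.4,
                       h2_afb_younger=0.1, h2_afb_older=0.2)
    causal, eff = simulate_effects(cfg, seed=1)
    b1, b2 = eff["liability"][causal], eff["younger"][causal]
    assert abs(np.corrcoef(b1, b2)[0, 1]) == pytest.approx(1.0, abs=1e-10)


def test_effect_correlations_match_targets():
    cfg = SimulationConfig(n_case=10, n_control=10, n_target=10, m=6000,
                           m_causal=5000, h2_liability=0.3, h2_afb_younger=0.1,
                           h2_afb_older=0.3, seed=2)
    causal, eff = simulate_effects(cfg, seed=8)
    se = 1.0 / np.sqrt(5000)
    r = np.corrcoef(eff["liability"][causal], eff["younger"][causal])[0, 1]
    assert r == pytest.approx(cfg.rg_liability_younger, abs=3 * se)
    r = np.corrcoef(eff["younger"][causal], eff["older"][causal])[0, 1]
    assert r == pytest.approx(cfg.rg_younger_older, abs=3 * se)


def test_zero_rg_targets_give_uncorrelated_effects():
    cfg = SimulationConfig(n_case=10, n_control=10, n_target=10, m=6000,
                           m_causal=5000, rg_liability_younger=0.0,
                           rg_liability_older=0.0, rg_younger_older=0.0, seed=3)
    causal, eff = simulate_effects(cfg, seed=9)
    se = 1.0 / np.sqrt(5000)
    for a, b in (("liability", "younger"), ("liability", "older"),
                 ("younger", "older")):
        r = np.corrcoef(eff[a][causal], eff[b][causal])[0, 1]
        assert abs(r) < 3 * se


def test_realized_h2_matches_target():
    cfg = SimulationConfig(n_case=10, n_control=10, n_target=2000, m=800,
                           m_causal=800, h2_afb_younger=0.5, seed=4)
    freq = draw_frequencies(cfg.m, cfg.maf_range, 44)
    _, eff = simulate_effects(cfg, seed=10)
    d = simulate_genotypes(2000, frequencies=freq, seed=11)
    g = genetic_values(d, eff, freq)["younger"]
    # genetic variance should be close to the 0.5 target (phenotypic var 1)
    assert g.var() == pytest.approx(0.5, rel=0.2)


def test_non_psd_rg_targets_rejected():
    with pytest.raises(ValueError, match="PSD"):
        SimulationConfig(rg_liability_younger=0.9, rg_liability_older=0.9,
                         rg_younger_older=-0.9)


def test_case_control_quota_exact():
    cfg = small_config(n_case=45, n_control=80)
    freq = draw_frequencies(cfg.m, cfg.maf_range, 1)
    _, eff = simulate_effects(cfg, seed=3)
    d, block, truth = simulate_case_control(cfg, eff, freq, seed=12)
    assert int(block.y.sum()) == 45
    assert len(block.y) == 125
    assert d.n_samples == 125


def test_case_control_quota_unreachable_raises():
    cfg = small_config(prevalence=0.001, n_case=500)
    freq = draw_frequencies(cfg.m, cfg.maf_range, 1)
    _, eff = simulate_effects(cfg, seed=3)
    with pytest.raises(RuntimeError, match="quota"):
        simulate_case_control(cfg, eff, freq, seed=1, max_draw_factor=0,
                              batch_size=200)


def test_null_genetics_case_status_independent_of_genotype():
    """K = 0.5 and h2 = 0: GWAS on case status is calibrated."""
    cfg = small_config(prevalence=0.5, h2_liability=0.0, n_case=150,
                       n_control=150, m=200, m_causal=100)
    freq = draw_frequencies(cfg.m, cfg.maf_range, 1)
    _, eff = simulate_effects(cfg, seed=3)
    d, block, _ = simulate_case_control(cfg, eff, freq, seed=21)
    stats = gwas_linear(d, block.y - block.y.mean())
    p = stats["p"].dropna()
    # uniform p-values: fraction below 0.05 in a 3-SE binomial band
    frac = (p < 0.05).mean()
    assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(p))


def test_afb_cohort_strata_and_truncation():
    cfg = small_config(n_target=400)
    freq = draw_frequencies(cfg.m, cfg.maf_range, 1)
    _, eff = simulate_effects(cfg, seed=3)
    d, table, truth = simulate_afb_cohort(cfg, eff, freq, seed=5)
    assert d.n_samples == 400
    assert set(table["stratum"]) == {"younger", "older"}
    frac_younger = (table["stratum"] == "younger").mean()
    assert abs(frac_younger - cfg.younger_fraction) < 0.1
    # stratum means separated around the cut-point
    assert table.loc[table.stratum == "younger", "afb"].mean() < cfg.cutpoint
    assert table.loc[table.stratum == "older", "afb"].mean() > cfg.cutpoint

    cfg_t = small_config(n_target=400, truncation=(26.0, np.inf))
    d_t, table_t, truth_t = simulate_afb_cohort(cfg_t, eff, freq, seed=5)
    assert (table_t["afb"] >= 26.0).all()
    assert d_t.n_samples == len(table_t)


def test_relatedness_injection():
    # panel dense enough that GRM noise (sd ~ 1/sqrt(m)) sits well below
    # the 0.05 relatedness threshold, as in a genome-wide panel
    m = 3000
    a = simulate_genotypes(50, m=m, seed=31, store_haplotypes=True,
                           sample_prefix="a")
    b = simulate_genotypes(60, m=m, seed=32, store_haplotypes=True,
                           sample_prefix="b",
                           frequencies=np.array([v.frequency_allele1
                                                 for v in a.variants]))
    a0, b0 = inject_relatedness(a, b, 0, seed=1)
    np.testing.assert_array_equal(b0.calls, b.calls)

    a1, b1 = inject_relatedness(a, b, 5, seed=1)
    from gremlkit.align import align_alleles, merge_datasets
    merged = merge_datasets(a1, b1, align_alleles(a1.variants, b1.variants))
    grm = compute_grm(merged)
    cross = grm.values[:50, 50:]
    top = np.sort(cross.ravel())[::-1][:5]
    # parent-offspring pairs show ~0.5 relatedness (3-SE band)
    assert (top > 0.5 - 3 * np.sqrt(0.5 / m) - 0.05).all()
    # and cross-cohort pruning at 0.05 breaks every injected pair
    kept = cross_cohort_prune(cross, 0.05, b_ids=b1.sample_ids)
    injected = {b1.sample_ids[j] for j in np.argsort(cross.max(axis=0))[-5:]}
    assert injected.isdisjoint(kept)
    assert len(kept) >= 40


def test_relatedness_requires_haplotypes():
    a = simulate_genotypes(5, m=10, seed=0)
    b = simulate_genotypes(5, m=10, seed=1)
    with pytest.raises(ValueError, match="haplotypes"):
        inject_relatedness(a, b, 1, seed=0)
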