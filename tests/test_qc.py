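"""QC filters: HWE exact test vs enumeration, thresholds, pruning."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import gammaln

from gremlkit.datasets import MISSING
from gremlkit.grm import GRMatrix
from gremlkit.qc import (QcThresholds, ancestry_filter, cross_cohort_prune,
                         filter_samples_by_call_rate, filter_variants,
                         filter_variants_by_metric, hwe_exact_test,
                         prune_related)

from conftest import make_dataset


# ---------------------------------------------------------------------------
# HWE oracle: direct log-factorial enumeration over heterozygote counts,
# independent of the recurrence used by the implementation
# ---------------------------------------------------------------------------

def _lfact(x):
    return gammaln(np.asarray(x, dtype=float) + 1.0)


def hwe_oracle(n_hom1: int, n_het: int, n_hom2: int) -> float:
    n = n_hom1 + n_het + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    valid = hom_c >= 0
    hets, hom_r, hom_c = hets[valid], hom_r[valid], hom_c[valid]
    logp = (
        _lfact(n) - _lfact(hom_r) - _lfact(hets) - _lfact(hom_c)
        + hets * np.log(2.0)
        + _lfact(n_rare) + _lfact(2 * n - n_rare) - _lfact(2 * n)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= obs * (1.0 + 1e-9)].sum()))


@pytest.mark.parametrize("counts", [
    (1, 0, 0),
    (0, 2, 0),
    (57, 14, 50),
    (10, 21, 10),
    (0, 1, 0),
    (3, 0, 3),
])
def test_hwe_matches_enumeration_oracle(counts):
    assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), abs=1e-12)


def test_hwe_two_diploids_full_enumeration():
    # 2 A and 2 a alleles in 2 diploids: configurations are het=0 (prob 1/3)
    # and het=2 (prob 2/3); observing het=2 gives p = 1
    assert hwe_exact_test(0, 2, 0) == pytest.approx(1.0, abs=1e-12)
    assert hwe_exact_test(1, 0, 1) == pytest.approx(1.0 / 3.0, abs=1e-12)


def test_hwe_symmetric_under_allele_relabeling():
    for a, h, b in [(5, 9, 2), (12, 3, 1), (0, 4, 8)]:
        assert hwe_exact_test(a, h, b) == pytest.approx(
            hwe_exact_test(b, h, a), abs=1e-14)


def test_hwe_monomorphic_returns_one():
    assert hwe_exact_test(7, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 5) == 1.0


def test_hwe_invalid_input():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 0, 1)
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


def test_hwe_exhaustive_small_totals():
    """Every configuration with <= 25 diploids agrees with the oracle."""
    for n in range(1, 26):
        for hom1 in range(n + 1):
            for het in range(n - hom1 + 1):
                hom2 = n - hom1 - het
                assert hwe_exact_test(hom1, het, hom2) == pytest.approx(
                    hwe_oracle(hom1, het, hom2), abs=1e-12), (hom1, het, hom2)


# ---------------------------------------------------------------------------
# Variant / sample filters
# ---------------------------------------------------------------------------

def test_call_rate_threshold_is_strict():
    d = make_dataset(1, 100, seed=0)
    d.calls[0, :6] = MISSING        # 94% call rate
    t = QcThresholds(variant_call_rate_min=0.95, maf_min=0.0, hwe_p_min=0.0)
    out, report = filter_variants(d, t)
    assert out.n_variants == 0
    assert report.steps[0]["step"] == "call_rate"
    assert report.steps[0]["removed"] == 1

    d.calls[0, :] = 1
    d.calls[0, :5] = MISSING        # exactly 95%: kept
    out, _ = filter_variants(d, t)
    assert out.n_variants == 1


def test_maf_boundary_kept():
    # exactly MAF 0.01 must survive a "MAF < 0.01 excluded" rule
    d = make_dataset(1, 100, seed=0)
    d.calls[0, :] = 0
    d.calls[0, 0] = 2               # frequency 0.01 exactly
    t = QcThresholds(variant_call_rate_min=0.0, maf_min=0.01, hwe_p_min=0.0)
    out, _ = filter_variants(d, t)
    assert out.n_variants == 1
    d.calls[0, 0] = 1               # frequency 0.005: removed
    out, report = filter_variants(d, t)
    assert out.n_variants == 0
    assert report.steps[1]["step"] == "maf"


def test_filter_survivors_match_per_variant_oracle():
    d = make_dataset(100, 80, seed=21, missing_rate=0.08)
    t = QcThresholds(variant_call_rate_min=0.95, maf_min=0.05, hwe_p_min=0.05)
    out, report = filter_variants(d, t)
    survivors = []
    for i in range(d.n_variants):
        row = d.calls[i]
        obs = row[row != MISSING]
        cr = len(obs) / d.n_samples
        freq = obs.sum() / (2 * len(obs)) if len(obs) else 0.0
        maf = min(freq, 1 - freq)
        hwe = hwe_oracle(int((obs == 2).sum()), int((obs == 1).sum()),
                         int((obs == 0).sum())) if len(obs) else 1.0
        if cr >= 0.95 and maf >= 0.05 and hwe >= 0.05:
            survivors.append(d.variants[i].id)
    assert out.variant_ids == survivors
    assert report.total_removed == d.n_variants - out.n_variants


def test_filters_are_idempotent():
    d = make_dataset(60, 50, seed=5, missing_rate=0.1)
    t = QcThresholds(variant_call_rate_min=0.92, maf_min=0.05, hwe_p_min=0.01)
    once, _ = filter_variants(d, t)
    twice, rep = filter_variants(once, t)
    assert twice.variant_ids == once.variant_ids
    assert rep.total_removed == 0
    s_once, _ = filter_samples_by_call_rate(d, 0.9)
    s_twice, rep2 = filter_samples_by_call_rate(s_once, 0.9)
    assert s_twice.sample_ids == s_once.sample_ids
    assert rep2.total_removed == 0


def test_case_control_hwe_uses_stratified_thresholds():
    d = make_dataset(1, 60, seed=0)
    status = np.array([0] * 30 + [1] * 30)
    # controls wildly out of HWE (all het), cases in HWE
    d.calls[0, :30] = 1
    d.calls[0, 30:] = np.random.default_rng(0).binomial(2, 0.5, 30)
    t = QcThresholds(variant_call_rate_min=0.0, maf_min=0.0)
    out, report = filter_variants(d, t, case_status=status)
    assert out.n_variants == 0          # controls fail 1e-6
    out, _ = filter_variants(d, t, case_status=1 - status)
    assert out.n_variants == 1          # as cases, threshold 1e-10 tolerates it


def test_sample_call_rate_filter():
    d = make_dataset(20, 10, seed=2)
    d.calls[:, 3] = MISSING             # all-missing sample removed
    out, report = filter_samples_by_call_rate(d, 0.98)
    assert d.sample_ids[3] in report.steps[0]["removed_ids"]
    assert out.n_samples == 9
    # per-sample oracle on a mixed fixture
    d2 = make_dataset(40, 15, seed=3, missing_rate=0.05)
    out2, _ = filter_samples_by_call_rate(d2, 0.95)
    expected = [s for j, s in enumerate(d2.sample_ids)
                if (d2.calls[:, j] != MISSING).mean() >= 0.95]
    assert out2.sample_ids == expected


def test_metric_passthrough_filter():
    d = make_dataset(5, 4, seed=0)
    info = np.array([0.9, 0.5, 0.61, 0.59, 0.6])
    out, report = filter_variants_by_metric(d, info, 0.6, name="info")
    assert out.variant_ids == ["rs0", "rs2", "rs4"]
    assert report.steps[0]["step"] == "info"


# ---------------------------------------------------------------------------
# Ancestry and relatedness
# ---------------------------------------------------------------------------

def test_ancestry_filter_boundaries():
    mean = np.zeros(2)
    sd = np.ones(2)
    pcs = np.array([
        [0.0, 0.0],     # at the mean: kept
        [7.0, 0.0],     # 7 SD on PC1: removed
        [6.0, -6.0],    # exactly 6 SD: kept (inclusive)
        [0.0, 6.0001],  # just outside: removed
    ])
    kept = ancestry_filter(pcs, mean, sd, limit=6.0)
    assert kept == [0, 2]


def test_ancestry_filter_zero_sd_rejected():
    with pytest.raises(ValueError, match="SD"):
        ancestry_filter(np.zeros((3, 2)), np.zeros(2), np.array([0.0, 1.0]), 6.0)


def _grm_from(values):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return GRMatrix(values=values, n_snps_used=np.full((n, n), 100),
                    sample_ids=[f"s{i}" for i in range(n)])


def test_prune_related_no_pairs_all_kept():
    g = _grm_from(np.eye(4) + 0.01)
    assert prune_related(g, 0.05, seed=0) == g.sample_ids


def test_prune_related_single_pair_removes_one():
    v = np.eye(3)
    v[0, 1] = v[1, 0] = 0.5
    kept = prune_related(_grm_from(v), 0.05, seed=0)
    assert len(kept) == 2
    assert "s2" in kept


def test_prune_related_chain_removes_middle():
    # A-B and B-C related, A-C not: removing B alone is the minimum cover
    v = np.eye(3)
    v[0, 1] = v[1, 0] = 0.3
    v[1, 2] = v[2, 1] = 0.3
    kept = prune_related(_grm_from(v), 0.05, seed=0)
    assert kept == ["s0", "s2"]


def test_prune_related_deterministic_given_seed():
    rng = np.random.default_rng(8)
    v = rng.uniform(0, 0.1, (12, 12))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    g = _grm_from(v)
    assert prune_related(g, 0.05, seed=3) == prune_related(g, 0.05, seed=3)


def test_prune_related_postcondition_verified():
    rng = np.random.default_rng(19)
    v = rng.uniform(0, 0.12, (25, 25))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    g = _grm_from(v)
    kept = prune_related(g, 0.05, seed=1)
    idx = [g.sample_ids.index(s) for s in kept]
    sub = v[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, 0.0)
    assert sub.max() <= 0.05


def test_cross_cohort_prune():
    block = np.zeros((3, 4))
    assert cross_cohort_prune(block, 0.05) == [0, 1, 2, 3]
    block[1, 2] = 0.3
    assert cross_cohort_prune(block, 0.05, b_ids=list("wxyz")) == ["w", "x", "z"]
    # row-max oracle on a seeded fixture
    rng = np.random.default_rng(4)
    block = rng.uniform(0, 0.1, (10, 20))
    kept = cross_cohort_prune(block, 0.05)
    assert kept == [j for j in range(20) if block[:, j].max() <= 0.05]
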